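"""Per-nucleus classification and per-section morphological parameters.

A nucleus is *internalized* when its centre lies deeper than one nucleus
length from the reconstructed egg shell and, independently, *ingressed* when
deeper than one nucleus length from the apical epithelial surface.  Each
transversal ROI section is then summarized by five parameters: percent
internalization, epithelial integrity, furrow depth, maximal cell depth
(both in nuclear diameters) and furrow width (% of embryo width), plus a
mitosis count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ParameterError
from .geometry import SurfaceMesh, points_mesh_distance
from .segment import NucleusRecord, centroid_array

__all__ = [
    "SectionMetrics",
    "Centerline",
    "classify_nuclei",
    "section_metrics",
    "furrow_width",
    "centerline",
    "measure_gbe",
    "proxy_deviation",
]


@dataclass
class SectionMetrics:
    """Morphological parameters of one transversal slab.

    ``internalization`` and ``integrity`` in percent; ``furrow_depth`` and
    ``max_cell_depth`` in nuclear diameters; ``furrow_width`` in percent of
    embryo width.  ``integrity`` is NaN when the slab has no internalized
    nucleus under the ``internalized_only`` variant (the ``all_cells``
    variant must be used for no-internalization phenotypes).
    """

    embryo_id: str
    section_index: int
    internalization: float
    max_cell_depth: float
    integrity: float
    integrity_variant: str
    furrow_depth: float
    furrow_width: float
    mitosis_count: int
    n_nuclei: int

    def __post_init__(self) -> None:
        if self.integrity_variant not in ("internalized_only", "all_cells"):
            raise ParameterError(f"unknown integrity variant {self.integrity_variant!r}")


@dataclass
class Centerline:
    """Ordered transversal path through the nuclei of one section."""

    section_index: int
    nucleus_ids: list
    vertices: np.ndarray  # (k, 3) um polyline, including the two edge anchors
    total_length: float


def classify_nuclei(
    records,
    shell_mesh: SurfaceMesh,
    apical_epithelium_mesh: SurfaceMesh,
    nucleus_diameter: float,
):
    """Fill ``d_shell``, ``d_epi`` and the internalized/ingressed flags.

    Both thresholds are one nucleus length; distances are stored in um.
    """
    if shell_mesh is None or apical_epithelium_mesh is None:
        raise AnalysisError("both reference meshes are required for classification")
    if nucleus_diameter <= 0:
        raise ParameterError("nucleus_diameter must be positive")
    if len(records) == 0:
        return records
    pts = centroid_array(records)
    d_shell = points_mesh_distance(pts, shell_mesh)
    d_epi = points_mesh_distance(pts, apical_epithelium_mesh)
    for rec, ds, de in zip(records, d_shell, d_epi):
        rec.d_shell = float(ds)
        rec.d_epi = float(de)
        rec.internalized = bool(ds > nucleus_diameter)
        rec.ingressed = bool(de > nucleus_diameter)
    return records


def furrow_width(slab_records, embryo_width: float, nucleus_diameter: float) -> float:
    """Furrow width as percent of embryo width.

    The furrow is delimited by its abutting nuclei: the ML span of the
    centroids of internalized, non-ingressed nuclei plus one nucleus
    diameter (edge to edge).  0 when the slab holds no furrow nucleus.
    """
    if embryo_width <= 0:
        raise ValueError("embryo_width must be positive")
    furrow = [r for r in slab_records if r.internalized and not r.ingressed]
    if not furrow:
        return 0.0
    ml = np.array([r.centroid[1] for r in furrow])
    return float(100.0 * (ml.max() - ml.min() + nucleus_diameter) / embryo_width)


def section_metrics(
    slab_records,
    embryo_id: str,
    section_index: int,
    nucleus_diameter: float,
    embryo_width: float,
    integrity_variant: str = "internalized_only",
) -> SectionMetrics:
    """Summarize one classified transversal slab.

    internalization = 100 * #internalized / #slab nuclei;
    max_cell_depth = max d_shell over ALL slab nuclei (nuclear diameters);
    furrow_depth = max d_shell over internalized AND non-ingressed
    (epithelium) nuclei, 0 if none; integrity (internalized_only) = 100 *
    #(internalized and not ingressed) / #internalized, NaN when no nucleus is
    internalized; integrity (all_cells) = 100 * #(not ingressed) / #slab.
    """
    recs = list(slab_records)
    n = len(recs)
    if n == 0:
        raise AnalysisError(f"section {section_index} of {embryo_id} holds no nuclei")
    if any(r.internalized is None or r.d_shell is None for r in recs):
        raise AnalysisError("records must be classified before section_metrics")
    internal = [r for r in recs if r.internalized]
    epithelial = [r for r in internal if not r.ingressed]
    d = nucleus_diameter
    max_depth = max(r.d_shell for r in recs) / d
    f_depth = max((r.d_shell for r in epithelial), default=0.0) / d
    if integrity_variant == "internalized_only":
        integrity = (
            100.0 * len(epithelial) / len(internal) if internal else float("nan")
        )
    elif integrity_variant == "all_cells":
        integrity = 100.0 * sum(1 for r in recs if not r.ingressed) / n
    else:
        raise ParameterError(f"unknown integrity variant {integrity_variant!r}")
    return SectionMetrics(
        embryo_id=embryo_id,
        section_index=section_index,
        internalization=100.0 * len(internal) / n,
        max_cell_depth=max_depth,
        integrity=integrity,
        integrity_variant=integrity_variant,
        furrow_depth=f_depth,
        furrow_width=furrow_width(recs, embryo_width, d),
        mitosis_count=sum(1 for r in recs if r.mitotic),
        n_nuclei=n,
    )


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

def _path_length(points: np.ndarray, order) -> float:
    p = points[list(order)]
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def _exact_open_path(points: np.ndarray) -> list:
    """Shortest Hamiltonian path from point 0 to point -1 (Held-Karp DP)."""
    n = len(points)
    inner = list(range(1, n - 1))
    m = len(inner)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    if m == 0:
        return list(range(n))
    # dp[mask][j] = best cost reaching inner node j having visited mask
    best = {}
    for j in range(m):
        best[(1 << j, j)] = (dist[0, inner[j]], -1)
    for mask in range(1, 1 << m):
        for j in range(m):
            if not mask & (1 << j) or (mask, j) not in best:
                continue
            cost_j = best[(mask, j)][0]
            for k in range(m):
                if mask & (1 << k):
                    continue
                nm = mask | (1 << k)
                cand = cost_j + dist[inner[j], inner[k]]
                if (nm, k) not in best or cand < best[(nm, k)][0]:
                    best[(nm, k)] = (cand, j)
    full = (1 << m) - 1
    end_costs = [
        (best[(full, j)][0] + dist[inner[j], n - 1], j) for j in range(m)
    ]
    _, j = min(end_costs)
    order = [n - 1]
    mask = full
    while j >= 0:
        order.append(inner[j])
        _, prev = best[(mask, j)]
        mask ^= 1 << j
        j = prev
    order.append(0)
    return order[::-1]


def _two_opt_path(points: np.ndarray) -> list:
    """Greedy nearest-neighbour construction refined by 2-opt."""
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    left, right = 0, n - 1
    unvisited = set(range(1, n - 1))
    order = [left]
    cur = left
    while unvisited:
        nxt = min(unvisited, key=lambda j: dist[cur, j])
        order.append(nxt)
        unvisited.discard(nxt)
        cur = nxt
    order.append(right)
    improved = True
    while improved:
        improved = False
        # 2-opt: reverse a sub-path
        for i in range(1, n - 2):
            for j in range(i + 1, n - 1):
                a, bnode, cnode, dnode = (
                    order[i - 1],
                    order[i],
                    order[j],
                    order[j + 1],
                )
                delta = (
                    dist[a, cnode]
                    + dist[bnode, dnode]
                    - dist[a, bnode]
                    - dist[cnode, dnode]
                )
                if delta < -1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
        # or-opt: relocate short segments (length 1 or 2)
        for seg_len in (1, 2):
            i = 1
            while i + seg_len - 1 < n - 1:
                seg = order[i : i + seg_len]
                rest = order[:i] + order[i + seg_len :]
                removal = (
                    dist[order[i - 1], seg[0]]
                    + dist[seg[-1], order[i + seg_len]]
                    - dist[order[i - 1], order[i + seg_len]]
                )
                best_gain, best_pos, best_rev = -1e-12, None, False
                for k in range(1, len(rest)):
                    base = dist[rest[k - 1], rest[k]]
                    for rev in (False, True):
                        s0, s1 = (seg[-1], seg[0]) if rev else (seg[0], seg[-1])
                        insertion = dist[rest[k - 1], s0] + dist[s1, rest[k]] - base
                        gain = insertion - removal
                        if gain < best_gain:
                            best_gain, best_pos, best_rev = gain, k, rev
                if best_pos is not None:
                    placed = seg[::-1] if best_rev else seg
                    order = rest[:best_pos] + placed + rest[best_pos:]
                    improved = True
                else:
                    i += 1
    return order


def centerline(slab_records, epithelium_edges, section_index: int = 0) -> Centerline:
    """Transversal centre-line through all nuclei of a section.

    The shortest path from the left to the right edge of the ventral
    epithelium passing once through every nucleus centre, projected to the
    section (y, z) plane: solved exactly by dynamic programming for up to 12
    nuclei, and by a greedy + 2-opt heuristic above that.
    ``epithelium_edges`` supplies the (left, right) anchor points.
    """
    recs = list(slab_records)
    if not recs:
        raise AnalysisError("cannot build a centerline for an empty section")
    left, right = (np.asarray(e, dtype=float) for e in epithelium_edges)
    pts3 = np.vstack([left] + [r.centroid for r in recs] + [right])
    proj = pts3[:, 1:]  # (y, z): transversal section plane
    if len(recs) <= 12:
        order = _exact_open_path(proj)
    else:
        order = _two_opt_path(proj)
    vertices = pts3[order]
    ids = [recs[i - 1].nucleus_id for i in order if 1 <= i <= len(recs)]
    return Centerline(
        section_index=section_index,
        nucleus_ids=ids,
        vertices=vertices,
        total_length=_path_length(proj, order),
    )


# ---------------------------------------------------------------------------
# staging and the nucleus-vs-outline proxy check
# ---------------------------------------------------------------------------

#: germband-extension staging windows used for quantification (% GBE):
#: C. riparius embryos are comparable between 13 and 22 % GBE, D. melanogaster
#: between the onset of extension and 10 %
STAGING_WINDOWS = {"C.riparius": (13.0, 22.0), "D.melanogaster": (0.0, 10.0)}


def stage_filter(gbe_percent: float, species_label: str = "C.riparius") -> bool:
    """True when an embryo's %GBE falls in its species' staging window."""
    lo, hi = STAGING_WINDOWS.get(species_label, (0.0, 100.0))
    return lo <= gbe_percent <= hi


def measure_gbe(posterior_midgut_position: float) -> float:
    """Percent germband extension from the displacement of the infolding
    posterior midgut, expressed as a fraction of egg length from the
    posterior pole (0 = non-extended germband)."""
    p = float(posterior_midgut_position)
    if not (0.0 <= p <= 1.0):
        raise ValueError("posterior midgut position must be in [0, 1] egg lengths")
    return 100.0 * p


def proxy_deviation(nucleus_centroids, outline_centroids, cell_length: float, threshold: float = 0.10):
    """Fraction of cells whose nucleus- and outline-based centroids deviate
    by more than ``threshold`` (default 10%) of cell length, per axis.

    Returns a dict with keys ``x``/``y``/``z`` (breadth, width, height).
    """
    a = np.atleast_2d(np.asarray(nucleus_centroids, dtype=float))
    b = np.atleast_2d(np.asarray(outline_centroids, dtype=float))
    if a.shape != b.shape:
        raise ValueError("centroid sets must be paired 1:1 with equal shapes")
    if cell_length <= 0:
        raise ValueError("cell_length must be positive")
    exceed = np.abs(a - b) / cell_length > threshold
    frac = exceed.mean(axis=0)
    return {"x": float(frac[0]), "y": float(frac[1]), "z": float(frac[2])}
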