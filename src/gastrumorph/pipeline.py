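"""End-to-end quantification of single embryos and cohorts.

Ties the modules together: alignment, egg-shell and epithelium surface
reconstruction, nucleus classification, ROI sectioning and per-section
metrics.  Both entry points (a pre-segmented nucleus table, or an image
stack that is first segmented) converge on the same geometry code: the
epithelium layer is reconstructed from a Gaussian-blob rasterization of the
segmented nuclei — the digital analogue of blurring the nuclear staining
into a connected layer — so stack- and table-based runs of the same embryo
agree up to centroid-extraction error.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometrics, morphostats, segment, synthgen
from .errors import AnalysisError
from .geometry import (
    ROISpec,
    SurfaceMesh,
    align_embryo,
    build_egg_shell,
    mesh_ml_extent,
    section_slabs,
)
from .imgio import DEFAULT_VOXEL_SIZE, EmbryoMeta
from .segment import AnalysisParams, centroid_array

logger = logging.getLogger(__name__)

__all__ = ["EmbryoQuant", "quantify_embryo", "quantify_stack", "sections_frame", "embryos_frame"]

#: voxel pitch (um) of the epithelium-reconstruction grid
EPITHELIUM_GRID_UM = 2.0
#: physical blur fusing nucleus blobs into a layer (um)
EPITHELIUM_BLUR_UM = 3.0
#: layer threshold as a fraction of the blurred single-blob peak
EPITHELIUM_THRESHOLD_FRACTION = 0.45


@dataclass
class EmbryoQuant:
    """Quantification result of one embryo."""

    embryo_id: str
    group_label: str
    gbe_percent: float
    nucleus_diameter: float
    n_roi: int
    n_internalized: int
    sections: list
    records: list
    shell_mesh: SurfaceMesh
    apical_mesh: SurfaceMesh
    centerlines: list = field(default_factory=list)

    @property
    def roi_internalization_percent(self) -> float:
        """Whole-ROI internalization (aggregate over all sections)."""
        return 100.0 * self.n_internalized / self.n_roi if self.n_roi else 0.0


def _epithelium_meshes(records, params: AnalysisParams, grid_um: float):
    """Apical epithelium mesh from a nucleus-blob rasterization.

    Only the ventral half of the embryo (below the cross-section midplane)
    is rasterized: the epithelium layer of interest lies there, and the
    crop keeps the grid small.
    """
    pts = centroid_array(records)
    diams = np.array([r.equivalent_diameter for r in records])
    d_max = float(diams.max())
    margin = 1.5 * d_max
    z_mid = 0.5 * (pts[:, 2].min() + pts[:, 2].max())
    ventral = pts[:, 2] < z_mid + d_max
    if not ventral.any():
        raise AnalysisError("no nuclei on the ventral side")
    vpts, vdiams = pts[ventral], diams[ventral]
    origin = vpts.min(axis=0) - margin
    top = vpts.max(axis=0) + margin
    shape = tuple(np.ceil((top - origin) / grid_um).astype(int)[::-1] + 1)
    voxel = (grid_um, grid_um, grid_um)
    dna = synthgen.rasterize_nuclei(vpts, vdiams, voxel, origin, shape)
    # blur_sigma/hole_max_gap are specified in voxels at the acquisition
    # pitch; on this coarser grid use a physically sized fusion blur and
    # rescale the closing radius
    gap_vox = params.hole_max_gap * DEFAULT_VOXEL_SIZE[0] / grid_um
    grid_params = segment.AnalysisParams(
        blur_sigma=max(EPITHELIUM_BLUR_UM / grid_um, 0.5),
        contrast_saturation=params.contrast_saturation,
        hole_max_gap=gap_vox,
        mitosis_overlap_fraction=params.mitosis_overlap_fraction,
    )
    # the raster is a sum of unit-amplitude Gaussian blobs (sd = d/4), so
    # the blurred single-blob peak is known in closed form; thresholding at
    # a fixed fraction of it gives a layer about one nucleus thick.  The
    # fusion blur adapts to the observed nucleus spacing so the layer stays
    # connected for any monolayer packing: two blobs nn apart merge at
    # threshold fraction f when the blurred sd reaches
    # (nn/2) / sqrt(2 ln(2/f)).
    d_med = float(np.median(vdiams))
    sd_blob = d_med / 4.0
    from scipy.spatial import cKDTree

    nn = float(np.median(cKDTree(vpts).query(vpts, k=2)[0][:, 1]))
    f = EPITHELIUM_THRESHOLD_FRACTION
    sd_needed = (nn / 2.0) / np.sqrt(2.0 * np.log(2.0 / f))
    sd_blur = max(EPITHELIUM_BLUR_UM, np.sqrt(max(sd_needed**2 - sd_blob**2, 0.0)))
    peak = (sd_blob**2 / (sd_blob**2 + sd_blur**2)) ** 1.5
    grid_params = dataclasses.replace(
        grid_params, blur_sigma=max(sd_blur / grid_um, 0.5)
    )
    logger.info(
        "epithelium grid %.2g um: blur sd %.2f um, threshold %.3f (%.2f of blob peak), "
        "closing gap %.1f vox",
        grid_um, sd_blur, f * peak, f, gap_vox,
    )
    volume = segment.build_epithelium_volume(
        dna, grid_params, threshold=f * peak
    )
    # apical boundary: shell-facing envelope of the ventrally shadow-filled
    # component (yolk-side bulges of ingressed nuclei do not count), with
    # sub-cellular gaps in the nuclear layer sealed at one nucleus diameter
    envelope = segment.ventral_envelope(volume, seal_radius_voxels=d_med / grid_um)
    _, apical = segment.extract_epithelium_surfaces(envelope, voxel, origin)
    return apical


def quantify_embryo(
    records,
    meta: EmbryoMeta | None = None,
    roi: ROISpec | None = None,
    params: AnalysisParams | None = None,
    integrity_variant: str = "internalized_only",
    grid_um: float = EPITHELIUM_GRID_UM,
    with_centerlines: bool = False,
) -> EmbryoQuant:
    """Quantify mesoderm internalization for one embryo.

    Steps: align axes -> egg-shell hull (+ ventral expansion) -> epithelium
    surfaces -> internalized/ingressed classification -> ROI sectioning ->
    per-section metrics.  Sections without nuclei are skipped.
    """
    meta = meta or EmbryoMeta()
    roi = roi or ROISpec()
    params = params or AnalysisParams()
    if len(records) < 4:
        raise AnalysisError("need at least 4 nuclei to quantify an embryo")
    rot, center, aligned = align_embryo(centroid_array(records))
    for rec, pos in zip(records, aligned):
        rec.centroid = pos
    d = segment.estimate_nucleus_diameter(records, params)
    logger.info(
        "embryo %s: nucleus diameter %.2f um, alpha probe %s",
        meta.embryo_id, d, params.alpha_probe_radius,
    )
    shell = build_egg_shell(aligned, d, params.alpha_probe_radius)
    apical = _epithelium_meshes(records, params, grid_um)
    morphometrics.classify_nuclei(records, shell, apical, d)
    slabs = section_slabs(aligned, roi, shell_mesh=shell)
    sections = []
    centerlines = []
    n_roi = 0
    n_internal = 0
    for slab in slabs:
        slab_records = [records[i] for i in slab.indices]
        if not slab_records:
            continue
        n_roi += len(slab_records)
        n_internal += sum(1 for r in slab_records if r.internalized)
        width = mesh_ml_extent(shell, slab.ap_lo, slab.ap_hi)
        sections.append(
            morphometrics.section_metrics(
                slab_records,
                embryo_id=meta.embryo_id,
                section_index=slab.index,
                nucleus_diameter=d,
                embryo_width=width,
                integrity_variant=integrity_variant,
            )
        )
        for rec in slab_records:
            rec.extras["section_index"] = slab.index
        if with_centerlines:
            ml = [r.centroid[1] for r in slab_records]
            lo_rec = slab_records[int(np.argmin(ml))]
            hi_rec = slab_records[int(np.argmax(ml))]
            anchors = (
                lo_rec.centroid - np.array([0.0, d, 0.0]),
                hi_rec.centroid + np.array([0.0, d, 0.0]),
            )
            centerlines.append(
                morphometrics.centerline(slab_records, anchors, slab.index)
            )
    if not sections:
        raise AnalysisError("no ROI section holds any nucleus")
    return EmbryoQuant(
        embryo_id=meta.embryo_id,
        group_label=meta.group_label,
        gbe_percent=meta.gbe_percent,
        nucleus_diameter=d,
        n_roi=n_roi,
        n_internalized=n_internal,
        sections=sections,
        records=records,
        shell_mesh=shell,
        apical_mesh=apical,
        centerlines=centerlines,
    )


def quantify_stack(
    stack: np.ndarray,
    meta: EmbryoMeta,
    roi: ROISpec | None = None,
    params: AnalysisParams | None = None,
    integrity_variant: str = "internalized_only",
    grid_um: float = EPITHELIUM_GRID_UM,
) -> EmbryoQuant:
    """Quantify an embryo from a (C, Z, Y, X) stack.

    Segments nuclei from the DNA channel, calls mitosis from the pHisH3
    channel if present, then runs :func:`quantify_embryo`.
    """
    params = params or AnalysisParams()
    cmap = meta.channel_map
    if "dna" not in cmap:
        raise AnalysisError("channel map does not name a 'dna' channel")
    dna = stack[int(cmap["dna"])]
    records, labels = segment.segment_nuclei(
        dna, meta.voxel_size, params, origin=meta.origin_um
    )
    if "phish3" in cmap:
        segment.detect_mitosis(
            records, stack[int(cmap["phish3"])], params, label_volume=labels
        )
    return quantify_embryo(
        records, meta, roi, params, integrity_variant, grid_um
    )


# ---------------------------------------------------------------------------
# tidy tables
# ---------------------------------------------------------------------------

def sections_frame(quants) -> pd.DataFrame:
    """Tidy per-section table (one row per embryo x section)."""
    rows = []
    for q in quants:
        for s in q.sections:
            rows.append(
                {
                    "embryo_id": s.embryo_id,
                    "group_label": q.group_label,
                    "gbe_percent": q.gbe_percent,
                    "section_index": s.section_index,
                    "internalization": s.internalization,
                    "integrity": s.integrity,
                    "integrity_variant": s.integrity_variant,
                    "furrow_depth": s.furrow_depth,
                    "max_cell_depth": s.max_cell_depth,
                    "furrow_width": s.furrow_width,
                    "mitosis_count": s.mitosis_count,
                    "n_nuclei": s.n_nuclei,
                }
            )
    return pd.DataFrame(rows)


def embryos_frame(quants) -> pd.DataFrame:
    """Per-embryo aggregates (inputs of the efficiency analysis)."""
    return pd.DataFrame(
        [
            {
                "embryo_id": q.embryo_id,
                "group_label": q.group_label,
                "gbe_percent": q.gbe_percent,
                "nucleus_diameter_um": q.nucleus_diameter,
                "n_roi": q.n_roi,
                "n_internalized": q.n_internalized,
                "roi_internalization_percent": q.roi_internalization_percent,
            }
            for q in quants
        ]
    )


def morphospace_points(section_table: pd.DataFrame, parameters=morphostats.TIME_INDEPENDENT_PARAMS):
    """Z-score the section table (pooled over groups) into morphospace points.

    Sections with undefined parameters (NaN integrity) are dropped; z-scoring
    is fit on the pooled data so all groups share one space.
    """
    cols = list(parameters)
    clean = section_table.dropna(subset=cols)
    if len(clean) < 2:
        raise AnalysisError("fewer than 2 sections with defined parameters")
    z = morphostats.zscore(clean[cols].to_numpy())
    points = [
        morphostats.MorphospacePoint(
            embryo_id=row.embryo_id,
            section_index=int(row.section_index),
            group_label=row.group_label,
            coords=z[i],
        )
        for i, row in enumerate(clean.itertuples())
    ]
    return points, clean.reset_index(drop=True)
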