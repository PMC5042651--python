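"""Nucleus and epithelium segmentation from 3D image stacks.

A deterministic intensity pipeline stands in for interactive pixel
classification: nuclei are extracted as thresholded connected components of
the DNA channel, mitosis is called by overlap with the phospho-Histone-H3
channel, and the ventral epithelium is obtained by blurring the nuclei into
a connected layer, thresholding, keeping the largest component and closing
residual holes.  Voxel indices are 0-based in array order (z, y, x); all
emitted coordinates are physical micrometres in (x, y, z) order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import FormatError, ParameterError, SegmentationError
from .geometry import SurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusRecord",
    "AnalysisParams",
    "extract_centroids",
    "segment_nuclei",
    "estimate_nucleus_diameter",
    "detect_mitosis",
    "build_epithelium_volume",
    "ventral_envelope",
    "extract_epithelium_surfaces",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus and its downstream classification state.

    ``centroid`` is (x, y, z) in micrometres; ``d_shell`` / ``d_epi`` are the
    distances to the reconstructed egg shell and apical epithelium surface
    (filled by the morphometrics layer); a nucleus is *internalized* when it
    lies deeper than one nucleus length from the egg shell and *ingressed*
    when deeper than one nucleus length from the epithelial surface.
    """

    nucleus_id: int
    centroid: np.ndarray
    equivalent_diameter: float
    voxel_count: int = 0
    mitotic: bool = False
    d_shell: float | None = None
    d_epi: float | None = None
    internalized: bool | None = None
    ingressed: bool | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (3,):
            raise ParameterError("centroid must be a 3-vector (x, y, z) in um")


def centroid_array(records) -> np.ndarray:
    """(n, 3) array of centroids from a sequence of records."""
    if len(records) == 0:
        return np.empty((0, 3))
    return np.vstack([r.centroid for r in records])


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable thresholds of the segmentation/analysis pipeline.

    blur_sigma : Gaussian blur in voxels used to merge nuclei into an
        epithelium layer (default 3).
    contrast_saturation : percent of pixels saturated during contrast
        enhancement, ImageJ-style (default 0.35, i.e. 0.175% per tail).
    hole_max_gap : maximal gap, in voxels at the acquisition pitch, closed in
        the epithelium volume (default 20).
    min_nucleus_voxels / max_nucleus_voxels : component size filter.
    binarize_quantile : quantile of the nonzero normalized intensities used
        as nucleus threshold; None selects Otsu's threshold.
    mitosis_overlap_fraction : fraction of a nucleus's voxels that must be
        pHisH3-positive to call it mitotic (default 0.5).
    alpha_probe_radius : probe radius of the egg-shell alpha hull in um;
        "auto" yields the convex hull.
    nucleus_diameter_override : fixed nucleus diameter in um, or "auto" to
        estimate it from the segmented nuclei.
    """

    blur_sigma: float = 3.0
    contrast_saturation: float = 0.35
    hole_max_gap: float = 20.0
    min_nucleus_voxels: int = 20
    max_nucleus_voxels: int = 500_000
    binarize_quantile: float | None = None
    mitosis_overlap_fraction: float = 0.5
    alpha_probe_radius: float | str = "auto"
    nucleus_diameter_override: float | str = "auto"

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ParameterError("blur_sigma must be > 0")
        if not (0 < self.contrast_saturation < 1):
            raise ParameterError("contrast_saturation must be in (0, 1)")
        if self.hole_max_gap < 0:
            raise ParameterError("hole_max_gap must be >= 0")
        if self.binarize_quantile is not None and not (
            0 < self.binarize_quantile < 1
        ):
            raise ParameterError("binarize_quantile must be in (0, 1)")
        if not (0 <= self.mitosis_overlap_fraction <= 1):
            raise ParameterError("mitosis_overlap_fraction must be in [0, 1]")


def _as_zyx_voxel(voxel_size) -> np.ndarray:
    """Voxel size given as (x, y, z) um -> array in array-axis order (z, y, x)."""
    v = np.asarray(voxel_size, dtype=float)
    if v.shape != (3,) or np.any(v <= 0):
        raise ParameterError(f"voxel_size must be a positive (x, y, z) triple, got {voxel_size}")
    return v[::-1]


def _normalize(volume: np.ndarray) -> np.ndarray:
    vol = np.asarray(volume, dtype=np.float32)
    lo, hi = float(vol.min()), float(vol.max())
    if hi <= lo:
        return np.zeros_like(vol)
    return (vol - lo) / (hi - lo)


def segment_nuclei(dna_channel, voxel_size, params: AnalysisParams | None = None, origin=(0.0, 0.0, 0.0)):
    """Segment nuclei; returns ``(records, label_volume)``.

    The DNA channel is min-max normalized, thresholded (Otsu by default or at
    ``binarize_quantile`` of the nonzero intensities), labelled with
    26-connectivity, size-filtered, and summarized per component by the
    intensity-weighted centre of mass (converted to um using ``voxel_size``
    and ``origin``, both in (x, y, z) order) and the equivalent spherical
    diameter.
    """
    params = params or AnalysisParams()
    vol = np.asarray(dna_channel)
    if vol.ndim != 3:
        raise FormatError(f"expected a 3D DNA channel, got shape {vol.shape}")
    vzyx = _as_zyx_voxel(voxel_size)
    norm = _normalize(vol)
    if norm.max() == 0:
        logger.warning("blank DNA channel: no nuclei")
        return [], np.zeros(vol.shape, dtype=np.int32)
    if params.binarize_quantile is None:
        thr = threshold_otsu(norm)
    else:
        nz = norm[norm > 0]
        thr = float(np.quantile(nz, params.binarize_quantile))
    binary = norm > thr
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    voxel_volume = float(np.prod(vzyx))
    origin = np.asarray(origin, dtype=float)
    records: list[NucleusRecord] = []
    next_id = 0
    keep_labels = np.zeros(labels.max() + 1, dtype=np.int32)
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        count = int(mask.sum())
        if count < params.min_nucleus_voxels or count > params.max_nucleus_voxels:
            continue
        w = norm[sl] * mask
        total = float(w.sum())
        zz, yy, xx = np.nonzero(mask)
        off = np.array([s.start for s in sl], dtype=float)
        com_zyx = (
            np.stack([zz, yy, xx], axis=1) * w[zz, yy, xx][:, None]
        ).sum(axis=0) / total + off
        centroid = com_zyx[::-1] * vzyx[::-1] + origin  # -> (x, y, z) um
        eq_diam = 2.0 * (3.0 * count * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        next_id += 1
        keep_labels[lab] = next_id
        records.append(
            NucleusRecord(
                nucleus_id=next_id,
                centroid=centroid,
                equivalent_diameter=eq_diam,
                voxel_count=count,
            )
        )
    if not records:
        logger.warning("no nuclei survived the size filter")
    return records, keep_labels[labels]


def extract_centroids(dna_channel, voxel_size, params: AnalysisParams | None = None, origin=(0.0, 0.0, 0.0)):
    """Nucleus records from a DNA channel (see :func:`segment_nuclei`)."""
    records, _ = segment_nuclei(dna_channel, voxel_size, params, origin)
    return records


def estimate_nucleus_diameter(records, params: AnalysisParams | None = None) -> float:
    """Median equivalent diameter, robust against merged or split nuclei.

    ``params.nucleus_diameter_override`` short-circuits the estimate.
    """
    params = params or AnalysisParams()
    if params.nucleus_diameter_override != "auto":
        return float(params.nucleus_diameter_override)
    if len(records) == 0:
        raise ValueError("cannot estimate nucleus diameter from zero records")
    return float(np.median([r.equivalent_diameter for r in records]))


def _phish3_threshold(channel: np.ndarray) -> float:
    """Absolute positivity threshold for the pHisH3 channel.

    Otsu over the foreground intensities, so positive pHisH3 objects are
    delineated at the same scale as the DNA-channel nucleus objects.  When
    the channel carries no signal beyond the noise floor (max < median +
    10 * MAD) no voxel is considered positive.
    """
    vol = np.asarray(channel, dtype=np.float32)
    med = float(np.median(vol))
    mad = float(np.median(np.abs(vol - med)))
    vmax = float(vol.max())
    if vmax < med + 10.0 * max(mad, 1e-6) or vmax <= 0:
        return np.inf
    if len(np.unique(vol)) < 2:
        return 0.5 * vmax
    # same global-Otsu rule as the DNA-channel nucleus binarization, so
    # pHisH3-positive objects are delineated at the nucleus-object scale
    vmin = float(vol.min())
    return vmin + float(threshold_otsu((vol - vmin) / (vmax - vmin))) * (vmax - vmin)


def detect_mitosis(records, phish3_channel, params: AnalysisParams | None = None, label_volume=None, voxel_size=None, origin=(0.0, 0.0, 0.0)):
    """Set ``mitotic`` flags by overlap with pHisH3-positive staining.

    A nucleus is mitotic when at least ``mitosis_overlap_fraction`` of its
    voxels exceed the pHisH3 positivity threshold.  ``label_volume`` (from
    :func:`segment_nuclei`) supplies the per-nucleus voxel sets; without it,
    a ball of the nucleus's equivalent diameter around its centroid is used
    (requires ``voxel_size``).
    """
    params = params or AnalysisParams()
    vol = np.asarray(phish3_channel)
    if label_volume is not None and np.shape(label_volume) != vol.shape:
        raise FormatError(
            f"channel shape {vol.shape} does not match label volume "
            f"{np.shape(label_volume)}"
        )
    thr = _phish3_threshold(vol)
    positive = vol > thr if np.isfinite(thr) else np.zeros(vol.shape, dtype=bool)
    if label_volume is not None:
        for rec in records:
            mask = label_volume == rec.nucleus_id
            count = int(mask.sum())
            frac = positive[mask].mean() if count else 0.0
            rec.mitotic = bool(frac >= params.mitosis_overlap_fraction and count > 0)
        return records
    if voxel_size is None:
        raise ParameterError("voxel_size required when no label volume is given")
    vzyx = _as_zyx_voxel(voxel_size)
    origin = np.asarray(origin, dtype=float)
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in vol.shape], indexing="ij"), axis=-1
    ) * vzyx  # (z, y, x, 3) in um, axis order (z, y, x)
    for rec in records:
        c_zyx = (rec.centroid - origin)[::-1]
        r = rec.equivalent_diameter / 2.0
        mask = ((grid - c_zyx) ** 2).sum(axis=-1) <= r * r
        count = int(mask.sum())
        frac = positive[mask].mean() if count else 0.0
        rec.mitotic = bool(frac >= params.mitosis_overlap_fraction and count > 0)
    return records


# ---------------------------------------------------------------------------
# ventral epithelium
# ---------------------------------------------------------------------------

def _closing(binary: np.ndarray, radius_voxels: float) -> np.ndarray:
    """Ball closing via Euclidean distance transforms (isotropic voxels)."""
    if radius_voxels <= 0:
        return binary
    dilated = ndimage.distance_transform_edt(~binary) <= radius_voxels
    # erode the dilation back: keep voxels whose distance to the dilated
    # background exceeds the radius
    inner = ndimage.distance_transform_edt(dilated) > radius_voxels
    return binary | inner


def build_epithelium_volume(
    dna_channel,
    params: AnalysisParams | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Binary volume of the connected ventral epithelium layer.

    Gaussian blur (``blur_sigma`` voxels) merges individual nuclei into a
    layer; contrast is stretched saturating ``contrast_saturation`` percent
    of the foreground pixels; Otsu's threshold binarizes; the largest
    26-connected component is kept and internal holes with gaps up to
    ``hole_max_gap`` voxels are closed.

    ``threshold``, if given, is an absolute intensity applied to the
    blurred (unstretched) volume instead of the contrast-stretch + Otsu
    step — used when the caller knows the intensity model of the volume
    (e.g. a rasterization of unit-amplitude nucleus blobs).
    """
    params = params or AnalysisParams()
    vol = np.asarray(dna_channel, dtype=np.float32)
    if vol.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {vol.shape}")
    blurred = ndimage.gaussian_filter(vol, sigma=params.blur_sigma)
    vmax = float(blurred.max())
    if vmax <= 0:
        raise SegmentationError("empty or constant volume: no epithelium component")
    if threshold is not None:
        binary = blurred > threshold
        if not binary.any():
            raise SegmentationError("threshold above all blurred intensities")
    else:
        # contrast stretch and threshold over foreground voxels: on a
        # mostly-empty volume, whole-volume percentiles and a whole-volume
        # histogram would land deep in the blob tails and fuse separate
        # structures.  ImageJ-style saturation: contrast_saturation is a
        # percent of (foreground) pixels.
        fg = blurred[blurred > 0.02 * vmax]
        if fg.size < 2 or fg.min() == fg.max():
            raise SegmentationError("no foreground intensity structure in volume")
        tail = params.contrast_saturation / 2.0
        lo, hi = np.percentile(fg, [tail, 100.0 - tail])
        if hi <= lo:
            raise SegmentationError("empty or constant volume: no epithelium component")
        stretched = np.clip((blurred - lo) / (hi - lo), 0.0, 1.0)
        thr = threshold_otsu(stretched[stretched > 0.02])
        binary = stretched > thr
    if not binary.any():
        raise SegmentationError("thresholding produced an empty volume")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    largest = np.argmax(ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))) + 1
    component = labels == largest
    closed = _closing(component, params.hole_max_gap / 2.0)
    # fill fully enclosed cavities
    closed = ndimage.binary_fill_holes(closed)
    return closed


def ventral_envelope(binary_volume: np.ndarray, seal_radius_voxels: float = 0.0) -> np.ndarray:
    """Shadow-fill a binary layer from its shell-facing (low-z) side.

    Every voxel at or above (in z) the first occupied voxel of its (y, x)
    column is set; the lower boundary of the result is the apical envelope
    of the layer, immune to yolk-side bulges from ingressed nuclei.

    ``seal_radius_voxels`` > 0 additionally applies a grey opening of that
    radius to the first-occupied height map: gaps in the nuclear layer
    narrower than the structuring disk (nuclei missing where cells have
    ingressed, while the epithelial surface itself remains continuous) are
    sealed at the level of the surrounding layer.
    """
    binary = np.asarray(binary_volume, dtype=bool)
    if seal_radius_voxels <= 0:
        return np.maximum.accumulate(binary, axis=0)
    nz = binary.shape[0]
    occupied = binary.any(axis=0)
    zlow = np.where(occupied, np.argmax(binary, axis=0), 4 * nz).astype(np.int32)
    r = max(int(round(seal_radius_voxels)), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2) <= r * r
    # robust local surface: columns rising far above the lower-quartile
    # height of their neighbourhood are gaps, not epithelium
    q25 = ndimage.percentile_filter(zlow, 25, footprint=disk, mode="nearest")
    thresh = max(0.6 * seal_radius_voxels, 1.0)
    sealed = np.where(zlow > q25 + thresh, q25, zlow)
    valid = sealed < 2 * nz
    env = np.arange(nz, dtype=np.int32)[:, None, None] >= sealed[None, :, :]
    return env & valid[None, :, :]


def extract_epithelium_surfaces(binary_volume, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Split the 0.5-isosurface of a binary volume into upper/lower meshes.

    Faces are partitioned by the z-sign of their outward normals: the lower
    mesh (negative z, facing the egg shell) approximates the apical side of
    the epithelium; the upper mesh faces the yolk (basal).  Returns
    ``(upper, lower)`` as :class:`SurfaceMesh` with orientation tags.
    """
    binary = np.asarray(binary_volume).astype(bool)
    if not binary.any():
        raise SegmentationError("empty binary volume")
    vzyx = _as_zyx_voxel(voxel_size)
    padded = np.pad(binary, 1).astype(np.float32)
    verts, faces, normals, _ = measure.marching_cubes(padded, 0.5, spacing=tuple(vzyx))
    # skimage normals point outward (towards lower values) for a binary solid
    verts = verts - vzyx  # undo padding offset
    verts_xyz = verts[:, ::-1] + np.asarray(origin, dtype=float)
    # winding consistent with outward normals: flip faces where disagreeing
    tri = verts_xyz[faces]
    geom_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vert_n = normals[:, ::-1][faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", geom_n, vert_n) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    face_nz = vert_n[:, 2]
    lower_faces = faces[face_nz < 0]
    upper_faces = faces[face_nz >= 0]
    upper = SurfaceMesh(verts_xyz, upper_faces, "epithelium_basal")
    lower = SurfaceMesh(verts_xyz, lower_faces, "epithelium_apical")
    if upper.n_faces == 0 or lower.n_faces == 0:
        raise SegmentationError("isosurface could not be split into upper/lower meshes")
    return upper, lower
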