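"""Readers and writers for every artifact of the pipeline.

Image stacks are multi-page TIFF with axis order (channel, z, y, x) and a
human-diffable YAML sidecar carrying the embryo metadata; nucleus tables are
CSV; meshes are ascii PLY with an orientation comment; configuration is a
flat key-value file.  All readers and writers are exact inverses on valid
inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, FormatError
from .geometry import ROISpec, SurfaceMesh
from .segment import AnalysisParams, NucleusRecord
from .synthgen import DEFAULT_CHANNEL_MAP, GenParams

__all__ = [
    "EmbryoMeta",
    "read_stack",
    "write_stack",
    "read_nuclei_table",
    "write_nuclei_table",
    "read_mesh",
    "write_mesh",
    "load_config",
]

#: acquisition voxel size of the reference C. riparius imaging, um (x, y, z)
DEFAULT_VOXEL_SIZE = (0.28, 0.28, 0.42)


@dataclass
class EmbryoMeta:
    """Per-embryo metadata carried alongside every stack and table."""

    embryo_id: str = "embryo"
    group_label: str = "control"
    species_label: str = "C.riparius"
    gbe_percent: float = 0.0
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    origin_um: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"voxel_size must be a positive triple, got {self.voxel_size}")
        if not (0.0 <= self.gbe_percent <= 100.0):
            raise FormatError(f"gbe_percent must be in [0, 100], got {self.gbe_percent}")
        self.origin_um = tuple(float(v) for v in self.origin_um)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        d["origin_um"] = list(self.origin_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown metadata keys: {sorted(unknown)}")
        return cls(**d)


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.yaml")


def write_meta(meta: EmbryoMeta, data_path) -> None:
    """Write the YAML sidecar for any data file (same basename)."""
    with open(_sidecar_path(data_path), "w") as fh:
        yaml.safe_dump(meta.to_dict(), fh, sort_keys=True)


def read_meta(data_path, default: EmbryoMeta | None = None) -> EmbryoMeta | None:
    """Read the YAML sidecar of a data file, or ``default`` if absent."""
    sidecar = _sidecar_path(data_path)
    if not sidecar.exists():
        return default
    with open(sidecar) as fh:
        return EmbryoMeta.from_dict(yaml.safe_load(fh) or {})


def write_stack(stack: np.ndarray, path, meta: EmbryoMeta) -> None:
    """Write a (C, Z, Y, X) stack as multi-page TIFF plus a YAML sidecar."""
    arr = np.asarray(stack)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise FormatError(f"expected a 3D or 4D stack, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"stacks must be 8- or 16-bit, got {arr.dtype}")
    tifffile.imwrite(path, arr, photometric="minisblack")
    write_meta(meta, path)


def read_stack(path):
    """Read a stack and its sidecar metadata; returns ``(array, EmbryoMeta)``.

    The array is normalized to axis order (channel, z, y, x); every channel
    named in the metadata's channel map must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such stack: {path}")
    arr = tifffile.imread(path)
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"stacks must be 8- or 16-bit, got {arr.dtype}")
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise FormatError(f"cannot interpret stack of shape {arr.shape}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = EmbryoMeta.from_dict(yaml.safe_load(fh) or {})
    else:
        meta = EmbryoMeta(embryo_id=path.stem)
    n_chan = arr.shape[0]
    bad = {k: v for k, v in meta.channel_map.items() if not (0 <= int(v) < n_chan)}
    if bad:
        raise FormatError(
            f"channel map names channels {bad} but the stack has {n_chan} channel(s)"
        )
    return arr, meta


# ---------------------------------------------------------------------------
# nucleus tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "embryo_id",
    "nucleus_id",
    "x_um",
    "y_um",
    "z_um",
    "diameter_um",
    "mitotic",
)
_OPTIONAL_COLUMNS = (
    "voxel_count",
    "d_shell_um",
    "d_epi_um",
    "internalized",
    "ingressed",
    "section_index",
)


def write_nuclei_table(records, path, embryo_id: str = "embryo", extra_columns: dict | None = None) -> None:
    """Write nucleus records as CSV (one row per nucleus).

    Ground-truth columns (prefixed ``gt_``) or any other per-nucleus arrays
    can be attached via ``extra_columns``; per-record ``extras`` survive the
    round trip as additional columns.
    """
    rows = []
    for r in records:
        row = {
            "embryo_id": embryo_id,
            "nucleus_id": r.nucleus_id,
            "x_um": r.centroid[0],
            "y_um": r.centroid[1],
            "z_um": r.centroid[2],
            "diameter_um": r.equivalent_diameter,
            "mitotic": bool(r.mitotic),
            "voxel_count": r.voxel_count,
        }
        for col in ("d_shell", "d_epi"):
            val = getattr(r, col)
            if val is not None:
                row[f"{col}_um"] = val
        for col in ("internalized", "ingressed"):
            val = getattr(r, col)
            if val is not None:
                row[col] = bool(val)
        row.update(r.extras)
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra_columns:
        for name, values in extra_columns.items():
            df[name] = values
    df.to_csv(path, index=False)


def read_nuclei_table(path):
    """Read a nucleus CSV; returns ``(records, embryo_id)``.

    Unknown columns are preserved in each record's ``extras``; a missing
    required column or a non-numeric/NaN coordinate raises
    :class:`FormatError` naming the column or row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such table: {path}")
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    for col in ("x_um", "y_um", "z_um", "diameter_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if bad.size:
            raise FormatError(
                f"non-numeric or NaN value in column {col!r} at row {int(bad[0])} "
                f"of {path.name}"
            )
        df[col] = vals
    records = []
    known = set(_REQUIRED_COLUMNS) | set(_OPTIONAL_COLUMNS) | {"d_shell_um", "d_epi_um"}
    extra_cols = [c for c in df.columns if c not in known]
    for _, row in df.iterrows():
        rec = NucleusRecord(
            nucleus_id=int(row["nucleus_id"]),
            centroid=np.array([row["x_um"], row["y_um"], row["z_um"]]),
            equivalent_diameter=float(row["diameter_um"]),
            voxel_count=int(row.get("voxel_count", 0) or 0),
            mitotic=bool(row["mitotic"]),
        )
        if "d_shell_um" in df.columns and pd.notna(row.get("d_shell_um")):
            rec.d_shell = float(row["d_shell_um"])
        if "d_epi_um" in df.columns and pd.notna(row.get("d_epi_um")):
            rec.d_epi = float(row["d_epi_um"])
        for col in ("internalized", "ingressed"):
            if col in df.columns and pd.notna(row.get(col)):
                setattr(rec, col, bool(row[col]))
        rec.extras = {c: row[c] for c in extra_cols}
        records.append(rec)
    embryo_id = str(df["embryo_id"].iloc[0]) if len(df) else "embryo"
    return records, embryo_id


# ---------------------------------------------------------------------------
# meshes (ascii PLY)
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Ascii PLY with vertices in um and the orientation tag as a comment."""
    if mesh.n_faces < 1:
        raise ValueError("refusing to write an empty mesh")
    if not np.all(np.isfinite(mesh.vertices)):
        raise ValueError("mesh has non-finite vertices")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment orientation {mesh.orientation_tag}\n")
        fh.write("comment units micrometre\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path) -> SurfaceMesh:
    """Read an ascii PLY written by :func:`write_mesh`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mesh: {path}")
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path.name} is not a PLY file")
    tag = "egg_shell"
    n_vert = n_face = None
    body_at = None
    for i, line in enumerate(lines[1:], start=1):
        parts = line.split()
        if parts[:2] == ["comment", "orientation"]:
            tag = parts[2]
        elif parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:1] == ["end_header"]:
            body_at = i + 1
            break
    if body_at is None or n_vert is None or n_face is None:
        raise FormatError(f"malformed PLY header in {path.name}")
    verts = np.array(
        [[float(x) for x in lines[body_at + k].split()] for k in range(n_vert)]
    )
    faces = np.array(
        [
            [int(x) for x in lines[body_at + n_vert + k].split()[1:4]]
            for k in range(n_face)
        ],
        dtype=np.int64,
    )
    return SurfaceMesh(verts, faces, tag)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_ALIASES = {
    "roi_ventral_fraction": "ventral_circumference_fraction",
    "roi_n_sections": "n_sections",
    "roi_ap_low": None,  # handled specially below
    "roi_ap_high": None,
}


def _param_registry():
    reg = {}
    for cls, slot in ((GenParams, "gen"), (ROISpec, "roi"), (AnalysisParams, "analysis")):
        for f in dataclasses.fields(cls):
            reg[f.name] = (slot, f.name)
    return reg


def load_config(path):
    """Load a flat key-value configuration file.

    Returns a dict with validated ``GenParams``, ``ROISpec`` and
    ``AnalysisParams`` under the keys ``gen``, ``roi`` and ``analysis``;
    missing keys take their defaults.  Unknown keys and type mismatches
    raise :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        # tolerate "key = value" lines
        data = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"cannot parse config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            data[key] = yaml.safe_load(val)
    registry = _param_registry()
    buckets: dict = {"gen": {}, "roi": {}, "analysis": {}}
    ap_bounds = {}
    for key, value in data.items():
        if isinstance(value, dict):
            raise ConfigError(f"config must be flat; nested value under {key!r}")
        name = _ALIASES.get(key, key) if key in _ALIASES else key
        if key in ("roi_ap_low", "roi_ap_high"):
            ap_bounds[key] = value
            continue
        if name not in registry:
            raise ConfigError(f"unknown config key {key!r}")
        slot, field_name = registry[name]
        buckets[slot][field_name] = value
    if ap_bounds:
        lo = ap_bounds.get("roi_ap_low", 0.25)
        hi = ap_bounds.get("roi_ap_high", 0.75)
        buckets["roi"]["ap_fraction_bounds"] = (lo, hi)
    out = {}
    for slot, cls in (("gen", GenParams), ("roi", ROISpec), ("analysis", AnalysisParams)):
        kwargs = buckets[slot]
        for f in dataclasses.fields(cls):
            if f.name in kwargs:
                val = kwargs[f.name]
                if isinstance(val, bool) and f.type not in ("bool",):
                    raise ConfigError(f"type mismatch for config key {f.name!r}: {val!r}")
                if isinstance(val, list):
                    kwargs[f.name] = tuple(val)
        try:
            out[slot] = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration for {cls.__name__}: {exc}") from exc
    return out
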