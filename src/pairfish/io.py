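"""Reading and writing pipeline artifacts.

Conventions
-----------
* Image stacks are multi-page TIFFs with axes (channel, z, y, x); voxel sizes
  and channel names are embedded as a JSON document in the TIFF description
  and mirrored to a ``<name>.json`` sidecar (the sidecar wins if both exist
  and disagree; an error is raised if neither is present).
* Label masks are 16-bit TIFFs with axes (z, y, x); 0 is background.
* Tables are CSV with documented column names and a ``schema_version``
  column.  Lateral coordinates are micrometres from the image origin; z is
  carried both as a 0-based plane index and in micrometres (index * z_step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import SCHEMA_VERSION, STAGES


class MetadataError(ValueError):
    """Raised when an image file lacks required voxel-size metadata."""


class TableError(ValueError):
    """Raised when a CSV table violates its schema."""


@dataclass
class ImageStack:
    """A multi-channel 3D intensity grid with voxel-size metadata.

    voxels : float or integer array, shape (n_channels, n_z, n_y, n_x)
    lateral_size_um : micrometres per pixel in y and x
    z_step_um : micrometres per z plane
    channel_names : ordered channel labels
    """

    voxels: np.ndarray
    lateral_size_um: float
    z_step_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must have axes (c, z, y, x); got shape {self.voxels.shape}"
            )
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        if self.lateral_size_um <= 0:
            raise ValueError("lateral_size_um must be > 0")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match channel axis")
        if len(self.channel_names) < 1:
            raise ValueError("at least one channel required")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if self.voxels.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's (z, y, x) grid."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {list(self.channel_names)}"
            ) from None
        return self.voxels[idx]


def _meta_dict(stack: ImageStack) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "lateral_size_um": stack.lateral_size_um,
        "z_step_um": stack.z_step_um,
        "channel_names": list(stack.channel_names),
        "shape": list(stack.voxels.shape),
    }


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    meta = _meta_dict(stack)
    tifffile.imwrite(path, stack.voxels, description=json.dumps(meta),
                     photometric="minisblack")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Metadata is taken from the sidecar if present, else from the TIFF
    description; a stack with neither raises :class:`MetadataError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        desc = tf.pages[0].description or ""
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = None
    if not isinstance(meta, dict) or "z_step_um" not in meta:
        raise MetadataError(
            f"{path} carries no voxel-size metadata; write a sidecar "
            f"{sidecar.name} with lateral_size_um, z_step_um and channel_names"
        )
    shape = tuple(meta.get("shape", voxels.shape))
    voxels = voxels.reshape(shape)
    return ImageStack(
        voxels=voxels,
        lateral_size_um=float(meta["lateral_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        channel_names=tuple(meta["channel_names"]),
    )


def write_masks(masks: np.ndarray, path: str | Path) -> Path:
    """Write a (z, y, x) label grid as 16-bit TIFF."""
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("masks must have axes (z, y, x)")
    if masks.min() < 0 or masks.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    tifffile.imwrite(Path(path), masks.astype(np.uint16),
                     photometric="minisblack")
    return Path(path)


def read_masks(path: str | Path) -> np.ndarray:
    masks = tifffile.imread(Path(path))
    if masks.ndim != 3:
        raise TableError(f"mask file {path} must be a 3D label grid")
    return masks.astype(np.int32)


CELL_COLUMNS = (
    "cell_id", "field", "stage", "genotype", "mask_label",
    "mid_plane", "cycle_tag", "schema_version",
)

_STAGE_LOOKUP = {s.lower(): s for s in STAGES}
_CYCLE_TAGS = {"G2", "S", "unknown"}


def normalize_stage(label: str) -> str:
    """Map a case-insensitive stage label onto the canonical vocabulary."""
    key = str(label).strip().lower().replace("-", "_")
    if key in _STAGE_LOOKUP:
        return _STAGE_LOOKUP[key]
    raise TableError(
        f"unknown stage label {label!r}; allowed (case-insensitive): {list(STAGES)}"
    )


def write_cells(cells: pd.DataFrame, path: str | Path) -> Path:
    out = cells.copy()
    out["schema_version"] = SCHEMA_VERSION
    out.to_csv(Path(path), index=False)
    return Path(path)


def read_cells(path: str | Path, n_planes: int | None = None) -> pd.DataFrame:
    """Read and validate a cell annotation table.

    Checks cell_id uniqueness, normalizes stage labels, and (when
    ``n_planes`` is given) checks that mid-plane indices are in range.
    """
    cells = pd.read_csv(Path(path))
    missing = set(CELL_COLUMNS) - {"cycle_tag", "schema_version"} - set(cells.columns)
    if missing:
        raise TableError(f"cell table {path} lacks columns {sorted(missing)}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise TableError(f"duplicate cell_id values: {sorted(set(dup))}")
    cells["stage"] = cells["stage"].map(normalize_stage)
    if "cycle_tag" not in cells.columns:
        cells["cycle_tag"] = "unknown"
    bad_cycle = set(cells["cycle_tag"].dropna()) - _CYCLE_TAGS
    if bad_cycle:
        raise TableError(f"unknown cycle_tag values {sorted(bad_cycle)}")
    if n_planes is not None:
        out_of_range = cells[(cells["mid_plane"] < 0) | (cells["mid_plane"] >= n_planes)]
        if len(out_of_range):
            raise TableError(
                f"mid_plane out of range for cells {list(out_of_range['cell_id'])}"
            )
    return cells


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    out = df.copy()
    out["schema_version"] = SCHEMA_VERSION
    out.to_csv(Path(path), index=False)
    return Path(path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


@dataclass
class FieldOfView:
    """One simulated/imaged field: a stack plus its label masks."""

    name: str
    stack: ImageStack
    masks: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.masks.shape != self.stack.voxels.shape[1:]:
            raise ValueError(
                f"mask shape {self.masks.shape} does not match stack "
                f"shape {self.stack.voxels.shape[1:]}"
            )


def write_fields(fields: list[FieldOfView], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fov in fields:
        paths.append(write_stack(fov.stack, out_dir / f"{fov.name}.tif"))
        paths.append(write_masks(fov.masks, out_dir / f"{fov.name}_masks.tif"))
    return paths


def read_fields(out_dir: str | Path) -> list[FieldOfView]:
    out_dir = Path(out_dir)
    fields = []
    for tif in sorted(out_dir.glob("*.tif")):
        if tif.stem.endswith("_masks"):
            continue
        masks_path = out_dir / f"{tif.stem}_masks.tif"
        if not masks_path.exists():
            raise TableError(f"mask file missing for field {tif.stem}: {masks_path}")
        fields.append(
            FieldOfView(name=tif.stem, stack=read_stack(tif), masks=read_masks(masks_path))
        )
    return fields
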