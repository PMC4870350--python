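"""Volume and annotation I/O plus the prescreening subsampling.

A :class:`Volume` is a rank-3 grey-level grid indexed ``data[x, y, z]`` with
physical voxel spacing in mm and the origin at the *center* of voxel
``(0, 0, 0)``; the z axis is the reconstructed slice axis (coarse spacing,
typically 1 mm, versus 0.1 mm in-plane).  Supported on-disk formats are
MetaImage (``.mha``/``.mhd``) and NIfTI (``.nii``/``.nii.gz``) through
SimpleITK, and raw binary with a JSON sidecar for lightweight fixtures.

Annotations are axis-aligned boxes in physical mm, stored as delimited text
with columns ``label, xmin_mm, xmax_mm, ymin_mm, ymax_mm, zmin_mm, zmax_mm``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
from skimage.measure import block_reduce

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Fallback voxel spacing (mm) when a file carries no spacing metadata:
#: the reference reconstruction geometry of 0.1 mm in-plane pitch and a
#: 1 mm slice interval.
DEFAULT_SPACING = (0.1, 0.1, 1.0)

_SITK_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")

ANNOTATION_COLUMNS = [
    "label",
    "xmin_mm",
    "xmax_mm",
    "ymin_mm",
    "ymax_mm",
    "zmin_mm",
    "zmax_mm",
]


@dataclass
class Volume:
    """A 3D grey-level field on a regular anisotropic grid.

    Parameters
    ----------
    data
        Array indexed ``[x, y, z]``; z is the slice axis.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be rank 3, got rank {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValidationError("origin must have 3 components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for ``(..., 3)`` indices."""
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new volume on the same grid carrying ``data`` (a derived field)."""
        if data.shape != self.data.shape:
            raise ValidationError(
                f"derived field shape {data.shape} != grid shape {self.data.shape}"
            )
        return Volume(data, self.spacing, self.origin)

    def same_grid(self, other: "Volume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class Annotation:
    """An axis-aligned region in physical mm (the ground-truth carrier).

    ``box`` is a ``(3, 2)`` array of per-axis ``(min, max)`` bounds.  Voxel
    masks are converted to their tight bounding box on load, since the
    true-positive criterion only needs overlap volume > 0.
    """

    label: str
    box: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3, 2)
        if np.any(self.box[:, 0] > self.box[:, 1]):
            raise ValidationError(f"annotation '{self.label}': box min > max in {self.box}")

    @classmethod
    def from_mask(
        cls,
        label: str,
        mask: np.ndarray,
        spacing: Sequence[float],
        origin: Sequence[float] = (0.0, 0.0, 0.0),
        provenance: str = "mask",
    ) -> "Annotation":
        """Tight physical bounding box of the true voxels of ``mask``.

        Each voxel is treated as a box of extent ``spacing`` centered on its
        physical position.
        """
        idx = np.argwhere(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            raise ValidationError("mask annotation has no foreground voxels")
        sp = np.asarray(spacing, dtype=float)
        og = np.asarray(origin, dtype=float)
        lo = idx.min(axis=0) * sp + og - sp / 2
        hi = idx.max(axis=0) * sp + og + sp / 2
        return cls(label, np.stack([lo, hi], axis=1), provenance)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def _matched_suffix(path: Path) -> str:
    name = path.name.lower()
    for suf in _SITK_SUFFIXES:
        if name.endswith(suf):
            return suf
    if name.endswith(".raw"):
        return ".raw"
    return path.suffix.lower()


def read_volume(path: str | Path, format_hint: str | None = None) -> Volume:
    """Read a volume from MetaImage, NIfTI, or raw + JSON sidecar.

    A raw file is accompanied by ``<stem>.json`` holding ``shape``, ``dtype``
    and optionally ``spacing`` and ``origin``; missing spacing falls back to
    :data:`DEFAULT_SPACING` with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = (format_hint or _matched_suffix(path)).lower()
    if suffix == ".raw" or suffix == "raw":
        return _read_raw(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - depends on ITK message
        raise FormatError(f"cannot read volume from {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a rank-3 volume, got rank {img.GetDimension()}")
    # SimpleITK arrays come back [z, y, x]; transpose to our [x, y, z].
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _read_raw(path: Path) -> Volume:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"raw volume {path} has no sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    try:
        shape = tuple(int(n) for n in meta["shape"])
        dtype = np.dtype(meta["dtype"])
    except KeyError as exc:
        raise FormatError(f"{sidecar}: sidecar missing required key {exc}") from exc
    if len(shape) != 3:
        raise FormatError(f"{sidecar}: shape must have rank 3, got {shape}")
    if "spacing" in meta:
        spacing = tuple(float(s) for s in meta["spacing"])
    else:
        spacing = DEFAULT_SPACING
        logger.warning(
            "%s: no spacing in sidecar; falling back to default %s mm", path, DEFAULT_SPACING
        )
    origin = tuple(float(o) for o in meta.get("origin", (0.0, 0.0, 0.0)))
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: raw size {data.size} does not match sidecar shape {shape}"
        )
    return Volume(data.reshape(shape), spacing, origin)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume; the format follows the file suffix.

    Round-trips bit-identically through :func:`read_volume` (within format
    precision for metadata).  NaN voxels are rejected: they would silently
    poison every downstream convolution.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory {path.parent} does not exist")
    if np.isnan(v.data).any():
        raise ValidationError("volume contains NaN voxels; refusing to write")
    suffix = _matched_suffix(path)
    if suffix == ".raw":
        np.ascontiguousarray(v.data).tofile(path)
        sidecar = {
            "shape": list(v.shape),
            "dtype": v.data.dtype.name,
            "spacing": list(v.spacing),
            "origin": list(v.origin),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(v.data, (2, 1, 0))))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Prescreening subsampling
# ---------------------------------------------------------------------------


def subsample_xy(v: Volume, factor: int) -> Volume:
    """Reduce in-plane resolution by max-pooling ``factor``×``factor`` blocks.

    Each z slice is tiled with non-overlapping windows and the maximum grey
    level is kept as the representative value; edge windows smaller than the
    full block reduce over the voxels available.  The z axis is untouched.
    Output spacing is ``(dx·factor, dy·factor, dz)`` and the origin moves to
    the center of the first block so voxel centers stay physically aligned.
    """
    factor = int(factor)
    if factor < 1:
        raise ValidationError(f"subsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return Volume(v.data.copy(), v.spacing, v.origin)
    pooled = block_reduce(v.data, (factor, factor, 1), np.max, cval=-np.inf)
    dx, dy, dz = v.spacing
    half = (factor - 1) / 2.0
    origin = (v.origin[0] + half * dx, v.origin[1] + half * dy, v.origin[2])
    return Volume(pooled, (dx * factor, dy * factor, dz), origin)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read box annotations from delimited text (CSV; TSV autodetected)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        return []
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    annots: list[Annotation] = []
    for i, row in df.iterrows():
        try:
            box = [
                [float(row["xmin_mm"]), float(row["xmax_mm"])],
                [float(row["ymin_mm"]), float(row["ymax_mm"])],
                [float(row["zmin_mm"]), float(row["zmax_mm"])],
            ]
            annots.append(
                Annotation(str(row["label"]), np.array(box), provenance=str(path))
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ParseError(f"{path}: malformed annotation row {i}: {exc}") from exc
    return annots


def write_annotations(annots: Sequence[Annotation], path: str | Path) -> None:
    rows = []
    for a in annots:
        rows.append(
            {
                "label": a.label,
                "xmin_mm": a.box[0, 0],
                "xmax_mm": a.box[0, 1],
                "ymin_mm": a.box[1, 0],
                "ymax_mm": a.box[1, 1],
                "zmin_mm": a.box[2, 0],
                "zmax_mm": a.box[2, 1],
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
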