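"""SUV image data model and volume I/O.

A PET volume is held as a 3-D grid of standardized uptake values (SUV)
together with its voxel spacing, physical origin, and scan metadata.
SUV is the tissue radioactivity concentration normalized to injected
activity and body weight,

    SUV = activity [Bq/ml] * body weight [g] / injected activity [Bq],

which is dimensionless when tissue density is taken as 1 g/ml.  Volumes
are persisted as NIfTI files with a JSON sidecar that carries the scan
metadata (and spacing/origin at full float precision — the NIfTI header
stores the affine in float32).

Conventions: grid indices are 0-based; the physical position of voxel
(i, j, k) is ``origin + index * spacing`` (voxel-center semantics); the
third axis is axial (slice) direction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PHASES",
    "ScanMeta",
    "SuvImage",
    "InvalidMetadataError",
    "VolumeFormatError",
    "suv_from_activity",
    "read_volume",
    "write_volume",
]

#: Recognized uptake-phase labels: early (~60 min p.i.) and delayed (~120 min).
PHASES = ("early", "delayed")


class InvalidMetadataError(ValueError):
    """Scan metadata is missing or physically impossible."""


class VolumeFormatError(ValueError):
    """Volume file and sidecar disagree or the grid is malformed."""


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata needed for SUV bookkeeping.

    Parameters
    ----------
    subject_id : str
        Case identifier.
    phase : str
        ``"early"`` or ``"delayed"`` uptake phase.
    uptake_time_min : float
        Minutes between injection and scan start.
    injected_activity_Bq : float
        Injected FDG activity in Bq.
    body_weight_g : float
        Body weight in grams (the unit of the SUV formula; convert from
        kg at ingestion).
    """

    subject_id: str
    phase: str
    uptake_time_min: float
    injected_activity_Bq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidMetadataError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not self.uptake_time_min > 0:
            raise InvalidMetadataError("uptake_time_min must be > 0")
        if not self.injected_activity_Bq > 0:
            raise InvalidMetadataError("injected_activity_Bq must be > 0")
        if not self.body_weight_g > 0:
            raise InvalidMetadataError("body_weight_g must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SuvImage:
    """A 3-D SUV grid with geometry and scan metadata.

    ``values`` has one dimensionless SUV per voxel; ``spacing`` are the
    voxel edge lengths in mm; ``origin`` is the physical position of the
    first voxel center in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    meta: ScanMeta
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise VolumeFormatError("values must be a non-empty 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("SUV values must be finite")
        if np.any(self.values < 0):
            raise VolumeFormatError("SUV values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (spacing product in mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


def suv_from_activity(
    activity_Bq_per_ml: float | np.ndarray,
    body_weight_g: float,
    injected_Bq: float,
) -> float | np.ndarray:
    """Convert a tissue activity concentration to SUV.

    SUV = activity (Bq/ml) x body weight (g) / injected activity (Bq).
    Accepts scalars or arrays of activities.
    """
    if not body_weight_g > 0:
        raise InvalidMetadataError("body_weight_g must be > 0")
    if not injected_Bq > 0:
        raise InvalidMetadataError("injected_Bq must be > 0")
    activity = np.asarray(activity_Bq_per_ml, dtype=float)
    if np.any(activity < 0):
        raise ValueError("activity must be >= 0")
    suv = activity * float(body_weight_g) / float(injected_Bq)
    return float(suv) if np.isscalar(activity_Bq_per_ml) else suv


# --- persistence -----------------------------------------------------------

_SIDECAR_META_KEYS = (
    "subject_id",
    "phase",
    "uptake_time_min",
    "injected_activity_Bq",
    "body_weight_g",
)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(img: SuvImage, path: str | Path, *, overwrite: bool = False) -> None:
    """Write a :class:`SuvImage` as NIfTI plus a JSON metadata sidecar.

    Refuses to clobber an existing volume unless ``overwrite`` is set.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not overwrite and (path.exists() or sidecar.exists()):
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    affine = np.diag(list(img.spacing) + [1.0])
    affine[:3, 3] = img.origin
    nii = nib.Nifti1Image(img.values, affine)
    nii.set_data_dtype(img.values.dtype)
    nii.to_filename(str(path))
    payload = {
        **img.meta.to_dict(),
        "spacing_mm": list(img.spacing),
        "origin_mm": list(img.origin),
        "shape": list(img.shape),
    }
    sidecar.write_text(json.dumps(payload, indent=1))


def read_volume(path: str | Path) -> SuvImage:
    """Read a NIfTI volume + JSON sidecar pair written by :func:`write_volume`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise InvalidMetadataError(f"metadata sidecar {sidecar} not found")
    payload = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_META_KEYS if k not in payload]
    if missing:
        raise InvalidMetadataError(f"sidecar missing required fields: {missing}")
    meta = ScanMeta(**{k: payload[k] for k in _SIDECAR_META_KEYS})

    nii = nib.load(str(path))
    values = np.asarray(nii.dataobj, dtype=nii.get_data_dtype())
    if "shape" in payload and list(values.shape) != list(payload["shape"]):
        raise VolumeFormatError(
            f"volume shape {values.shape} does not match sidecar shape {payload['shape']}"
        )
    # Sidecar geometry is authoritative (full float precision); fall back to
    # the NIfTI affine for volumes written by other tools.
    if "spacing_mm" in payload:
        spacing = tuple(payload["spacing_mm"])
        origin = tuple(payload.get("origin_mm", (0.0, 0.0, 0.0)))
    else:
        affine = nii.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        origin = tuple(float(x) for x in affine[:3, 3])
    return SuvImage(values=values, spacing=spacing, origin=origin, meta=meta)
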