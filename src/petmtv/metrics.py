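"""Per-lesion volumetric and intensity metrics.

* **SUVmax** — hottest voxel inside the VOI.
* **SUVpeak** — mean SUV over voxels whose centers fall within a 1-ml
  sphere (12 mm diameter) centered on the SUVmax voxel.
* **MTV** — metabolic tumor volume: segmented voxel count x voxel volume
  (ml).  With a 4.0 x 4.0 x 2.0 mm grid one voxel is 0.032 ml.
* **SUVmean** — mean SUV over the segmented region; undefined (NaN) for
  an empty region, never reported as 0.
* **TLG** — total lesion glycolysis: MTV x SUVmean (ml.SUV; the "g"
  label seen in the literature assumes tissue density 1 g/ml), 0 for an
  empty region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .delineate import MethodSpec, Segmentation, Voi
from .image import SuvImage

__all__ = [
    "VolumetricResult",
    "compute_suvmax",
    "compute_suvpeak",
    "compute_metrics",
]


@dataclass
class VolumetricResult:
    """All metrics for one (lesion, phase, observation, method) cell."""

    subject_id: str
    phase: str
    operator_id: int
    observation_id: int
    method: MethodSpec
    suv_max: float
    mtv_ml: float
    tlg_ml_suv: float
    suv_mean: float = float("nan")  # NaN when the segmentation is empty
    suv_peak: float | None = None
    success: bool = True


def compute_suvmax(img: SuvImage, voi: Voi) -> float:
    """Maximum SUV over the VOI."""
    if not voi.mask.any():
        raise ValueError("VOI is empty")
    return float(img.values[voi.mask].max())


def compute_suvpeak(img: SuvImage, voi: Voi, sphere_diameter_mm: float = 12.0) -> float:
    """Mean SUV within a sphere centered on the hottest VOI voxel.

    The default 12-mm diameter encloses ~1 ml.  Voxels are included when
    their centers lie within the sphere; the sphere may extend beyond the
    VOI but is clipped (with a warning) at the grid edge.
    """
    if not voi.mask.any():
        raise ValueError("VOI is empty")
    masked = np.where(voi.mask, img.values, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(masked)), img.shape)
    center = np.array([img.voxel_centers_mm(a)[peak_idx[a]] for a in range(3)])
    radius = sphere_diameter_mm / 2.0
    lo, hi = [], []
    clipped = False
    for a in range(3):
        r_vox = int(np.ceil(radius / img.spacing[a]))
        lo.append(peak_idx[a] - r_vox)
        hi.append(peak_idx[a] + r_vox + 1)
        if lo[a] < 0 or hi[a] > img.shape[a]:
            clipped = True
        lo[a] = max(lo[a], 0)
        hi[a] = min(hi[a], img.shape[a])
    if clipped:
        warnings.warn("SUVpeak sphere clipped at the grid edge", stacklevel=2)
    axes = [img.voxel_centers_mm(a)[lo[a]:hi[a]] - center[a] for a in range(3)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    inside = dx * dx + dy * dy + dz * dz <= radius * radius
    block = img.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return float(block[inside].mean())


def compute_metrics(
    img: SuvImage,
    seg: Segmentation,
    voi: Voi,
    *,
    with_peak: bool = False,
) -> VolumetricResult:
    """Assemble MTV / SUVmean / TLG (and VOI-level SUVmax) for a segmentation."""
    if seg.mask.shape != img.shape:
        raise ValueError(
            f"segmentation shape {seg.mask.shape} does not match image {img.shape}"
        )
    n_vox = int(seg.mask.sum())
    mtv = n_vox * img.voxel_volume_ml
    if n_vox > 0:
        suv_mean = float(img.values[seg.mask].mean())
        tlg = mtv * suv_mean
    else:
        suv_mean = float("nan")
        tlg = 0.0
    return VolumetricResult(
        subject_id=img.meta.subject_id,
        phase=img.meta.phase,
        operator_id=voi.operator_id,
        observation_id=voi.observation_id,
        method=seg.method,
        suv_max=compute_suvmax(img, voi),
        suv_peak=compute_suvpeak(img, voi) if with_peak else None,
        suv_mean=suv_mean,
        mtv_ml=mtv,
        tlg_ml_suv=tlg,
        success=seg.success,
    )
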