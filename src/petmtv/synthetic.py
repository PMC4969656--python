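"""Synthetic dual-time-point PET phantom cohort with known ground truth.

Emulates a preoperative chest FDG-PET protocol: an ellipsoidal lesion in
a lung field (low background, SUV ~0.5) next to a mediastinal blood-pool
slab (SUV ~1.0), scanned at an early (~60 min) and a delayed (~120 min)
uptake phase.  Between the phases the lesion accumulates tracer (default
delayed/early factor 1.22, matching the typical SUVmax rise of malignant
lesions) while the backgrounds wash out (lung x0.85, mediastinum x0.90).
The piecewise-constant compartment image is blurred with the scanner
point-spread function (Gaussian, default 8.4 mm FWHM), Gaussian noise is
added in SUV space, and negatives are clipped.  All randomness is seeded;
the same seed yields bitwise-identical images.

Ground truth records the voxelized lesion (centers inside the ellipsoid)
so that noise-free, blur-free phantoms are recovered *exactly* by any
threshold between background and lesion SUV.

Simulated operators draw generous per-slice polygons around the visible
(blurred) lesion with a random extra margin, mirroring the manual-VOI
step; a margin that would clip supra-threshold voxels raises an error
instead of silently corrupting reproducibility analyses.

The printed 50-patient cohort table ships as a CSV fixture
(:func:`load_table1_fixture`).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.ndimage import gaussian_filter

from .delineate import Voi, build_voi, PolygonRoi
from .image import ScanMeta, SuvImage

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomBundle",
    "CohortRecord",
    "VoiClipError",
    "make_phantom",
    "simulate_operator_voi",
    "make_cohort",
    "load_table1_fixture",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class VoiClipError(ValueError):
    """A simulated VOI would cut into the supra-threshold lesion signal."""


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion: position/semi-axes in mm, uptake per phase."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv_early: float
    uptake_factor: float = 1.22  # delayed / early lesion uptake

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be > 0")
        if not self.suv_early > 0 or not self.uptake_factor > 0:
            raise ValueError("lesion uptake must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Scanner/background model for one phantom scan pair."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 2.0)
    lung_suv: float = 0.5
    lung_delayed_factor: float = 0.85
    mediastinum_suv: float = 1.0
    mediastinum_delayed_factor: float = 0.90
    mediastinum_halfwidth_mm: float = 24.0
    psf_fwhm_mm: float = 8.4
    noise_sd: float = 0.15  # additive Gaussian noise in SUV units
    rng_seed: int = 0
    early_uptake_min: float = 60.0
    delayed_uptake_min: float = 120.0
    injected_activity_Bq: float = 2.24e8
    body_weight_g: float = 56000.0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Exact voxelized lesion for one phantom."""

    lesion: LesionSpec
    spec: PhantomSpec
    lesion_mask: np.ndarray  # voxel centers inside the ellipsoid
    true_volume_ml: float
    suv_early: float
    suv_delayed: float


@dataclass
class PhantomBundle:
    """One synthetic subject: both phases, truth, and all operator VOIs."""

    subject_id: str
    early: SuvImage
    delayed: SuvImage
    truth: GroundTruth
    vois: dict = field(default_factory=dict)  # vois[phase][(op, ob)] -> Voi


def _voxel_centers(spec: PhantomSpec):
    return [
        spec.spacing[a] * np.arange(spec.shape[a], dtype=float)
        for a in range(3)
    ]


def make_phantom(
    spec: PhantomSpec, lesion: LesionSpec, subject_id: str = "phantom"
) -> tuple[SuvImage, SuvImage, GroundTruth]:
    """Simulate the early/delayed image pair for one lesion.

    Pipeline: compartment map (lesion / mediastinum slab / lung) ->
    per-phase uptake scaling -> Gaussian PSF blur -> additive Gaussian
    noise -> clip at 0.  Deterministic per ``spec.rng_seed``.
    """
    xs, ys, zs = _voxel_centers(spec)
    gx = xs[:, None, None]
    gy = ys[None, :, None]
    gz = zs[None, None, :]
    cx, cy, cz = lesion.center_mm
    a, b, c = lesion.radii_mm
    lesion_mask = (
        ((gx - cx) / a) ** 2 + ((gy - cy) / b) ** 2 + ((gz - cz) / c) ** 2 <= 1.0
    )
    if not lesion_mask.any():
        raise ValueError("lesion contains no voxel centers")
    edge_touch = (
        lesion_mask[0].any() or lesion_mask[-1].any()
        or lesion_mask[:, 0].any() or lesion_mask[:, -1].any()
        or lesion_mask[:, :, 0].any() or lesion_mask[:, :, -1].any()
    )
    if edge_touch:
        raise ValueError("lesion extends to the grid boundary")
    x_mid = xs.mean()
    med_mask = np.broadcast_to(
        np.abs(gx - x_mid) <= spec.mediastinum_halfwidth_mm, spec.shape
    )

    rng = np.random.default_rng(spec.rng_seed)
    voxel_volume_ml = float(np.prod(spec.spacing)) / 1000.0
    truth = GroundTruth(
        lesion=lesion,
        spec=spec,
        lesion_mask=lesion_mask,
        true_volume_ml=float(lesion_mask.sum()) * voxel_volume_ml,
        suv_early=lesion.suv_early,
        suv_delayed=lesion.suv_early * lesion.uptake_factor,
    )

    images = []
    for phase in ("early", "delayed"):
        if phase == "early":
            lung, med, tumor = spec.lung_suv, spec.mediastinum_suv, lesion.suv_early
            uptake_min = spec.early_uptake_min
        else:
            lung = spec.lung_suv * spec.lung_delayed_factor
            med = spec.mediastinum_suv * spec.mediastinum_delayed_factor
            tumor = lesion.suv_early * lesion.uptake_factor
            uptake_min = spec.delayed_uptake_min
        vol = np.full(spec.shape, lung, dtype=np.float64)
        vol[med_mask] = med
        vol[lesion_mask] = tumor
        if spec.psf_fwhm_mm > 0:
            sigma_vox = [
                spec.psf_fwhm_mm / _FWHM_TO_SIGMA / s for s in spec.spacing
            ]
            vol = gaussian_filter(vol, sigma=sigma_vox)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        vol = np.maximum(vol, 0.0).astype(np.float32)
        meta = ScanMeta(
            subject_id=subject_id,
            phase=phase,
            uptake_time_min=uptake_min,
            injected_activity_Bq=spec.injected_activity_Bq,
            body_weight_g=spec.body_weight_g,
        )
        images.append(SuvImage(values=vol, spacing=spec.spacing, meta=meta))
    return images[0], images[1], truth


def simulate_operator_voi(
    truth: GroundTruth,
    img: SuvImage,
    margin_mm: tuple[float, float] = (8.0, 16.0),
    rng_seed: int = 0,
    *,
    operator_id: int = 1,
    observation_id: int = 1,
    floor_suv: float = 2.0,
    n_vertices: int = 32,
) -> Voi:
    """Draw generous per-slice polygons around the (blurred) lesion.

    The per-slice outline is the lesion cross-section seen through the
    scanner PSF — the geometric cross-section widened by the in-plane
    extent of blur from neighboring slices plus one FWHM — dilated by a
    random margin drawn uniformly from ``margin_mm`` for every slice.
    Slices are drawn over the lesion's axial extent plus one FWHM of
    padding, emulating an operator enclosing everything visible.

    Raises :class:`VoiClipError` if the resulting VOI fails to contain
    either the true lesion voxels or any voxel with SUV >= ``floor_suv``
    near the lesion (the smallest analysis threshold must never be
    clipped, otherwise reproducibility is corrupted by the VOI itself).
    """
    rng = np.random.default_rng(rng_seed)
    spec = truth.spec
    cx, cy, cz = truth.lesion.center_mm
    a, b, c = truth.lesion.radii_mm
    fwhm = spec.psf_fwhm_mm
    zs = img.voxel_centers_mm(2)
    z_lo, z_hi = cz - c - fwhm, cz + c + fwhm
    slices = np.nonzero((zs >= z_lo) & (zs <= z_hi))[0]
    if slices.size == 0:
        raise VoiClipError("lesion axial extent covers no slices")

    def cross_section(z: float) -> float:
        u = (z - cz) / c
        return float(np.sqrt(max(0.0, 1.0 - u * u)))

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    rois = []
    for k in slices:
        z = zs[k]
        # widest geometric cross-section within one FWHM of this slice,
        # as the blurred image shows it
        s = max(
            cross_section(z_neigh)
            for z_neigh in np.linspace(z - fwhm, z + fwhm, 9)
            if z_lo <= z_neigh <= z_hi
        )
        margin = rng.uniform(*margin_mm) if margin_mm[0] < margin_mm[1] else margin_mm[0]
        rx = max(a * s, 2.0) + fwhm + margin
        ry = max(b * s, 2.0) + fwhm + margin
        verts = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
        rois.append(PolygonRoi(slice_index=int(k), vertices=verts))
    voi = build_voi(rois, img, operator_id=operator_id, observation_id=observation_id)

    if np.any(truth.lesion_mask & ~voi.mask):
        raise VoiClipError("VOI clips the true lesion volume")
    # supra-floor voxels near the lesion must all be enclosed
    idx = np.argwhere(truth.lesion_mask)
    pad_mm = margin_mm[1] + 2.0 * fwhm
    lo = idx.min(axis=0) - np.ceil(pad_mm / np.array(img.spacing)).astype(int)
    hi = idx.max(axis=0) + 1 + np.ceil(pad_mm / np.array(img.spacing)).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, img.shape)
    box = tuple(slice(lo[i], hi[i]) for i in range(3))
    hot = img.values[box] >= floor_suv
    if np.any(hot & ~voi.mask[box]):
        raise VoiClipError(
            f"VOI clips voxels at or above SUV {floor_suv} near the lesion"
        )
    return voi


def make_cohort(
    n: int,
    base_seed: int = 0,
    *,
    spec: PhantomSpec | None = None,
    margin_mm: tuple[float, float] = (8.0, 16.0),
    volume_range_ml: tuple[float, float] = (1.0, 60.0),
    suv_range: tuple[float, float] = (4.0, 20.0),
    uptake_factor_mean: float = 1.22,
    uptake_factor_sd: float = 0.05,
) -> list[PhantomBundle]:
    """Generate a heterogeneous cohort of dual-time-point phantoms.

    Lesion volumes are log-uniform over ``volume_range_ml``, lesion
    uptakes log-uniform over ``suv_range``, shapes mildly anisotropic
    ellipsoids, positions random within a lung field clear of the
    mediastinum and grid edges.  Each subject gets early+delayed images
    and four operator VOIs per phase (Op1Ob1 ... Op2Ob2), all seeded from
    ``base_seed``.
    """
    if n < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    base = spec or PhantomSpec()
    rng = np.random.default_rng(base_seed)
    bundles = []
    ext = [base.spacing[i] * (base.shape[i] - 1) for i in range(3)]
    for i in range(n):
        vol_ml = float(np.exp(rng.uniform(*np.log(volume_range_ml))))
        r = (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        f1, f2 = rng.uniform(0.9, 1.12, size=2)
        radii = (r * f1, r * f2, r / (f1 * f2))
        suv = float(np.exp(rng.uniform(*np.log(suv_range))))
        uf = float(np.clip(rng.normal(uptake_factor_mean, uptake_factor_sd), 1.02, 1.45))
        side = rng.choice([-1.0, 1.0])
        x_mid = ext[0] / 2.0
        off_lo = base.mediastinum_halfwidth_mm + radii[0] + 8.0
        off_hi = x_mid - radii[0] - 24.0
        cx = x_mid + side * rng.uniform(off_lo, min(off_hi, off_lo + 40.0))
        cy = rng.uniform(radii[1] + 24.0, ext[1] - radii[1] - 24.0)
        cz = rng.uniform(radii[2] + 22.0, ext[2] - radii[2] - 22.0)
        lesion = LesionSpec(
            center_mm=(cx, cy, cz), radii_mm=radii, suv_early=suv, uptake_factor=uf
        )
        phantom_seed = int(rng.integers(2**31))
        subj_spec = dataclasses.replace(base, rng_seed=phantom_seed)
        subject_id = f"S{i + 1:03d}"
        early, delayed, truth = make_phantom(subj_spec, lesion, subject_id=subject_id)
        vois: dict = {}
        for phase, img in (("early", early), ("delayed", delayed)):
            vois[phase] = {}
            for op in (1, 2):
                for ob in (1, 2):
                    voi_seed = int(rng.integers(2**31))
                    vois[phase][(op, ob)] = simulate_operator_voi(
                        truth, img, margin_mm=margin_mm, rng_seed=voi_seed,
                        operator_id=op, observation_id=ob,
                    )
        bundles.append(PhantomBundle(
            subject_id=subject_id, early=early, delayed=delayed,
            truth=truth, vois=vois,
        ))
    return bundles


# --- printed cohort table --------------------------------------------------


@dataclass(frozen=True)
class CohortRecord:
    """One row of the patient-characteristics table."""

    case: int
    age_range_y: str
    weight_kg: float
    dosage_MBq: float
    dosage_per_weight_MBq_kg: float
    tumor_location: str
    pathology: str
    tnm: str
    stage: str

    def __post_init__(self) -> None:
        # printed dosage/weight must agree with dosage / weight up to the
        # table's one-decimal rounding
        recomputed = self.dosage_MBq / self.weight_kg
        if abs(recomputed - self.dosage_per_weight_MBq_kg) > 0.06:
            raise ValueError(
                f"case {self.case}: dosage/weight {self.dosage_per_weight_MBq_kg} "
                f"inconsistent with {recomputed:.3f}"
            )


def load_table1_fixture() -> list[CohortRecord]:
    """The 50-patient characteristics table shipped with the package."""
    path = resources.files("petmtv").joinpath(
        "data/table1_patient_characteristics.csv"
    )
    records = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(CohortRecord(
                case=int(row["case"]),
                age_range_y=row["age_range_y"],
                weight_kg=float(row["weight_kg"]),
                dosage_MBq=float(row["dosage_MBq"]),
                dosage_per_weight_MBq_kg=float(row["dosage_per_weight_MBq_kg"]),
                tumor_location=row["tumor_location"],
                pathology=row["pathology"],
                tnm=row["tnm"],
                stage=row["stage"],
            ))
    return records
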