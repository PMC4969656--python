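"""Tumor delineation: manual VOIs and the three boundary methods.

The workflow mirrors clinical volumetric PET reading.  An operator draws
generous polygonal ROIs slice by slice around the tumor; their union is a
3-D volume of interest (VOI).  Within the VOI the tumor boundary is then
delineated by one of three methods:

1. **Absolute SUV threshold** (``MTV_p``): voxels with SUV >= p, for a
   predetermined p such as 2.0, 2.5, 3.0 or 3.5.
2. **Fixed %SUVmax threshold** (``MTV_q%``): voxels with SUV >= q% of the
   SUVmax inside the VOI (q = 35, 40 or 45).  Invariant under global
   rescaling of the image, unlike the absolute method.
3. **Adaptive region growing** (``MTV_ARG``): seeded at the hottest voxel,
   a neighbor is admitted when

       neighbor SUV >= (mean of current region) x (threshold fraction).

   Sweeping the fraction from 100% down to 0% yields a volume curve with a
   sharp jump where growth floods into background; the tumor region is the
   region just above that jump.  Given the image, the result depends only
   on the seed voxel, which is why repeated and inter-operator measurements
   agree exactly as long as the VOIs contain the same hottest voxel.

Threshold comparisons are inclusive (>=) so that q = 100% and flat
plateaus are well defined.  ARG candidate processing is highest-SUV-first
with a lexicographic index tie-break, which makes the order-dependent
running mean fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from numba import njit
from scipy import ndimage
from shapely.geometry import Polygon

from .image import SuvImage

__all__ = [
    "PolygonRoi",
    "Voi",
    "MethodSpec",
    "Segmentation",
    "ArgCurve",
    "InvalidRoiError",
    "EmptyVoiError",
    "rasterize_roi",
    "build_voi",
    "segment_absolute",
    "segment_percent_max",
    "arg_grow",
    "arg_volume_curve",
    "detect_knee",
    "segment_arg",
    "rois_to_json",
    "rois_from_json",
]


class InvalidRoiError(ValueError):
    """A polygonal ROI is degenerate or self-intersecting."""


class EmptyVoiError(ValueError):
    """A VOI rasterized to no voxels."""


@dataclass(frozen=True)
class PolygonRoi:
    """A closed polygon drawn on one axial slice.

    ``vertices`` are ordered in-plane points in mm, shape (n, 2); the
    polygon is implicitly closed.  Must have >= 3 vertices and be
    non-self-intersecting.
    """

    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidRoiError("a ROI needs >= 3 in-plane (x, y) vertices")
        object.__setattr__(self, "vertices", verts)
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidRoiError("ROI polygon is self-intersecting or degenerate")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class Voi:
    """A 3-D volume of interest: union of per-slice polygon masks."""

    mask: np.ndarray
    source_rois: list[PolygonRoi] = field(default_factory=list)
    operator_id: int = 1
    observation_id: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise EmptyVoiError("VOI mask must be 3-D")
        if not self.mask.any():
            raise EmptyVoiError("VOI mask is empty")

    @property
    def key(self) -> tuple[int, int]:
        return (self.operator_id, self.observation_id)


@dataclass(frozen=True)
class MethodSpec:
    """Descriptor of a delineation method.

    kind: ``"absolute"`` (threshold ``p`` in SUV), ``"percent_max"``
    (threshold ``q`` in % of VOI SUVmax) or ``"arg"``.
    """

    kind: str
    p: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "percent_max", "arg"):
            raise ValueError(f"unknown method kind {self.kind!r}")
        if self.kind == "absolute" and not (self.p is not None and self.p > 0):
            raise ValueError("absolute method requires p > 0")
        if self.kind == "percent_max" and not (self.q is not None and 0 < self.q <= 100):
            raise ValueError("percent_max method requires 0 < q <= 100")

    @property
    def label(self) -> str:
        """Parameter suffix as printed in reports: ``2.5``, ``40%`` or ``ARG``."""
        if self.kind == "absolute":
            return f"{self.p:.1f}"
        if self.kind == "percent_max":
            return f"{self.q:g}%"
        return "ARG"


@dataclass
class Segmentation:
    """A binary tumor mask plus the method and threshold that produced it."""

    mask: np.ndarray
    method: MethodSpec
    applied_threshold_suv: float
    seed: tuple[int, int, int] | None = None
    success: bool = True


@dataclass
class ArgCurve:
    """ARG threshold sweep: region volume at each descending growth fraction."""

    thresholds: np.ndarray  # descending fractions in [0, 1]
    volumes_ml: np.ndarray
    knee_index: int | None = None
    # admission bookkeeping so the region at any fraction can be rebuilt
    # without re-running the growth (internal)
    _order: np.ndarray | None = None
    _prefix_len: np.ndarray | None = None
    _bounds: tuple[slice, slice, slice] | None = None
    _shape: tuple[int, int, int] | None = None

    def region_mask(self, index: int) -> np.ndarray:
        """Full-grid boolean mask of the region at ``thresholds[index]``."""
        if self._order is None:
            raise ValueError("curve does not carry admission bookkeeping")
        mask = np.zeros(self._shape, dtype=bool)
        sub = np.zeros(tuple(s.stop - s.start for s in self._bounds), dtype=bool)
        sub.ravel()[self._order[: self._prefix_len[index]]] = True
        mask[self._bounds] = sub
        return mask


# --- VOI construction ------------------------------------------------------


def rasterize_roi(roi: PolygonRoi, img: SuvImage) -> np.ndarray:
    """Rasterize one polygon onto the in-plane grid of ``img``.

    A pixel belongs to the ROI iff its center lies inside the polygon
    (even-odd rule); centers exactly on the boundary count as inside.
    Returns a 2-D boolean mask of shape ``img.shape[:2]``.
    """
    nx, ny, nz = img.shape
    if not 0 <= roi.slice_index < nz:
        raise InvalidRoiError(
            f"slice_index {roi.slice_index} outside grid with {nz} slices"
        )
    poly = roi.polygon()
    xs = img.voxel_centers_mm(0)
    ys = img.voxel_centers_mm(1)
    # restrict the point-in-polygon test to the polygon's bounding box
    minx, miny, maxx, maxy = poly.bounds
    i0, i1 = np.searchsorted(xs, [minx, maxx])
    j0, j1 = np.searchsorted(ys, [miny, maxy])
    i0, j0 = max(i0 - 1, 0), max(j0 - 1, 0)
    i1, j1 = min(i1 + 1, nx), min(j1 + 1, ny)
    mask = np.zeros((nx, ny), dtype=bool)
    if i1 <= i0 or j1 <= j0:
        return mask
    gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel())
    mask[i0:i1, j0:j1] = inside.reshape(gx.shape)
    return mask


def build_voi(
    rois: list[PolygonRoi],
    img: SuvImage,
    operator_id: int = 1,
    observation_id: int = 1,
) -> Voi:
    """Combine per-slice ROIs into a 3-D VOI (union of rasterizations)."""
    if not rois:
        raise InvalidRoiError("at least one ROI is required")
    mask = np.zeros(img.shape, dtype=bool)
    for roi in rois:
        plane = rasterize_roi(roi, img)  # validates the slice index
        mask[:, :, roi.slice_index] |= plane
    if not mask.any():
        raise EmptyVoiError("ROIs rasterized to an empty VOI")
    return Voi(mask=mask, source_rois=list(rois),
               operator_id=operator_id, observation_id=observation_id)


# --- threshold methods -----------------------------------------------------


def _keep_hottest_component(mask: np.ndarray, values: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    flat = np.where(mask, values, -np.inf)
    hottest = labels[np.unravel_index(np.argmax(flat), mask.shape)]
    return labels == hottest


def segment_absolute(
    img: SuvImage, voi: Voi, p: float, *, connected_only: bool = False
) -> Segmentation:
    """Absolute SUV threshold: voxels in the VOI with SUV >= p.

    An empty result is a valid outcome (MTV 0) — with thresholds of 3.0+
    a substantial fraction of low-uptake lesions segments to zero volume.
    ``connected_only`` optionally keeps only the component containing the
    hottest voxel (off by default: plain thresholding).
    """
    method = MethodSpec(kind="absolute", p=float(p))
    mask = voi.mask & (img.values >= p)
    if connected_only and mask.any():
        mask = _keep_hottest_component(mask, img.values)
    return Segmentation(mask=mask, method=method, applied_threshold_suv=float(p))


def segment_percent_max(
    img: SuvImage, voi: Voi, q: float, *, connected_only: bool = False
) -> Segmentation:
    """Fixed %SUVmax threshold: voxels with SUV >= (q/100) x SUVmax(VOI).

    Always contains the hottest voxel, hence never empty.  Invariant under
    global positive rescaling of the image.
    """
    method = MethodSpec(kind="percent_max", q=float(q))
    suvmax = float(img.values[voi.mask].max())
    threshold = (q / 100.0) * suvmax
    mask = voi.mask & (img.values >= threshold)
    if connected_only:
        mask = _keep_hottest_component(mask, img.values)
    return Segmentation(mask=mask, method=method, applied_threshold_suv=threshold)


# --- adaptive region growing ----------------------------------------------

_OFFSETS_6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)
_OFFSETS_26 = np.array(
    [[di, dj, dk] for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
     if (di, dj, dk) != (0, 0, 0)],
    dtype=np.int64,
)


@njit(cache=False)
def _heap_push(hv, hi, size, v, i):
    hv[size] = v
    hi[size] = i
    c = size
    while c > 0:
        parent = (c - 1) >> 1
        # higher SUV first; lexicographic (smaller flat index) tie-break
        if hv[c] > hv[parent] or (hv[c] == hv[parent] and hi[c] < hi[parent]):
            hv[c], hv[parent] = hv[parent], hv[c]
            hi[c], hi[parent] = hi[parent], hi[c]
            c = parent
        else:
            break
    return size + 1


@njit(cache=False)
def _heap_pop(hv, hi, size):
    v = hv[0]
    i = hi[0]
    size -= 1
    hv[0] = hv[size]
    hi[0] = hi[size]
    c = 0
    while True:
        left = 2 * c + 1
        if left >= size:
            break
        best = left
        right = left + 1
        if right < size and (
            hv[right] > hv[left] or (hv[right] == hv[left] and hi[right] < hi[left])
        ):
            best = right
        if hv[best] > hv[c] or (hv[best] == hv[c] and hi[best] < hi[c]):
            hv[c], hv[best] = hv[best], hv[c]
            hi[c], hi[best] = hi[best], hi[c]
            c = best
        else:
            break
    return v, i, size


@njit(cache=False)
def _flood(vals, bx, by, bz, seed, frac_stop, offsets):
    """Grow from ``seed`` admitting the hottest frontier voxel while

        value >= (running region mean) x frac_stop.

    Runs on the flat C-ordered array of the cropped bounds box.  Returns
    the admission order, the admission ratio value/mean-before-admission
    for every admitted voxel (a large sentinel for the seed), and the
    number of admissions.  Because the heap order does not depend on the
    fraction, the region grown at any fraction f >= frac_stop is exactly
    the longest admission prefix whose ratios all stay >= f.
    """
    n = vals.size
    nb = offsets.shape[0]
    in_region = np.zeros(n, dtype=np.bool_)
    in_heap = np.zeros(n, dtype=np.bool_)
    order = np.empty(n, dtype=np.int64)
    ratios = np.empty(n, dtype=np.float64)
    hv = np.empty(n + 1, dtype=np.float64)
    hi = np.empty(n + 1, dtype=np.int64)

    in_region[seed] = True
    order[0] = seed
    ratios[0] = 1.0e300
    total = vals[seed]
    count = 1
    size = 0

    # push neighbors of the newest member; re-pushes are skipped via in_heap
    current = seed
    while True:
        ci = current // (by * bz)
        cj = (current // bz) % by
        ck = current % bz
        for m in range(nb):
            ni = ci + offsets[m, 0]
            nj = cj + offsets[m, 1]
            nk = ck + offsets[m, 2]
            if 0 <= ni < bx and 0 <= nj < by and 0 <= nk < bz:
                f = (ni * by + nj) * bz + nk
                if not in_region[f] and not in_heap[f]:
                    in_heap[f] = True
                    size = _heap_push(hv, hi, size, vals[f], f)
        if size == 0:
            break
        v, idx, size = _heap_pop(hv, hi, size)
        in_heap[idx] = False
        mean = total / count
        if mean <= 0.0:
            ratio = 1.0e300
        else:
            ratio = v / mean
        if ratio < frac_stop:
            break
        in_region[idx] = True
        order[count] = idx
        ratios[count] = ratio
        total += v
        count += 1
        current = idx
    return order[:count], ratios[:count], count


def _normalize_bounds(
    bounds: tuple | None, shape: tuple[int, int, int]
) -> tuple[slice, slice, slice]:
    if bounds is None:
        return tuple(slice(0, s) for s in shape)
    out = []
    for b, s in zip(bounds, shape):
        if isinstance(b, slice):
            start = 0 if b.start is None else b.start
            stop = s if b.stop is None else b.stop
        else:
            start, stop = b
        if not (0 <= start < stop <= s):
            raise ValueError(f"bounds {bounds} do not fit grid shape {shape}")
        out.append(slice(int(start), int(stop)))
    return tuple(out)


def _run_flood(
    img: SuvImage,
    seed: tuple[int, int, int],
    bounds: tuple[slice, slice, slice],
    frac_stop: float,
    connectivity: int,
):
    offs = {6: _OFFSETS_6, 26: _OFFSETS_26}[connectivity]
    sub = np.ascontiguousarray(img.values[bounds], dtype=np.float64)
    bx, by, bz = sub.shape
    si, sj, sk = (seed[a] - bounds[a].start for a in range(3))
    if not (0 <= si < bx and 0 <= sj < by and 0 <= sk < bz):
        raise ValueError(f"seed {seed} outside growth bounds")
    seed_flat = (si * by + sj) * bz + sk
    order, ratios, count = _flood(sub.ravel(), bx, by, bz, seed_flat, frac_stop, offs)
    return order, ratios, count, sub.shape


def arg_grow(
    img: SuvImage,
    seed: tuple[int, int, int],
    fraction: float,
    bounds: tuple | None = None,
    *,
    connectivity: int = 6,
) -> np.ndarray:
    """Grow a region from ``seed`` at a fixed threshold fraction.

    Returns a full-grid boolean mask.  Growth is restricted to ``bounds``
    (a triple of slices or (start, stop) pairs; defaults to the whole
    grid).  Every admitted voxel satisfied
    ``value >= running_mean * fraction`` at the moment of admission.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    b = _normalize_bounds(bounds, img.shape)
    order, _, count, bshape = _run_flood(img, seed, b, float(fraction), connectivity)
    mask = np.zeros(img.shape, dtype=bool)
    sub = np.zeros(bshape, dtype=bool)
    sub.ravel()[order[:count]] = True
    mask[b] = sub
    return mask


def arg_volume_curve(
    img: SuvImage,
    seed: tuple[int, int, int],
    bounds: tuple | None = None,
    *,
    step_percent: float = 1.0,
    connectivity: int = 6,
) -> ArgCurve:
    """Sweep the growth fraction from 100% down to 0% and record volumes.

    Volume is non-decreasing as the fraction decreases; the region at each
    fraction is an admission prefix of a single flood (see :func:`_flood`),
    so one growth pass yields the whole curve.
    """
    b = _normalize_bounds(bounds, img.shape)
    order, ratios, count, bshape = _run_flood(img, seed, b, 0.0, connectivity)
    n_steps = int(round(100.0 / step_percent))
    fractions = np.linspace(1.0, 0.0, n_steps + 1)
    # region at fraction f = longest prefix with min(ratio) >= f
    prefix_min = np.minimum.accumulate(ratios)
    # prefix_min is non-increasing; count entries >= f
    prefix_len = np.searchsorted(-prefix_min, -fractions, side="right").astype(np.int64)
    prefix_len = np.maximum(prefix_len, 1)  # seed is always in
    prefix_len[fractions == 0.0] = count  # 0% floods all of bounds
    volumes_ml = prefix_len * img.voxel_volume_ml
    return ArgCurve(
        thresholds=fractions,
        volumes_ml=volumes_ml,
        _order=order,
        _prefix_len=prefix_len,
        _bounds=b,
        _shape=img.shape,
    )


def detect_knee(curve: ArgCurve, min_jump: float = 2.0) -> tuple[int | None, bool]:
    """Locate the sharp volume-increase point of an ARG sweep.

    The knee is the index i maximizing ``volumes[i+1] / volumes[i]`` over
    consecutive descending-fraction pairs (first occurrence on ties); the
    tumor region is the region at index i, just above the jump.  If the
    maximal jump is below ``min_jump`` the boundary is considered
    undetermined and ``success`` is False — the method does not always
    find a boundary on noisy or low-contrast images.
    """
    v = np.asarray(curve.volumes_ml, dtype=float)
    if v.size < 2:
        return None, False
    jumps = v[1:] / v[:-1]
    i = int(np.argmax(jumps))
    if jumps[i] < min_jump:
        return None, False
    curve.knee_index = i
    return i, True


def segment_arg(
    img: SuvImage,
    voi: Voi,
    *,
    min_jump: float = 2.0,
    step_percent: float = 1.0,
    connectivity: int = 6,
    bounds_dilation: float = 0.5,
) -> tuple[Segmentation, ArgCurve]:
    """Adaptive region growing seeded at the hottest VOI voxel.

    The seed is the SUVmax voxel inside the VOI (lexicographic tie-break).
    Growth is bounded by the VOI bounding box dilated by
    ``bounds_dilation`` x its side length on each side (default doubles
    each dimension), clipped to the grid — the VOI shape itself does not
    constrain the boundary, only the seed, so the result is identical for
    any two generous VOIs sharing the same hottest voxel.  A knee below
    ``min_jump`` is reported as ``success=False`` with an empty mask.
    """
    masked = np.where(voi.mask, img.values, -np.inf)
    seed = np.unravel_index(int(np.argmax(masked)), img.shape)
    idx = np.argwhere(voi.mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    bounds = []
    for a in range(3):
        pad = int(np.ceil(bounds_dilation * (hi[a] - lo[a])))
        bounds.append(slice(max(0, lo[a] - pad), min(img.shape[a], hi[a] + pad)))
    curve = arg_volume_curve(
        img, tuple(seed), tuple(bounds),
        step_percent=step_percent, connectivity=connectivity,
    )
    knee, success = detect_knee(curve, min_jump=min_jump)
    method = MethodSpec(kind="arg")
    if not success:
        return (
            Segmentation(
                mask=np.zeros(img.shape, dtype=bool),
                method=method,
                applied_threshold_suv=float("nan"),
                seed=tuple(int(s) for s in seed),
                success=False,
            ),
            curve,
        )
    mask = curve.region_mask(knee)
    fraction = float(curve.thresholds[knee])
    applied = fraction * float(img.values[mask].mean())
    return (
        Segmentation(
            mask=mask,
            method=method,
            applied_threshold_suv=applied,
            seed=tuple(int(s) for s in seed),
            success=True,
        ),
        curve,
    )


# --- serialization ---------------------------------------------------------


def rois_to_json(rois: list[PolygonRoi], operator_id: int, observation_id: int) -> dict:
    """JSON-serializable representation of a set of per-slice ROIs."""
    return {
        "operator_id": operator_id,
        "observation_id": observation_id,
        "rois": [
            {"slice_index": r.slice_index, "vertices": r.vertices.tolist()}
            for r in rois
        ],
    }


def rois_from_json(payload: dict) -> tuple[list[PolygonRoi], int, int]:
    rois = [
        PolygonRoi(slice_index=int(r["slice_index"]),
                   vertices=np.asarray(r["vertices"], dtype=float))
        for r in payload["rois"]
    ]
    return rois, int(payload["operator_id"]), int(payload["observation_id"])
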