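"""Vessel geometry: region extraction and perpendicular-chord diameters.

The diameter of a segmented vessel cross-section is defined as the longest
chord between two pixel centers of the region whose direction is perpendicular
(within a projection tolerance) to the region's long axis.  The long axis is
the principal PCA direction of the pixel coordinates.  Two implementations of
the chord search are provided: a sorted-projection sweep used in production
(:func:`perpendicular_diameter`) and a literal all-pairs enumeration kept as a
reference oracle (:func:`diameter_oracle`); they are contractually identical.

Coordinates are (row, col), 0-based, with pixel centers at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateRegion, MissingVessel

#: label alphabet of the three-vessel view
BACKGROUND, PA, AO, SVC = 0, 1, 2, 3
CLASS_NAMES = {PA: "PA", AO: "Ao", SVC: "SVC"}
VESSEL_CLASSES = (PA, AO, SVC)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LabelMask:
    """2D grid of per-pixel vessel classes (0 bg, 1 PA, 2 Ao, 3 SVC)."""

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("label mask must be a non-empty 2D array")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError("label mask must be integer-valued")
        if grid.min() < 0 or grid.max() > SVC:
            raise ValueError("label mask values must lie in {0,1,2,3}")
        object.__setattr__(self, "grid", grid)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def classes_present(self) -> set[int]:
        return set(np.unique(self.grid)) - {BACKGROUND}


def as_mask(mask) -> LabelMask:
    """Coerce an array-like or LabelMask to a LabelMask."""
    if isinstance(mask, LabelMask):
        return mask
    return LabelMask(np.asarray(mask))


@dataclass(frozen=True)
class VesselRegion:
    """One vessel's pixel set — the region over which chords are maximized."""

    class_code: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.intp)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("pixels must be a non-empty (n, 2) array")
        object.__setattr__(self, "pixels", px)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


@dataclass(frozen=True)
class Axis:
    """Long axis of a vessel region from PCA of its pixel coordinates.

    ``anisotropy`` is the ratio of the principal to the secondary covariance
    eigenvalue (>= 1, inf for collinear pixels); regions with anisotropy close
    to 1 are near-circular and their long axis is unstable — which is harmless
    for the diameter, as chords through a near-disk are direction-insensitive.
    """

    direction: np.ndarray  # unit (row, col) vector
    centroid: np.ndarray
    anisotropy: float

    def is_near_circular(self, threshold: float = 1.05) -> bool:
        return self.anisotropy < threshold


@dataclass(frozen=True)
class DiameterMeasurement:
    """Endpoints and length of the maximal perpendicular chord."""

    a: tuple[int, int]
    b: tuple[int, int]
    length_px: float
    axis: Axis
    near_circular: bool = False


@dataclass(frozen=True)
class MeasureConfig:
    """Tunables for frame measurement.

    tol_px: half-width of the admissible projection of a chord onto the long
        axis; 0.5 px (half the pixel-center spacing) by default.
    pixel_extent_correction: if True, 1 px is added to each chord length so
        diameters count pixel extents instead of center-to-center distance.
        The convention cancels in the PA/Ao ratio; off by default.
    ratio_cap: ratios above this value are treated as outliers and clipped.
    """

    tol_px: float = 0.5
    pixel_extent_correction: bool = False
    ratio_cap: float = 3.5
    near_circular_threshold: float = 1.05


@dataclass(frozen=True)
class FrameMeasurement:
    """Per-frame result: PA/Ao (and optional SVC) diameters plus the ratio."""

    pa: DiameterMeasurement
    ao: DiameterMeasurement
    svc: Optional[DiameterMeasurement]
    ratio: float
    clipped: bool
    config: MeasureConfig = field(default_factory=MeasureConfig)

    @property
    def pa_px(self) -> float:
        return self.pa.length_px

    @property
    def ao_px(self) -> float:
        return self.ao.length_px


def extract_vessel_region(mask, class_code: int) -> VesselRegion:
    """Largest 8-connected component of ``class_code`` pixels.

    Ties on component size are broken by the topmost-then-leftmost pixel of
    the component, so extraction is deterministic.
    """
    m = as_mask(mask)
    if class_code not in VESSEL_CLASSES:
        raise ValueError(f"class_code must be one of {VESSEL_CLASSES}")
    binary = m.grid == class_code
    if not binary.any():
        raise MissingVessel(CLASS_NAMES[class_code])
    labels, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # anchor = lexicographically smallest (row, col) in the component
        rows, cols = np.nonzero(np.isin(labels, best))
        comp = labels[rows, cols]
        order = np.lexsort((cols, rows))
        chosen = comp[order[0]]
    else:
        chosen = best[0]
    pixels = np.argwhere(labels == chosen)
    return VesselRegion(class_code=class_code, pixels=pixels)


def principal_axis(region: VesselRegion) -> Axis:
    """PCA long axis of the region's pixel coordinates.

    The direction is the principal eigenvector of the coordinate covariance,
    sign-normalized so its first nonzero component is positive.
    """
    if region.n_pixels < 2:
        raise DegenerateRegion("principal axis needs at least 2 pixels")
    coords = region.pixels.astype(float)
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, -1]
    nz = np.flatnonzero(np.abs(direction) > 1e-12)
    if direction[nz[0]] < 0:
        direction = -direction
    lam2, lam1 = max(evals[0], 0.0), max(evals[1], 0.0)
    anisotropy = float(lam1 / lam2) if lam2 > 0 else float("inf")
    return Axis(direction=direction, centroid=centroid, anisotropy=anisotropy)


def _projections(region: VesselRegion, axis: Axis):
    coords = region.pixels.astype(float)
    d = axis.direction
    perp = np.array([-d[1], d[0]])
    return coords @ d, coords @ perp


def perpendicular_diameter(
    region: VesselRegion, axis: Optional[Axis] = None, tol_px: float = 0.5
) -> DiameterMeasurement:
    """Longest chord perpendicular (within ``tol_px``) to the long axis.

    Sorted-projection sweep: pixels are ordered by their projection t onto the
    axis; only pairs inside the sliding window |t_i - t_j| <= tol_px are
    admissible, and the Euclidean distance is maximized exactly over each
    window.  Identical results to :func:`diameter_oracle`.
    """
    if tol_px < 0:
        raise ValueError("tol_px must be >= 0")
    if region.n_pixels < 2:
        raise DegenerateRegion("chord needs at least 2 pixels")
    if axis is None:
        axis = principal_axis(region)
    t, s = _projections(region, axis)
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    idx = order
    n = len(t)
    best_d2 = -1.0
    best_pair = None
    j0 = 0
    for i in range(1, n):
        while t[i] - t[j0] > tol_px:
            j0 += 1
        if j0 == i:
            continue
        dt = t[j0:i] - t[i]
        ds = s[j0:i] - s[i]
        d2 = dt * dt + ds * ds
        k = int(np.argmax(d2))
        if d2[k] > best_d2:
            best_d2 = float(d2[k])
            best_pair = (idx[j0 + k], idx[i])
    if best_pair is None:
        raise DegenerateRegion("no pixel pair is perpendicular to the axis within tolerance")
    a = tuple(int(v) for v in region.pixels[best_pair[0]])
    b = tuple(int(v) for v in region.pixels[best_pair[1]])
    return DiameterMeasurement(
        a=a,
        b=b,
        length_px=float(np.sqrt(best_d2)),
        axis=axis,
        near_circular=axis.is_near_circular(),
    )


def diameter_oracle(
    region: VesselRegion, axis: Optional[Axis] = None, tol_px: float = 0.5
) -> float:
    """Reference all-pairs enumeration of the maximal perpendicular chord.

    O(n^2) over every pixel pair; exists to validate the sweep implementation
    and for small regions where clarity beats speed.
    """
    if tol_px < 0:
        raise ValueError("tol_px must be >= 0")
    if region.n_pixels < 2:
        raise DegenerateRegion("chord needs at least 2 pixels")
    if axis is None:
        axis = principal_axis(region)
    t, s = _projections(region, axis)
    n = len(t)
    best = -1.0
    chunk = 256
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dt = t[start:stop, None] - t[None, :]
        admissible = np.abs(dt) <= tol_px
        # exclude self-pairs
        ii = np.arange(start, stop)
        admissible[ii - start, ii] = False
        if not admissible.any():
            continue
        ds = s[start:stop, None] - s[None, :]
        d2 = np.where(admissible, dt * dt + ds * ds, -1.0)
        m = float(d2.max())
        if m > best:
            best = m
    if best < 0:
        raise DegenerateRegion("no pixel pair is perpendicular to the axis within tolerance")
    return float(np.sqrt(best))


def measure_frame(mask, config: MeasureConfig | None = None) -> FrameMeasurement:
    """Measure PA and Ao diameters (SVC when present) and the PA/Ao ratio.

    Raises MissingVessel naming the absent class if PA or Ao is missing;
    the SVC is optional and silently skipped when absent.
    """
    from . import cohort  # local import to avoid a cycle

    cfg = config or MeasureConfig()
    m = as_mask(mask)

    def _measure(code: int) -> DiameterMeasurement:
        region = extract_vessel_region(m, code)
        axis = principal_axis(region)
        meas = perpendicular_diameter(region, axis, tol_px=cfg.tol_px)
        if cfg.pixel_extent_correction:
            meas = DiameterMeasurement(
                a=meas.a,
                b=meas.b,
                length_px=meas.length_px + 1.0,
                axis=meas.axis,
                near_circular=meas.near_circular,
            )
        return meas

    pa = _measure(PA)
    ao = _measure(AO)
    svc = None
    if (m.grid == SVC).any():
        svc = _measure(SVC)
    raw = cohort.compute_ratio(pa.length_px, ao.length_px)
    ratio, clipped = cohort.clip_ratio(raw, cap=cfg.ratio_cap)
    return FrameMeasurement(pa=pa, ao=ao, svc=svc, ratio=ratio, clipped=clipped, config=cfg)
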