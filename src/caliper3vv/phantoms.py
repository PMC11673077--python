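"""Synthetic vessel phantoms: rasterized ellipses, cohorts, mask degradations.

Clinical three-vessel-view data cannot ship with the package, so every other
module is exercised against phantoms with known geometry: vessel
cross-sections are rasterized ellipses whose true perpendicular diameter is
the full minor axis 2b, cohorts draw PA/Ao ratios from stated normal / CHD
mixture distributions and realize them as ellipse pairs, and controlled mask
degradations (erosion, dilation, shift, dropout) provide ground-truth cases
for Dice evaluation and noise-propagation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .cohort import RatioRecord, clip_ratio
from .errors import OutOfCanvas, OverlapError
from .geometry import AO, CLASS_NAMES, PA, SVC, LabelMask, VesselRegion, as_mask

DEFAULT_CANVAS = (192, 384)


@dataclass(frozen=True)
class EllipseSpec:
    """A vessel cross-section: rotated ellipse with known axes.

    The ground-truth perpendicular diameter of the rasterized region is the
    full minor axis ``2 * b`` (the longest chord orthogonal to the major
    axis passes through the center).
    """

    center: tuple[float, float]  # (row, col)
    a: float  # semi-major, px
    b: float  # semi-minor, px
    theta_deg: float
    class_code: int

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.b

    def half_extents(self) -> tuple[float, float]:
        """Bounding half-extents (rows, cols) of the rotated ellipse."""
        th = np.deg2rad(self.theta_deg)
        hr = np.hypot(self.a * np.sin(th), self.b * np.cos(th))
        hc = np.hypot(self.a * np.cos(th), self.b * np.sin(th))
        return float(hr), float(hc)


def _inside(spec: EllipseSpec, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rows - spec.center[0]
    dc = cols - spec.center[1]
    th = np.deg2rad(spec.theta_deg)
    # coordinates in the ellipse frame; major axis along +col at theta=0
    u = dc * np.cos(th) + dr * np.sin(th)
    v = -dc * np.sin(th) + dr * np.cos(th)
    return (u / spec.a) ** 2 + (v / spec.b) ** 2 <= 1.0


def rasterize_ellipse(spec: EllipseSpec, canvas: tuple[int, int] = DEFAULT_CANVAS) -> VesselRegion:
    """Pixels whose centers satisfy the rotated-ellipse inequality.

    Pixel-center-inside rasterization without anti-aliasing, so pixel counts
    are exactly reproducible.
    """
    hr, hc = spec.half_extents()
    r0, c0 = spec.center
    if r0 - hr < 0 or r0 + hr > canvas[0] - 1 or c0 - hc < 0 or c0 + hc > canvas[1] - 1:
        raise OutOfCanvas(
            f"ellipse at {spec.center} with half-extents ({hr:.1f}, {hc:.1f}) "
            f"does not fit canvas {canvas}"
        )
    pixels = np.argwhere(_inside(spec, canvas))
    return VesselRegion(class_code=spec.class_code, pixels=pixels)


def generate_phantom_frame(
    pa: EllipseSpec,
    ao: EllipseSpec,
    svc: Optional[EllipseSpec] = None,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> tuple[LabelMask, dict]:
    """Rasterize a synthetic 3VV frame and its ground-truth geometry.

    Returns the label mask plus a record of each vessel's true diameter (2b)
    and the implied PA/Ao ratio.  Raises OverlapError naming the colliding
    pair if two rasterized vessels share a pixel.
    """
    specs = [pa, ao] + ([svc] if svc is not None else [])
    grid = np.zeros(canvas, dtype=np.uint8)
    occupied: dict[int, np.ndarray] = {}
    for spec in specs:
        region = rasterize_ellipse(spec, canvas)
        flat = region.pixels[:, 0] * canvas[1] + region.pixels[:, 1]
        for other_code, other_flat in occupied.items():
            if np.intersect1d(flat, other_flat, assume_unique=True).size:
                raise OverlapError(CLASS_NAMES[other_code], CLASS_NAMES[spec.class_code])
        occupied[spec.class_code] = np.sort(flat)
        grid[region.pixels[:, 0], region.pixels[:, 1]] = spec.class_code
    truth = {
        "pa_diameter": pa.diameter,
        "ao_diameter": ao.diameter,
        "ratio": pa.diameter / ao.diameter,
    }
    if svc is not None:
        truth["svc_diameter"] = svc.diameter
    return LabelMask(grid), truth


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic screening cohort.

    Normal-case ratios are Normal(normal_mu, normal_sigma); CHD ratios come
    from a three-component mixture over the low/normal/high groups.  The
    default mixture is patterned loosely on published group means and is a
    fixture choice, not a clinical estimate.  ``ao_px`` is the fixed full
    minor-axis diameter of the aorta; the PA's minor axis is scaled to
    realize the drawn ratio.
    """

    n_normal: int = 280
    n_chd: int = 35
    normal_mu: float = 1.237
    normal_sigma: float = 0.182  # half of the 0.364 2SD half-width
    chd_weights: tuple[float, float, float] = (0.3, 0.4, 0.3)
    chd_means: tuple[float, float, float] = (0.9, 1.25, 1.65)
    chd_sigmas: tuple[float, float, float] = (0.15, 0.15, 0.15)
    ao_px: float = 30.0
    seed: int = 0
    canvas: tuple[int, int] = DEFAULT_CANVAS

    def __post_init__(self):
        if abs(sum(self.chd_weights) - 1.0) > 1e-9:
            raise ValueError("CHD mixture weights must sum to 1")
        if any(s < 0 for s in self.chd_sigmas) or self.normal_sigma < 0:
            raise ValueError("sigmas must be >= 0")

    @classmethod
    def default(cls, **kw) -> "CohortSpec":
        return cls(**kw)

    @classmethod
    def separable(cls, **kw) -> "CohortSpec":
        """Cohort with CHD group means well outside the normal band.

        Used for screening-recovery checks where the normal and CHD score
        distributions should be nearly disjoint.
        """
        kw.setdefault("chd_weights", (0.5, 0.0, 0.5))
        kw.setdefault("chd_means", (0.75, 1.237, 1.75))
        kw.setdefault("chd_sigmas", (0.08, 0.08, 0.08))
        return cls(**kw)

    @classmethod
    def null(cls, **kw) -> "CohortSpec":
        """Degenerate cohort: CHD ratios drawn from the normal distribution.

        Screening on such a cohort should be at chance (AUC ~ 0.5).
        """
        kw.setdefault("chd_weights", (0.0, 1.0, 0.0))
        kw.setdefault("chd_means", (1.237, 1.237, 1.237))
        kw.setdefault("chd_sigmas", (0.182, 0.182, 0.182))
        return cls(**kw)


@dataclass
class PhantomCase:
    """One synthetic case: the true-ratio record and (optionally) its mask."""

    record: RatioRecord
    mask: Optional[LabelMask] = None
    truth: dict = field(default_factory=dict)


# ratio draws are truncated to keep the PA ellipse on-canvas and positive;
# the bounds sit many sigma from every default mixture component
_RATIO_BOUNDS = (0.35, 3.4)


def _draw_ratio(rng: np.random.Generator, mu: float, sigma: float) -> float:
    r = float(rng.normal(mu, sigma))
    return float(np.clip(r, *_RATIO_BOUNDS))


def generate_cohort(spec: CohortSpec, rasterize: bool = True) -> list[PhantomCase]:
    """Seeded synthetic cohort of normal and CHD cases.

    Each case draws a true PA/Ao ratio from its cohort distribution and, when
    ``rasterize`` is on, realizes it as a non-overlapping ellipse pair (plus
    an SVC) on the canvas: the Ao minor diameter is fixed at ``spec.ao_px``
    and the PA minor diameter is ``ratio * ao_px``.  With ``rasterize=False``
    only the true-ratio records are produced (fast path for statistical
    checks at large n).
    """
    rng = np.random.default_rng(spec.seed)
    cases: list[PhantomCase] = []
    labels = ["normal"] * spec.n_normal + ["CHD"] * spec.n_chd
    for i, label in enumerate(labels):
        if label == "normal":
            r = _draw_ratio(rng, spec.normal_mu, spec.normal_sigma)
        else:
            comp = int(rng.choice(3, p=spec.chd_weights))
            r = _draw_ratio(rng, spec.chd_means[comp], spec.chd_sigmas[comp])
        r, was_clipped = clip_ratio(r)
        b_ao = spec.ao_px / 2.0
        b_pa = r * b_ao
        record = RatioRecord(
            case_id=f"case{i:04d}",
            frame_id="f0",
            cohort_label=label,
            pa_px=2.0 * b_pa,
            ao_px=2.0 * b_ao,
            ratio=r,
            clipped=was_clipped,
        )
        case = PhantomCase(record=record)
        if rasterize:
            elong = rng.uniform(1.05, 1.5, size=3)
            thetas = rng.uniform(0.0, 180.0, size=3)
            jitter = rng.uniform(-5.0, 5.0, size=6)
            h, w = spec.canvas
            pa_spec = EllipseSpec(
                center=(h / 2 + jitter[0], 0.22 * w + jitter[1]),
                a=b_pa * elong[0], b=b_pa, theta_deg=thetas[0], class_code=PA,
            )
            ao_spec = EllipseSpec(
                center=(h / 2 + jitter[2], 0.56 * w + jitter[3]),
                a=b_ao * elong[1], b=b_ao, theta_deg=thetas[1], class_code=AO,
            )
            b_svc = float(rng.uniform(4.0, 7.0))
            svc_spec = EllipseSpec(
                center=(h / 2 + jitter[4], 0.83 * w + jitter[5]),
                a=b_svc * elong[2], b=b_svc, theta_deg=thetas[2], class_code=SVC,
            )
            mask, truth = generate_phantom_frame(pa_spec, ao_spec, svc_spec, canvas=spec.canvas)
            case.mask = mask
            case.truth = truth
        cases.append(case)
    return cases


def degrade_mask(mask, operation: str, magnitude_px: float, seed: int | None = None) -> LabelMask:
    """Controlled per-class perturbation of a label mask.

    operation:
      * ``erode`` / ``dilate`` — binary morphology with an 8-connected
        structuring element, ``int(magnitude_px)`` iterations per class;
      * ``shift`` — each class translated by a seeded random direction of
        length ~ ``magnitude_px`` (rounded to integer offsets, zero fill);
      * ``dropout`` — each foreground pixel dropped independently with
        probability ``magnitude_px`` (interpreted as a fraction in [0, 1]).

    Magnitude 0 is the identity.  When perturbed classes collide, the higher
    class code wins (applied in class order).
    """
    m = as_mask(mask)
    if magnitude_px < 0:
        raise ValueError("magnitude must be >= 0")
    if operation not in {"erode", "dilate", "shift", "dropout"}:
        raise ValueError(f"unknown degradation {operation!r}")
    if magnitude_px == 0:
        return LabelMask(m.grid.copy())
    rng = np.random.default_rng(seed)
    structure = np.ones((3, 3), dtype=bool)
    out = np.zeros_like(m.grid)
    for code in sorted(m.classes_present()):
        binary = m.grid == code
        if operation == "erode":
            binary = ndimage.binary_erosion(binary, structure, iterations=int(magnitude_px))
        elif operation == "dilate":
            binary = ndimage.binary_dilation(binary, structure, iterations=int(magnitude_px))
        elif operation == "shift":
            angle = rng.uniform(0, 2 * np.pi)
            dr = int(round(magnitude_px * np.sin(angle)))
            dc = int(round(magnitude_px * np.cos(angle)))
            shifted = np.zeros_like(binary)
            src = binary[
                max(0, -dr) : binary.shape[0] - max(0, dr),
                max(0, -dc) : binary.shape[1] - max(0, dc),
            ]
            shifted[
                max(0, dr) : shifted.shape[0] - max(0, -dr),
                max(0, dc) : shifted.shape[1] - max(0, -dc),
            ] = src
            binary = shifted
        elif operation == "dropout":
            p = min(float(magnitude_px), 1.0)
            keep = rng.random(size=binary.shape) >= p
            binary = binary & keep
        out[binary] = code
    return LabelMask(out)


def random_ellipse_spec(
    rng: np.random.Generator,
    b_range: tuple[float, float] = (5.0, 25.0),
    max_elongation: float = 2.5,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    class_code: int = PA,
) -> EllipseSpec:
    """Random vessel cross-section: arbitrary orientation and sub-pixel center.

    The center gets a uniform sub-pixel offset — vessels are never aligned to
    the pixel lattice, and integer-centered ellipses are a degenerate special
    case whose mirror symmetry biases chord measurements.
    """
    b = float(rng.uniform(*b_range))
    a = b * float(rng.uniform(1.0, max_elongation))
    center = (
        canvas[0] / 2.0 + float(rng.uniform(0, 1)),
        canvas[1] / 2.0 + float(rng.uniform(0, 1)),
    )
    return EllipseSpec(
        center=center, a=a, b=b, theta_deg=float(rng.uniform(0, 180)), class_code=class_code
    )


def random_blob(rng: np.random.Generator, n_pixels: int, class_code: int = PA) -> VesselRegion:
    """Random 8-connected blob of exactly ``n_pixels`` pixels.

    Grown by repeatedly annexing a uniformly chosen boundary neighbor;
    produces irregular but connected regions for property tests.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    start = (0, 0)
    blob = {start}
    frontier = set()
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in offsets]
    frontier.update(neighbors(start))
    while len(blob) < n_pixels:
        candidates = sorted(frontier)
        pick = candidates[int(rng.integers(len(candidates)))]
        frontier.remove(pick)
        blob.add(pick)
        frontier.update(p for p in neighbors(pick) if p not in blob)
    pixels = np.array(sorted(blob), dtype=np.intp)
    pixels -= pixels.min(axis=0)  # shift into the positive quadrant
    return VesselRegion(class_code=class_code, pixels=pixels)
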