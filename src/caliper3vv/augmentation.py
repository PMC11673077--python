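"""Training-set augmentation: bounded rotation plus linear intensity transform.

Each variant applies ``dst = saturate_cast(src * alpha + beta)`` pixel-wise
(gain alpha in [0.7, 1.3], offset beta in [-30, 30]) and a rotation within
+/-15 degrees about the image center.  With the default 20 variants per image
the output set is 21x the input — originals are kept alongside the variants.
Paired label masks receive the identical rotation with nearest-neighbor
interpolation so the class alphabet is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .errors import InvalidImage

ANGLE_RANGE = (-15.0, 15.0)
ALPHA_RANGE = (0.7, 1.3)
BETA_RANGE = (-30.0, 30.0)


@dataclass(frozen=True)
class AugmentationParams:
    """One variant's draw: rotation angle (deg), gain alpha, offset beta."""

    angle: float
    alpha: float
    beta: float


def draw_params(rng: np.random.Generator) -> AugmentationParams:
    """Uniform draw of (angle, alpha, beta) over the stated ranges."""
    return AugmentationParams(
        angle=float(rng.uniform(*ANGLE_RANGE)),
        alpha=float(rng.uniform(*ALPHA_RANGE)),
        beta=float(rng.uniform(*BETA_RANGE)),
    )


def saturate_cast(value):
    """Round half away from zero, then clamp to the 8-bit range [0, 255].

    Works element-wise on arrays; scalar in, scalar out.
    """
    arr = np.asarray(value, dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    clamped = np.clip(rounded, 0, 255).astype(np.uint8)
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(clamped)
    return clamped


def adjust_brightness_contrast(image: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Pixel-wise linear gain/offset with saturating cast back to uint8."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise InvalidImage(f"expected 8-bit grayscale image, got dtype {img.dtype}")
    if alpha == 1.0 and beta == 0.0:
        return img.copy()
    return saturate_cast(img.astype(float) * alpha + beta)


def rotate(image_or_mask: np.ndarray, angle: float, is_mask: bool = False) -> np.ndarray:
    """Rotate about the image center, canvas size preserved, 0-fill outside.

    Bilinear interpolation for images; nearest-neighbor for masks so the
    label set survives.  Angle 0 is a bit-exact identity.
    """
    arr = np.asarray(image_or_mask)
    if abs(angle) > 15.0 + 1e-9:
        warnings.warn(f"rotation angle {angle} deg outside the +/-15 deg augmentation range")
    if angle == 0.0:
        return arr.copy()
    order = 0 if is_mask else 1
    out = _sk_rotate(
        arr.astype(float), angle, resize=False, order=order, cval=0.0, preserve_range=True
    )
    if is_mask:
        return np.round(out).astype(arr.dtype)
    return saturate_cast(out) if arr.dtype == np.uint8 else out.astype(arr.dtype)


def augment_set(
    images: list[np.ndarray],
    n_variants: int = 20,
    seed: int | None = None,
    masks: list[np.ndarray] | None = None,
):
    """Originals plus ``n_variants`` independently drawn variants per image.

    Output length is ``len(images) * (1 + n_variants)``; with the default 20
    variants a training set grows 21-fold.  When ``masks`` is given, each
    variant's rotation is applied identically to the paired mask (which gets
    no intensity transform) and a (images, masks) pair is returned.  All
    random draws come from one seeded generator, so the same seed reproduces
    the output bit for bit.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    if masks is not None and len(masks) != len(images):
        raise ValueError("images and masks must pair up")
    rng = np.random.default_rng(seed)
    out_images: list[np.ndarray] = []
    out_masks: list[np.ndarray] = []
    for i, img in enumerate(images):
        out_images.append(np.asarray(img).copy())
        if masks is not None:
            out_masks.append(np.asarray(masks[i]).copy())
        for _ in range(n_variants):
            p = draw_params(rng)
            var = adjust_brightness_contrast(np.asarray(img), p.alpha, p.beta)
            out_images.append(rotate(var, p.angle, is_mask=False))
            if masks is not None:
                out_masks.append(rotate(np.asarray(masks[i]), p.angle, is_mask=True))
    if masks is not None:
        return out_images, out_masks
    return out_images
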