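"""Random paired image/mask augmentation: shear, rotation, zoom, horizontal flip.

One affine transform (shear -> rotate -> zoom about the image center, then an
optional horizontal flip) is applied identically to the intensity slice
(bilinear) and its mask (nearest neighbor). Parameter bounds follow the
training protocol: shear within 0.3 rad, rotation within 30 degrees, zoom
within 20 percent, flips with probability one half.  Streams are driven by a
seeded generator so the training pipeline is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import affine_transform

SHEAR_MAX_RAD = 0.3
ROTATION_MAX_DEG = 30.0
ZOOM_MAX_FRAC = 0.2


@dataclass(frozen=True)
class AugmentParams:
    shear_rad: float
    rotation_deg: float
    zoom_frac: float
    hflip: bool
    seed_draw: int = 0

    def __post_init__(self) -> None:
        if abs(self.shear_rad) > SHEAR_MAX_RAD + 1e-12:
            raise ValueError(f"shear {self.shear_rad} out of [-{SHEAR_MAX_RAD}, {SHEAR_MAX_RAD}]")
        if abs(self.rotation_deg) > ROTATION_MAX_DEG + 1e-9:
            raise ValueError(f"rotation {self.rotation_deg} out of bounds")
        if abs(self.zoom_frac) > ZOOM_MAX_FRAC + 1e-12:
            raise ValueError(f"zoom {self.zoom_frac} out of bounds")

    @property
    def is_identity(self) -> bool:
        return (self.shear_rad == 0.0 and self.rotation_deg == 0.0
                and self.zoom_frac == 0.0 and not self.hflip)


def sample_augment_params(rng: np.random.Generator) -> AugmentParams:
    """Draw each parameter uniformly within its bound; flip with p = 0.5."""
    return AugmentParams(
        shear_rad=float(rng.uniform(-SHEAR_MAX_RAD, SHEAR_MAX_RAD)),
        rotation_deg=float(rng.uniform(-ROTATION_MAX_DEG, ROTATION_MAX_DEG)),
        zoom_frac=float(rng.uniform(-ZOOM_MAX_FRAC, ZOOM_MAX_FRAC)),
        hflip=bool(rng.random() < 0.5),
        seed_draw=int(rng.integers(0, 2**31 - 1)),
    )


def _forward_matrix(params: AugmentParams) -> np.ndarray:
    """Output = M @ input coordinate (row, col), about the image center."""
    s = math.tan(params.shear_rad)
    shear = np.array([[1.0, s], [0.0, 1.0]])
    th = math.radians(params.rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    zoom = (1.0 + params.zoom_frac) * np.eye(2)
    m = shear @ rot @ zoom
    if params.hflip:
        m = np.array([[1.0, 0.0], [0.0, -1.0]]) @ m
    return m


def apply_augment(image: np.ndarray, mask: np.ndarray,
                  params: AugmentParams) -> tuple[np.ndarray, np.ndarray]:
    """Apply one affine transform identically to an image slice and its mask.

    The image is interpolated bilinearly, the mask by nearest neighbor, both
    zero-padded outside the frame; output shapes equal input shapes and the
    mask stays binary. Identity parameters return exact copies, and a pure
    horizontal flip is performed as an exact axis reversal (an involution).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape or image.ndim != 2:
        raise ValueError(f"image/mask shape mismatch: {image.shape} vs {mask.shape}")
    if params.is_identity:
        return image.copy(), mask.copy()
    if params.shear_rad == 0.0 and params.rotation_deg == 0.0 and params.zoom_frac == 0.0:
        return image[:, ::-1].copy(), mask[:, ::-1].copy()
    m = _forward_matrix(params)
    minv = np.linalg.inv(m)
    center = (np.asarray(image.shape, dtype=np.float64) - 1.0) / 2.0
    offset = center - minv @ center
    out_img = affine_transform(image.astype(np.float32), minv, offset=offset,
                               order=1, mode="constant", cval=0.0)
    out_mask = affine_transform(mask.astype(np.uint8), minv, offset=offset,
                                order=0, mode="constant", cval=0)
    return out_img, (out_mask > 0).astype(mask.dtype)


def augment_stream(pairs: Sequence[tuple[np.ndarray, np.ndarray]], factor: int,
                   seed: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``factor * len(pairs)`` freshly augmented pairs, reproducibly.

    Each yielded pair uses an independent parameter draw from a generator
    seeded with ``seed``; the stream makes ``factor`` passes over the input
    list in order.
    """
    if len(pairs) == 0:
        raise ValueError("augment_stream requires at least one pair")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(factor):
        for image, mask in pairs:
            yield apply_augment(image, mask, sample_augment_params(rng))
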