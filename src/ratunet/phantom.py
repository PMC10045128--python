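"""Synthetic stroke-rat MR phantoms for end-to-end testing without scanner data.

Each subject is a 15-slice coronal volume over a 2.56 x 2.56 cm field of view
(matrix 128 for DWI-like, 256 for T2WI-like; smaller matrices are allowed for
desk-scale runs). Per slice the phantom contains, from inside out: a bright
elliptical "brain" whose semi-axes shrink toward the first and last slices, a
dark skull gap ring, and a scalp ring deliberately close to brain intensity so
plain thresholding cannot solve the task. A hyperintense circular lesion
(emulating DWI-bright acute infarct) sits inside one hemisphere on a
contiguous subset of slices. The clean image is degraded by a smooth
multiplicative bias field (exponential of a low-order 2-D polynomial, the
radiofrequency-inhomogeneity surrogate) and Rician noise (magnitude of signal
plus complex Gaussian). The ground-truth mask is the exact brain-ellipse
interior — lesion included, rings excluded — so metric upper bounds are known
by construction.

The generator is deterministic given its parameters and seed; cohorts derive
per-subject seeds from one master seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preprocess import BinaryMask, MRVolume, write_manifest, write_mask, write_mr_volume

FOV_MM = 25.6

#: tissue intensities of the noiseless phantom (arbitrary units)
BRAIN_INTENSITY = 1.0
SCALP_INTENSITY = 0.7
SKULL_GAP_INTENSITY = 0.15
BACKGROUND_INTENSITY = 0.0


@dataclass(frozen=True)
class PhantomParams:
    """Generative knobs for one synthetic subject.

    Geometry is specified in mm so the same anatomy renders consistently at
    any matrix size; ``matrix_size``/``fov_mm`` fix the in-plane spacing
    (0.2 mm at 128, 0.1 mm at 256) and slices are 1 mm thick.
    """

    matrix_size: int = 128
    n_slices: int = 15
    fov_mm: float = FOV_MM
    brain_a_mm: float = 7.5      # in-plane semi-axis along columns (width)
    brain_b_mm: float = 5.5      # in-plane semi-axis along rows (height)
    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    skull_gap_width_mm: float = 0.5
    scalp_ring_width_mm: float = 1.0
    lesion_offset_mm: tuple[float, float] = (0.0, 2.8)  # (row, col) from brain center
    lesion_radius_mm: float = 2.0
    lesion_gain: float = 1.5
    lesion_slices: tuple[int, int] = (5, 11)  # half-open slice range
    bias_amplitude: float = 0.2
    noise_sigma: float = 1.0 / 15.0  # brain SNR ~ 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size % 32 != 0:
            raise ValueError("matrix_size must be a multiple of 32")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if not 0.0 <= self.bias_amplitude <= 0.3:
            raise ValueError("bias amplitude must lie in [0, 0.3]")
        if self.lesion_gain < 1.0:
            raise ValueError("lesion gain must be >= 1 (hyperintense)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        px = self.fov_mm / self.matrix_size
        return (1.0, px, px)


def _slice_scale(z: int, n_slices: int) -> float:
    """Head-to-tail size profile: largest mid-volume, shrinking to the ends."""
    return 0.55 + 0.45 * math.sin(math.pi * (z + 0.5) / n_slices)


def _check_lesion_inside(params: PhantomParams) -> None:
    lo, hi = params.lesion_slices
    dr, dc = params.lesion_offset_mm
    for z in range(max(lo, 0), min(hi, params.n_slices)):
        s = _slice_scale(z, params.n_slices)
        a, b = params.brain_a_mm * s, params.brain_b_mm * s
        ang = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
        rr = dr + params.lesion_radius_mm * np.sin(ang)
        cc = dc + params.lesion_radius_mm * np.cos(ang)
        if np.any((cc / a) ** 2 + (rr / b) ** 2 > 1.0):
            raise ValueError(f"lesion leaves the brain ellipse on slice {z}")


def generate_phantom_subject(params: PhantomParams,
                             subject_id: str = "phantom000",
                             modality: str = "synthetic") -> tuple[MRVolume, BinaryMask]:
    """Render one subject; bit-identical for identical params (incl. seed)."""
    _check_lesion_inside(params)
    rng = np.random.default_rng(params.seed)
    n, ns = params.matrix_size, params.n_slices
    px = params.fov_mm / n
    # mm coordinates of voxel centers relative to the (possibly offset) center
    rows = (np.arange(n) - (n - 1) / 2.0) * px - params.center_offset_mm[0]
    cols = (np.arange(n) - (n - 1) / 2.0) * px - params.center_offset_mm[1]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    volume = np.zeros((ns, n, n), dtype=np.float32)
    mask = np.zeros((ns, n, n), dtype=np.uint8)

    # one smooth multiplicative bias field, evaluated on every slice
    coeffs = rng.normal(size=5)
    u = cc / (params.fov_mm / 2.0)
    v = rr / (params.fov_mm / 2.0)
    poly = (coeffs[0] * u + coeffs[1] * v + coeffs[2] * u * v
            + coeffs[3] * u * u + coeffs[4] * v * v)
    peak = float(np.abs(poly).max())
    if peak > 0:
        poly *= params.bias_amplitude / peak
    bias = np.exp(poly).astype(np.float32)

    lo, hi = params.lesion_slices
    for z in range(ns):
        s = _slice_scale(z, ns)
        a, b = params.brain_a_mm * s, params.brain_b_mm * s
        # elliptical "radius": <=1 inside the brain
        er = np.sqrt((cc / a) ** 2 + (rr / b) ** 2)
        brain = er <= 1.0
        gap_a, gap_b = a + params.skull_gap_width_mm, b + params.skull_gap_width_mm
        scalp_a = gap_a + params.scalp_ring_width_mm
        scalp_b = gap_b + params.scalp_ring_width_mm
        in_gap = (~brain) & (np.sqrt((cc / gap_a) ** 2 + (rr / gap_b) ** 2) <= 1.0)
        in_scalp = (np.sqrt((cc / gap_a) ** 2 + (rr / gap_b) ** 2) > 1.0) \
            & (np.sqrt((cc / scalp_a) ** 2 + (rr / scalp_b) ** 2) <= 1.0)
        img = np.full((n, n), BACKGROUND_INTENSITY, dtype=np.float32)
        img[brain] = BRAIN_INTENSITY
        img[in_gap] = SKULL_GAP_INTENSITY
        img[in_scalp] = SCALP_INTENSITY
        if lo <= z < hi:
            lesion = (np.sqrt((rr - params.lesion_offset_mm[0]) ** 2
                              + (cc - params.lesion_offset_mm[1]) ** 2)
                      <= params.lesion_radius_mm) & brain
            img[lesion] *= params.lesion_gain
        # mild smoothing emulates partial-volume blur at tissue borders
        img = gaussian_filter(img, sigma=0.6)
        img *= bias
        volume[z] = img
        mask[z] = brain.astype(np.uint8)

    if params.noise_sigma > 0:
        real = volume + rng.normal(0.0, params.noise_sigma, volume.shape)
        imag = rng.normal(0.0, params.noise_sigma, volume.shape)
        volume = np.sqrt(real ** 2 + imag ** 2).astype(np.float32)

    spacing = params.spacing_mm
    return (MRVolume(voxels=volume, spacing_mm=spacing, modality=modality,
                     subject_id=subject_id),
            BinaryMask(voxels=mask, spacing_mm=spacing, subject_id=subject_id))


def sample_phantom_params(rng: np.random.Generator, matrix_size: int = 128,
                          n_slices: int = 15) -> PhantomParams:
    """Randomize geometry, lesion, bias, and noise within realistic ranges."""
    brain_a = float(rng.uniform(6.8, 8.2))
    brain_b = float(rng.uniform(5.0, 6.2))
    side = 1.0 if rng.random() < 0.5 else -1.0
    lesion_r = float(rng.uniform(1.5, 2.4))
    # keep the lesion comfortably inside the narrowest slice it occupies
    lo = int(rng.integers(3, 6))
    hi = int(rng.integers(9, 12))
    min_scale = min(_slice_scale(z, n_slices) for z in range(lo, hi))
    max_off = brain_a * min_scale - lesion_r - 0.3
    lesion_c = side * float(rng.uniform(0.45, 0.95)) * max(max_off, 0.5)
    return PhantomParams(
        matrix_size=matrix_size,
        n_slices=n_slices,
        brain_a_mm=brain_a,
        brain_b_mm=brain_b,
        center_offset_mm=(float(rng.uniform(-0.8, 0.8)), float(rng.uniform(-0.8, 0.8))),
        skull_gap_width_mm=float(rng.uniform(0.4, 0.7)),
        scalp_ring_width_mm=float(rng.uniform(0.8, 1.3)),
        lesion_offset_mm=(float(rng.uniform(-0.5, 0.5)), lesion_c),
        lesion_radius_mm=lesion_r,
        lesion_gain=float(rng.uniform(1.3, 1.8)),
        lesion_slices=(lo, hi),
        bias_amplitude=float(rng.uniform(0.05, 0.3)),
        noise_sigma=float(rng.uniform(0.05, 0.08)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_phantom_dataset(n_subjects: int, modality_like: str = "DWI",
                             seed: int = 0, outdir: str | os.PathLike | None = None,
                             matrix_size: int | None = None,
                             ) -> list[tuple[MRVolume, BinaryMask]]:
    """Generate a cohort of randomized subjects; optionally write NIfTI + manifest.

    Matrix size defaults to 128 for DWI-like and 256 for T2WI-like cohorts;
    an explicit ``matrix_size`` overrides it for desk-scale runs. When
    ``outdir`` is given, image/mask NIfTI pairs and a manifest CSV
    (subject_id, image_path, mask_path, modality) are written there.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if modality_like not in ("DWI", "T2WI"):
        raise ValueError(f"modality_like must be DWI or T2WI, got {modality_like!r}")
    if matrix_size is None:
        matrix_size = 128 if modality_like == "DWI" else 256
    rng = np.random.default_rng(seed)
    subjects = []
    rows = []
    for i in range(n_subjects):
        sid = f"{modality_like.lower()}{i:03d}"
        params = sample_phantom_params(rng, matrix_size=matrix_size)
        vol, mask = generate_phantom_subject(params, subject_id=sid,
                                             modality=modality_like)
        subjects.append((vol, mask))
        if outdir is not None:
            outdir_p = Path(outdir)
            outdir_p.mkdir(parents=True, exist_ok=True)
            img_path = outdir_p / f"{sid}_image.nii.gz"
            mask_path = outdir_p / f"{sid}_mask.nii.gz"
            write_mr_volume(vol, img_path)
            write_mask(mask, mask_path)
            rows.append({"subject_id": sid, "image_path": str(img_path),
                         "mask_path": str(mask_path), "modality": modality_like})
    if outdir is not None:
        write_manifest(rows, Path(outdir) / "manifest.csv")
    return subjects
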