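"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here deliberately use explicit voxel loops and full O(n*m)
pairwise distance matrices so they share no code path with the package's
vectorized / KD-tree implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ratunet.io_preprocess import BinaryMask
from ratunet.phantom import PhantomParams, generate_phantom_subject


# ---------------------------------------------------------------------------
# brute-force metric oracles

def oracle_confusion(sp: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = fn = tn = 0
    for s, g in zip(sp.ravel(), gt.ravel()):
        if s and g:
            tp += 1
        elif s and not g:
            fp += 1
        elif not s and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def oracle_dice(sp: np.ndarray, gt: np.ndarray) -> float:
    tp, fp, fn, _ = oracle_confusion(sp, gt)
    denom = 2 * tp + fn + fp
    return 1.0 if denom == 0 else 2.0 * tp / denom


def oracle_sensitivity(sp: np.ndarray, gt: np.ndarray) -> float:
    tp, _, fn, _ = oracle_confusion(sp, gt)
    return tp / (tp + fn)


def oracle_sensibility(sp: np.ndarray, gt: np.ndarray) -> float:
    tp, fp, fn, _ = oracle_confusion(sp, gt)
    return 1.0 - fp / (tp + fn)


def oracle_contour_points(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Per-slice 4-neighbor boundary voxels mapped to mm, by explicit loops."""
    pts = []
    ns, nr, nc = mask.shape
    for z in range(ns):
        for r in range(nr):
            for c in range(nc):
                if not mask[z, r, c]:
                    continue
                boundary = False
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nr and 0 <= cc < nc) or not mask[z, rr, cc]:
                        boundary = True
                        break
                if boundary:
                    pts.append((z * spacing[0], r * spacing[1], c * spacing[2]))
    return np.asarray(pts, dtype=np.float64)


def oracle_hausdorff(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(max, average) symmetric Hausdorff from the full pairwise matrix."""
    dmat = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    d_ab = dmat.min(axis=1)
    d_ba = dmat.min(axis=0)
    return (max(d_ab.max(), d_ba.max()),
            (d_ab.mean() + d_ba.mean()) / 2.0)


def random_mask_pair(rng: np.random.Generator, shape=(2, 32, 32),
                     spacing=(1.0, 0.2, 0.2)) -> tuple[BinaryMask, BinaryMask]:
    """A random non-empty prediction/ground-truth pair of blobby masks."""
    def blob():
        m = np.zeros(shape, dtype=np.uint8)
        for z in range(shape[0]):
            r0, c0 = rng.integers(4, shape[1] - 4, size=2)
            rad = rng.integers(2, 9)
            rr, cc = np.ogrid[:shape[1], :shape[2]]
            m[z] = ((rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2).astype(np.uint8)
            # sprinkle noise voxels so contours are irregular
            noise = rng.random(m[z].shape) < 0.02
            m[z] ^= noise.astype(np.uint8)
        if not m.any():
            m[0, shape[1] // 2, shape[2] // 2] = 1
        for z in range(shape[0]):
            if not m[z].any():
                m[z, shape[1] // 2, shape[2] // 2] = 1
        return m

    return (BinaryMask(blob(), spacing), BinaryMask(blob(), spacing))


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64-px phantom subject (volume, mask)."""
    params = PhantomParams(matrix_size=64, seed=7)
    return generate_phantom_subject(params, subject_id="fix000")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
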