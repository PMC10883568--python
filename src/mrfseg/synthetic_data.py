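"""Ground-truthed phantom generation.

Phantoms follow exactly the generative model the segmenter and denoiser
assume: a discrete label field (either a Gibbs-sampled Potts configuration on
the 8-neighbor system, or background-plus-disks "cell" layouts), rendered to
class-mean grey levels and corrupted with additive Gaussian white noise
``z = y + n``.  Noise is added on the unclipped real line; a [0, 255]-clipped
copy is available for export.

The default phantom suite used throughout validation is a 64x64 Potts field
(K=3, beta=1.5, means 50/128/200) and a 128x128 two-class blob phantom
(means 40/190), each at noise std 0, 15, 25 or 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "Phantom",
    "sample_potts_field",
    "make_blob_phantom",
    "render_and_noise",
    "POTTS_SUITE",
    "BLOB_SUITE",
    "default_potts_phantom",
    "default_blob_phantom",
]

POTTS_SUITE = dict(height=64, width=64, K=3, beta=1.5, means=(50.0, 128.0, 200.0))
BLOB_SUITE = dict(height=128, width=128, K=2, means=(40.0, 190.0), n_blobs=12,
                  radius_range=(8, 20))
NOISE_LEVELS = (15.0, 25.0, 50.0)


@dataclass(frozen=True)
class Phantom:
    """A clean/noisy image pair with its ground-truth label field."""

    labels: np.ndarray
    clean: np.ndarray
    noisy: np.ndarray
    sigma: float
    seed: int

    @property
    def noisy_clipped(self) -> np.ndarray:
        return np.clip(self.noisy, 0.0, 255.0)


def sample_potts_field(
    height: int, width: int, K: int, beta: float, sweeps: int, seed: int
) -> np.ndarray:
    """Gibbs-sample the pure Potts prior on the 8-neighbor lattice.

    Starts from an iid uniform configuration and runs ``sweeps`` raster-order
    Gibbs sweeps of the full conditional at coupling ``beta``.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=(height, width)).astype(np.int64)
    if beta != 0.0:
        unif = rng.random((sweeps, height, width))
        _kernels.potts_gibbs_sweeps_inplace(labels, K, float(beta), unif)
    return labels


def make_blob_phantom(
    height: int,
    width: int,
    K: int,
    n_blobs: int,
    radius_range: tuple[int, int],
    seed: int = 0,
) -> np.ndarray:
    """Background class 0 plus ``n_blobs`` random disks of classes 1..K-1.

    Disk centres are placed so every disk fits inside the lattice.  When
    ``n_blobs >= K - 1`` every foreground class is guaranteed to appear.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    r_lo, r_hi = radius_range
    if 2 * r_hi >= min(height, width):
        raise ValueError("blobs cannot fit in the lattice")
    rng = np.random.default_rng(seed)
    labels = np.zeros((height, width), dtype=np.int64)
    rows, cols = np.ogrid[:height, :width]
    classes = []
    for b in range(n_blobs):
        if b < K - 1 and n_blobs >= K - 1:
            classes.append(1 + b)  # guarantee each foreground class once
        else:
            classes.append(int(rng.integers(1, K)))
    rng.shuffle(classes)
    for cls in classes:
        r = int(rng.integers(r_lo, r_hi + 1))
        cy = int(rng.integers(r, height - r))
        cx = int(rng.integers(r, width - r))
        mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
        labels[mask] = cls
    return labels


def render_and_noise(
    labels: np.ndarray, means, sigma: float, seed: int = 0
) -> Phantom:
    """Render class means to grey levels and add Gaussian white noise.

    ``clean[s] = means[labels[s]]``; ``noisy = clean + N(0, sigma^2)`` iid,
    left unclipped so that the realized noise is exactly Gaussian.
    """
    labels = np.asarray(labels)
    means = np.asarray(means, dtype=float)
    if labels.max() >= means.size:
        raise ValueError("means must cover every label")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    clean = means[labels]
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()
    return Phantom(labels=labels, clean=clean, noisy=noisy, sigma=float(sigma), seed=seed)


def default_potts_phantom(sigma: float, seed: int = 0, sweeps: int = 120) -> Phantom:
    """The 64x64 three-class Potts suite phantom at the given noise std.

    Gibbs coarsening at beta = 1.5 can extinguish a class; a valid K-class
    phantom needs every class present, so draws where any class falls below
    2% of the pixels are discarded (seed advanced deterministically).
    """
    su = POTTS_SUITE
    n = su["height"] * su["width"]
    for attempt in range(64):
        labels = sample_potts_field(
            su["height"], su["width"], su["K"], su["beta"],
            sweeps=sweeps, seed=seed + 7919 * attempt,
        )
        counts = np.bincount(labels.ravel(), minlength=su["K"])
        if counts.min() >= 0.02 * n:
            break
    else:  # pragma: no cover - 64 failures would mean a broken sampler
        raise RuntimeError("could not draw a phantom with all classes present")
    return render_and_noise(labels, su["means"], sigma, seed=seed + 1)


def default_blob_phantom(sigma: float, seed: int = 0) -> Phantom:
    """The 128x128 two-class blob suite phantom at the given noise std."""
    labels = make_blob_phantom(
        BLOB_SUITE["height"], BLOB_SUITE["width"], BLOB_SUITE["K"],
        BLOB_SUITE["n_blobs"], BLOB_SUITE["radius_range"], seed=seed,
    )
    return render_and_noise(labels, BLOB_SUITE["means"], sigma, seed=seed + 1)
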