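"""Markov random field model for image labeling.

A label field ``x`` on the pixel lattice is modelled as a Gibbs/Potts
distribution on the second-order (8-connected) neighborhood system,

    P(x) = Z^{-1} exp( -U(x) / T ),      U(x) = sum_{<s,r>} V(x_s, x_r),

with the isotropic pairwise Potts potential V(a, b) = -beta if a == b and
+beta otherwise, summed over every unordered 8-neighbor pair (the four clique
orientations: horizontal, vertical and both diagonals).  Observed grey levels
``y`` follow a class-conditional Gaussian feature field,

    P(y_s | x_s = l) = N(y_s; mu_l, sigma_l^2),

and MAP segmentation minimizes the posterior energy

    E(x | y) = U(x) / T  -  sum_s log P(y_s | x_s).

Only local conditionals are ever normalized; the global partition constant Z
is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GibbsPrior",
    "FeatureParams",
    "clique_potential",
    "prior_energy",
    "log_likelihood",
    "local_conditional",
    "posterior_energy",
    "local_energy_delta",
    "neighbor_labels",
]

# Unordered-pair offsets: east, south, south-east, south-west.  Scanning these
# four orientations over the lattice enumerates every unordered 8-neighbor
# pair exactly once (pairs are truncated at the border; no wraparound).
PAIR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

# All eight neighbor offsets of a site.
NEIGHBOR_OFFSETS = tuple(
    (di, dj)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    if not (di == 0 and dj == 0)
)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GibbsPrior:
    """Potts prior on the 8-neighbor system.

    Parameters
    ----------
    beta : float
        Pairwise coupling strength (dimensionless, > 0).  Larger values favor
        smoother label fields.
    temperature : float
        The temperature constant ``T`` dividing the prior energy, > 0.
    """

    beta: float = 1.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass
class FeatureParams:
    """Per-class Gaussian mean/std of the feature field, grey levels.

    ``mu[l]`` and ``sigma[l]`` parameterize class ``l``.  ``canonical()``
    returns an equivalent parameter set re-ordered by ascending mean (the
    identifiability convention used throughout) together with the label
    permutation that realizes it.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D arrays of equal length")
        if self.mu.size < 1:
            raise ValueError("at least one class required")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be > 0")

    @property
    def K(self) -> int:
        return int(self.mu.size)

    def canonical(self) -> tuple["FeatureParams", np.ndarray]:
        """Sort classes by ascending mean.

        Returns the sorted parameters and the permutation ``perm`` such that
        new label ``k`` corresponds to old label ``perm[k]``; old labels are
        remapped via ``relabel = argsort(perm)``.
        """
        perm = np.argsort(self.mu, kind="stable")
        return FeatureParams(self.mu[perm], self.sigma[perm]), perm


def _check_labels(labels: np.ndarray, K: int) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integers")
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError(f"labels must lie in [0, {K})")
    return labels


def clique_potential(label_a: int, label_b: int, prior: GibbsPrior, K: int | None = None) -> float:
    """Potts pair potential: ``-beta`` for equal labels, ``+beta`` otherwise."""
    for lab in (label_a, label_b):
        if lab < 0 or (K is not None and lab >= K):
            raise ValueError(f"invalid class index {lab}")
    return -prior.beta if label_a == label_b else prior.beta


def prior_energy(labels: np.ndarray, prior: GibbsPrior) -> float:
    """Potts energy U(x): sum of the pair potential over every unordered
    8-neighbor pair, counted once, truncated at the image border."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D field")
    energy = 0.0
    for di, dj in PAIR_OFFSETS:
        a = labels[max(0, -di):labels.shape[0] - max(0, di),
                   max(0, -dj):labels.shape[1] - max(0, dj)]
        b = labels[max(0, di):labels.shape[0] + min(0, di),
                   max(0, dj):labels.shape[1] + min(0, dj)]
        same = int(np.count_nonzero(a == b))
        energy += prior.beta * ((a.size - same) - same)
    return float(energy)


def log_likelihood(y, label: int, params: FeatureParams):
    """Gaussian feature-field log density ln P(y | x = label).

    ``y`` may be a scalar or an array; the result has the same shape.
    """
    if label < 0 or label >= params.K:
        raise ValueError(f"invalid class index {label}")
    mu = params.mu[label]
    sigma = params.sigma[label]
    y = np.asarray(y, dtype=float)
    out = -_LOG_SQRT_2PI - np.log(sigma) - (y - mu) ** 2 / (2.0 * sigma**2)
    return float(out) if out.ndim == 0 else out


def _all_log_likelihood(y: np.ndarray, params: FeatureParams) -> np.ndarray:
    """Log-likelihood of every class at every pixel; shape (K,) + y.shape."""
    y = np.asarray(y, dtype=float)
    mu = params.mu.reshape((-1,) + (1,) * y.ndim)
    sigma = params.sigma.reshape((-1,) + (1,) * y.ndim)
    return -_LOG_SQRT_2PI - np.log(sigma) - (y - mu) ** 2 / (2.0 * sigma**2)


def neighbor_labels(site: tuple[int, int], labels: np.ndarray) -> np.ndarray:
    """Labels of the in-lattice 8-neighbors of ``site``."""
    i, j = site
    H, W = labels.shape
    vals = [
        labels[i + di, j + dj]
        for di, dj in NEIGHBOR_OFFSETS
        if 0 <= i + di < H and 0 <= j + dj < W
    ]
    return np.asarray(vals, dtype=labels.dtype)


def local_conditional(
    site: tuple[int, int],
    labels: np.ndarray,
    obs: np.ndarray,
    prior: GibbsPrior,
    params: FeatureParams,
    temperature: float | None = None,
) -> np.ndarray:
    """Normalized conditional P(x_s = l | y_s, neighbors) over the K classes.

    Proportional to exp{ ln P(y_s | l) - (1/T) sum_r V(l, x_r) } with the sum
    over the in-lattice 8-neighbors of ``site``.
    """
    i, j = site
    if not (0 <= i < labels.shape[0] and 0 <= j < labels.shape[1]):
        raise ValueError(f"site {site} outside lattice {labels.shape}")
    T = prior.temperature if temperature is None else temperature
    nbr = neighbor_labels(site, labels)
    K = params.K
    same = np.array([np.count_nonzero(nbr == l) for l in range(K)])
    # V contribution for label l: -beta*same + beta*(n - same)
    pair_energy = prior.beta * (nbr.size - 2 * same)
    log_p = _all_log_likelihood(float(obs[i, j]), params) - pair_energy / T
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


def posterior_energy(
    labels: np.ndarray,
    obs: np.ndarray,
    prior: GibbsPrior,
    params: FeatureParams,
    temperature: float | None = None,
) -> float:
    """Posterior energy E(x|y) = U(x)/T - sum_s ln P(y_s | x_s).

    Lower is more probable; the MAP labeling is the argmin.
    """
    labels = _check_labels(labels, params.K)
    obs = np.asarray(obs, dtype=float)
    if labels.shape != obs.shape:
        raise ValueError(f"lattice mismatch: {labels.shape} vs {obs.shape}")
    T = prior.temperature if temperature is None else temperature
    loglik = np.take_along_axis(
        _all_log_likelihood(obs, params), labels[None], axis=0
    )[0]
    return prior_energy(labels, prior) / T - float(loglik.sum())


def local_energy_delta(
    site: tuple[int, int],
    new_label: int,
    labels: np.ndarray,
    obs: np.ndarray,
    prior: GibbsPrior,
    params: FeatureParams,
    temperature: float | None = None,
) -> float:
    """Change in posterior energy from relabeling ``site`` to ``new_label``.

    Computed from the 8-neighborhood only; agrees with the full recomputation,
    which is what makes single-site Metropolis updates exact.
    """
    i, j = site
    cur = int(labels[i, j])
    if new_label == cur:
        return 0.0
    T = prior.temperature if temperature is None else temperature
    nbr = neighbor_labels(site, labels)
    same_new = int(np.count_nonzero(nbr == new_label))
    same_cur = int(np.count_nonzero(nbr == cur))
    dU = 2.0 * prior.beta * (same_cur - same_new)
    y = float(obs[i, j])
    dloglik = log_likelihood(y, new_label, params) - log_likelihood(y, cur, params)
    return dU / T - dloglik
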