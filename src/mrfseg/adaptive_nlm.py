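"""Adaptive non-local-means denoising with MCMC similar-block search.

The observed image is modelled as ``z(x) = y(x) + n(x)`` with ``n`` additive
Gaussian white noise of standard deviation ``sigma`` (0-255 grey scale).

Two denoisers are provided:

* :func:`nlm_filter` — classic non-local means over a square search window:
  every pixel becomes a convex combination of window pixels, weighted by
  ``exp(-D/h^2)`` where ``D`` is the Gaussian-weighted squared distance
  between the surrounding patches.

* :func:`denoise` — the adaptive two-stage scheme.  Stage one searches, per
  estimation point, for a set of similar d x d blocks with a Metropolis chain
  over block locations: Gaussian random-walk proposals (spatial std
  ``sigma_s``), similarity ``phi = exp(-||F' - F||^2 / C)`` against the
  reference block, and acceptance ``min{1, phi'/phi_prev}``.  The block size
  ``d`` is chosen adaptively: candidate sizes are scanned and the largest
  size whose group-averaged block set is self-consistent (variance below a
  noise-derived threshold) wins.  Stage two estimates each member block as
  the phi-weighted (symmetric, hence "bidirectional") average of the block
  set and aggregates the overlapping block estimates per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels

__all__ = [
    "SearchFailureError",
    "Patch",
    "DenoiseConfig",
    "BlockSet",
    "WeightField",
    "patch_distance",
    "nlm_weights",
    "nlm_filter",
    "propose_location",
    "similarity_phi",
    "acceptance_prob",
    "mcmc_block_search",
    "optimal_block_size",
    "denoise",
    "estimate_noise_sigma",
]


class SearchFailureError(RuntimeError):
    """The block-search chain found fewer than two distinct locations."""


@dataclass(frozen=True)
class Patch:
    """A d x d grey-level block centred at ``center`` (d odd)."""

    center: tuple[int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] % 2 == 0:
            raise ValueError("patch must be square with odd side")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the adaptive denoiser (grey levels unless noted).

    ``sigma`` is the noise std; leave ``None`` to estimate it from the image.
    ``h = h_factor * sigma`` controls attenuation of the non-local weights,
    and the block-similarity constant is ``C = 2 h^2 d^2``.  ``sigma_s`` is
    the spatial std (pixels) of the chain's random-walk proposal, defaulting
    to ``search_radius / 3``.  ``threshold_mode`` picks the adaptive-size
    threshold: ``"scaled"`` uses T = sigma^2 / 4 (variance scale), ``"paper"``
    the literal T = 1 / sigma^2.
    """

    candidate_sizes: tuple[int, ...] = (3, 5, 7, 9)
    N: int = 16
    chain_len: int = 400
    search_radius: int = 10
    sigma_s: float | None = None
    h_factor: float = 0.75
    patch_size: int = 7
    n_groups: int = 4
    sigma: float | None = None
    threshold_mode: str = "scaled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.chain_len < self.N:
            raise ValueError("chain_len must be >= N")
        if any(d % 2 == 0 or d < 3 for d in self.candidate_sizes):
            raise ValueError("candidate sizes must be odd and >= 3")
        if tuple(sorted(self.candidate_sizes)) != tuple(self.candidate_sizes):
            raise ValueError("candidate sizes must be ascending")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be > 0 when given")
        if self.threshold_mode not in ("paper", "scaled"):
            raise ValueError("threshold_mode must be 'paper' or 'scaled'")
        if self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd")

    @property
    def spatial_std(self) -> float:
        return self.search_radius / 3.0 if self.sigma_s is None else self.sigma_s

    def h(self, sigma: float) -> float:
        return self.h_factor * sigma

    def C(self, sigma: float, d: int) -> float:
        return 2.0 * self.h(sigma) ** 2 * d**2

    def size_threshold(self, sigma: float) -> float:
        if self.threshold_mode == "paper":
            return 1.0 / sigma**2
        return sigma**2 / 4.0


@dataclass
class BlockSet:
    """Similar-block set discovered around an estimation point.

    ``members`` are distinct in-lattice block centres (the estimation point
    first by construction of the search), ``blocks`` their d x d values,
    ``mean_block`` the elementwise average and ``variance`` the mean over
    pixels of the per-pixel variance across member blocks.
    """

    center: tuple[int, int]
    size: int
    members: list[tuple[int, int]]
    phis: np.ndarray
    blocks: np.ndarray
    mean_block: np.ndarray = field(init=False)
    variance: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_block = self.blocks.mean(axis=0)
        self.variance = float(self.blocks.var(axis=0).mean())


@dataclass(frozen=True)
class WeightField:
    """Normalized non-local weights w(x, y) of one reference pixel."""

    x: tuple[int, int]
    candidates: list[tuple[int, int]]
    weights: np.ndarray


def _values(p) -> np.ndarray:
    return p.values if isinstance(p, Patch) else np.asarray(p, dtype=float)


def gaussian_patch_kernel(d: int, std: float) -> np.ndarray:
    """Centred 2-D Gaussian kernel on a d x d grid, normalized to sum 1."""
    r = d // 2
    ax = np.arange(-r, r + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * std**2))
    g = np.outer(g1, g1)
    return g / g.sum()


def patch_distance(a, b, kernel_std: float | None = None) -> float:
    """Gaussian-weighted squared Euclidean distance between two patches.

    ``sum_i g_i (a_i - b_i)^2`` with ``g`` a normalized centred Gaussian of
    std ``kernel_std`` (default d/4).  Symmetric; zero iff identical.
    """
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError(f"patch size mismatch: {av.shape} vs {bv.shape}")
    d = av.shape[0]
    g = gaussian_patch_kernel(d, d / 4.0 if kernel_std is None else kernel_std)
    return float((g * (av - bv) ** 2).sum())


def _reflect_pad(image: np.ndarray, radius: int) -> np.ndarray:
    return np.pad(np.asarray(image, dtype=float), radius, mode="reflect")


def _patch_at(padded: np.ndarray, loc: tuple[int, int], d: int) -> np.ndarray:
    # padded has margin d//2, so image coordinate (r, c) maps to padded[r:r+d]
    r, c = loc
    return padded[r:r + d, c:c + d]


def nlm_weights(
    x: tuple[int, int],
    candidates: list[tuple[int, int]],
    image: np.ndarray,
    config: DenoiseConfig,
    sigma: float | None = None,
) -> WeightField:
    """Normalized similarity weights of ``x`` against candidate pixels.

    ``w(x, y) ∝ exp(-D(x, y) / h^2)`` with D the Gaussian-weighted patch
    distance; the normalizer Z(x) makes the weights sum to 1.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    image = np.asarray(image, dtype=float)
    sigma = _resolve_sigma(image, config, sigma)
    h = config.h(sigma)
    d = config.patch_size
    padded = _reflect_pad(image, d // 2)
    ref = _patch_at(padded, x, d)
    dist = np.array([patch_distance(ref, _patch_at(padded, y, d)) for y in candidates])
    logw = -dist / h**2
    logw -= logw.max()
    w = np.exp(logw)
    return WeightField(x=x, candidates=list(candidates), weights=w / w.sum())


def nlm_filter(
    image: np.ndarray, config: DenoiseConfig | None = None, sigma: float | None = None
) -> np.ndarray:
    """Classic non-local means over a square search window (the baseline).

    NL z(x) = sum_y w(x, y) z(y) over the (2R+1)^2 window around x, using the
    same patch weights as :func:`nlm_weights` (near the border, candidates are
    taken from the reflect-padded image).  The output is a convex combination
    of input intensities.
    """
    if config is None:
        config = DenoiseConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("grayscale 2-D image required")
    sigma = _resolve_sigma(image, config, sigma)
    h = config.h(sigma)
    d = config.patch_size
    pr = d // 2
    R = config.search_radius
    g = gaussian_patch_kernel(d, d / 4.0)
    pad = R + pr
    P = _reflect_pad(image, pad)
    H, W = image.shape
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    A = P[pad - pr:pad + H + pr, pad - pr:pad + W + pr]
    for di in range(-R, R + 1):
        for dj in range(-R, R + 1):
            B = P[pad + di - pr:pad + di + H + pr, pad + dj - pr:pad + dj + W + pr]
            sq = (A - B) ** 2
            D = ndimage.correlate(sq, g, mode="constant")[pr:pr + H, pr:pr + W]
            w = np.exp(-D / h**2)
            num += w * P[pad + di:pad + di + H, pad + dj:pad + dj + W]
            den += w
    return num / den


def propose_location(
    current: tuple[int, int],
    sigma_s: float,
    rng: np.random.Generator,
    shape: tuple[int, int],
) -> tuple[int, int]:
    """Gaussian random-walk proposal, rounded to pixels, clamped in-lattice."""
    if not sigma_s > 0:
        raise ValueError("sigma_s must be > 0")
    dr, dc = rng.normal(0.0, sigma_s, 2)
    r = int(np.clip(current[0] + int(np.rint(dr)), 0, shape[0] - 1))
    c = int(np.clip(current[1] + int(np.rint(dc)), 0, shape[1] - 1))
    return (r, c)


def similarity_phi(candidate, reference, C: float) -> float:
    """Block similarity phi = exp(-sum_i (F'_i - F_i)^2 / C), in (0, 1]."""
    if not C > 0:
        raise ValueError("C must be > 0")
    a, b = _values(candidate), _values(reference)
    if a.shape != b.shape:
        raise ValueError("patch size mismatch")
    return float(np.exp(-((a - b) ** 2).sum() / C))


def acceptance_prob(candidate_phi: float, previous_phi: float) -> float:
    """Metropolis acceptance min{1, phi'/phi_prev} for the block chain."""
    if not previous_phi > 0:
        raise ValueError("previous_phi must be > 0")
    return min(1.0, candidate_phi / previous_phi)


def mcmc_block_search(
    s0: tuple[int, int],
    d: int,
    image: np.ndarray,
    config: DenoiseConfig,
    rng: np.random.Generator,
    sigma: float | None = None,
    padded: np.ndarray | None = None,
) -> BlockSet:
    """Metropolis search for the similar-block set of the point ``s0``.

    Runs ``chain_len`` proposal steps, collects the distinct locations the
    chain accepts (``s0`` always included) and keeps the ``N`` of highest
    similarity phi to the reference block.  Ties break in row-major order so
    the result is reproducible.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    sigma = _resolve_sigma(image, config, sigma)
    C = config.C(sigma, d)
    if padded is None:
        padded = _reflect_pad(image, d // 2)
    disp = rng.normal(0.0, config.spatial_std, size=(config.chain_len, 2))
    unif = rng.random(config.chain_len)
    rows, cols, phis = _kernels.block_chain(
        padded, H, W, d // 2, s0[0], s0[1], disp, unif, C
    )
    seen: dict[tuple[int, int], float] = {}
    for r, c, p in zip(rows, cols, phis):
        seen.setdefault((int(r), int(c)), float(p))
    if len(seen) < 2:
        raise SearchFailureError(
            f"block search at {s0} (d={d}) found {len(seen)} distinct locations; "
            "consider widening sigma_s"
        )
    # keep s0 plus the highest-phi distinct members, row-major tie-break
    others = [(loc, p) for loc, p in seen.items() if loc != tuple(s0)]
    others.sort(key=lambda t: (-t[1], t[0]))
    members = [tuple(s0)] + [loc for loc, _ in others[: config.N - 1]]
    phi_arr = np.array([1.0] + [p for _, p in others[: config.N - 1]])
    blocks = np.stack([np.array(_patch_at(padded, m, d)) for m in members])
    return BlockSet(center=tuple(s0), size=d, members=members, phis=phi_arr, blocks=blocks)


def _group_mean_variance(blocks: np.ndarray, n_groups: int, rng: np.random.Generator) -> float:
    """Consistency statistic: mean per-pixel sample variance across the
    group-averaged blocks (random equal split into ``n_groups`` groups)."""
    n = blocks.shape[0]
    if n < n_groups:
        return np.inf
    idx = rng.permutation(n)
    groups = np.array_split(idx, n_groups)
    means = np.stack([blocks[g].mean(axis=0) for g in groups])
    return float(means.var(axis=0, ddof=1).mean())


def optimal_block_size(
    s0: tuple[int, int],
    image: np.ndarray,
    config: DenoiseConfig,
    rng: np.random.Generator,
    sigma: float | None = None,
    padded_by_size: dict[int, np.ndarray] | None = None,
) -> tuple[int, BlockSet]:
    """Adaptive block-size rule: the largest candidate d whose group-averaged
    similar blocks agree to within the noise threshold T.

    Candidate sizes are scanned in ascending order; for each, the block set is
    split into ``n_groups`` groups whose elementwise means {E_p} must have
    variance V < T for the size to qualify.  If no size qualifies the smallest
    candidate is returned.
    """
    image = np.asarray(image, dtype=float)
    sigma = _resolve_sigma(image, config, sigma)
    T = config.size_threshold(sigma)
    chosen: tuple[int, BlockSet] | None = None
    fallback: tuple[int, BlockSet] | None = None
    for d in config.candidate_sizes:
        padded = None if padded_by_size is None else padded_by_size.get(d)
        bs = mcmc_block_search(s0, d, image, config, rng, sigma=sigma, padded=padded)
        if fallback is None:
            fallback = (d, bs)
        V = _group_mean_variance(bs.blocks, config.n_groups, rng)
        if V < T:
            chosen = (d, bs)
    return chosen if chosen is not None else fallback


def _block_set_with_retry(
    s0: tuple[int, int],
    image: np.ndarray,
    config: DenoiseConfig,
    rng: np.random.Generator,
    sigma: float,
    padded_by_size: dict[int, np.ndarray],
) -> tuple[int, BlockSet]:
    """Adaptive-size search with sigma_s widening on failure.

    A block on unique structure can reject every proposal (all candidate
    similarities are ~0 against phi(s0) = 1); widening the proposal std twice
    gives the chain a chance to reach distant look-alikes, and if none exist
    the block is kept as a singleton set (its pixels pass through unsmoothed).
    """
    import dataclasses

    cfg = config
    for widen in range(3):
        try:
            return optimal_block_size(
                s0, image, cfg, rng, sigma=sigma, padded_by_size=padded_by_size
            )
        except SearchFailureError:
            cfg = dataclasses.replace(cfg, sigma_s=cfg.spatial_std * 2.0)
    d = min(config.candidate_sizes)
    block = np.array(_patch_at(padded_by_size[d], s0, d))
    return d, BlockSet(center=tuple(s0), size=d, members=[tuple(s0)],
                       phis=np.array([1.0]), blocks=block[None])


def denoise(
    image: np.ndarray, config: DenoiseConfig | None = None
) -> np.ndarray:
    """Two-stage adaptive non-local denoiser.

    Estimation points are visited on an overlapping grid (stride d/2, where d
    is the locally chosen block size, so every pixel is covered).  For each
    point the optimal-size block set is found by MCMC search; each member
    block is then estimated as the phi-weighted average of the set, and all
    overlapping block estimates are aggregated per pixel by uniform
    averaging.  Output is clipped to [0, 255].  Deterministic given
    ``config.seed``.
    """
    if config is None:
        config = DenoiseConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("grayscale 2-D image required")
    H, W = image.shape
    sigma = _resolve_sigma(image, config, None)
    rng = np.random.default_rng(config.seed)
    padded_by_size = {d: _reflect_pad(image, d // 2) for d in config.candidate_sizes}

    num = np.zeros_like(image)
    cnt = np.zeros_like(image)
    i = 0
    while i <= H - 1:
        row_min_rad = max(config.candidate_sizes) // 2
        j = 0
        while j <= W - 1:
            d, bs = _block_set_with_retry(
                (i, j), image, config, rng, sigma, padded_by_size
            )
            rad = d // 2
            row_min_rad = min(row_min_rad, rad)
            C = config.C(sigma, d)
            # symmetric phi weights between member blocks
            diffs = bs.blocks[:, None] - bs.blocks[None, :]
            phi_mat = np.exp(-(diffs**2).sum(axis=(2, 3)) / C)
            est = (phi_mat[:, :, None, None] * bs.blocks[None]).sum(axis=1)
            est /= phi_mat.sum(axis=1)[:, None, None]
            for (mr, mc), block_est in zip(bs.members, est):
                r0, r1 = max(0, mr - rad), min(H, mr + rad + 1)
                c0, c1 = max(0, mc - rad), min(W, mc + rad + 1)
                br0, bc0 = r0 - (mr - rad), c0 - (mc - rad)
                num[r0:r1, c0:c1] += block_est[br0:br0 + (r1 - r0), bc0:bc0 + (c1 - c0)]
                cnt[r0:r1, c0:c1] += 1.0
            j += max(1, rad)
        i += max(1, row_min_rad)
    uncovered = cnt == 0
    cnt[uncovered] = 1.0
    out = num / cnt
    out[uncovered] = image[uncovered]
    return np.clip(out, 0.0, 255.0)


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust noise-std estimate from the Laplacian residual.

    The image is convolved with the discrete Laplacian, whose response to
    iid Gaussian noise has std ``sigma * sqrt(20)``; the median absolute
    deviation of the residual, scaled to a Gaussian std, estimates sigma
    while staying insensitive to edges.  Invariant to constant offsets.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 8:
        raise ValueError("image must be 2-D and at least 8x8")
    lap = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    resid = ndimage.convolve(image, lap, mode="reflect")
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(mad / 0.6744897501960817 / np.sqrt(20.0))


def _resolve_sigma(image: np.ndarray, config: DenoiseConfig, sigma: float | None) -> float:
    if sigma is not None:
        return float(sigma)
    if config.sigma is not None:
        return float(config.sigma)
    est = estimate_noise_sigma(image)
    return max(est, 1e-3)
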