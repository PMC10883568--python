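# Methods

## Label-field model

The segmentation model is a pairwise Markov random field on the 8-connected
(second-order) neighborhood system. By the Gibbs–MRF equivalence the prior is
`P(x) ∝ exp(−U(x)/T)` with `U(x) = Σ_{⟨s,r⟩} V(x_s, x_r)` summed over every
unordered 8-neighbor pair, truncated at the image border (no padding, no
torus). The pair potential is the isotropic Potts form `V(a,b) = −β·1[a=b] +
β·1[a≠b]`; single-site and higher-order cliques of the second-order system
carry zero potential. This is the standard multi-level-logistic reading of a
pairwise label prior; nothing in the inference depends on the global
partition constant, which is never computed — only local conditionals are
normalized.

Observations are modelled per pixel as class-conditional Gaussians
`y_s | x_s = l ~ N(μ_l, σ_l²)` in grey levels on a 0–255 scale. The
posterior energy minimized by MAP inference is

    E(x|y) = U(x)/T − Σ_s log N(y_s; μ_{x_s}, σ_{x_s}²).

The temperature divides only the prior term; the likelihood is untempered.
Classes are always reported sorted by ascending mean (identifiability
convention; mixture labels are otherwise arbitrary).

## MAP inference

`segment` runs single-site Metropolis with uniform random different-label
proposals, raster-order visitation, and acceptance `min{1, exp(−ΔE)}` where
ΔE is the local energy change computed from the 8-neighborhood only (the
incremental form is tested against full recomputation to 1e-9). The
temperature follows a geometric schedule `T_k = T0·c^k`.

Initialization ("Monte-Carlo initial state"): the intensity histogram is
split into K quantile bands; the band means/stds seed a short EM fit of a
one-dimensional K-component Gaussian mixture, and the initial labels are
drawn stochastically from the likelihood-only posterior. The EM step is
load-bearing: a plain quantile split mis-centers classes whenever class
proportions are unequal (it is a self-consistent fixed point of hard
assignment), and the single-site sampler then freezes whole mis-labelled
domains as the temperature drops — observed as a minority-class collapse on
the Potts phantom. Class means and stds are re-estimated from the current
labeling after **every** sweep (empty classes keep their previous
parameters; stds are floored at 1 grey level) for the same reason: deferring
re-estimation lets a badly initialized class starve irreversibly.

The returned labeling is the best-energy state over all sweep-end states,
evaluated at the reference temperature (the prior's own `T`, default 1), so
`min(energy_trace)` is exactly the returned labeling's posterior energy.
Early stopping triggers when fewer than `conv_tol` of the pixels change in a
sweep.

Defaults: `T0 = 4.0`, `cooling = 0.97`, `max_sweeps = 300`, `burn_in = 20`,
`conv_tol = 1e-4`, `β = 1.0`. These are sized so a 64×64 three-class problem
converges in well under a minute on one core; on the phantom suite the run
typically stops after 15–50 sweeps.

`icm_baseline` shares the initialization but replaces sampling by greedy
argmax of the local conditional with fixed parameters, which makes every
sweep exact coordinate descent: its posterior energy is non-increasing and
it terminates at a fixed point (ties break toward the lower class index).

`mcmc_expectation` estimates an observable's expectation under the chain's
stationary law as the post-burn-in sample-path mean; the sampler itself is
validated against exhaustive enumeration of all labelings of a 2×3 binary
lattice (per-site marginals to 0.01 total variation).

## Adaptive non-local denoising

Noise model: `z = y + n`, `n` iid Gaussian with std σ (given, or estimated
by the median absolute deviation of the discrete-Laplacian residual scaled
by `1/(0.6745·√20)` — robust to edges, exact for iid noise, invariant to
intensity offsets).

**Stage 1 — similar-block search.** For an estimation point s₀ and block
size d, a Metropolis chain over block locations proposes isotropic Gaussian
displacements (std `sigma_s`, default `search_radius/3` with
`search_radius = 10`), rounded to pixels and clamped to the lattice, and
accepts with `min{1, φ(s′)/φ(s_prev)}` where `φ(s) = exp(−‖F_s − F_{s₀}‖²/C)`
is the similarity of the d×d block at s to the reference block
(`C = 2h²d²`, `h = 0.75σ`; this makes φ and the classic NLM weight induce
the same similarity ordering at equal block size). Distinct accepted
locations are collected (s₀ always included; duplicates rejected for
membership but kept for chain dynamics) and the N = 16 highest-φ members
form the block set, ties broken in row-major order for reproducibility.
Patches are extracted from a reflect-padded image. If a chain on unique
structure accepts nothing (all candidate φ ≈ 0 against φ(s₀) = 1), the
proposal std is doubled up to twice; failing that the point is kept as a
singleton set and its pixels pass through unsmoothed.

**Adaptive size rule.** Candidate sizes {3,5,7,9} are scanned in ascending
order. For each size the N members are randomly split into P = 4 equal
groups; the variance statistic V is the per-pixel sample variance across the
P group-mean blocks, averaged over pixels. The chosen d is the largest
candidate with V < T; if none passes, the smallest candidate is used. The
threshold is `T = σ²/4` (`threshold_mode="scaled"`, the default — the
variance of a 4-block average of pure noise), with the literal
`T = 1/σ²` available as `threshold_mode="paper"`. The literal form is
dimensionally inconsistent on a 0–255 intensity scale (it *shrinks* as noise
grows, so no size ever passes on a noisy image, degenerating the rule to the
smallest size; this behavior is retained and used to exercise the fallback
path). One consequence of the scaled threshold worth stating: locally
noise-dominated (flat) regions select the *largest* block size, because
group averaging suppresses their variance below T — which is the desirable
behavior for denoising flat regions, though it means a globally pure-noise
image also selects large blocks rather than small ones.

**Stage 2 — bidirectional averaging.** Estimation points are visited on an
overlapping grid with stride ⌊d/2⌋ (row stride uses the row's smallest
chosen d), which guarantees every pixel is covered by at least one block.
Each member block is estimated as the φ-weighted average of the whole set,
with φ evaluated between block pairs — symmetric in both directions by
construction, which is how the "bidirectional" similarity structure is
realized here — and all overlapping block estimates are aggregated per pixel
by uniform averaging (block-combination estimation). Output is clipped to
[0, 255].

The classic NLM baseline (`nlm_filter`) uses a 7×7 patch, Gaussian patch
kernel of std d/4, weights `exp(−D/h²)` with D the kernel-weighted squared
patch distance (per-pixel normalized), and a 21×21 search window; it is
implemented by shifted-window convolution and tested for exact agreement
with the definitional per-pixel weights in the image interior.

## Phantoms

`synthetic_data` generates exactly the data the model assumes, which is what
makes the recovery tests well-posed: label fields are either Gibbs-sampled
Potts configurations (raster-order Gibbs sweeps of the full conditional from
an iid start) or background-plus-disks blob layouts; rendering assigns each
class its mean grey level and adds iid Gaussian noise on the unclipped real
line (a clipped copy is provided for export and display). The default suite
is a 64×64 Potts phantom (K=3, β=1.5, means 50/128/200) and a 128×128
two-class blob phantom (means 40/190), each at σ ∈ {0, 15, 25, 50}. Gibbs
coarsening at β=1.5 occasionally extinguishes a class; suite draws where any
class holds under 2% of pixels are discarded with a deterministic seed
advance, since a K-class phantom without K classes makes recovery
meaningless. What these phantoms deliberately do *not* contain: texture,
illumination gradients, correlated or signal-dependent sensor noise, and
partial-volume boundaries — so passing here demonstrates correctness of the
inference machinery under its own assumptions, not robustness to real
microscopy data.

## Metrics

Predicted class indices are arbitrary, so all pixel-count metrics first
apply the agreement-maximizing bijection between predicted and true classes
(Hungarian assignment on the K×K contingency table). "Accuracy" is reported
both as macro-averaged per-class intersection-over-union and as plain pixel
accuracy, clearly separated, since the two readings are both in circulation;
recall and DICE are macro-averaged per class (classes absent from the truth,
or empty in both fields, are excluded). Per class, DICE equals the harmonic
mean of precision and recall — asserted as an identity in the tests. PSNR is
`10·log₁₀(255²/MSE)` with an infinite sentinel at zero MSE. SSIM uses a 7×7
Gaussian window (std 1.5) and the standard constants K1 = 0.01, K2 = 0.03 on
a dynamic range of 255.

## Numerical and reproducibility notes

- All per-site inner loops (Metropolis, ICM, Gibbs, the block chain) are
  numba-compiled; every random draw is pre-generated by numpy `Generator`s
  outside the compiled code, so results are bit-reproducible from the seeds
  and independent of the JIT runtime.
- Log-domain softmax with max-subtraction is used for all local
  conditionals; local conditionals sum to 1 within 1e-12.
- Metropolis accepts on `ΔE ≤ 0` without drawing, then on `u < exp(−ΔE)`;
  the per-sweep acceptance fraction is reported.
- The CLI derives one child seed per stage from the global `--seed` via
  `numpy.random.SeedSequence`, records them in the manifest, and never
  mutates its inputs.
- Assignment ties in label matching may resolve either way; metrics are
  permutation-invariant only when the optimal matching is unique (tested
  accordingly).

## Known limitations

- Single-site Metropolis cannot flip whole regions at low temperature;
  severely mis-initialized runs can freeze (mitigated by the EM-seeded
  initialization, not eliminated).
- The denoiser's block search is O(candidate sizes × chain length) per grid
  point; it is sized for ≤256² images on one core, not for throughput.
- K is fixed by the user; there is no model selection over the class count,
  no β estimation, and no non-Gaussian feature field.
- Only additive Gaussian white noise is modelled; no sensor/Poisson noise.
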