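# mrfseg

Markov-random-field image segmentation by Markov-chain Monte Carlo, with an
adaptive non-local-means denoiser whose similar-patch search is itself an
MCMC chain. Built for grey-scale raster images on a 0–255 scale — the kind
produced in biological imaging, where class counts are small, regions are
contiguous, and additive Gaussian sensor noise is the dominant corruption.
Everything is exercisable on built-in ground-truthed phantoms, so no external
data is needed to validate any stage.

## The model

A segmentation is a hidden label field `x = {x_s}` over the pixel lattice,
modelled as a Gibbs/Potts distribution on the 8-connected (second-order)
neighborhood system,

    P(x) = Z⁻¹ exp( −U(x)/T ),    U(x) = Σ_{⟨s,r⟩} V(x_s, x_r),

with the isotropic pair potential `V(a,b) = −β` if `a = b` and `+β`
otherwise, summed over every unordered 8-neighbor pair. Observed intensities
follow a class-conditional Gaussian feature field
`P(y_s | x_s = l) = N(y_s; μ_l, σ_l²)`. MAP segmentation
`x̂ = argmax P(x|y)` is equivalent to minimizing the posterior energy

    E(x|y) = U(x)/T − Σ_s log P(y_s | x_s),

which `mrfseg` does by single-site Metropolis sampling with a geometric
annealing schedule, re-estimating `(μ_l, σ_l)` from the current labeling
every sweep. An ICM (iterated conditional modes) coordinate-descent baseline
is included.

The denoiser assumes `z = y + n` with `n` Gaussian white noise of std `σ`.
For each estimation point it runs a Metropolis chain over patch locations —
Gaussian random-walk proposals, acceptance `min{1, φ′/φ}` with patch
similarity `φ = exp(−‖F′−F‖²/C)` — to collect the `N` most similar d×d
blocks; the block size `d` is chosen adaptively as the largest candidate
whose group-averaged block set stays self-consistent relative to a
noise-derived threshold. Each member block is then estimated as the
φ-weighted average of the set and overlapping estimates are averaged
per pixel. A classic non-local-means filter is provided as the baseline.

## Worked example

```python
import numpy as np
from mrfseg import GibbsPrior, SamplerConfig, DenoiseConfig, segment, denoise
from mrfseg import evaluation as ev
from mrfseg.synthetic_data import default_potts_phantom, default_blob_phantom

# --- segmentation: 64x64 three-class Potts phantom, noise std 15
ph = default_potts_phantom(sigma=15.0, seed=42)
res = segment(ph.noisy, SamplerConfig(K=3, seed=1), GibbsPrior(beta=1.0))
print(f"pixel accuracy : {ev.pixel_accuracy(res.map_labels, ph.labels):.2f} %")
print(f"mean DICE      : {ev.dice(res.map_labels, ph.labels):.2f} %")
print(f"class means    : {np.round(res.params.mu, 1)}  (truth: [ 50. 128. 200.])")

# --- denoising: 128x128 blob phantom, noise std 25
blob = default_blob_phantom(sigma=25.0, seed=3)
restored = denoise(blob.noisy_clipped, DenoiseConfig(sigma=25.0, seed=11))
print(f"PSNR noisy     : {ev.psnr(blob.clean, blob.noisy_clipped):.2f} dB")
print(f"PSNR denoised  : {ev.psnr(blob.clean, restored):.2f} dB")
print(f"SSIM           : {ev.ssim(blob.clean, blob.noisy_clipped):.3f} -> "
      f"{ev.ssim(blob.clean, restored):.3f}")
```

prints

```
pixel accuracy : 99.98 %
mean DICE      : 99.98 %
class means    : [ 50.2 127.5 200.3]  (truth: [ 50. 128. 200.])
PSNR noisy     : 20.43 dB
PSNR denoised  : 28.59 dB
SSIM           : 0.284 -> 0.649
```

The segmenter recovers the phantom's labels almost perfectly and the class
means to well under a grey level; the denoiser gains ~8 dB PSNR and more
than doubles SSIM at this noise level.

The same pipeline is available from the shell:

```sh
mrfseg simulate --seed 1 --out run/         # phantom + ground truth
mrfseg denoise  --input run/noisy.png --sigma 15 --out run/
mrfseg segment  --input run/denoised.png --k 3 --out run/
mrfseg evaluate --pred run/segmentation.png --truth run/labels.png --out run/
mrfseg pipeline --seed 1 --out run/         # all of the above in one go
```

Each command writes a `manifest.yaml` (config, derived seeds, outputs) that
suffices to replay the run exactly.

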