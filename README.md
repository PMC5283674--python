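# tgvshear

Joint **multiplicative-noise (speckle) removal and non-blind deblurring**
for 2-D images, built for coherent imaging data (ultrasound, SAR, laser)
where the observation follows

```
f = (H u) · η,      η ~ mean-one Gamma(L, 1/L)  (variance 1/L)
```

with `H` a known convolution kernel.  The restored image minimizes a
variational energy combining the Gamma maximum-a-posteriori fidelity with
a quadratic ratio term, shearlet-frame sparsity, and second-order total
generalized variation (TGV²):

```
E(u, p) = ⟨log(Hu), 1⟩ + ⟨f/Hu, 1⟩ + α‖Hu/f − 1‖₂²
        + λ Σⱼ ‖SHⱼ(u)‖₁ + γ₁‖∇u − p‖₁ + γ₀‖ε̄(p)‖₁ ,     α ≥ 26/9
```

minimized by ADMM: closed-form shrinkage updates for the splitting
variables, Fourier-diagonal linear solves, and a pointwise damped-Newton
step for the fidelity nonlinearity.  TGV² suppresses the staircase
artifact of plain TV; the band-limited shearlet Parseval frame preserves
curved edges.  Grayscale and RGB images are supported, including
cross-channel blurs.  See `docs/methods.md` for the model, discretization
and parameter details.

The package is aimed at researchers benchmarking despeckling/deconvolution
methods: everything (test images, blur kernels, noise) is generated
programmatically, so no external data is needed.

## Library example

```python
import tgvshear as tv

clean = tv.make_test_image("phantom", 256)            # Shepp-Logan, [0, 255]
psf   = tv.make_psf(tv.BlurSpec("motion", {"length": 5, "angle": 30}))
f, _  = tv.degrade(clean, psf, tv.NoiseSpec("gamma", L=10, seed=1))

cfg = tv.SolverConfig(lam=0.05, alpha=5.0, gamma1=0.9, gamma0=1.8,
                      max_iter=300, tol=2e-5, n_scales=3)
u, diag = tv.admm_restore(f.pixels, psf, cfg)

print(tv.psnr(u, clean.pixels), diag["n_iter"])
```

## Command line

```
tgvshear degrade deg.png --fixture phantom --size 256 --noise gamma -L 10 --seed 1
tgvshear restore deg.png --outdir out --max-iter 300
tgvshear metrics out/restored.png clean.png
tgvshear suite table4        # phantom denoising scenarios (L = 10, 6)
tgvshear suite table5        # motion / Gaussian deblurring + speckle
```

## Worked example

Restoring the 256² Shepp-Logan phantom corrupted by mean-one Gamma
speckle with `L = 10` (no blur), using the package's benchmark preset:

```python
from tgvshear.presets import scenario_run_config
from tgvshear.cli_io import run_restore

cfg = scenario_run_config("denoise_L10", seed=1)
print(run_restore(cfg))
```

prints (timing machine-dependent):

```
n_iter 112
converged True
wall_time_s 17.14
psnr_degraded 23.753076331833448
psnr 27.842107953772704
ssim 0.9712933381818257
rel_err 0.037420448086571335
```

The degraded phantom starts at 23.75 dB PSNR; 112 ADMM iterations (the
relative-change stop 2×10⁻⁵ fired) raise it to 27.84 dB with global SSIM
0.97 — speckle in the flat regions is removed while the skull ring and
interior ellipses keep sharp boundaries.  `run_restore` also writes the
clean/degraded/restored images, a per-iteration diagnostics CSV and a
metrics CSV to `cfg.outdir`.

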