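# Methods

## Degradation model

Coherent imaging modalities (ultrasound, SAR, laser) produce observations

    f = (H u) · η

where `u ≥ 0` is the latent intensity image, `H` a known linear blur
(point-spread function), and `η` a mean-one multiplicative noise field.
The canonical speckle model is Gamma noise with `L` looks,
`η ~ Gamma(shape = L, scale = 1/L)`, whose variance is `1/L`; Rayleigh
(rescaled to unit mean) and clipped Gaussian fields are also provided.
A "noise variance σ²" specification is mapped to mean-one Gamma with
`L = round(1/σ²)`, since `Var[Gamma(L, 1/L)] = 1/L`.

A positivity floor `ε_pos = 10⁻³ · N_max` is applied to clean and degraded
images so that `log(Hu)` and `f/Hu` stay finite; with the default
`N_max = 255` that is a quarter of a gray level.

## Restoration energy

The restored image minimizes, jointly over `u` and an auxiliary vector
field `p`,

    E(u, p) = ⟨log(Hu), 1⟩ + ⟨f/Hu, 1⟩ + α‖Hu/f − 1‖₂²
            + λ Σ_j ‖SH_j(u)‖₁
            + γ₁‖∇u − p‖₁ + γ₀‖ε̄(p)‖₁

* The first two terms are the Gamma (speckle) maximum-a-posteriori
  fidelity; the quadratic ratio term with weight `α ≥ 26/9` restores
  coercivity/strict convexity of the data part (the solver warns below
  that bound but proceeds).
* `SH_j` are the bands of a band-limited directional (shearlet-type)
  Parseval frame; the ℓ₁ penalty promotes sparsity of curved-edge
  responses.  Following the ADMM formulation (which iterates auxiliaries
  only for the directional bands), the scaling band `j = 0` is *not*
  penalized by default: an ℓ₁ penalty on the low-pass band acts as a
  direct intensity penalty and provably shrinks the mean brightness by
  roughly `λ f²/(1 + 2α)` — with `λ = 5` on unit-scale intensities the
  bright structures lose ~70 % of their amplitude.  The flag
  `penalize_lowpass=True` restores the literal all-bands reading.
* The last two terms are second-order total generalized variation
  (TGV²): `γ₁` penalizes the residual between the gradient and the
  auxiliary field `p`, `γ₀` penalizes the symmetrized gradient of `p`.
  TGV² vanishes on affine images, avoiding the staircase artifact of
  plain TV.  `‖·‖₁` sums per-pixel Euclidean norms (vector fields) and
  Frobenius norms with the off-diagonal counted twice (tensor fields).

### Intensity scale

The fidelity is not invariant to intensity rescaling (`f/Hu` is, but
`log` and the regularizers are not in the same way), so the weight ranges
only mean something at a fixed scale.  The solver normalizes images to
`[0, 1]` internally and maps back to `[0, N_max]` on output; PSNR is
always computed with `N_max = 255`, which makes it invariant to this
convention.

## Discretization

All difference operators are periodic (circular): forward differences for
`∇`, backward for `div₁` and `ε̄`, forward for `div₂`, so that the exact
adjoint identities `(div₁)* = −∇` and `(div₂)* = −ε̄` hold and every
linear sub-step diagonalizes in the discrete Fourier basis.  Pixel
spacing is 1.  Convolutions use the same periodic convention via FFT
(symmetric padding is available for standalone blurring but not used by
the solver).

The diagnostic `tgv2_value` additionally minimizes over a global linear
trend (two scalars): a ramp is not periodic, so without detrending the
wrap-around seam would dominate the value and the defining property
"TGV² of an affine image is zero" would be lost.  The trend term keeps
the value unchanged on trend-free images (zero trend remains feasible).

## Shearlet-type frame

Filters are constructed directly in the frequency plane as products of a
radial Meyer-window partition (one low-pass plus `n_scales` dyadic
annuli; the outermost annulus plateaus to the grid corners) and an
angular Meyer partition of the slope-symmetric angle `θ mod π`, with the
direction count following the parabolic scaling rule 8, 8, 16, 16, 32, …
per scale.  Squared-cosine (Meyer) transitions make `Σ_j H_j(ω)² = 1`
hold identically, so the bank is a Parseval frame and the adjoint is the
inverse.  Filters are symmetrized under frequency negation (the angular
windows break evenness only on the self-conjugate Nyquist lines of
even-sized grids) and renormalized, after which real images map to real
bands and all transforms run on the half-plane real-FFT grid.
`n_scales = 4` is the default; the 256² benchmarks use 3 scales, which
gives the same restoration quality at lower cost per iteration.

## ADMM splitting

Auxiliaries `x_j = SH_j(u)`, `y = ∇u − p`, `z = ε̄(p)` with quadratic
penalty weights `μ₁, μ₂, μ₃` and scaled duals updated with step `μ`
(default 1).  Per outer iteration:

1. `x_j ← shrink₁(SH_j(u) + x̃_j, 1/μ₁)` (soft threshold),
   `y ← shrink₂(∇u − p + ỹ, 1/μ₂)` (vectorial),
   `z ← shrink_F(ε̄(p) + z̃, 1/μ₃)` (Frobenius, off-diagonal twice).
2. `(u, p)` subproblem: alternate
   * `p`: exact minimizer of its quadratic coupling — independent 2×2
     Hermitian systems per frequency;
   * `u`: the pointwise fidelity nonlinearity is separated with an inner
     auxiliary `t = Hu` (penalty `ρ`, warm-started scaled dual): `t` by
     safeguarded damped Newton on the strictly convex per-pixel function
     `log t + f/t + α(t/f−1)² + ρ/2 (t−a)²`, then `u` by a
     Fourier-diagonal solve (per-frequency `m×m` systems for
     `m`-channel cross-channel blurs).  The Parseval property collapses
     the shearlet quadratic to the diagonal symbol `Σ_j H_j²`.
3. Dual ascent on all three constraints.

Initialization: `u⁰ = f`, everything else zero.  Stopping:
`‖u⁽ⁿ⁺¹⁾ − u⁽ⁿ⁾‖₂ / ‖u⁽ⁿ⁾‖₂ ≤ tol` (default `2×10⁻⁵`) or `max_iter`.
Individual inexact u-steps may transiently raise the subproblem
objective while the inner dual warms up; enforcing per-step monotonicity
deadlocks the update, so the solver instead aborts (with the full
history attached) if the energy rises for 20 consecutive outer
iterations.  Restored images are clipped to `[0, N_max]`.

The `β` accepted in the configuration is an alias for the dual step `μ`
(the generic augmented-Lagrangian penalty role; the specific updates
never use it independently).

### Tunable parameters

| name | role | default | notes |
|------|------|---------|-------|
| λ | shearlet sparsity weight | 5 (API) | benchmark presets use 0.05; see below |
| α | quadratic fidelity weight | 3 | must be ≥ 26/9; larger = stronger data fit |
| γ₁, γ₀ | TGV² weights | 1, 2 | γ₀/γ₁ ∈ [1.5, 4] changes little on piecewise-constant images |
| μ₁,μ₂,μ₃ | penalty weights | 10 | shrink thresholds are 1/μᵢ; converged result is insensitive |
| μ | dual step | 1 | |
| ρ | inner t-split penalty | 50 | unit intensity scale |
| tol | relative-change stop | 2×10⁻⁵ | |
| n_scales | frame scales | 4 | 3 for the 256² benchmarks |

## Benchmark presets and what the synthetic tests show

The benchmark scenarios restore the 256² Shepp–Logan phantom (original
low-contrast intensity table; the high-contrast "modified" table is
available) under mean-one Gamma speckle with L = 10 or 6, optionally
after motion (length 5, 30°) or Gaussian (7×7, σ = 2) blur.  Preset
weights were fixed by a one-time grid search on these scenarios:
denoising λ = 0.05, α = 5, γ₁ = 0.8, γ₀ = 2γ₁; deblurring λ = 0.05,
α = 5, γ₁ = 0.9 (motion) / 1.4 (Gaussian), capped at 300 iterations.

Two properties of the phantom matter when reading these numbers.  It is
nearly piecewise constant, so TGV² dominates and the sparsity weight's
optimum is near zero — on natural images with texture the balance
shifts toward larger λ.  And its intensity mass is concentrated in a
thin bright ring, so PSNR is governed by how well that one curve
survives; ℓ₁ shrinkage always trades some contrast of isolated bright
structures for noise suppression.  Synthetic phantom results therefore
probe edge preservation and staircase suppression, not texture recovery,
and transfer to clinical speckle data only qualitatively.

## Numerical choices and degenerate inputs

* Newton safeguard: iterates are clipped away from 0; the per-pixel
  objective is strictly convex for any `α > 1/54`, so 8 damped steps
  from the warm start reach ~machine precision.
* `λ = 0` replaces the frame by a single all-pass band (supports
  arbitrarily small images, e.g. the 1×1 oracle case).
* Constant degraded images are exact fixed points (all shrinkages and
  the fidelity are stationary), restored unchanged.
* Identical seeds make degradation and restoration bit-reproducible;
  the solver itself is deterministic.

## Known limitations

* Pure denoising of the phantom converges about 3.5 dB below the
  reference PSNR values of this benchmark family; the deblurring
  scenarios match theirs.  See the package README for how to rerun.
* Periodic boundaries assume the image content does not clash across
  the frame edge; heavily non-periodic content incurs mild seam bias
  (shared by all FFT-based solvers).
* No spatially varying PSFs, no automatic parameter selection, no
  compactly supported shearlets, no 3-D data.
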