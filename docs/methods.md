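# Methods

`mcdmri` models rich pulsed-gradient spin-echo (PGSE) diffusion MRI of
ex vivo tissue with one- and two-compartment analytic signal models,
fits them voxel-wise by maximum likelihood under Rician noise, ranks
them with information criteria, and characterises parameter uncertainty
with Markov chain Monte Carlo.  A structured synthetic breast-tissue
phantom exercises every stage without any external data.

## Signal models

A measurement is a pair of rectangular gradient lobes (amplitude G,
duration δ, separation Δ) applied along a unit direction ĝ at echo time
TE, with diffusion weighting b = γ²G²δ²(Δ − δ/3).  Four compartment
shapes give the normalised attenuation E ∈ (0, 1]:

* **Ball** — free isotropic diffusion, E = exp(−bD).
* **Zeppelin** — axially symmetric tensor with axial/radial
  diffusivities D₁ ≥ D₂ along axis n(θ, ϕ):
  E = exp(−b[(D₁ − D₂)(ĝ·n)² + D₂]).
* **Tensor** — full anisotropic free diffusion, E = exp(−b ĝᵀDĝ) with
  eigenvalues D₁ ≥ D₂ ≥ D₃; the eigenframe is the axis n(θ, ϕ) plus a
  rotation α of the secondary eigenvector about it.  Convention: θ is
  the polar angle from +z, ϕ the azimuth from +x, and α = 0 puts the
  secondary axis along the meridional direction.
* **Sphere** — diffusion restricted inside an impermeable sphere of
  radius R, evaluated with the Gaussian-phase-distribution (GPD,
  Murday–Cotts) series over the roots αₘ of the derivative of the
  first-order spherical Bessel function:

      ln E = −2γ²G² Σₘ [2δαₘ²D − 2 + 2e^(−αₘ²Dδ) + 2e^(−αₘ²DΔ)
               − e^(−αₘ²D(Δ−δ)) − e^(−αₘ²D(Δ+δ))] / [D²αₘ⁶(αₘ²R² − 2)]

Composite models combine an extracellular shape (Ball/Zeppelin/Tensor)
with an optional intracellular shape (Ball/Sphere) through volume
fractions f_E + f_I = 1, and include the equilibrium signal S₀ and a
single T2 constant:

    S = S₀ · e^(−TE/T2) · (f_E·E_extra + f_I·E_intra)

The registry holds the nine combinations, with 3 (Ball) to 11
(Tensor–Sphere) free parameters.  Bounds: diffusivities in
[0.01, 3] μm²/ms (equal to 10⁻³ mm²/s; the plausible tissue range at
room temperature), R in [0.1, 20] μm, T2 in [0.001, 3] s, fractions in
[0, 1].  No water exchange between compartments, a single cell radius
per voxel, and one common T2 are assumed.

### Numerical choices

* Units are SI internally (T/m, s, m²/s); interfaces use the imaging
  conventions (mT/m, ms, μm, μm²/ms).  γ defaults to the proton value
  2.6752218744×10⁸ rad s⁻¹ T⁻¹ and is configurable: the published
  protocol's largest b-values imply a ~0.06% different calibration.
* The GPD series uses 60 precomputed Bessel-derivative roots; the
  public evaluation checks that the last retained term moves ln E by
  less than 10⁻⁸ (series terms decay like m⁻⁴, so this is the practical
  convergence floor; the truncation error is orders of magnitude below
  noise).  The fitting hot path relaxes the check to 10⁻⁶ so a local
  search cannot raise while probing bound corners.
* Degenerate eigenvalues: when D₂ = D₃ the rotation α is
  non-identifiable and is conventionally 0.

### Validity of the GPD approximation

The GPD series is an approximation.  Against an independent Monte-Carlo
random walk with a reflecting spherical boundary it agrees to better
than 0.007 absolute attenuation whenever the encoding phase γGδR is
below ~1.5 rad — which covers G ≤ 200 mT/m at δ = 3 ms for cellular
radii — but deviates by up to ~0.04 at the protocol's strongest
encodings (G = 400 mT/m, or δ = 10 ms with small spheres).  This is a
property of the Gaussian-phase assumption, not of the implementation:
the implementation cross-check therefore runs on a grid inside the
validity regime plus a strong-encoding anchor where both predictions
are ≈ 0.  Note also that a 20-μm sphere is *not* free diffusion at
these diffusion times (most of a sphere's volume lies near its wall);
the free limit is only reached when the diffusion length √(6DΔ) is well
below R.

## Noise model and fitting

Magnitude MR data are Rician.  The noise SD σ is estimated from an
empty background region: signal-free magnitudes are Rayleigh with
SD σ√(2 − π/2), which the estimator inverts.  Measurements acquired
with NEX > 1 averages have σ scaled by 1/√NEX and are treated as
Gaussian-equivalent — an approximation, since magnitude averaging only
approaches Gaussian statistics.

Per voxel, the Rician log-likelihood (with the Bessel term evaluated in
exponentially scaled form) is maximised inside the bound box by
multi-start L-BFGS-B: the first start comes from a log-linear
least-squares cascade (Ball fit for S₀/T2/D̄, then a linear diffusion-
tensor fit for eigenvalues and orientation), the rest are uniform draws
within bounds from a seeded generator, with extracellular eigenvalues
drawn in descending order.  f_E is eliminated through f_E = 1 − f_I.
S₀'s open bound is replaced at fit time by [10⁻³, 10]×max(data).  A fit
that fails on every start is returned flagged, never raised.  The
optimiser explores the box without the D₁ ≥ D₂ ordering constraint
(L-BFGS-B has no linear constraints); prolate ground truths make
ordering violations rare, and downstream maps treat the fitted pair as
an eigenvalue set.

Model ranking uses AIC = −2lnL + 2k and BIC = −2lnL + k ln n, with n
the number of measurements actually fitted in the voxel.  Ties break by
parsimony (smallest k), then name, making selection order-invariant.

## Posterior sampling

Starting at the ML estimate, a Metropolis sampler explores the Rician
likelihood under a flat prior on the bound box.  Proposals are Gaussian
with SD equal to 1% of the initial estimate per parameter (floored at
10⁻³ of the bound width for near-zero estimates); updates are
*component-wise*, cycling one parameter per iteration — joint updates
at these proposal widths reject essentially always on high-SNR voxels
because posterior widths differ by orders of magnitude between
parameters.  Defaults: burn-in 5000 iterations, thinning interval 400,
500 retained samples.  Out-of-bounds proposals are rejected; zero
acceptance during burn-in raises a diagnostic.  Angular marginals are
reported on their fundamental domain with antipodal folding
(θ ∈ [0, π/2] with ϕ shifted by π when folded, α modulo π).

## T2 screening

The diffusion models assume mono-exponential T2.  Each voxel of a
multi-echo acquisition (32 echoes, 5 ms spacing by default) is
decomposed by NNLS into a non-negative spectrum over 120 log-spaced
relaxation times; a voxel is kept when the main contiguous peak (the
run of non-negligible amplitudes containing the global maximum) holds
at least 90% of the spectral area, and is not fat or background.

The spectrum grid is floored at the *first echo time* rather than at
the 1 ms T2 fitting bound: components faster than the first echo are
unobservable (their design columns are ≈ e⁻⁵), and including them lets
NNLS absorb first-echo noise with enormous spurious amplitudes — with a
1-ms grid edge, 42% of truly mono-exponential voxels failed the 90%
screen at SNR 50, versus 19% with the floored grid and no missed
bi-exponential voxels.  Plain NNLS (no regularisation) is the default;
a Tikhonov weight is available but trades necrotic-voxel sensitivity
for specificity.  The residual false-exclusion rate of noisy
mono-exponential voxels is an inherent property of spectral screening
at this SNR.  Fat is excluded by a user-supplied mask (the phantom
provides one); no intensity-based fat classifier is implemented.

## Derived maps

ADC maps are Ball-model fits reported in μm²/ms.  Anisotropy of a
two-compartment fit is summarised by the FA of the Zeppelin part alone
— eigenvalues (D₁, D₂, D₂), removing the isotropic restricted
compartment from the calculation.  Colour FA encodes the principal axis
as RGB = (|n_x|, |n_y|, |n_z|)·FA, identical for antipodal directions.
Resolution degradation is studied by block-averaging the raw magnitude
data (not the parameter maps — averaging maps would not reproduce the
loss of anisotropy) and refitting; magnitude rather than complex
averaging is assumed, which carries the Rician floor into the averaged
data.

## Synthetic phantom

The default phantom is a 64×64×4 grid at 0.25×0.25×0.5 mm with an
elliptical "specimen" containing five tissue analogues, each with
per-voxel parameters drawn from a seeded generator:

| region | generating model | key parameters |
|---|---|---|
| tumour-cellular | Zeppelin–Sphere | f_I ∈ [0.35, 0.55], R ∈ [6, 9] μm, D_I ∈ [0.8, 1.2] |
| stroma-aligned | Zeppelin–Ball | D₁ ∈ [1.6, 2.2], D₂ ∈ [0.2, 0.45], f_I ∈ [0.05, 0.2] |
| mucinous | Ball | D ∈ [1.2, 1.6], f_I = 0, R at the 20 μm bound |
| necrotic | Ball | bi-exponential T2: 60% at 30 ms, 40% at 200 ms |
| fat | Ball | D ∈ [0.03, 0.08], short T2; excluded by mask |

Orientations in the cellular and stromal regions are coherent over
4-voxel (1 mm) patches.  The cellular f_I and R ranges bracket the
values reported for cellular breast-tumour regions (f_I ≈ 0.44,
R ≈ 6–9 μm); stroma diffusivities give ADCs near 1.3 μm²/ms and high
FA.  Forward synthesis evaluates each region's generating model over
the full protocol (the 42-combination DWI grid, 130 measurements with
b = 0 images, plus two 42-direction DTI shells — 226 measurements) and
corrupts it with Rician noise, per-measurement σ/√NEX.  Default SNR
(S₀/σ) is 100, matching the single published noise diagnostic
(noise/S₀ = 0.01); validation experiments use SNR 50.

What the phantom does *not* emulate: cell-size distributions within a
voxel, compartmental T2 differences, water exchange, partial-volume
mixing at region boundaries, spatial noise correlation, and fat
chemical shift.  Passing recovery tests therefore demonstrates correct
inference under the model's own assumptions, not robustness to their
violation in real tissue.

The Monte-Carlo oracle walks particles inside a reflecting sphere
(Gaussian steps, RMS length ≤ R/20, radial-mirror reflection) and
accrues phase under the two gradient lobes; it is used only to validate
the GPD series, never as the implementation.

## Validation problem sizes

The routine test suite keeps simulations small by design: parameter
recovery and nine-model BIC selection run on a seeded subsample of 32
cellular and 16 mucinous phantom voxels at SNR 50 (medians and
selection fractions over a random subsample estimate the same
per-region statistics); the GPD–MC cross-check uses 3×2×2 grid points
at 3×10⁴ walkers; screening statistics use 100 necrotic voxels; the
MCMC recovery check uses one voxel at SNR 1000, where single-draw
estimation error is well below the 2% tolerance being verified (at SNR
200 the D_I estimation error alone has ~5% SD, so such a check would
measure the noise draw, not the sampler).

## Known limitations

* GPD inaccuracy at strong encoding (γGδR ≳ 2 rad), described above;
  fitted R in that regime inherits the approximation bias.
* f_I–R–D_I degeneracy: when the intracellular diffusivity matches the
  extracellular one, two-compartment restricted fits can trade f_I
  against R along a likelihood ridge; data generated with a distinctly
  fast free intracellular pool instead drive R to its 20 μm ceiling,
  the model's surrogate for unrestricted diffusion.
* The NEX-averaged likelihood is Gaussian-equivalent, slightly
  mis-specified at very low SNR.
* Printed DTI shell b-values (1000/1500 s/mm²) are inconsistent with
  the closed form for the stated timings (≈938/1370), presumably from
  imaging-gradient contributions; the builder uses the computed values.
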