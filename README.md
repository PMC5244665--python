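# mcdmri — multi-compartment diffusion MRI microstructure modelling

`mcdmri` analyses rich pulsed-gradient spin-echo (PGSE) diffusion MRI of
ex vivo tissue — the kind of multi-b-value, multi-diffusion-time
protocol used to probe breast-cancer microstructure at high field.  The
conventional apparent diffusion coefficient (ADC) collapses all tissue
water into one decay constant; this package instead fits a family of
one- and two-compartment models in which extracellular water diffuses
freely (isotropically or anisotropically) and intracellular water is
restricted inside impermeable spheres, separating cell volume fraction
from cell size.

For practitioners of quantitative diffusion MRI it provides, per voxel:

* **Signal models** — Ball, Zeppelin (axially symmetric tensor), Tensor,
  and Sphere (restricted diffusion via the Gaussian-phase-distribution /
  Murday–Cotts series), combined into nine composite models
  S = S₀·e^(−TE/T2)·(f_E·E_extra + f_I·E_intra) with 3–11 free
  parameters (Ball … Tensor–Sphere).
* **Rician maximum-likelihood fitting** with background noise estimation
  (σ = SD/√(2 − π/2) of an empty region), NEX-aware noise scaling, and
  multi-start box-constrained optimisation.
* **Model selection** by AIC = −2lnL + 2k and BIC = −2lnL + k·ln n.
* **Posterior sampling** by component-wise Metropolis (burn-in 5000,
  thinning 400, 500 retained samples, 1%-of-estimate proposals).
* **T2 screening** — NNLS relaxation spectra exclude voxels whose main
  peak holds < 90% of the spectral area (non-mono-exponential T2, e.g.
  necrosis).
* **Derived maps** — ADC, f_I, R, Zeppelin FA with the restricted
  compartment removed, direction-encoded colour FA, and block-average
  downsampling for resolution studies.
* **A synthetic breast-tissue phantom** (cellular tumour, aligned
  stroma, mucinous, necrotic, fat) with ground truth, plus a
  Monte-Carlo reflecting-sphere walker used to validate the GPD series.

See `docs/methods.md` for the model equations, assumptions, numerical
choices and limitations.

## Worked example

Fit candidate models to one synthetic cellular-tumour voxel at SNR 50
over the full 226-measurement protocol (42 gradient
duration/separation/strength combinations × 3 directions, b = 0 images,
and two 42-direction DTI shells):

```python
import numpy as np
from mcdmri.protocol import b_value, build_full_protocol
from mcdmri.compartments import (PrecomputedScheme, ParamVector,
                                 get_model, predict_scheme)
from mcdmri.fitting import NoiseEstimate, fit_voxel
from mcdmri.selection import select_models
from mcdmri.synthgen import add_rician_noise

print(f"b(G=400, d=3, D=10) = {b_value(400, 3, 10):.1f} s/mm^2")

scheme = build_full_protocol()
cache = PrecomputedScheme(scheme)
spec = get_model("Zeppelin-Sphere")
truth = ParamVector(D1=0.95, D2=0.60, theta=1.0, phi=0.7,
                    D_I=1.0, R=7.5, f_I=0.44, S0=1.0, T2=0.07)
rng = np.random.default_rng(0)
data = add_rician_noise(predict_scheme(spec, truth.to_array(spec), cache),
                        1/50, rng, n_avg=cache.n_avg)
noise = NoiseEstimate(sigma=1/50)
fits = {name: fit_voxel(data, scheme, name, noise, n_starts=3, seed=1,
                        cache=cache)
        for name in ("Ball", "Zeppelin", "Zeppelin-Ball", "Zeppelin-Sphere")}
sel = select_models(fits)
for name, d in sel.per_model.items():
    print(f"{name:16s} lnL={d['lnL']:8.1f}  k={d['k']:2d}  BIC={d['BIC']:8.1f}")
print("best by BIC:", sel.best_bic)
zs = fits["Zeppelin-Sphere"].params
print(f"fitted f_I={zs.f_I:.3f} (true 0.440), R={zs.R:.2f} um (true 7.50)")
```

prints

```
b(G=400, d=3, D=10) = 927.5 s/mm^2
Ball             lnL=   451.4  k= 3  BIC=  -886.6
Zeppelin         lnL=   480.7  k= 6  BIC=  -929.0
Zeppelin-Ball    lnL=   539.1  k= 8  BIC= -1034.9
Zeppelin-Sphere  lnL=   602.7  k= 9  BIC= -1156.7
best by BIC: Zeppelin-Sphere
fitted f_I=0.428 (true 0.440), R=7.66 um (true 7.50)
```

The 927.5 s/mm² matches the protocol's printed strongest short-timing
b-value (928 after rounding).  BIC decisively prefers the generating
Zeppelin–Sphere model — a restricted intracellular pool plus an
anisotropic extracellular pool — over its unrestricted and isotropic
reductions, and the intracellular volume fraction and cell radius are
recovered to within a few percent from a single noisy voxel.

The same stages run from the shell:

```sh
mcdmri run --out results/demo --seed 1 --snr 100 --max-voxels 200
mcdmri simulate --out data/phantom --seed 1        # phantom dataset only
mcdmri fit --dwi data/phantom/dwi.nii.gz --scheme data/phantom/scheme.txt \
           --models Zeppelin-Sphere --sigma 0.01 --out fits.csv
```

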