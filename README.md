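# dsbdyn

Quantitative analysis of the **early DNA double-strand-break (DSB) response**
in living cells: how fast repair proteins such as NBS1 (reporting the MRN
sensor complex), ATM and MDC1 accumulate at radiation-induced foci, how
tightly they bind there, and why accumulation accelerates as the lesion
density (LET, in keV/µm) of the incident charged particles grows.

The package is aimed at researchers analyzing live-cell FRAP and beamline
recruitment measurements, and at modelers who want a small, fully tested
reaction-kinetic description of the MRN–ATM–γH2AX–MDC1 signaling axis.

## What it computes

**FRAP forward models and fitting** (`frap_models`, `frap_fitting`)

* Pure diffusion in a uniform circular bleach spot (Soumpasis):
  `F(t) = e^(−2τ_D/t) [I₀(2τ_D/t) + I₁(2τ_D/t)]`, `τ_D = w²/4D`.
* Diffusion–reaction with nucleus-wide ("global") binding sites, solved in
  the Laplace domain and inverted numerically with the Stehfest algorithm.
* Diffusion–reaction with focus-confined ("local") binding sites: a
  two-region radial boundary-value problem (binding only inside the bleached
  focus, pure diffusion outside, zero flux at the nuclear envelope), solved
  in closed form per Laplace variable and validated against an independent
  finite-difference PDE solver.
* Double normalization of raw measurements, effective-diffusion estimation
  (`D_eff = D/(1 + k*_on/k_off)`), binding-constant estimation with a
  13×13 decade start-value grid (10⁻⁶…10⁶ 1/s), cube-root mass scaling of
  diffusion coefficients and mean traversal times `t = r²/4D`.

**Recruitment kinetics** (`recruitment_analysis`)

* Normalization of beamline curves to baseline 0 / plateau 1 and extraction
  of the mono-exponential time constant τ (time to 63% of plateau), tabulated
  against LET.

**Kinetic model of focus formation** (`ddr_model`, `param_estimation`)

* A minimal mass-action ODE model: MRN binds DSB ends directly (*inner
  focus*, capacity ∝ LET via 28 DSBs per 170 keV/µm) and, after ATM
  activation, H2AX phosphorylation and MDC1 recruitment, to MDC1-decorated
  chromatin (*outer focus*, capacity 3500 sites). Variants: CK2 inhibition
  (no outer MRN binding) and diffusion-limited MDC1 supply (∝ √(4Dt)).
* Joint Nelder-Mead fitting of one shared parameter set to whole panels of
  recruitment curves, with only the DSB number differing between curves.

**Synthetic data** (`synthetic_data`) regenerates every input the pipeline
consumes — raw FRAP triplets and multi-LET recruitment panels — from the
forward models with seeded noise, so all estimators are testable round-trip.

## Worked example

```python
import numpy as np
from dsbdyn import (BleachGeometry, BindingRates, DiffusionParams, FrapCurve,
                    fit_binding_constants, local_binding_frap)

geom = BleachGeometry(spot_radius_um=1.5, nucleus_radius_um=9.4)

# MDC1 binding at X-ray-induced foci: generate a noise-free recovery curve
# at the measured constants, then refit it blind via the decade start grid
truth = BindingRates(kon_star=587e-3, koff=425e-5)   # 1/s
t = np.geomspace(0.5, 5 / truth.koff, 120)
y = local_binding_frap(t, DiffusionParams(0.029), truth, geom)

fit = fit_binding_constants(FrapCurve(t, y), "local_binding",
                            DiffusionParams(0.029), geom)
print(f"k*_on = {fit.rates.kon_star:.4g} 1/s, k_off = {fit.rates.koff:.4g} 1/s,"
      f" starts tried = {fit.start_values_tried}")
```

prints

```
k*_on = 0.587 1/s, k_off = 0.00425 1/s, starts tried = 169
```

i.e. the effective association rate (0.587 1/s) and dissociation rate
(4.25×10⁻³ 1/s) of MDC1 at damaged chromatin are recovered exactly from the
curve alone, after searching all 169 decade start pairs.

The command line mirrors the library:

```
dsbdyn report                                  # mass-scaled D and traversal times
dsbdyn simulate-recruitment --let 170 --let 10290 --out panel.csv
dsbdyn fit-recruitment panel.csv               # tau vs LET table
dsbdyn fit-model panel.csv --restarts 2        # shared-parameter ODE fit
```

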