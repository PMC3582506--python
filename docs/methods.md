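# Methods

This note documents the models implemented in `dsbdyn`, their assumptions,
the default parameters and the numerical choices, in the package's own
words. No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## FRAP forward models

All three models describe recovery of fluorescence in a uniform circular
bleach spot of radius *w* inside a cylindrical nucleus of radius *R_n*,
after an instantaneous bleach at *t* = 0 that leaves a fraction θ
(`bleach_depth`) of the pre-bleach intensity inside the spot. The measured
laser spot has a FWHM of 3.0 µm; the uniform-disc idealization uses
*w* = FWHM/2 = 1.5 µm by default, and *R_n* = 9.4 µm. Bound complexes are
immobile; binding is first-order with effective association rate *k\*_on*
(intrinsic on-rate × equilibrium free-site density) and dissociation rate
*k_off*.

**Pure diffusion.** The Soumpasis closed form
F(t) = e^(−2τ_D/t)[I₀(2τ_D/t) + I₁(2τ_D/t)], τ_D = w²/4D, evaluated with
exponentially scaled Bessel functions (stable at arbitrarily small *t*).
The curve depends on time only through t/τ_D.

**Global binding.** Binding sites distributed homogeneously through the
nucleus. The Laplace-domain solution

F̄(p) = 1/p − (F_eq/p)[1 − 2K₁(qw)I₁(qw)][1 + k*_on/(p+k_off)] − C_eq/(p+k_off),
q² = (p/D)(1 + k*_on/(p+k_off)),

with F_eq = k_off/(k*_on+k_off), C_eq = 1 − F_eq, is inverted with the
Stehfest algorithm. The Bessel product K₁(x)I₁(x) is computed from scaled
functions `k1e·i1e`, which is exact and overflow-free at any argument.

**Local binding.** Sites confined to the bleached focus (bleach region,
binding region and focus coincide — no separate focus radius is exposed
because none is measured). Per Laplace variable *p* the two-region problem
— reversible binding inside *r* < *w*, pure diffusion outside, regularity at
0, continuity of concentration and flux at *w*, zero flux at *R_n* — is
solved in closed form with the basis A·I₀(qr) inside and
E·[I₀(vr)K₁(vR_n) + K₀(vr)I₁(vR_n)] outside (the bracket has zero radial
derivative at *R_n* by construction), v² = p/D. Growth factors of the
scaled Bessel functions are absorbed into the coefficients, so no
overflow or singular linear system arises. The reported value is the
disc average of free + bound over *r* < *w*, normalized to pre-bleach.

*Pool normalization.* In a bounded nucleus the bleached fluorophores are
gone for good, so the raw pre-bleach-normalized disc signal plateaus at the
redistribution value T₁/T₀ < 1 (T₀ = F_eq·R_n² + C_eq·w², T₁ = T₀ −
(1−θ)w²). Measured curves are *double normalized* — divided by the
whole-cell signal — which removes exactly that loss. The model therefore
applies the same constant factor T₀/T₁ by default (`pool_correction=True`),
so model and data share one convention and the curve recovers to 1;
the raw bounded-domain solution is available with `pool_correction=False`
and is the convention used when comparing against the finite-difference
oracle or the unbounded Soumpasis limit.

*Unbound-protein mobility.* Following the measurement procedure, the local
model is evaluated with the effective diffusion coefficient obtained from
untreated-cell FRAP (for MDC1: 0.029 µm²/s); the global model takes a free
or fixed D by configuration.

**Stehfest inversion.** f(t) ≈ (ln2/t) Σ V_j f̄(j ln2/t) with exact-integer
weights; N = 12 terms by default (the double-precision accuracy/round-off
compromise; N is configurable, even, 6–18). Verified against five
closed-form transform pairs; accuracy is ~10⁻⁵ for smooth transforms and
~10⁻³ for the 1/√p weak singularity. Curve values that exceed 1 by less
than 10⁻⁴ (inversion error near the plateau) are clamped to 1; larger
excursions raise an error.

## FRAP fitting

Raw triplets (bleach-ROI, whole-cell, optional background) are double
normalized: out = [roi−bg]/mean_pre[roi−bg] × mean_pre[whole−bg]/[whole−bg].
Acquisition photobleaching cancels exactly. Fits exclude pre-bleach frames
and use unweighted residuals (no weighting scheme is prescribed by the
measurements emulated here).

Diffusion fits optimize log₁₀D (bounded 10⁻⁶…10⁴ µm²/s) from three spread
starts. Binding fits hold D fixed, permute start values for (k\*_on, k_off)
over the decade grid 10⁻⁶…10⁶ (13×13 pairs), run a bounded trust-region
least-squares refinement in log₁₀ space from every start (bounds
10⁻⁸…10⁸ 1/s), then polish the three best basins plus the no-binding
boundary. Among polished fits whose SSE agrees within 0.1% the smallest
association rate is reported: a parsimony tie-break that resolves the
nested pure-diffusion limit, where k\*_on is structurally non-identifiable
(any fast-exchange pair with small k\*_on/k_off fits equally well).

Mobility arithmetic: D_calc = D_ref(m_ref/m)^{1/3} for spherical proteins of
equal density; traversal time t = r²/4D (2-D mean-squared displacement).
Display rounding is 2 significant figures.

## Recruitment analysis

Curves are normalized to pre-irradiation mean 0 and fitted plateau 1. The
plateau is estimated jointly with τ by least squares on
I(t) = P(1 − e^{−(t−lag)/τ}) rather than from the last frames (robust to
noise at the curve end). τ is by construction the time after onset at which
the curve reaches 1 − 1/e ≈ 63% of P. The onset lag is fixed at 0 by
default (NBS1, ATM and MDC1 accumulate without measurable delay) and can be
freed for late recruiters with a pronounced lag phase. A curve whose fitted
plateau is below 3 pre-irradiation standard deviations is flagged
"no recruitment" instead of being scaled. The reported uncertainty of τ is
the asymptotic standard error from the fit Jacobian.

## The kinetic model of focus formation

Species (relative concentrations in a fixed effective volume around the
damage foci of one traversal): free MRN, free inner sites, inner-bound MRN
(bare / with captured ATM / with active ATM), free ATM, free active ATM,
H2AX, free γH2AX, free MDC1, recruited MDC1, outer-bound MRN and
outer-bound active ATM. Reactions:

1. MRN + inner site ⇌ MRN_inner (k_mi_on, k_mi_off)
2. ATM + MRN_inner → MRN_inner·ATM (k_act_on) — capture
3. MRN_inner·ATM → MRN_inner + ATM* (k_act) — activation-release
4. ATM* + MRN_inner ⇌ MRN_inner·ATM* (k_ai_on, k_ai_off)
5. ATM* + H2AX → ATM* + γH2AX (k_ph, catalytic)
6. MDC1 + γH2AX ⇌ MDC1_recruited (k_md_on, k_md_off)
7. MRN + MDC1_recruited ⇌ MRN_outer (k_mo_on, k_mo_off)
8. ATM* + MDC1_recruited → ATM_outer (k_ao_on, irreversible)

MRN whose inner site is occupied by ATM in either form cannot dissociate
(reactions 2–4 suppress the k_mi_off channel), which produces the transient
inner-MRN overshoot at high LET once ATM activation saturates.
Deliberately absent, to keep the model minimal: free-ATM
autophosphorylation, γH2AX dephosphorylation, ATM dissociation from the
outer focus and H2AX phosphorylation by outer-bound ATM.

Bookkeeping on recruited MDC1 uses independent site occupancies: MRN
docking and ATM docking are independent saturable occupancies of the
recruited pool (no combinatorial complexes), and only cargo-free recruited
MDC1 — fraction (1−M_outer/R)(1−ATM_outer/R) of R under independence —
undergoes k_md_off. Both choices are exposed in one place
(`build_reaction_system`) and keep all four conservation laws exact by
construction.

Damage input: inner-site capacity = sites_per_dsb × DSB, with DSB =
(28/170) × LET — continuous, no rounding, since it enters only as a
capacity scale. Variants: `ck2_inhibited` sets k_mo_on = 0 (CK2 inhibition
abolishes the MDC1–NBS1 interaction, isolating inner binding);
`mdc1_diffusion_limited` caps available MDC1 at c_geom·√(4Dt) with
D = 0.029 µm²/s — the diffusive supply in cylindrical geometry, with
c_geom a configuration parameter (no measured value exists for it).

**Default parameters.** k_md_off = 425×10⁻⁵ 1/s is the measured X-ray MDC1
dissociation rate. The MRN dissociation defaults (k_mi_off = k_mo_off =
10⁻³ 1/s) are explicit placeholders — the per-LET measured table they
would come from is not reproduced here — and must be set from configuration
for quantitative reuse. The remaining rates and totals (mrn_total 4000,
atm_total 1500, mdc1_total 10000, h2ax_total 3500, k_mi_on 5×10⁻⁶,
k_act_on 4×10⁻⁶, k_act 0.05, k_ai_on 10⁻⁶, k_ai_off 5×10⁻⁴, k_ph 4.5×10⁻⁴,
k_md_on 5×10⁻⁴, k_mo_on 10⁻⁵, k_ao_on 10⁻⁶) were chosen once so that the
default model expresses the documented phenomenology on the 0–700 s
observation window: recruitment time constants that fall from ~270 s at
170 keV/µm to ~70 s above 10⁴ keV/µm; ATM activation that saturates within
~10 minutes at uranium-like LET but stays far from saturation at carbon
LET; a transient inner-MRN dip ~160 s into a high-LET simulation; MDC1
recruitment that saturates at the outer-site capacity 3500 with
binding-dominant margins (k_md_on × free MDC1 ≫ k_md_off). They are model
defaults, not measured constants.

**Integration.** `scipy.integrate.solve_ivp`, LSODA by default (the system
becomes moderately stiff at high LET), relative tolerance 10⁻⁸, absolute
tolerance 10⁻¹⁰ × the largest pool. Conservation of all four pools holds to
<10⁻⁶ relative along every tested trajectory. Steady-state quantities
extend the horizon geometrically until the trailing 1000 s change is below
0.1%.

## Shared-parameter estimation

The objective is the plain sum of squared residuals over all curves and
time points of a panel; every curve is simulated with the same parameter
set, only the DSB number (from the curve's LET) differs. Because measured
curves are plateau-normalized per curve, the model counterpart of each
measurement is its own plateau-normalized signal times a per-protein scale
factor (truth value 1 for synthetic panels); scales are shared per protein,
switchable. MDC1 curves are excluded from the default objective and
compared post hoc (their recruitment is diffusion-influenced at low LET and
nucleus-wide-binding-influenced at high LET, neither of which the standard
variant represents); a config switch includes them.

Optimization is Nelder-Mead in log₁₀ parameter space (rates span decades;
the simplex is far better conditioned there), adaptive variant, with
seeded multi-start (default 5 restarts, spread 0.3 log₁₀ units) because the
simplex is a local method. FRAP-derived dissociation rates are passed as
fixed parameters. A failed simulation contributes a large finite penalty
and is logged, so one bad vertex cannot abort a fit. Results are
deterministic given (panel, config, seed).

## Synthetic data

The generator emulates the acquisition schedules of the emulated
experiments: FRAP with 5 pre-bleach frames and post-bleach sampling to
several multiples of the slowest timescale; recruitment over 0–700 s with
pre-irradiation frames. Noise is multiplicative Gaussian (σ default 0.02,
matching the visual scatter of published recruitment data without claiming
their noise model); acquisition photobleaching is an exponential decay
applied to both ROI and whole-cell series and cancels under double
normalization. Seeded runs are bit-reproducible.

What the generator does *not* emulate — and therefore what passing
round-trip tests do not show about real data: focal drift and registration
error, photon-counting statistics, cell-to-cell variability of geometry and
expression level, reversible photophysics, 3-D bleach profiles, and any
model misspecification (real recruitment is not exactly the minimal
reaction set, real FRAP spots are not uniform discs). Parameter-recovery
rates quoted by the tests are therefore upper bounds on what identical
procedures achieve on measured curves.

## Known limitations

* The local-binding FRAP model assumes one bound state and immobile
  complexes; multi-state binding or anomalous diffusion are out of scope.
* The exact reaction-rate laws of the kinetic model (e.g. the explicit
  ATM-capture intermediate versus single-step activation) are one of
  several minimal formulations consistent with the documented interaction
  scheme; steady-state capacities and conservation structure do not depend
  on this choice, transient shapes can.
* The nucleus-wide γH2AX/MDC1 extension at very high LET and repair-pathway
  proteins (DNA-PKcs, Ku70/80, 53BP1 mechanism) are deliberately excluded;
  53BP1-like curves serve only as lag-phase fixtures for the recruitment
  fitter.
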