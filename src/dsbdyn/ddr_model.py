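"""Minimal mass-action model of the early DNA double-strand-break response.

The model tracks, in a fixed effective volume around the damage foci of one
ion traversal, the MRN sensor complex (reported via its NBS1 subunit), the
ATM kinase, the histone variant H2AX and the mediator MDC1.  Two binding
compartments exist:

* the *inner focus*: MRN binds reversibly to sites at the DSB ends, whose
  number scales linearly with LET; inner-bound MRN captures free ATM and
  releases it as active ATM (activation), and active ATM can re-bind inner
  MRN — MRN carrying ATM in either form cannot dissociate;
* the *outer focus*: active ATM phosphorylates H2AX (catalytically), MDC1
  binds the resulting γH2AX, and recruited MDC1 provides docking sites for
  further MRN (reversible) and active ATM (irreversible in the minimal
  model), independent of each other.

Deliberately absent (minimal model): free-ATM autophosphorylation, γH2AX
dephosphorylation, ATM dissociation from the outer focus, and H2AX
phosphorylation by outer-bound ATM.

All concentrations are relative units in that fixed volume; rates are 1/s
(first order) or 1/(conc·s) (second order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

STANDARD = "standard"
CK2_INHIBITED = "ck2_inhibited"
MDC1_DIFFUSION_LIMITED = "mdc1_diffusion_limited"
VARIANTS = (STANDARD, CK2_INHIBITED, MDC1_DIFFUSION_LIMITED)

#: printed X-ray MDC1 dissociation rate from FRAP (1/s)
MDC1_KOFF_XRAY = 425e-5


@dataclass(frozen=True)
class DdrParameters:
    """Rate constants, species totals and readout scalings.

    The dissociation rates of MRN (``k_mi_off``, ``k_mo_off``) and MDC1
    (``k_md_off``) are fixed from FRAP measurements when fitting recruitment
    data.  ``k_md_off`` defaults to the printed X-ray MDC1 value; the MRN
    dissociation defaults are placeholders (the corresponding measured table
    is not reproduced here) and should be set from configuration for any
    quantitative reuse.  The remaining defaults were chosen once so that the
    default model reproduces the qualitative recruitment phenomenology:
    faster NBS1 recruitment at higher LET, ATM activation saturating early
    only at high LET, a transient inner-MRN dip at high LET, and recruited
    MDC1 saturating at the outer-focus site capacity.
    """

    # inner focus: MRN <-> DSB sites
    k_mi_on: float = 5e-6
    k_mi_off: float = 1e-3       # placeholder, non-measured
    # ATM capture at inner MRN and activation-release
    k_act_on: float = 4e-6
    k_act: float = 5e-2
    # active ATM re-binding to inner MRN (blocks MRN dissociation)
    k_ai_on: float = 1e-6
    k_ai_off: float = 5e-4
    # H2AX phosphorylation by free active ATM (catalytic)
    k_ph: float = 4.5e-4
    # MDC1 <-> gammaH2AX
    k_md_on: float = 5e-4
    k_md_off: float = MDC1_KOFF_XRAY
    # MRN <-> recruited MDC1 (outer focus)
    k_mo_on: float = 1e-5
    k_mo_off: float = 1e-3       # placeholder, non-measured
    # active ATM -> recruited MDC1 (irreversible)
    k_ao_on: float = 1e-6
    # species totals (relative concentration units)
    mrn_total: float = 4000.0
    atm_total: float = 1500.0
    mdc1_total: float = 10000.0
    h2ax_total: float = 3500.0   # outer-focus site capacity
    # damage scaling
    sites_per_dsb: float = 1.0
    dsb_per_let: float = 28.0 / 170.0   # DSBs per keV/µm
    # readout scalings
    signal_scale_nbs1: float = 1.0
    signal_scale_atm: float = 1.0
    signal_scale_mdc1: float = 1.0
    # diffusion-limited MDC1 variant
    mdc1_diffusion_D: float = 0.029     # µm²/s
    mdc1_geometry_coeff: float = 300.0  # conc per µm of diffusive reach

    def __post_init__(self) -> None:
        for name in ("k_mi_on", "k_mi_off", "k_act_on", "k_act", "k_ai_on",
                     "k_ai_off", "k_ph", "k_md_on", "k_md_off", "k_mo_on",
                     "k_mo_off", "k_ao_on", "sites_per_dsb", "dsb_per_let"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mrn_total", "atm_total", "mdc1_total", "h2ax_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_updates(self, **kwargs) -> "DdrParameters":
        return replace(self, **kwargs)


# state vector layout
SPECIES = (
    "M_free",          # free MRN
    "S_inner_free",    # free inner (DSB-end) binding sites
    "M_inner",         # MRN at inner sites
    "M_inner_ATM",     # inner MRN with captured (inactive) ATM
    "M_inner_ATMp",    # inner MRN with bound active ATM
    "ATM_free",        # free inactive ATM
    "ATMp_free",       # free active ATM
    "H2AX",            # unphosphorylated H2AX in the outer focus
    "gH2AX_free",      # gammaH2AX without MDC1
    "MDC1_free",       # free MDC1
    "MDC1_recruited",  # total MDC1 bound to gammaH2AX
    "M_outer",         # MRN docked on recruited MDC1
    "ATM_outer",       # active ATM docked on recruited MDC1
)
_I = {name: i for i, name in enumerate(SPECIES)}


@dataclass
class DdrState:
    """Named view of one state vector."""

    y: np.ndarray

    def __getattr__(self, name):
        try:
            return self.y[_I[name]]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def mdc1_recruited_bare(self) -> float:
        """Recruited MDC1 with neither MRN nor ATM cargo (independent sites)."""
        return _bare_recruited(self.y)


def _bare_recruited(y: np.ndarray) -> float:
    r = y[_I["MDC1_recruited"]]
    if r <= 0.0:
        return 0.0
    fm = max(0.0, 1.0 - y[_I["M_outer"]] / r)
    fa = max(0.0, 1.0 - y[_I["ATM_outer"]] / r)
    return r * fm * fa


def dsb_count(let_value: float, params: DdrParameters) -> float:
    """DSB number from the linear LET map (continuous, no rounding)."""
    if let_value < 0:
        raise ValueError(f"LET must be >= 0, got {let_value}")
    return params.dsb_per_let * let_value


def initial_state(params: DdrParameters, n_dsb: float) -> np.ndarray:
    """All proteins free, H2AX unphosphorylated, inner sites empty."""
    y0 = np.zeros(len(SPECIES))
    y0[_I["M_free"]] = params.mrn_total
    y0[_I["S_inner_free"]] = params.sites_per_dsb * n_dsb
    y0[_I["ATM_free"]] = params.atm_total
    y0[_I["H2AX"]] = params.h2ax_total
    y0[_I["MDC1_free"]] = params.mdc1_total
    return y0


def build_reaction_system(params: DdrParameters, n_dsb: float,
                          variant: str = STANDARD) -> Callable:
    """Return the mass-action derivative evaluator ``rhs(t, y)``.

    Conservation of the MRN, ATM, H2AX-site and MDC1 pools holds by
    construction (every reaction moves matter within a pool).  The
    ``ck2_inhibited`` variant zeroes the outer MRN association;
    ``mdc1_diffusion_limited`` caps the available MDC1 pool at
    c_geom * sqrt(4 D t), the diffusive supply in cylindrical geometry.
    """
    if n_dsb < 0:
        raise ValueError("n_dsb must be >= 0")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    p = params
    k_mo_on = 0.0 if variant == CK2_INHIBITED else p.k_mo_on
    diffusion_limited = variant == MDC1_DIFFUSION_LIMITED

    i = _I

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        m_free = y[i["M_free"]]
        s_free = y[i["S_inner_free"]]
        m_in = y[i["M_inner"]]
        m_in_atm = y[i["M_inner_ATM"]]
        atm_free = y[i["ATM_free"]]
        atmp_free = y[i["ATMp_free"]]
        h2ax = y[i["H2AX"]]
        gh_free = y[i["gH2AX_free"]]
        mdc1_free = y[i["MDC1_free"]]
        rec = y[i["MDC1_recruited"]]
        m_out = y[i["M_outer"]]
        atm_out = y[i["ATM_outer"]]
        m_in_atmp = y[i["M_inner_ATMp"]]

        if diffusion_limited:
            avail = min(p.mdc1_total,
                        p.mdc1_geometry_coeff * np.sqrt(4.0 * p.mdc1_diffusion_D * max(t, 0.0)))
            mdc1_free_eff = max(0.0, avail - rec)
        else:
            mdc1_free_eff = mdc1_free

        bare = _bare_recruited(y)

        r1f = p.k_mi_on * m_free * s_free          # MRN + site -> inner
        r1b = p.k_mi_off * m_in                    # inner MRN dissociates (only cargo-free)
        r2 = p.k_act_on * atm_free * m_in          # ATM capture at inner MRN
        r3 = p.k_act * m_in_atm                    # activation-release
        r4f = p.k_ai_on * atmp_free * m_in         # active ATM re-binds inner MRN
        r4b = p.k_ai_off * m_in_atmp
        r5 = p.k_ph * atmp_free * h2ax             # H2AX phosphorylation (catalytic)
        r6f = p.k_md_on * mdc1_free_eff * gh_free  # MDC1 recruitment to gammaH2AX
        r6b = p.k_md_off * bare                    # only cargo-free recruited MDC1 leaves
        r7f = k_mo_on * m_free * (rec - m_out)     # MRN docking on recruited MDC1
        r7b = p.k_mo_off * m_out
        r8 = p.k_ao_on * atmp_free * (rec - atm_out)  # active ATM docking (irreversible)

        dy = np.empty_like(y)
        dy[i["M_free"]] = -r1f + r1b - r7f + r7b
        dy[i["S_inner_free"]] = -r1f + r1b
        dy[i["M_inner"]] = r1f - r1b - r2 + r3 - r4f + r4b
        dy[i["M_inner_ATM"]] = r2 - r3
        dy[i["M_inner_ATMp"]] = r4f - r4b
        dy[i["ATM_free"]] = -r2
        dy[i["ATMp_free"]] = r3 - r4f + r4b - r8
        dy[i["H2AX"]] = -r5
        dy[i["gH2AX_free"]] = r5 - r6f + r6b
        dy[i["MDC1_free"]] = -r6f + r6b
        dy[i["MDC1_recruited"]] = r6f - r6b
        dy[i["M_outer"]] = r7f - r7b
        dy[i["ATM_outer"]] = r8
        return dy

    return rhs


@dataclass
class ModelOutput:
    """Simulated readout time courses (relative signal units)."""

    times: np.ndarray
    nbs1_signal: np.ndarray
    nbs1_inner_signal: np.ndarray
    atm_signal: np.ndarray
    atm_inner_signal: np.ndarray
    mdc1_signal: np.ndarray
    atmp_total: np.ndarray
    states: np.ndarray  # (n_species, n_times)

    def pool_totals(self) -> dict[str, np.ndarray]:
        y = self.states
        return {
            "mrn": y[_I["M_free"]] + y[_I["M_inner"]] + y[_I["M_inner_ATM"]]
                   + y[_I["M_inner_ATMp"]] + y[_I["M_outer"]],
            "atm": y[_I["ATM_free"]] + y[_I["ATMp_free"]] + y[_I["M_inner_ATM"]]
                   + y[_I["M_inner_ATMp"]] + y[_I["ATM_outer"]],
            "h2ax": y[_I["H2AX"]] + y[_I["gH2AX_free"]] + y[_I["MDC1_recruited"]],
            "mdc1": y[_I["MDC1_free"]] + y[_I["MDC1_recruited"]],
            "sites": y[_I["S_inner_free"]] + y[_I["M_inner"]] + y[_I["M_inner_ATM"]]
                     + y[_I["M_inner_ATMp"]],
        }


class IntegrationError(RuntimeError):
    pass


def simulate(params: DdrParameters, let_value: float, t_grid,
             variant: str = STANDARD, rtol: float = 1e-8,
             method: str = "LSODA") -> ModelOutput:
    """Integrate the model from irradiation (t=0) over ``t_grid``.

    Adaptive integration (relative tolerance <= 1e-8 by default).  Readouts:
    NBS1 signal = scale * (inner MRN in all forms + outer MRN); ATM signal =
    scale * (ATM at inner MRN + outer ATM); MDC1 signal = scale * recruited
    MDC1.  Inner contributions are reported separately.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at >= 0")
    n_dsb = dsb_count(let_value, params)
    rhs = build_reaction_system(params, n_dsb, variant)
    y0 = initial_state(params, n_dsb)
    sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), y0, t_eval=t_grid,
                    method=method, rtol=rtol, atol=1e-10 * max(params.mrn_total, 1.0))
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0}: "
            f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}"
        )
    y = sol.y
    inner_mrn = y[_I["M_inner"]] + y[_I["M_inner_ATM"]] + y[_I["M_inner_ATMp"]]
    inner_atm = y[_I["M_inner_ATM"]] + y[_I["M_inner_ATMp"]]
    return ModelOutput(
        times=sol.t,
        nbs1_signal=params.signal_scale_nbs1 * (inner_mrn + y[_I["M_outer"]]),
        nbs1_inner_signal=params.signal_scale_nbs1 * inner_mrn,
        atm_signal=params.signal_scale_atm * (inner_atm + y[_I["ATM_outer"]]),
        atm_inner_signal=params.signal_scale_atm * inner_atm,
        mdc1_signal=params.signal_scale_mdc1 * y[_I["MDC1_recruited"]],
        atmp_total=y[_I["ATMp_free"]] + y[_I["M_inner_ATMp"]] + y[_I["ATM_outer"]],
        states=y,
    )


def readout_inner_fraction(output: ModelOutput, t: float) -> float:
    """Inner-focus share of the NBS1 signal at time t (interpolated)."""
    if not (output.times[0] <= t <= output.times[-1]):
        raise ValueError("t outside simulated range")
    total = np.interp(t, output.times, output.nbs1_signal)
    inner = np.interp(t, output.times, output.nbs1_inner_signal)
    if total <= 0:
        raise ValueError("zero total signal: inner fraction undefined")
    return float(inner / total)


def steady_state_mdc1(params: DdrParameters, let_value: float,
                      variant: str = STANDARD, rel_change: float = 1e-3,
                      window_s: float = 1000.0, t_max: float = 3e6) -> float:
    """Asymptotic recruited MDC1: extend time until change < rel_change/window."""
    t_end = 2e4
    prev = None
    while t_end <= t_max:
        out = simulate(params, let_value, np.linspace(0.0, t_end, 400), variant)
        m = out.mdc1_signal
        # change over the trailing window
        t_w = t_end - window_s
        m_w = np.interp(t_w, out.times, m)
        if m[-1] > 0 and abs(m[-1] - m_w) / m[-1] < rel_change:
            return float(m[-1])
        prev = m[-1]
        t_end *= 4.0
    return float(prev)
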