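"""Shared-parameter fitting of the damage-response model to curve panels.

One parameter set is fitted jointly to a panel of recruitment curves
spanning proteins and LET values; the only quantity that differs between the
per-curve simulations is the DSB number derived from each curve's LET.  The
objective is the plain sum of squared residuals over all curves and time
points, minimized with the Nelder-Mead downhill simplex in log10 parameter
space (rates span many decades), with seeded multi-start restarts.

Dissociation rates measured by FRAP are held fixed; by default MDC1 curves
are excluded from the objective (they are compared post hoc), matching the
way the recruitment data were originally fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .ddr_model import DdrParameters, STANDARD, simulate
from .recruitment_analysis import RecruitmentCurve

#: parameters allowed to vary by default: forward rates and readout scales
DEFAULT_FREE_PARAMETERS = (
    "k_mi_on", "k_act_on", "k_act", "k_ph", "k_md_on", "k_mo_on", "k_ao_on",
    "signal_scale_nbs1", "signal_scale_atm",
)

LARGE_PENALTY = 1e12


@dataclass
class PanelEntry:
    curve: RecruitmentCurve
    protein: str
    let_value: float
    weight: float = 1.0


@dataclass
class DataSetPanel:
    """A collection of recruitment curves fitted jointly."""

    entries: list

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel needs at least one entry")
        for e in self.entries:
            if not (e.let_value > 0):
                raise ValueError("LET values must be positive")

    def subset(self, proteins) -> "DataSetPanel":
        keep = [e for e in self.entries if e.protein in proteins]
        return DataSetPanel(entries=keep)


@dataclass
class EstimationConfig:
    """Free/fixed parameter split and simplex settings."""

    free_parameter_names: tuple = DEFAULT_FREE_PARAMETERS
    fixed_parameters: dict = field(default_factory=dict)
    log10_bounds: tuple = (-8.0, 8.0)
    initial_step: float = 0.15          # log10 units
    xatol: float = 1e-4
    fatol: float = 1e-8
    max_iterations: int = 4000
    restarts: int = 5
    restart_scale: float = 0.3          # log10 spread of restart points
    seed: int = 0
    include_mdc1: bool = False
    variant: str = STANDARD

    def __post_init__(self) -> None:
        overlap = set(self.free_parameter_names) & set(self.fixed_parameters)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")


@dataclass
class FitReport:
    params: DdrParameters
    objective: float
    converged: bool
    n_evaluations: int
    per_curve_sse: list
    objective_trace: list = field(default_factory=list, repr=False)
    failures: list = field(default_factory=list)


def _apply(params: DdrParameters, names, values_log10) -> DdrParameters:
    return replace(params, **{n: 10.0 ** v for n, v in zip(names, values_log10)})


def model_prediction(params: DdrParameters, entry: PanelEntry,
                     variant: str = STANDARD) -> np.ndarray:
    """Model prediction of a plateau-normalized recruitment measurement.

    Measured curves are normalized to plateau 1 per curve, so the model
    counterpart is its own plateau-normalized signal times the per-protein
    readout scale (the scale absorbs any systematic normalization bias; its
    truth value for synthetic panels is 1).
    """
    curve = entry.curve
    t = curve.times[curve.post_mask]
    out = simulate(params, entry.let_value, t, variant=variant)
    signal, scale = {
        "NBS1": (out.nbs1_signal, params.signal_scale_nbs1),
        "ATM": (out.atm_signal, params.signal_scale_atm),
        "MDC1": (out.mdc1_signal, params.signal_scale_mdc1),
    }[entry.protein]
    if signal[-1] <= 0:
        raise ValueError(f"no {entry.protein} signal at LET {entry.let_value}")
    # signal already carries the scale; normalizing cancels it, then the
    # scale is re-applied as the data-vs-model normalization factor
    return scale * signal / signal[-1]


def _entry_sse(params: DdrParameters, entry: PanelEntry, variant: str,
               failures: list | None = None) -> float:
    curve = entry.curve
    y = curve.intensities[curve.post_mask]
    try:
        m = model_prediction(params, entry, variant)
    except Exception as exc:
        if failures is not None:
            failures.append((entry.protein, entry.let_value, str(exc)))
        return LARGE_PENALTY
    return float(np.sum((m - y) ** 2) * entry.weight)


def panel_objective(params: DdrParameters, panel: DataSetPanel,
                    variant: str = STANDARD,
                    failures: list | None = None) -> float:
    """Summed squared residuals of one parameter set over the whole panel.

    Simulations share every parameter; only the DSB number (from each
    entry's LET) differs.  A failed simulation contributes a large finite
    penalty and is logged, never an exception mid-optimization.
    """
    return sum(_entry_sse(params, e, variant, failures) for e in panel.entries)


def fit_parameters(panel: DataSetPanel, config: EstimationConfig,
                   start: DdrParameters | None = None) -> FitReport:
    """Nelder-Mead fit of the shared parameter set to a curve panel.

    Deterministic for a fixed (panel, config, seed).  Parameters are
    optimized in log10 space; the best restart is returned with per-curve
    residuals and the best-vertex objective trace (non-increasing).
    """
    base = start if start is not None else DdrParameters()
    if config.fixed_parameters:
        base = replace(base, **config.fixed_parameters)
    names = tuple(config.free_parameter_names)
    fit_panel = panel if config.include_mdc1 else panel.subset({"NBS1", "ATM"})

    x0 = np.array([np.log10(getattr(base, n)) for n in names])
    lo, hi = config.log10_bounds
    failures: list = []
    trace: list = []

    def objective(x):
        if np.any(x < lo) or np.any(x > hi):
            return LARGE_PENALTY
        val = panel_objective(_apply(base, names, x), fit_panel,
                              config.variant, failures)
        return val

    rng = np.random.default_rng(config.seed)
    best = None
    n_eval = 0
    for k in range(max(1, config.restarts)):
        xs = x0 if k == 0 else x0 + config.restart_scale * rng.standard_normal(x0.size)
        res = optimize.minimize(
            objective, xs, method="Nelder-Mead",
            options={
                "xatol": config.xatol, "fatol": config.fatol,
                "maxiter": config.max_iterations,
                "initial_simplex": _simplex(xs, config.initial_step),
                "adaptive": True,
            },
        )
        n_eval += res.nfev
        trace.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    params_best = _apply(base, names, best.x)
    per_curve = [
        (e.protein, e.let_value, _entry_sse(params_best, e, config.variant))
        for e in panel.entries
    ]
    return FitReport(
        params=params_best,
        objective=float(best.fun),
        converged=bool(best.success),
        n_evaluations=n_eval,
        per_curve_sse=per_curve,
        objective_trace=trace,
        failures=failures,
    )


def _simplex(x0: np.ndarray, step: float) -> np.ndarray:
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    for j in range(n):
        simplex[j + 1, j] += step
    return simplex


def curve_rms(params: DdrParameters, entry: PanelEntry,
              variant: str = STANDARD) -> float:
    """Root-mean-square deviation between model prediction and one curve."""
    y = entry.curve.intensities[entry.curve.post_mask]
    m = model_prediction(params, entry, variant)
    return float(np.sqrt(np.mean((m - y) ** 2)))
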