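"""Recruitment-curve normalization and time-constant extraction.

Beamline recruitment curves (mean focus intensity vs time after irradiation)
are normalized to 0 before irradiation and to 1 at the fitted plateau, then
summarized by the mono-exponential time constant tau: the time after onset
at which the curve reaches 1 - 1/e (~63%) of its plateau.  tau is tabulated
against LET across ion species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class RecruitmentCurve:
    """Normalized recruitment curve tagged with ion species and LET."""

    times: np.ndarray
    intensities: np.ndarray
    let_value: float = np.nan
    ion: str = ""
    protein: str = ""
    flagged: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def post_mask(self) -> np.ndarray:
        return self.times >= 0


@dataclass
class TimeConstantResult:
    """Mono-exponential fit summary: I(t) = P (1 - exp(-(t-lag)/tau))."""

    tau: float
    plateau: float
    lag: float = 0.0
    sse: float = np.nan
    tau_stderr: float = np.nan
    success: bool = True
    message: str = ""


def _mono_exp(t, plateau, tau, lag=0.0):
    out = plateau * (1.0 - np.exp(-np.clip(t - lag, 0.0, None) / tau))
    out[t < lag] = 0.0
    return out


def fit_mono_exponential(curve: RecruitmentCurve,
                         fit_lag: bool = False) -> TimeConstantResult:
    """Least-squares mono-exponential fit of a normalized recruitment curve.

    tau is the time after onset at which the fitted curve reaches
    1 - 1/e of its plateau.  The plateau is fitted jointly with tau (more
    robust than taking the last-frame mean).  The onset lag defaults to 0
    (appropriate for NBS1/ATM/MDC1-like immediate recruiters) and may be
    freed for proteins with a pronounced lag phase.  The reported standard
    error of tau is the asymptotic (linearized) one.
    """
    t = curve.times[curve.post_mask]
    y = curve.intensities[curve.post_mask]
    if t.size < 5:
        return TimeConstantResult(np.nan, np.nan, success=False,
                                  message="too few post-irradiation frames")

    plateau0 = max(y[-max(1, t.size // 10):].mean(), 1e-6)
    # initial tau: first crossing of 63% of the crude plateau
    above = np.nonzero(y >= (1 - np.exp(-1)) * plateau0)[0]
    tau0 = max(float(t[above[0]]) if above.size else float(t[-1] / 3), 1e-3)

    def residuals(x):
        plateau, ltau = x[0], x[1]
        lag = x[2] if fit_lag else 0.0
        return _mono_exp(t, plateau, 10.0**ltau, lag) - y

    x0 = [plateau0, np.log10(tau0)] + ([0.0] if fit_lag else [])
    lo = [0.0, -3.0] + ([0.0] if fit_lag else [])
    hi = [np.inf, 6.0] + ([float(t[-1])] if fit_lag else [])
    res = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success and res.status <= 0:
        return TimeConstantResult(np.nan, np.nan, success=False, message=res.message)
    plateau, tau = res.x[0], 10.0 ** res.x[1]
    lag = res.x[2] if fit_lag else 0.0
    sse = float(2.0 * res.cost)
    # asymptotic standard error of tau from the fit Jacobian (chain rule for
    # the log10 parameterization: d tau = tau ln10 d log10tau)
    tau_se = np.nan
    dof = t.size - res.x.size
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (sse / dof)
            tau_se = float(np.sqrt(cov[1, 1]) * tau * np.log(10.0))
        except np.linalg.LinAlgError:
            pass
    return TimeConstantResult(float(tau), float(plateau), float(lag),
                              sse=sse, tau_stderr=tau_se)


def normalize_recruitment(times, intensities, irradiation_time: float = 0.0,
                          let_value: float = np.nan, ion: str = "",
                          protein: str = "",
                          min_snr: float = 3.0) -> RecruitmentCurve:
    """Normalize a raw recruitment record to baseline 0 and plateau 1.

    The pre-irradiation mean defines 0; the plateau of a jointly fitted
    mono-exponential defines 1.  If the fitted plateau is indistinguishable
    from the baseline scatter (< ``min_snr`` pre-irradiation standard
    deviations, or fit failure) the curve is returned flagged
    "no recruitment" with intensities baseline-subtracted only.
    """
    times = np.asarray(times, dtype=float) - irradiation_time
    intensities = np.asarray(intensities, dtype=float)
    pre = times < 0
    if pre.sum() < 3:
        raise ValueError("need >= 3 pre-irradiation frames")
    if (~pre).sum() < 10:
        raise ValueError("need >= 10 post-irradiation frames")
    baseline = intensities[pre].mean()
    noise = intensities[pre].std(ddof=1) if pre.sum() > 1 else 0.0
    shifted = intensities - baseline
    fit = fit_mono_exponential(
        RecruitmentCurve(times, shifted, let_value, ion, protein))
    if not fit.success or fit.plateau <= max(min_snr * noise, 1e-12):
        return RecruitmentCurve(times, shifted, let_value, ion, protein,
                                flagged=True, flag_reason="no recruitment")
    return RecruitmentCurve(times, shifted / fit.plateau, let_value, ion, protein)


def tau_vs_let(results) -> pd.DataFrame:
    """Tabulate fitted time constants against LET.

    ``results`` is an iterable of (TimeConstantResult, let_value, protein).
    One row per curve, sorted by LET with stable order for ties.
    """
    rows = [
        {
            "let_kev_um": let,
            "protein": protein,
            "tau_s": r.tau,
            "tau_stderr_s": r.tau_stderr,
            "plateau": r.plateau,
            "lag_s": r.lag,
            "sse": r.sse,
        }
        for (r, let, protein) in results
    ]
    if not rows:
        raise ValueError("need at least one result")
    return pd.DataFrame(rows).sort_values("let_kev_um", kind="stable").reset_index(drop=True)
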