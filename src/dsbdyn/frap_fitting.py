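"""Normalization of raw FRAP measurements and model fitting.

Implements the double normalization of raw bleach-region / whole-cell
intensity pairs, least-squares estimation of effective diffusion
coefficients (pure-diffusion model) and of binding constants
(diffusion-reaction models) with a decade start-value grid, plus the small
mobility arithmetic: mass-scaled expected diffusion coefficients and mean
traversal times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .frap_models import (
    BindingRates,
    BleachGeometry,
    DiffusionParams,
    global_binding_frap,
    local_binding_frap,
    soumpasis_frap,
)

PURE_DIFFUSION = "pure_diffusion"
GLOBAL_BINDING = "global_binding"
LOCAL_BINDING = "local_binding"

#: decade start values 10^-6 .. 10^6 permuted for (k*_on, k_off)
DEFAULT_START_DECADES = tuple(float(10.0**e) for e in range(-6, 7))

LOG_BOUND = 8.0  # fit bounds 10^-8 .. 10^8 1/s in log10 space


class DataQualityError(ValueError):
    """Raw measurement violates a precondition (named frame index included)."""


@dataclass
class FrapCurve:
    """A (normalized) FRAP measurement.

    ``times`` are seconds relative to the bleach event (negative = pre-bleach
    frames); ``intensities`` the double-normalized fluorescence.
    """

    times: np.ndarray
    intensities: np.ndarray
    n_prebleach: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach:]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.n_prebleach:]


@dataclass
class FrapFitResult:
    model_kind: str
    D_eff: DiffusionParams | None = None
    rates: BindingRates | None = None
    bleach_depth: float | None = None
    sse: float = np.inf
    success: bool = False
    message: str = ""
    start_values_tried: int = 0
    best_start: tuple[float, float] | None = None
    all_start_sse: dict = field(default_factory=dict, repr=False)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def double_normalize(times, roi_raw, whole_cell_raw, background=None,
                     n_prebleach: int = 1, label: str = "") -> FrapCurve:
    """Double normalization to pre-bleach intensity and acquisition loss.

    out(t) = [roi(t)-bg(t)] / mean_pre[roi-bg] * mean_pre[whole-bg] / [whole(t)-bg(t)]

    Any exponential loss of whole-cell signal during imaging (acquisition
    photobleaching) cancels because it multiplies both series.
    """
    times = np.asarray(times, dtype=float)
    roi = np.asarray(roi_raw, dtype=float)
    whole = np.asarray(whole_cell_raw, dtype=float)
    bg = np.zeros_like(roi) if background is None else np.asarray(background, dtype=float)
    if not (times.shape == roi.shape == whole.shape == bg.shape):
        raise DataQualityError("all series must share one time grid")
    if n_prebleach < 1:
        raise DataQualityError("need at least one pre-bleach frame")

    roi_c = roi - bg
    whole_c = whole - bg
    bad = np.nonzero(whole_c <= 0)[0]
    if bad.size:
        raise DataQualityError(f"whole-cell signal <= background at frame {bad[0]}")
    pre_roi = roi_c[:n_prebleach].mean()
    pre_whole = whole_c[:n_prebleach].mean()
    if pre_roi <= 0 or pre_whole <= 0:
        raise DataQualityError("non-positive pre-bleach mean")
    norm = (roi_c / pre_roi) * (pre_whole / whole_c)
    return FrapCurve(times, norm, n_prebleach=n_prebleach, label=label)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

def _model_curve(model_kind: str, t: np.ndarray, D: DiffusionParams,
                 rates: BindingRates | None, geom: BleachGeometry) -> np.ndarray:
    if model_kind == PURE_DIFFUSION:
        return np.atleast_1d(soumpasis_frap(t, D, geom))
    if model_kind == GLOBAL_BINDING:
        return global_binding_frap(t, D, rates, geom)
    if model_kind == LOCAL_BINDING:
        return local_binding_frap(t, D, rates, geom)
    raise ValueError(f"unknown model kind {model_kind!r}")


def fit_effective_diffusion(curve: FrapCurve, geom: BleachGeometry,
                            fit_bleach_depth: bool = False,
                            d_start: float = 1.0) -> FrapFitResult:
    """Fit the pure-diffusion recovery model, returning D_eff.

    Unweighted least squares over log10(D) (and optionally the bleach
    depth); pre-bleach frames are excluded.
    """
    t = curve.post_times
    y = curve.post_intensities
    if t.size < 10:
        return FrapFitResult(PURE_DIFFUSION, success=False,
                             message="need >= 10 post-bleach frames")
    if np.any(t <= 0):
        raise DataQualityError("post-bleach times must be > 0")

    theta0 = geom.bleach_depth

    def residuals(x):
        d = 10.0 ** x[0]
        th = x[1] if fit_bleach_depth else theta0
        g = BleachGeometry(geom.spot_radius_um, geom.nucleus_radius_um, th)
        return np.atleast_1d(soumpasis_frap(t, DiffusionParams(d), g)) - y

    x0 = [np.log10(d_start)] + ([theta0] if fit_bleach_depth else [])
    lo = [-6.0] + ([0.0] if fit_bleach_depth else [])
    hi = [4.0] + ([0.999] if fit_bleach_depth else [])
    best = None
    for start in (x0, [x0[0] + 2.0] + x0[1:], [x0[0] - 2.0] + x0[1:]):
        try:
            res = optimize.least_squares(residuals, start, bounds=(lo, hi), xtol=1e-14,
                                         ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - diagnostic path
            return FrapFitResult(PURE_DIFFUSION, success=False, message=str(exc))
        if best is None or res.cost < best.cost:
            best = res
    sse = 2.0 * best.cost
    theta = best.x[1] if fit_bleach_depth else theta0
    return FrapFitResult(
        PURE_DIFFUSION,
        D_eff=DiffusionParams(10.0 ** best.x[0]),
        bleach_depth=float(theta),
        sse=float(sse),
        success=True,
        start_values_tried=3,
    )


def fit_binding_constants(curve: FrapCurve, model_kind: str,
                          D_free: DiffusionParams, geom: BleachGeometry,
                          start_decades=DEFAULT_START_DECADES,
                          max_nfev: int = 60,
                          polish_nfev: int = 400) -> FrapFitResult:
    """Estimate (k*_on, k_off) for a diffusion-reaction model.

    Start values for the two rates are permuted over a decade grid
    (default 10^-6 .. 10^6); a bounded least-squares optimization in log10
    space runs from every start pair, the best converged fit is polished and
    returned.  D_free is held fixed (taken from untreated-cell analysis).
    """
    if model_kind not in (GLOBAL_BINDING, LOCAL_BINDING):
        raise ValueError(f"model_kind must be a binding model, got {model_kind!r}")
    t = curve.post_times
    y = curve.post_intensities
    if np.any(t <= 0):
        raise DataQualityError("post-bleach times must be > 0")

    def residuals(x):
        rates = BindingRates(10.0 ** x[0], 10.0 ** x[1])
        try:
            m = _model_curve(model_kind, t, D_free, rates, geom)
        except Exception:
            return np.full_like(y, 1e3)
        return m - y

    bounds = ([-LOG_BOUND, -LOG_BOUND], [LOG_BOUND, LOG_BOUND])
    tried = {}
    best = None
    best_start = None
    failures = []
    results_x = []
    for kon0, koff0 in itertools.product(start_decades, start_decades):
        x0 = [np.log10(kon0), np.log10(koff0)]
        try:
            res = optimize.least_squares(residuals, x0, bounds=bounds,
                                         max_nfev=max_nfev)
        except Exception as exc:
            failures.append(f"start ({kon0:g},{koff0:g}): {exc}")
            continue
        tried[(kon0, koff0)] = 2.0 * res.cost
        results_x.append((res.x, res.cost))
        if best is None or res.cost < best.cost:
            best, best_start = res, (kon0, koff0)
    if best is None:
        return FrapFitResult(model_kind, success=False,
                             message="all starts failed: " + "; ".join(failures[:5]),
                             start_values_tried=len(failures))
    # polish the best basins plus the no-binding boundary; among fits that
    # are indistinguishable in SSE, report the smallest association rate
    # (parsimony -- resolves the nested pure-diffusion limit, where kon* is
    # not identifiable)
    seeds = sorted(results_x, key=lambda xc: xc[1])[:3]
    seeds.append((np.array([-LOG_BOUND, 0.0]), np.inf))
    candidates = []
    for x_seed, _ in seeds:
        pol = optimize.least_squares(residuals, x_seed, bounds=bounds,
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                     max_nfev=polish_nfev)
        candidates.append(pol)
    sse_min = min(2.0 * c.cost for c in candidates)
    group = [c for c in candidates if 2.0 * c.cost <= sse_min * (1.0 + 1e-3)]
    winner = min(group, key=lambda c: c.x[0])
    return FrapFitResult(
        model_kind,
        D_eff=D_free,
        rates=BindingRates(10.0 ** winner.x[0], 10.0 ** winner.x[1]),
        bleach_depth=geom.bleach_depth,
        sse=float(2.0 * winner.cost),
        success=True,
        start_values_tried=len(tried),
        best_start=best_start,
        all_start_sse=tried,
    )


# --------------------------------------------------------------------------
# mobility arithmetic
# --------------------------------------------------------------------------

def scaled_diffusion_estimate(D_ref: DiffusionParams, mass_ref_kda: float,
                              mass_kda: float) -> DiffusionParams:
    """Expected diffusion coefficient of a heavier globular protein.

    For spherical proteins of equal density the Stokes radius grows with the
    cube root of mass: D_calc = D_ref * (mass_ref / mass)^(1/3).
    """
    if mass_ref_kda <= 0 or mass_kda <= 0:
        raise ValueError("masses must be > 0")
    return DiffusionParams(D_ref.D * (mass_ref_kda / mass_kda) ** (1.0 / 3.0))


def traversal_time(distance_um: float, D: DiffusionParams) -> float:
    """Mean time to diffuse a distance r in 2-D: t = r^2 / (4 D)."""
    if distance_um <= 0:
        raise ValueError("distance must be > 0")
    return distance_um**2 / (4.0 * D.D)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return float(np.format_float_positional(x, precision=sig, unique=False,
                                            fractional=False, trim="-"))
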