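"""Synthetic inputs for every pipeline stage.

Generates raw FRAP triplets (bleach-region, whole-cell and background
series, with pre-bleach frames and acquisition photobleaching) from the FRAP
forward models, and multi-LET recruitment panels from the damage-response
ODE model, with controlled multiplicative Gaussian noise.  Seeded runs are
bit-reproducible, so every fitting stage can be tested round-trip with no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import frap_fitting
from .ddr_model import DdrParameters, STANDARD, simulate
from .frap_models import (
    BindingRates,
    BleachGeometry,
    DiffusionParams,
    global_binding_frap,
    local_binding_frap,
    soumpasis_frap,
)
from .frap_fitting import GLOBAL_BINDING, LOCAL_BINDING, PURE_DIFFUSION
from .recruitment_analysis import RecruitmentCurve


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise plus acquisition photobleaching.

    ``relative_sigma`` scales intensity-proportional Gaussian noise
    (default 0.02, matching the visual scatter of published curves);
    ``acquisition_bleach_rate`` is an exponential whole-signal decay during
    imaging (removed again by double normalization).
    """

    relative_sigma: float = 0.02
    acquisition_bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0 or self.acquisition_bleach_rate < 0:
            raise ValueError("noise parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseModel(relative_sigma=0.0)


@dataclass(frozen=True)
class FrapSampling:
    """Acquisition schedule: pre-bleach frames, frame interval, duration."""

    n_prebleach: int = 5
    frame_interval_s: float = 0.5
    duration_s: float = 100.0


@dataclass
class FrapRawTriplet:
    """Raw FRAP record as acquired: ROI, whole-cell and background series."""

    times: np.ndarray
    roi: np.ndarray
    whole_cell: np.ndarray
    background: np.ndarray
    n_prebleach: int
    label: str = ""


def _forward_model(model_kind: str, t: np.ndarray, D: DiffusionParams,
                   rates: BindingRates | None, geom: BleachGeometry) -> np.ndarray:
    if model_kind == PURE_DIFFUSION:
        return np.atleast_1d(soumpasis_frap(t, D, geom))
    if model_kind == GLOBAL_BINDING:
        return global_binding_frap(t, D, rates, geom)
    if model_kind == LOCAL_BINDING:
        return local_binding_frap(t, D, rates, geom)
    raise ValueError(f"unknown model kind {model_kind!r}")


def generate_frap_raw(model_kind: str, D: DiffusionParams,
                      geom: BleachGeometry,
                      rates: BindingRates | None = None,
                      sampling: FrapSampling = FrapSampling(),
                      noise: NoiseModel = NOISELESS,
                      baseline_roi: float = 200.0,
                      baseline_whole: float = 1000.0,
                      background_level: float = 10.0,
                      label: str = "") -> FrapRawTriplet:
    """Emit a raw FRAP triplet whose double normalization equals the model.

    Pre-bleach frames sit at model value 1; the bleach occurs at t = 0 and
    post-bleach frames start one frame interval later.  Both the bleach-ROI
    and whole-cell series decay with the acquisition-bleach rate and carry
    independent multiplicative noise; the background is constant.
    """
    dt = sampling.frame_interval_s
    n_pre = sampling.n_prebleach
    t_pre = -dt * np.arange(n_pre, 0, -1)
    n_post = int(round(sampling.duration_s / dt))
    t_post = dt * np.arange(1, n_post + 1)
    t = np.concatenate([t_pre, t_post])

    model = np.ones_like(t)
    model[n_pre:] = _forward_model(model_kind, t_post, D, rates, geom)

    rng = noise.rng()
    acq = np.exp(-noise.acquisition_bleach_rate * (t - t[0]))
    eps_roi = 1.0 + noise.relative_sigma * rng.standard_normal(t.size)
    eps_whole = 1.0 + noise.relative_sigma * rng.standard_normal(t.size)
    roi = background_level + baseline_roi * model * acq * eps_roi
    # the forward models already describe double-normalized signals (the
    # whole-cell pool loss is divided out), so the emitted whole-cell series
    # carries only acquisition bleaching and noise
    whole = background_level + baseline_whole * acq * eps_whole
    bg = np.full_like(t, background_level)
    return FrapRawTriplet(t, roi, whole, bg, n_prebleach=n_pre, label=label)


def normalize_frap_raw(raw: FrapRawTriplet) -> frap_fitting.FrapCurve:
    """Double-normalize a raw triplet (convenience wrapper)."""
    return frap_fitting.double_normalize(
        raw.times, raw.roi, raw.whole_cell, raw.background,
        n_prebleach=raw.n_prebleach, label=raw.label)


@dataclass(frozen=True)
class RecruitmentSampling:
    """Acquisition schedule for beamline recruitment curves."""

    n_pre: int = 5
    frame_interval_s: float = 5.0
    duration_s: float = 700.0


def generate_recruitment_curve(params: DdrParameters, let_value: float,
                               protein: str,
                               sampling: RecruitmentSampling = RecruitmentSampling(),
                               noise: NoiseModel = NOISELESS,
                               variant: str = STANDARD,
                               rng: np.random.Generator | None = None) -> RecruitmentCurve:
    """One simulated recruitment curve, plateau-normalized, with noise."""
    dt = sampling.frame_interval_s
    t_post = np.arange(0.0, sampling.duration_s + dt / 2, dt)
    out = simulate(params, let_value, t_post, variant=variant)
    signal = {
        "NBS1": out.nbs1_signal,
        "ATM": out.atm_signal,
        "MDC1": out.mdc1_signal,
    }[protein]
    plateau = signal[-1]
    if plateau <= 0:
        raise ValueError(f"no recruitment signal for {protein} at LET {let_value}")
    norm = signal / plateau
    if rng is None:
        rng = noise.rng()
    eps = 1.0 + noise.relative_sigma * rng.standard_normal(norm.size)
    t_pre = -dt * np.arange(sampling.n_pre, 0, -1)
    times = np.concatenate([t_pre, t_post])
    values = np.concatenate([np.zeros(sampling.n_pre), norm * eps])
    return RecruitmentCurve(times, values, let_value=let_value, protein=protein)


def generate_recruitment_panel(params: DdrParameters, let_values,
                               proteins,
                               sampling: RecruitmentSampling = RecruitmentSampling(),
                               noise: NoiseModel = NOISELESS,
                               variant: str = STANDARD):
    """Panel of simulated recruitment curves over (LET, protein) pairs.

    Returns a :class:`~dsbdyn.param_estimation.DataSetPanel`.  One seeded
    generator drives all curves, so the panel is bit-reproducible.
    """
    from .param_estimation import DataSetPanel, PanelEntry

    rng = noise.rng()
    entries = []
    for protein in proteins:
        for let in let_values:
            curve = generate_recruitment_curve(
                params, let, protein, sampling=sampling, noise=noise,
                variant=variant, rng=rng)
            entries.append(PanelEntry(curve=curve, protein=protein, let_value=let))
    return DataSetPanel(entries=entries)
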