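"""Forward models of fluorescence recovery after photobleaching (FRAP).

Three models of recovery in a circular bleach spot of radius ``w`` inside a
cylindrical nucleus of radius ``R_n``:

* pure diffusion (Soumpasis closed form),
* diffusion-reaction with nucleus-wide ("global") homogeneous binding sites,
* diffusion-reaction with binding sites confined to the bleached focus
  ("local" binding).

The two reaction models are solved in the Laplace domain and inverted
numerically with the Stehfest algorithm.  Bound complexes are immobile; the
free species diffuses with coefficient ``D``.  Binding is parameterized by an
effective association rate ``k*_on`` (intrinsic on-rate times free-site
density) and a dissociation rate ``k_off``, both in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable

import numpy as np
from scipy import special


class ParameterDomainError(ValueError):
    """A model parameter or evaluation point lies outside its domain."""


class ModelEvaluationError(RuntimeError):
    """A forward-model evaluation produced an invalid result."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

DEFAULT_FWHM_UM = 3.0          # measured bleach-laser spot FWHM
DEFAULT_NUCLEUS_RADIUS_UM = 9.4  # cylindrical nucleus radius


@dataclass(frozen=True)
class BleachGeometry:
    """Geometry of the FRAP boundary-value problem.

    ``spot_radius_um`` is the radius *w* of the idealized uniform circular
    bleach region (default: half the measured FWHM), ``nucleus_radius_um``
    the radius *R_n* of the cylindrical nucleus, and ``bleach_depth`` the
    post-bleach intensity inside the spot relative to pre-bleach
    (0 = complete bleach).
    """

    spot_radius_um: float = DEFAULT_FWHM_UM / 2.0
    nucleus_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM
    bleach_depth: float = 0.0
    fwhm_um: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.spot_radius_um < self.nucleus_radius_um):
            raise ParameterDomainError(
                f"require 0 < spot radius < nucleus radius, got "
                f"w={self.spot_radius_um}, R_n={self.nucleus_radius_um}"
            )
        if not (0.0 <= self.bleach_depth < 1.0):
            raise ParameterDomainError(
                f"bleach_depth must lie in [0, 1), got {self.bleach_depth}"
            )

    @classmethod
    def from_fwhm(cls, fwhm_um: float = DEFAULT_FWHM_UM, **kwargs) -> "BleachGeometry":
        """Uniform-disc idealization: spot radius = FWHM / 2."""
        return cls(spot_radius_um=fwhm_um / 2.0, fwhm_um=fwhm_um, **kwargs)


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion coefficient in µm²/s."""

    D: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.D) or self.D <= 0:
            raise ParameterDomainError(f"diffusion coefficient must be > 0, got {self.D}")


@dataclass(frozen=True)
class BindingRates:
    """Effective association rate k*_on and dissociation rate k_off (1/s).

    k*_on is the product of the intrinsic on-rate and the equilibrium free
    binding-site density; the equilibrium free and bound fractions are
    ``F_eq = k_off/(k*_on+k_off)`` and ``C_eq = k*_on/(k*_on+k_off)``.
    """

    kon_star: float
    koff: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.kon_star) or self.kon_star < 0:
            raise ParameterDomainError(f"kon_star must be >= 0, got {self.kon_star}")
        if not np.isfinite(self.koff) or self.koff <= 0:
            raise ParameterDomainError(f"koff must be > 0, got {self.koff}")

    @property
    def free_fraction(self) -> float:
        return self.koff / (self.kon_star + self.koff)

    @property
    def bound_fraction(self) -> float:
        return self.kon_star / (self.kon_star + self.koff)


#: A Laplace-domain function: maps real p > 0 (possibly an array) to the
#: transform value.  Must be finite for every p the inverter requests.
LaplaceFunction = Callable[[np.ndarray], np.ndarray]


# --------------------------------------------------------------------------
# pure diffusion (Soumpasis)
# --------------------------------------------------------------------------

def soumpasis_frap(t, D: DiffusionParams, geom: BleachGeometry):
    """Pure-diffusion recovery for a uniform circular bleach spot.

    F(t) = exp(-2 tau_D / t) * [I0(2 tau_D/t) + I1(2 tau_D/t)] with
    tau_D = w^2 / (4 D).  Evaluated with exponentially scaled Bessel
    functions, so arbitrarily small t is safe.  For incomplete bleaching the
    curve is rescaled affinely onto [bleach_depth, 1].
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ParameterDomainError("times must be finite and >= 0")
    tau_d = geom.spot_radius_um**2 / (4.0 * D.D)
    out = np.zeros_like(t)
    pos = t > 0
    x = 2.0 * tau_d / t[pos]
    out[pos] = special.i0e(x) + special.i1e(x)
    theta = geom.bleach_depth
    result = theta + (1.0 - theta) * out
    return result if result.ndim else float(result)


def diffusion_timescale(D: DiffusionParams, geom: BleachGeometry) -> float:
    """Characteristic diffusion time tau_D = w^2/(4D) of the bleach spot."""
    return geom.spot_radius_um**2 / (4.0 * D.D)


def effective_diffusion_coefficient(D: DiffusionParams, rates: BindingRates) -> DiffusionParams:
    """Apparent diffusion coefficient under rapid transient binding.

    D_eff = D / (1 + k*_on / k_off); equals D when binding is absent.
    """
    return DiffusionParams(D.D / (1.0 + rates.kon_star / rates.koff))


# --------------------------------------------------------------------------
# Stehfest numerical inverse Laplace transform
# --------------------------------------------------------------------------

DEFAULT_STEHFEST_TERMS = 12


def stehfest_weights(n_terms: int = DEFAULT_STEHFEST_TERMS) -> np.ndarray:
    """Stehfest weights V_j, j = 1..N (N even).

    Computed with exact integer arithmetic before conversion to float; the
    usable N in double precision is limited by cancellation (N=12 default).
    """
    if n_terms % 2 != 0 or not (6 <= n_terms <= 18):
        raise ParameterDomainError(f"n_terms must be even and in [6, 18], got {n_terms}")
    m = n_terms // 2
    weights = []
    for j in range(1, n_terms + 1):
        s = 0
        for k in range((j + 1) // 2, min(j, m) + 1):
            num = k**m * factorial(2 * k)
            den = (
                factorial(m - k)
                * factorial(k)
                * factorial(k - 1)
                * factorial(j - k)
                * factorial(2 * k - j)
            )
            s += num // den if num % den == 0 else num / den
        weights.append((-1) ** (m + j) * s)
    return np.array(weights, dtype=float)


def stehfest_invert(fbar: LaplaceFunction, t, n_terms: int = DEFAULT_STEHFEST_TERMS):
    """Invert a Laplace transform on the real axis (Stehfest algorithm).

    f(t) ~ (ln 2 / t) * sum_j V_j * fbar(j ln2 / t).  ``fbar`` must accept a
    numpy array of p values.  Deterministic for fixed inputs.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ParameterDomainError("Stehfest inversion requires t > 0")
    v = stehfest_weights(n_terms)
    j = np.arange(1, n_terms + 1)
    ln2_over_t = np.log(2.0) / t
    p = ln2_over_t[:, None] * j[None, :]          # (nt, N)
    vals = fbar(p.ravel()).reshape(p.shape)
    if not np.all(np.isfinite(vals)):
        raise ModelEvaluationError("Laplace function returned non-finite values")
    out = ln2_over_t * (vals @ v)
    return out if out.shape[0] > 1 else float(out[0])


# --------------------------------------------------------------------------
# diffusion-reaction with global (nucleus-wide) binding
# --------------------------------------------------------------------------

def global_binding_laplace(D: DiffusionParams, rates: BindingRates,
                           geom: BleachGeometry) -> LaplaceFunction:
    """Laplace transform of the global-binding recovery (complete bleach).

    F̄(p) = 1/p − (F_eq/p)·[1 − 2 K1(q w) I1(q w)]·[1 + k*_on/(p+k_off)]
            − C_eq/(p+k_off),
    with q² = (p/D)(1 + k*_on/(p+k_off)).  Binding sites are homogeneous
    throughout the nucleus and bound complexes immobile.  The Bessel product
    K1(x)I1(x) is formed from exponentially scaled functions, so it remains
    finite for arbitrarily large q w (it decays as 1/(2x)).
    """
    w = geom.spot_radius_um
    feq = rates.free_fraction
    ceq = rates.bound_fraction
    kon, koff = rates.kon_star, rates.koff

    def fbar(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        g = 1.0 + kon / (p + koff)
        qw = np.sqrt(p / D.D * g) * w
        bessel = special.k1e(qw) * special.i1e(qw)   # = K1(qw) * I1(qw)
        return 1.0 / p - (feq / p) * (1.0 - 2.0 * bessel) * g - ceq / (p + koff)

    return fbar


def global_binding_frap(t_grid, D: DiffusionParams, rates: BindingRates,
                        geom: BleachGeometry,
                        n_terms: int = DEFAULT_STEHFEST_TERMS) -> np.ndarray:
    """Recovery curve for nucleus-wide binding, by Stehfest inversion."""
    t_grid = np.asarray(t_grid, dtype=float)
    _check_t_grid(t_grid)
    f = stehfest_invert(global_binding_laplace(D, rates, geom), t_grid, n_terms)
    f = _clamp_plateau(np.atleast_1d(f))
    theta = geom.bleach_depth
    return theta + (1.0 - theta) * f


# --------------------------------------------------------------------------
# diffusion-reaction with local (focus-confined) binding
# --------------------------------------------------------------------------

def local_binding_laplace(D_free: DiffusionParams, rates: BindingRates,
                          geom: BleachGeometry) -> LaplaceFunction:
    """Laplace transform of the local-binding recovery (complete bleach).

    Two-region radially symmetric problem: inside the bleached focus
    (r < w) the free species diffuses with D and binds reversibly to
    immobile sites; outside (w < r < R_n) it diffuses freely; zero flux at
    the nuclear boundary.  The closed-form solution uses the basis
    ``A I0(q r)`` inside and ``E [I0(v r) K1(v R) + K0(v r) I1(v R)]``
    outside (the bracket has zero radial derivative at R_n by construction),
    with concentration and flux matched at r = w.  All Bessel evaluations
    are exponentially scaled; growth factors are absorbed into the
    coefficients, so the expression is overflow-free.

    Returned value: disc average of free + bound over r < w, normalized to
    the pre-bleach signal.
    """
    w = geom.spot_radius_um
    rn = geom.nucleus_radius_um
    feq = rates.free_fraction
    ceq = rates.bound_fraction
    kon, koff = rates.kon_star, rates.koff
    d = D_free.D

    def fbar(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        g = 1.0 + kon / (p + koff)
        q = np.sqrt(p / d * g)
        v = np.sqrt(p / d)
        qw, vw, vr = q * w, v * w, v * rn
        # outer-region basis at r=w with the factor exp(v(R-w)) pulled out
        e2 = np.exp(-2.0 * (vr - vw))
        h0 = special.i0e(vw) * special.k1e(vr) * e2 + special.k0e(vw) * special.i1e(vr)
        h1 = special.i1e(vw) * special.k1e(vr) * e2 - special.k1e(vw) * special.i1e(vr)
        # match value and flux at r = w (A-tilde absorbs exp(qw))
        i0w, i1w = special.i0e(qw), special.i1e(qw)
        denom = v * h1 * i0w - q * i1w * h0
        with np.errstate(divide="ignore", invalid="ignore"):
            e_t = (feq / p) * q * i1w / denom
            a_t = e_t * v * h1 / (q * i1w)
        if not np.all(np.isfinite(e_t)) or not np.all(np.isfinite(a_t)):
            raise ModelEvaluationError(
                "singular boundary matching in local-binding model; "
                "refine the time grid or parameters"
            )
        mean_free = a_t * 2.0 * i1w / qw            # disc average of A I0(q r)
        mean_bound = kon * mean_free / (p + koff)
        return mean_free + mean_bound

    return fbar


def local_binding_frap(t_grid, D_free: DiffusionParams, rates: BindingRates,
                       geom: BleachGeometry,
                       n_terms: int = DEFAULT_STEHFEST_TERMS,
                       pool_correction: bool = True) -> np.ndarray:
    """Recovery curve for focus-confined binding, by Stehfest inversion.

    The bleach region, binding region and focus coincide; the free species
    moves with the effective diffusion coefficient measured in untreated
    cells.

    In the bounded nucleus the bleached fluorophores are permanently lost,
    so the raw pre-bleach-normalized disc signal plateaus below 1.  Measured
    curves are double normalized (divided by the whole-cell signal), which
    removes exactly that pool loss; with ``pool_correction`` (default) the
    same time-independent factor T0/T1 is applied here so model and data
    share one convention and the curve recovers to 1.  Set it to False for
    the raw pre-bleach-normalized solution of the bounded-domain PDE.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    _check_t_grid(t_grid)
    f = stehfest_invert(local_binding_laplace(D_free, rates, geom), t_grid, n_terms)
    f = np.atleast_1d(f)
    if np.any(f < -1e-6):
        raise ModelEvaluationError(
            f"local-binding model produced negative intensity {f.min():.3g}"
        )
    theta = geom.bleach_depth
    out = theta + (1.0 - theta) * _clamp_plateau(f)
    if pool_correction:
        w2, rn2 = geom.spot_radius_um**2, geom.nucleus_radius_um**2
        t0 = rates.free_fraction * rn2 + rates.bound_fraction * w2  # pre-bleach pool
        t1 = t0 - (1.0 - theta) * w2                                # post-bleach pool
        out = _clamp_plateau(out * (t0 / t1))
    return out


#: numerical-inversion tolerance: overshoots above 1 smaller than this are
#: clamped (Stehfest error near the plateau); larger ones raise
INVERSION_TOL = 1e-4


def _clamp_plateau(f: np.ndarray) -> np.ndarray:
    over = f - 1.0
    if np.any(over > INVERSION_TOL):
        raise ModelEvaluationError(
            f"inverted curve exceeds 1 by {over.max():.3g}")
    return np.minimum(f, 1.0)


def _check_t_grid(t_grid: np.ndarray) -> None:
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ParameterDomainError("t_grid must be a non-empty 1-D array")
    if np.any(t_grid <= 0):
        raise ParameterDomainError("t_grid values must be > 0 (post-bleach)")
    if np.any(np.diff(t_grid) <= 0):
        raise ParameterDomainError("t_grid must be strictly increasing")
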