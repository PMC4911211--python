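"""Closed-form onset probabilities and age-specific incidence rates.

For a naive-protective module with maturation time tau, failure time T and
disease propensity F, the probability of being permissive by age x is

    B(x) = (1 - w) (1 - exp(-x/tau)) + w (1 - exp(-x/T)),
    w = (1 - F) / (1 - tau/T),

the hitting-time CDF of the permissive (absorbing) state. The disease CDF
is the product of the module brackets; for the homogenized model it is
B(x)**N, and the age-specific incidence is its derivative

    I(x) = N B'(x) B(x)**(N-1),
    B'(x) = (1 - w) exp(-x/tau)/tau + w exp(-x/T)/T.

In the T -> inf limit the weights reduce to w -> 1 - F, B(x) -> F
(1 - exp(-x/tau)) and the lifetime risk plateaus at Phi**N.
"""

from __future__ import annotations

import numpy as np

from .params import HomogenizedParams, ModuleNetwork, ModuleSpec, as_age_grid

__all__ = [
    "module_permissive_cdf",
    "cdf_general",
    "cdf_homogenized",
    "incidence_rate",
    "incidence_curve",
    "incidence_bin_average",
]


def _check_ages(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("ages must be nonnegative")
    return x


def _bracket(tau: float, T: float, F: float, x: np.ndarray) -> np.ndarray:
    """Per-module permissive hitting CDF (naive-protective module)."""
    ex_tau = -np.expm1(-x / tau)  # 1 - exp(-x/tau), accurate at small x
    if not np.isfinite(T) or T / tau > 1e12:
        # explicit limit branch: w -> 1 - F and the slow-failure term vanishes
        return F * ex_tau
    w = (1.0 - F) / (1.0 - tau / T)
    ex_T = -np.expm1(-x / T)
    return (1.0 - w) * ex_tau + w * ex_T


def _bracket_deriv(tau: float, T: float, F: float, x: np.ndarray) -> np.ndarray:
    if not np.isfinite(T) or T / tau > 1e12:
        return F * np.exp(-x / tau) / tau
    w = (1.0 - F) / (1.0 - tau / T)
    return (1.0 - w) * np.exp(-x / tau) / tau + w * np.exp(-x / T) / T


def module_permissive_cdf(spec: ModuleSpec, x) -> np.ndarray:
    """Probability that a module occupies the disease-permissive state at age x.

    For ``naive_state="protective"`` the permissive state is absorbing and
    this is a proper CDF (0 at x=0, nondecreasing, -> 1 for finite T). For
    ``naive_state="permissive"`` the module starts permissive, stabilizes
    permissive with probability F, and mature permissive modules fail to
    protective at rate 1/T; the occupancy probability is then

        P(x) = exp(-x/tau) + F (exp(-x/T) - exp(-x/tau)) / (1 - tau/T),

    which starts at 1 and decays (it is not a CDF). Derived from the
    three-state transition matrix of the naive-permissive module type.
    """
    x = _check_ages(x)
    if spec.naive_state == "protective":
        return _bracket(spec.tau, spec.T, spec.F, x)
    # naive-permissive: still naive, or matured permissive and not yet failed
    naive = np.exp(-x / spec.tau)
    if spec.effectively_infinite_T:
        mature_perm = spec.F * (-np.expm1(-x / spec.tau))
    else:
        mature_perm = spec.F * (np.exp(-x / spec.T) - np.exp(-x / spec.tau)) / (
            1.0 - spec.tau / spec.T
        )
    return naive + mature_perm


def cdf_general(model: ModuleNetwork, x) -> np.ndarray:
    """Probability that all modules are permissive at age x (general model).

    With every module naive-protective this is the disease onset CDF."""
    x = _check_ages(x)
    out = np.ones_like(x, dtype=float)
    for spec in model.modules:
        out = out * module_permissive_cdf(spec, x)
    return out


def cdf_homogenized(params: HomogenizedParams, x) -> np.ndarray:
    """Onset CDF of the homogenized four-parameter model: B(x)**N."""
    x = _check_ages(x)
    return _bracket(params.tau, params.T, params.Phi, x) ** params.N


def incidence_rate(params: HomogenizedParams, x) -> np.ndarray:
    """Age-specific incidence rate I(x) = d/dx of the onset CDF, per person-year.

    Because the lifetime risk Phi**N is small, this unconditional onset
    density is numerically indistinguishable from the hazard and is the
    quantity compared against registry rates.
    """
    x = _check_ages(x)
    b = _bracket(params.tau, params.T, params.Phi, x)
    db = _bracket_deriv(params.tau, params.T, params.Phi, x)
    if params.N == 1:
        return db
    return params.N * db * b ** (params.N - 1)


def incidence_curve(params: HomogenizedParams, ages, scale: float = 1e5) -> np.ndarray:
    """Vectorized incidence over an age grid, scaled (default per 100,000)."""
    grid = as_age_grid(ages)
    if grid.size == 0:
        return np.empty(0)
    return scale * incidence_rate(params, grid)


# nodes/weights for 5-point Gauss-Legendre on [-1, 1]
_GL5 = np.polynomial.legendre.leggauss(5)


def incidence_bin_average(params: HomogenizedParams, age_lo, age_hi, scale: float = 1e5):
    """Average incidence over [age_lo, age_hi) by 5-point Gauss-Legendre.

    Provided as the alternative to midpoint evaluation for binned data."""
    lo = np.asarray(age_lo, dtype=float)
    hi = np.asarray(age_hi, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("need age_hi > age_lo")
    nodes, weights = _GL5
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    x = mid[..., None] + half[..., None] * nodes
    vals = incidence_rate(params, x.ravel()).reshape(x.shape)
    return scale * (vals * weights).sum(axis=-1) * 0.5
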