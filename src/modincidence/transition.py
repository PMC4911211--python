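"""Secular-trend simulation: incidence changes while an environmental risk
factor spreads through the population.

The scenario: a risk factor rolls out over calendar time, the exposed
fraction following a smooth sigmoid that reaches one half at calendar time
``t50``. A module that stabilizes while its carrier is unexposed adopts
the disease-permissive state with the pre-transition propensity Phi1; one
that stabilizes under exposure uses the post-transition propensity Phi2.
In addition, while the population is in transition mature protective
modules are transiently destabilized: they fail to the permissive state
at the faster rate 1/T* instead of 1/T.

The destabilization era is a fixed calendar interval around t50
(default [t50, t50 + 40] years): decade-by-decade registry fits
during the North-American outbreak show the fitted failure time dropping
to ~350 y around the transition and returning to ~1000 y three to four
decades later, so the era is anchored there rather than tied to the
rollout width.

For a birth cohort born in year b, the per-module permissive hitting CDF
at age x is

    P(x; b) = integral over stabilization age a in [0, x] of
              f(a) [ phi(b+a) + (1 - phi(b+a)) (1 - S(b+a, b+x)) ] da,

with f(a) = exp(-a/tau)/tau, phi(t) = Phi1 + (Phi2 - Phi1) eps(t) the
expected mature propensity at calendar time t, eps the exposed fraction,
and S(s, c) = exp(-Lambda(s, c)) the protective-state survival under the
piecewise-constant failure rate (1/T* inside the window, 1/T outside).
The cohort onset CDF is P**N and the cross-sectional age-specific
incidence at calendar time t is the age-derivative of the CDF of the
cohort born in t - x.

Both a quadrature evaluation (Gauss-Legendre over the stabilization age)
and a Monte-Carlo cohort simulation are provided; they are checked
against each other.

The exact published form of this transition model is not available; the
rollout form (logistic), the exposure-to-propensity coupling (propensity
set by exposure status at stabilization time) and the transient
destabilization window are this package's declared reconstruction, each a
named, swappable strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import cdf_homogenized, incidence_rate
from .params import HomogenizedParams, as_age_grid

__all__ = [
    "TransitionScenario",
    "SecularCurves",
    "exposure_fraction",
    "birth_cohort_cdf",
    "birth_cohort_pdf",
    "secular_curves",
    "detect_second_peak",
]

_GL_NODES = 192  # Gauss-Legendre nodes over the stabilization age


@dataclass(frozen=True)
class TransitionScenario:
    """An environmental-transition experiment.

    base : pre-exposure homogenized parameters (its Phi is Phi1).
    phi_after : post-exposure propensity Phi2 (>= Phi1: adverse factor).
    T_star : transient failure time of protective modules during the
        transition window, in years (T* <= T).
    t50 : calendar year at which half the population is exposed.
    transition_width : logistic scale of the rollout, in years.
    era : destabilization era as (start, end) offsets in years relative
        to t50 (default (0, 40)); mature protective modules fail at
        1/T* while the calendar time is inside this interval.
    destabilize : "all" (default; every mature protective module fails at
        1/T* during the era) or "legacy" (only modules that stabilized
        before their carrier was exposed — the old-regime states
        mismatched with the new environment).
    """

    base: HomogenizedParams
    phi_after: float
    T_star: float
    t50: float = 0.0
    transition_width: float = 10.0
    era: tuple = (0.0, 40.0)
    destabilize: str = "all"
    decade_offsets: tuple = (-20, -10, 0, 10, 20, 30, 40)
    age_max: float = 90.0

    def __post_init__(self):
        if not 0.0 <= self.base.Phi <= self.phi_after <= 1.0:
            raise ValueError("need 0 <= Phi1 <= Phi2 <= 1 (adverse risk factor)")
        if not 0 < self.T_star <= self.base.T:
            raise ValueError("need 0 < T* <= T")
        if not self.transition_width > 0:
            raise ValueError("transition_width must be positive")
        if not self.era[0] < self.era[1]:
            raise ValueError("era must satisfy start < end")
        if self.destabilize not in ("all", "legacy"):
            raise ValueError(f"unknown destabilization strategy {self.destabilize!r}")

    @property
    def window(self) -> tuple:
        """Calendar bounds of the destabilization era."""
        return (self.t50 + self.era[0], self.t50 + self.era[1])

    @property
    def stationary_before(self) -> HomogenizedParams:
        return self.base

    @property
    def stationary_after(self) -> HomogenizedParams:
        return self.base.replace(Phi=self.phi_after)


@dataclass(frozen=True)
class SecularCurves:
    """Cross-sectional incidence curves per calendar decade plus the
    annual population series around t50. Rates are per 100,000/yr."""

    decade_offsets: np.ndarray
    ages: np.ndarray
    curves: np.ndarray  # (n_decades, n_ages)
    annual_offsets: np.ndarray
    annual_series: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        frames = []
        for off, row in zip(self.decade_offsets, self.curves):
            frames.append(
                pd.DataFrame(
                    {"decade_offset": off, "age": self.ages, "incidence_per_100k": row}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def annual_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"year_offset": self.annual_offsets, "incidence_per_100k": self.annual_series}
        )


def exposure_fraction(scenario: TransitionScenario, t) -> np.ndarray:
    """Exposed population fraction: logistic in calendar time, 1/2 at t50."""
    from scipy.special import expit

    t = np.asarray(t, dtype=float)
    return expit((t - scenario.t50) / scenario.transition_width)


def _failure_exponent(scenario: TransitionScenario, s, c):
    """Lambda(s, c): integral of the protective-failure rate from calendar
    time s to c, with rate 1/T* inside the destabilization window."""
    lo, hi = scenario.window
    s = np.asarray(s, float)
    c = np.asarray(c, float)
    overlap = np.clip(np.minimum(c, hi) - np.maximum(s, lo), 0.0, None)
    return overlap / scenario.T_star + (c - s - overlap) / scenario.base.T


def _module_cdf_pdf(scenario: TransitionScenario, birth_year, x):
    """Per-module permissive hitting CDF and its age-derivative, by
    Gauss-Legendre quadrature over the stabilization age.

    birth_year and x broadcast elementwise."""
    p = scenario.base
    phi1, phi2 = p.Phi, scenario.phi_after
    b = np.asarray(birth_year, float)
    x = np.asarray(x, float)
    b, x = np.broadcast_arrays(b, x)
    shape = b.shape
    b = b.ravel()
    x = x.ravel()
    nodes, weights = np.polynomial.legendre.leggauss(_GL_NODES)
    # segment [0, x] at the era boundaries (kinks of the survival factor)
    # so each Gauss-Legendre panel integrates a smooth piece
    lo_edge, hi_edge = scenario.window
    knots = np.stack(
        [
            np.zeros_like(x),
            np.clip(lo_edge - b, 0.0, x),
            np.clip(hi_edge - b, 0.0, x),
            x,
        ],
        axis=1,
    )  # (npts, 4), nondecreasing since lo_edge < hi_edge
    seg_lo = knots[:, :-1]
    seg_hi = knots[:, 1:]
    half_seg = 0.5 * (seg_hi - seg_lo)  # (npts, 3)
    mid_seg = 0.5 * (seg_hi + seg_lo)
    a = (mid_seg[:, :, None] + half_seg[:, :, None] * nodes).reshape(x.size, -1)
    wq = (half_seg[:, :, None] * weights).reshape(x.size, -1)
    f = np.exp(-a / p.tau) / p.tau
    t_stab = b[:, None] + a
    eps = exposure_fraction(scenario, t_stab)
    t_now = (b + x)[:, None]
    if scenario.destabilize == "all":
        phi = phi1 + (phi2 - phi1) * eps
        surv = np.exp(-_failure_exponent(scenario, t_stab, t_now))
        integrand_cdf = f * (phi + (1.0 - phi) * (1.0 - surv))
        J = (wq * f * (1.0 - phi) * surv).sum(axis=1)
    else:
        # "legacy": only modules stabilized before exposure are destabilized
        surv_star = np.exp(-_failure_exponent(scenario, t_stab, t_now))
        surv_plain = np.exp(-(t_now - t_stab) / p.T)
        protective = (1.0 - eps) * (1.0 - phi1) * surv_star + eps * (1.0 - phi2) * surv_plain
        phi = phi1 + (phi2 - phi1) * eps
        integrand_cdf = f * (1.0 - protective)
        J = None  # split into legacy/new parts below
    cdf = (wq * integrand_cdf).sum(axis=1)
    # derivative: new stabilizations directly permissive + current failures
    lo, hi = scenario.window
    now = b + x
    in_window = (now > lo) & (now < hi)
    rate_now = np.where(in_window, 1.0 / scenario.T_star, 1.0 / p.T)
    f_x = np.exp(-x / p.tau) / p.tau
    phi_now = phi1 + (phi2 - phi1) * exposure_fraction(scenario, now)
    if scenario.destabilize == "all":
        pdf = f_x * phi_now + rate_now * J
    else:
        J_legacy = (wq * f * (1.0 - eps) * (1.0 - phi1) * surv_star).sum(axis=1)
        J_new = (wq * f * eps * (1.0 - phi2) * surv_plain).sum(axis=1)
        pdf = f_x * phi_now + rate_now * J_legacy + J_new / p.T
    return cdf.reshape(shape), pdf.reshape(shape)


def birth_cohort_cdf(
    scenario: TransitionScenario,
    birth_year,
    x,
    method: str = "quadrature",
    n_draws: int = 200_000,
    seed: int = 0,
):
    """Onset CDF by age x for the cohort born in ``birth_year``.

    method="quadrature" (deterministic, default) or "montecarlo"
    (simulates n_draws individuals; used as the internal cross-check)."""
    if method == "quadrature":
        cdf, _ = _module_cdf_pdf(scenario, birth_year, x)
        return cdf ** scenario.base.N
    if method == "montecarlo":
        draws = simulate_transition_onsets(scenario, float(birth_year), n_draws, seed)
        xarr = np.asarray(x, float)
        if xarr.ndim:
            return (draws <= xarr[..., None]).mean(axis=-1)
        return float((draws <= xarr).mean())
    raise ValueError(f"unknown method {method!r}")


def birth_cohort_pdf(scenario: TransitionScenario, birth_year, x):
    """Age-density of onset for the cohort born in ``birth_year`` (quadrature)."""
    cdf, pdf = _module_cdf_pdf(scenario, birth_year, x)
    N = scenario.base.N
    return N * pdf * cdf ** (N - 1)


def simulate_transition_onsets(
    scenario: TransitionScenario, birth_year: float, n: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo onset ages for one birth cohort (inf = no onset).

    Mirrors the quadrature model exactly: per module, the stabilization
    age is exponential(tau); exposure is Bernoulli with the exposed
    fraction at the stabilization time; protective modules fail under the
    piecewise-constant rate, inverted analytically."""
    p = scenario.base
    rng = np.random.default_rng(seed)
    lo, hi = scenario.window
    onset = np.full(n, -np.inf)
    for _ in range(p.N):
        a = rng.exponential(p.tau, size=n)
        t_stab = birth_year + a
        eps = exposure_fraction(scenario, t_stab)
        exposed = rng.random(n) < eps
        phi = np.where(exposed, scenario.phi_after, p.Phi)
        permissive = rng.random(n) < phi
        entry = np.where(permissive, a, np.inf)
        prot = ~permissive
        if np.any(prot):
            if scenario.destabilize == "legacy":
                fast = prot & ~exposed
                slow = prot & exposed
            else:
                fast = prot
                slow = np.zeros_like(prot)
            if np.any(slow):
                entry[slow] = a[slow] + rng.exponential(p.T, size=int(slow.sum()))
            if np.any(fast):
                s = t_stab[fast]
                E = rng.exponential(1.0, size=int(fast.sum()))
                # invert Lambda(s, .) = E over the three-piece rate profile
                c = _invert_failure_exponent(scenario, s, E)
                entry[fast] = c - birth_year
        onset = np.maximum(onset, entry)
    return onset


def _invert_failure_exponent(scenario: TransitionScenario, s, E):
    """Solve Lambda(s, c) = E for c (vectorized); Lambda is piecewise
    linear in c with slopes 1/T outside the window and 1/T* inside."""
    lo, hi = scenario.window
    T, Ts = scenario.base.T, scenario.T_star
    s = np.asarray(s, float)
    E = np.asarray(E, float)
    c = np.empty_like(s)
    # exponent accumulated when c reaches the window start / end
    L_lo = np.clip(lo - s, 0.0, None) / T
    L_hi = L_lo + np.clip(hi - np.maximum(s, lo), 0.0, None) / Ts
    before = E <= L_lo
    inside = (~before) & (E <= L_hi)
    after = (~before) & (~inside)
    c[before] = s[before] + E[before] * T
    c[inside] = np.maximum(s[inside], lo) + (E[inside] - L_lo[inside]) * Ts
    c[after] = hi + (E[after] - L_hi[after]) * T
    # cohorts born entirely after the window never see T*
    past = s >= hi
    c[past] = s[past] + E[past] * T
    return c


def secular_curves(
    scenario: TransitionScenario,
    age_grid=None,
    annual_offsets=None,
    age_weights=None,
) -> SecularCurves:
    """Cross-sectional age-specific incidence per calendar decade, plus the
    annual population incidence series around t50.

    Curves are assembled cohort-wise: the incidence at age x and calendar
    time t is the onset density at age x of the cohort born in t - x. The
    annual series averages the cross-sectional curve over a population age
    structure (default uniform over the age grid)."""
    if age_grid is None:
        age_grid = np.arange(0.0, scenario.age_max + 1.0)
    ages = as_age_grid(age_grid)
    if annual_offsets is None:
        annual_offsets = np.arange(-20.0, 81.0)
    annual_offsets = np.asarray(annual_offsets, float)
    offsets = np.asarray(scenario.decade_offsets, float)

    def cross_section(t):
        birth = t - ages
        return 1e5 * birth_cohort_pdf(scenario, birth, ages)

    curves = np.vstack([cross_section(scenario.t50 + off) for off in offsets])

    if age_weights is None:
        w = np.full(ages.size, 1.0 / ages.size)
    else:
        w = np.asarray(age_weights, float)
        if w.shape != ages.shape or np.any(w < 0):
            raise ValueError("age_weights must be nonnegative and match the age grid")
        w = w / w.sum()
    annual = np.array(
        [float(cross_section(scenario.t50 + off) @ w) for off in annual_offsets]
    )
    return SecularCurves(
        decade_offsets=offsets,
        ages=ages,
        curves=curves,
        annual_offsets=annual_offsets,
        annual_series=annual,
    )


def detect_second_peak(curve, ages=None, smooth: bool = True):
    """Locate interior strict local maxima of an age-specific curve.

    The curve is smoothed with a 3-point moving average first (documented
    default) so single-point noise does not register as a peak. Returns
    (count, locations) where locations are ages if ``ages`` is given, else
    indices into the curve."""
    y = np.asarray(curve, float)
    if y.size < 5:
        raise ValueError("need at least 5 points to detect peaks")
    if smooth:
        ys = y.copy()
        ys[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    else:
        ys = y
    interior = (ys[1:-1] > ys[:-2]) & (ys[1:-1] > ys[2:])
    idx = np.nonzero(interior)[0] + 1
    if ages is not None:
        ages = np.asarray(ages, float)
        return idx.size, ages[idx]
    return idx.size, idx
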