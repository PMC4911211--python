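"""Mapping between GWAS odds ratios and module disease propensities (MDPs).

A susceptibility locus with risk-allele frequency p is assumed to affect a
single module; F denotes that module's disease propensity among risk-
allele carriers (dominant coding: carriers of the risk allele versus
protective-allele homozygotes), while Phi is the population-mean
propensity. For a rare disease the odds ratio is

    OR = (1 - p)^2 F / (Phi - (1 - (1 - p)^2) F),

which is 1 exactly when F = Phi, strictly increasing in F, and inverts to

    F = OR * Phi / ((1 - p)^2 + OR * (2p - p^2)).

Given a distribution nu of odds ratios over loci and a distribution rho of
risk-allele frequencies, the implied density g of carrier MDPs follows by
a change of variables:

    g(x) = integral over p of
           nu(x (1-p)^2 / (Phi - x(2p - p^2)))
           * Phi (1-p)^2 / (Phi - x(2p - p^2))^2 * rho(p) dp.

Because small odds ratios are under-detected at genome-wide significance,
an observed OR histogram can first be corrected by inverse detection
power; the power model here (two-proportion z-test at alpha = 5e-8 under
carrier coding, configurable case/control counts) is this package's
reconstruction of that correction and is swappable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import integrate, stats

__all__ = [
    "LocusRecord",
    "OrDistribution",
    "RafDistribution",
    "MdpDensity",
    "or_from_mdp",
    "mdp_from_or",
    "mdp_density",
    "gwas_detection_power",
    "make_power_model",
    "correct_or_distribution",
]


@dataclass(frozen=True)
class LocusRecord:
    """One susceptibility locus: identifier, risk-allele frequency, odds
    ratio, and (optionally) the implied carrier MDP."""

    locus_id: str
    raf: float
    or_value: float
    mdp: Optional[float] = None

    def __post_init__(self):
        if not 0.0 < self.raf < 1.0:
            raise ValueError(f"raf must lie in (0, 1), got {self.raf}")
        if not self.or_value > 0:
            raise ValueError(f"odds ratio must be positive, got {self.or_value}")
        if self.mdp is not None and not 0.0 <= self.mdp <= 1.0:
            raise ValueError(f"mdp must lie in [0, 1], got {self.mdp}")


class OrDistribution:
    """Distribution nu of odds ratios across loci.

    Either parametric (log-normal, the natural choice for a quantity
    multiplicative around 1) or an empirical histogram with log-spaced
    bins. Provides a density, sampling, and support bounds.
    """

    def __init__(self, pdf: Callable, rvs: Callable, support: tuple, edges=None, weights=None):
        self._pdf = pdf
        self._rvs = rvs
        self.support = support
        self.edges = None if edges is None else np.asarray(edges, float)
        self.weights = None if weights is None else np.asarray(weights, float)

    def pdf(self, x):
        return self._pdf(np.asarray(x, float))

    def rvs(self, n: int, rng: np.random.Generator):
        return self._rvs(n, rng)

    @classmethod
    def lognormal(
        cls, mode: float = 1.1, sigma: float = 0.15, lower: Optional[float] = None
    ) -> "OrDistribution":
        """Log-normal nu parameterized by its mode (mode = exp(mu - sigma^2)).

        ``lower`` left-truncates the distribution: a catalogue of
        genome-wide-significant risk alleles has ORs strictly above 1, so
        analyses feeding the change-of-variables density typically use
        e.g. lower=1.02 (the implied-MDP density has an integrable
        singularity at Phi when the OR support touches 1)."""
        if mode <= 0 or sigma <= 0:
            raise ValueError("mode and sigma must be positive")
        mu = np.log(mode) + sigma ** 2
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        if lower is None:
            return cls(
                pdf=dist.pdf,
                rvs=lambda n, rng: dist.rvs(size=n, random_state=rng),
                support=(0.0, np.inf),
            )
        tail = dist.sf(lower)
        if tail <= 0:
            raise ValueError("truncation point beyond the distribution support")

        def pdf(x):
            x = np.asarray(x, float)
            return np.where(x >= lower, dist.pdf(x) / tail, 0.0)

        def rvs(n, rng):
            u = rng.uniform(dist.cdf(lower), 1.0, size=n)
            return dist.ppf(u)

        return cls(pdf=pdf, rvs=rvs, support=(float(lower), np.inf))

    @classmethod
    def from_histogram(cls, edges, weights) -> "OrDistribution":
        """Piecewise-constant density from bin edges and bin masses."""
        edges = np.asarray(edges, float)
        weights = np.asarray(weights, float)
        if edges.ndim != 1 or edges.size != weights.size + 1:
            raise ValueError("need len(edges) == len(weights) + 1")
        if np.any(np.diff(edges) <= 0) or np.any(weights < 0):
            raise ValueError("edges must increase and weights be nonnegative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("histogram has no mass")
        mass = weights / total
        dens = mass / np.diff(edges)

        def pdf(x):
            idx = np.searchsorted(edges, x, side="right") - 1
            ok = (idx >= 0) & (idx < dens.size) & (x <= edges[-1])
            out = np.zeros_like(np.asarray(x, float))
            out[ok] = dens[np.clip(idx, 0, dens.size - 1)][ok]
            return out

        def rvs(n, rng):
            k = rng.choice(mass.size, size=n, p=mass)
            return rng.uniform(edges[k], edges[k + 1])

        return cls(pdf=pdf, rvs=rvs, support=(float(edges[0]), float(edges[-1])),
                   edges=edges, weights=mass)

    @classmethod
    def point_mass(cls, value: float, width: float = 1e-6) -> "OrDistribution":
        """Numerical Dirac mass: a single very narrow histogram bin."""
        return cls.from_histogram([value - width / 2, value + width / 2], [1.0])


class RafDistribution:
    """Distribution rho of risk-allele frequencies on (0, 1)."""

    def __init__(self, pdf: Callable, rvs: Callable):
        self._pdf = pdf
        self._rvs = rvs

    def pdf(self, p):
        return self._pdf(np.asarray(p, float))

    def rvs(self, n: int, rng: np.random.Generator):
        return self._rvs(n, rng)

    @classmethod
    def beta(cls, a: float = 2.0, b: float = 2.0) -> "RafDistribution":
        dist = stats.beta(a, b)
        return cls(pdf=dist.pdf, rvs=lambda n, rng: dist.rvs(size=n, random_state=rng))

    @classmethod
    def from_samples(cls, samples) -> "RafDistribution":
        """Empirical rho via a histogram on 50 equal bins of (0, 1)."""
        samples = np.asarray(samples, float)
        hist, edges = np.histogram(samples, bins=50, range=(0.0, 1.0), density=True)

        def pdf(p):
            idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, hist.size - 1)
            return hist[idx]

        def rvs(n, rng):
            return rng.choice(samples, size=n, replace=True)

        return cls(pdf=pdf, rvs=rvs)


@dataclass(frozen=True)
class MdpDensity:
    """Density g of carrier MDPs on a regular grid over (0, 1)."""

    grid: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _carrier_fraction(raf):
    """Population fraction carrying at least one risk allele (HWE)."""
    return 1.0 - (1.0 - raf) ** 2


def or_from_mdp(mdp, raf, phi):
    """Odds ratio implied by a carrier MDP, vectorized.

    Raises on a nonpositive denominator (the carrier propensity is too
    large for the population mean phi to hold)."""
    F = np.asarray(mdp, float)
    p = np.asarray(raf, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("raf must lie strictly in (0, 1)")
    if np.any((F < 0) | (F > 1)):
        raise ValueError("mdp must lie in [0, 1]")
    denom = phi - _carrier_fraction(p) * F
    if np.any(denom <= 0):
        bad = np.argwhere(np.atleast_1d(denom <= 0)).ravel()[:5]
        raise ValueError(
            f"odds ratio undefined: phi - (2p - p^2) F <= 0 for (F, p, phi)="
            f"{(np.atleast_1d(F).ravel()[bad], np.atleast_1d(p).ravel()[bad], phi)}"
        )
    out = (1.0 - p) ** 2 * F / denom
    return out if out.ndim else float(out)


def mdp_from_or(or_value, raf, phi):
    """Carrier MDP implied by an odds ratio (algebraic inversion).

    Raises if the implied F falls outside [0, 1]."""
    v = np.asarray(or_value, float)
    p = np.asarray(raf, float)
    if np.any(v <= 0):
        raise ValueError("odds ratio must be positive")
    F = v * phi / ((1.0 - p) ** 2 + v * _carrier_fraction(p))
    if np.any((F < 0) | (F > 1 + 1e-12)):
        raise ValueError(
            f"inconsistent (OR, p, phi): implied MDP outside [0, 1] "
            f"(max {float(np.max(F)):.4f})"
        )
    F = np.clip(F, 0.0, 1.0)
    return F if F.ndim else float(F)


def _density_at_phi(nu, rho, phi, eps):
    """Density exactly at x = phi, where every allele frequency maps to
    OR = 1: the p-space integrand is nu(1) rho(p) / (phi (1-p)^2), which
    diverges unless nu vanishes at 1 faster than rho does at p = 1."""
    nu_at_one = float(np.asarray(nu.pdf(np.array([1.0]))).ravel()[0])
    if nu_at_one == 0.0:
        return 0.0

    def integrand(p):
        return nu_at_one * rho.pdf(p) / (phi * (1.0 - p) ** 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, eps, 1.0 - eps, limit=200)
    return val


def mdp_density(
    nu: OrDistribution,
    rho: RafDistribution,
    phi: float,
    grid,
    eps: float = 1e-6,
) -> MdpDensity:
    """Density g of carrier MDPs implied by (nu, rho, phi), by adaptive
    quadrature over the risk-allele frequency.

    The p-integral is evaluated after substituting u = OR(x, p), which is
    monotone in p at fixed x; the Jacobians combine into the smooth
    integrand nu(u) phi sqrt(q) rho(p) / (2 x |phi - x|) with
    q = (1 - p)^2 = u (phi - x) / (x (1 - u)). The reachable odds ratios
    at a given x are [x/phi, inf) above phi and (0, x/phi] below, so
    supports that never map to x contribute exactly zero, and narrow nu
    supports near x = phi are integrated without being missed. The single
    point x = phi (where every allele frequency maps to OR = 1 and the
    density may diverge logarithmically) is evaluated in p-space."""
    grid = np.asarray(grid, float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid must lie strictly in (0, 1)")
    lo_s, hi_s = nu.support
    out = np.zeros_like(grid)
    for i, x in enumerate(grid):
        if abs(x - phi) < 1e-12:
            out[i] = _density_at_phi(nu, rho, phi, eps)
            continue

        def h(u, x=x):
            u = np.asarray(u, float)
            q = u * (phi - x) / (x * (1.0 - u))
            sq = np.sqrt(np.clip(q, 0.0, 1.0))
            p = 1.0 - sq
            return nu.pdf(u) * phi * sq * rho.pdf(p) / (2.0 * x * abs(phi - x))

        if x > phi:
            u_lo, u_hi = max(x / phi, lo_s), hi_s
        else:
            u_lo, u_hi = max(lo_s, 1e-12), min(x / phi, hi_s)
        if u_hi <= u_lo:
            continue
        if nu.edges is not None:
            # piecewise-constant nu: exact per-bin Gauss-Legendre panels
            knots = np.unique(np.clip(nu.edges, u_lo, u_hi))
            knots = np.concatenate([[u_lo], knots, [u_hi]])
            knots = np.unique(knots)
            nodes, wts = np.polynomial.legendre.leggauss(24)
            val = 0.0
            for a, b_ in zip(knots[:-1], knots[1:]):
                if b_ - a <= 0:
                    continue
                uu = 0.5 * (a + b_) + 0.5 * (b_ - a) * nodes
                val += 0.5 * (b_ - a) * float(h(uu) @ wts)
            out[i] = val
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", integrate.IntegrationWarning)
                val, _ = integrate.quad(h, u_lo, u_hi, limit=200)
            out[i] = val
    return MdpDensity(grid=grid, density=out)


def mdp_density_binned(
    nu: OrDistribution, rho: RafDistribution, phi: float, edges, n_sub: int = 9
) -> np.ndarray:
    """Bin-averaged MDP density over ``edges`` (the quantity a histogram of
    sampled loci estimates). Each bin is averaged on an n_sub-point
    sub-grid by the trapezoid rule."""
    edges = np.asarray(edges, float)
    out = np.empty(edges.size - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sub = np.linspace(lo, hi, n_sub)
        dens = mdp_density(nu, rho, phi, sub).density
        out[i] = np.trapezoid(dens, sub) / (hi - lo)
    return out


def gwas_detection_power(
    or_value,
    raf,
    n_cases: int = 20_000,
    n_controls: int = 30_000,
    alpha: float = 5e-8,
):
    """Approximate power of a carrier-versus-noncarrier two-proportion
    z-test at significance alpha, vectorized over (or_value, raf)."""
    v = np.asarray(or_value, float)
    p = np.asarray(raf, float)
    q0 = _carrier_fraction(p)  # carrier fraction among controls ~ population
    odds0 = q0 / (1.0 - q0)
    odds1 = v * odds0
    q1 = odds1 / (1.0 + odds1)  # carrier fraction among cases
    se = np.sqrt(q1 * (1.0 - q1) / n_cases + q0 * (1.0 - q0) / n_controls)
    z_crit = stats.norm.isf(alpha / 2.0)
    z = np.abs(q1 - q0) / se
    power = stats.norm.sf(z_crit - z) + stats.norm.cdf(-z_crit - z)
    return power if power.ndim else float(power)


def make_power_model(
    rho: Optional[RafDistribution] = None,
    raf: Optional[float] = None,
    n_cases: int = 20_000,
    n_controls: int = 30_000,
    alpha: float = 5e-8,
    n_quad: int = 64,
) -> Callable:
    """Build power(or) for histogram correction: either at a fixed RAF or
    marginalized over a RAF distribution by Gauss-Legendre quadrature."""
    if (rho is None) == (raf is None):
        raise ValueError("give exactly one of rho or raf")
    if raf is not None:
        return lambda v: gwas_detection_power(v, raf, n_cases, n_controls, alpha)
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    p = 0.5 * (nodes + 1.0) * (1 - 2e-6) + 1e-6
    w = 0.5 * weights * (1 - 2e-6) * rho.pdf(p)
    w = w / w.sum()

    def power(v):
        v = np.asarray(v, float)
        pw = gwas_detection_power(v[..., None], p, n_cases, n_controls, alpha)
        return (pw * w).sum(axis=-1)

    return power


def correct_or_distribution(raw: OrDistribution, power_model: Callable) -> OrDistribution:
    """Reweight a detected-locus OR histogram by inverse detection power.

    Each occupied bin's mass is divided by the power at the bin center and
    the histogram renormalized, undoing the under-representation of small
    odds ratios among genome-wide-significant hits."""
    if raw.edges is None:
        raise ValueError("power correction requires a histogram OrDistribution")
    centers = np.sqrt(raw.edges[:-1] * raw.edges[1:])  # log-scale bin centers
    power = np.asarray(power_model(centers), float)
    occupied = raw.weights > 0
    if np.any(occupied & (power <= 0)):
        bad = centers[occupied & (power <= 0)]
        raise ValueError(
            f"zero detection power on occupied bins at OR~{bad[:3]}; "
            "truncate the histogram support before correcting"
        )
    new_w = np.where(occupied, raw.weights / np.where(power > 0, power, 1.0), 0.0)
    return OrDistribution.from_histogram(raw.edges, new_w)
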