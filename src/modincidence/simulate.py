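"""Synthetic-data generators: Monte-Carlo cohorts from the module Markov
chains, binned incidence registries with Poisson counting noise, and
locus catalogues.

Every generator is a pure function of (config, seed): each individual-
module pair draws from a named substream of one seeded generator, so
cohorts are bitwise reproducible.

The registry generator emulates population-based incidence registries:
5-year age bins to 90 years, a fixed person-year denominator per bin
(default 5e6, chosen so the Poisson scatter is comparable to the visual
scatter of published national registries — a plausibility choice), and
case counts that are Poisson around the model curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import incidence_rate
from .genetics import LocusRecord, OrDistribution, RafDistribution, mdp_from_or
from .io import IncidenceTable
from .params import HomogenizedParams, ModuleNetwork

__all__ = [
    "CohortConfig",
    "RegistryConfig",
    "simulate_onset_ages",
    "generate_registry",
    "generate_locus_catalogue",
]


@dataclass(frozen=True)
class CohortConfig:
    """Monte-Carlo cohort: n individuals followed to max_age."""

    n_individuals: int
    params: Union[HomogenizedParams, ModuleNetwork]
    seed: int = 0
    max_age: float = 90.0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.max_age > 0:
            raise ValueError("max_age must be positive")


@dataclass(frozen=True)
class RegistryConfig:
    """Synthetic binned registry derived from the model curve."""

    params: HomogenizedParams
    bin_width: float = 5.0
    max_age: float = 90.0
    person_years: float = 5e6
    seed: int = 0
    noise: str = "none"

    def __post_init__(self):
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if not self.person_years > 0:
            raise ValueError("person_years must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def simulate_onset_ages(config: CohortConfig) -> np.ndarray:
    """Onset ages for a simulated cohort; ``inf`` marks no onset by max_age.

    Per individual and module: the maturation age is exponential with the
    module's mean tau; the mature state is permissive with probability F,
    otherwise protective with a later exponential(T) failure. The onset
    age is the maximum over modules of the permissive-entry ages (disease
    requires all modules permissive; with naive-protective modules the
    permissive state is absorbing, so the maximum is exact).
    """
    params = config.params
    if isinstance(params, HomogenizedParams):
        network = params.expand()
    else:
        network = params
    if any(m.naive_state != "protective" for m in network.modules):
        raise ValueError(
            "onset simulation requires naive-protective modules (the "
            "permissive state must be absorbing for onset = max of entry times)"
        )
    n = config.n_individuals
    root = np.random.default_rng(config.seed)
    streams = root.spawn(network.n_modules)  # one named substream per module
    onset = np.full(n, -np.inf)
    for spec, rng in zip(network.modules, streams):
        a = rng.exponential(spec.tau, size=n)
        permissive = rng.random(n) < spec.F
        entry = np.where(permissive, a, np.inf)
        prot = ~permissive
        n_prot = int(prot.sum())
        if n_prot and np.isfinite(spec.T):
            entry[prot] = a[prot] + rng.exponential(spec.T, size=n_prot)
        onset = np.maximum(onset, entry)
    onset[onset > config.max_age] = np.inf
    return onset


def generate_registry(config: RegistryConfig) -> IncidenceTable:
    """Binned incidence registry from the model curve, optionally with
    Poisson case-count noise; incidence column on the per-100,000 scale."""
    edges = np.arange(0.0, config.max_age + config.bin_width / 2, config.bin_width)
    lo, hi = edges[:-1], edges[1:]
    mid = 0.5 * (lo + hi)
    expected = incidence_rate(config.params, mid) * config.person_years
    if config.noise == "none":
        incidence = expected / config.person_years * 1e5
        return IncidenceTable(
            age_lo=lo,
            age_hi=hi,
            incidence=incidence,
            person_years=np.full(lo.size, config.person_years),
        )
    rng = np.random.default_rng(config.seed)
    cases = rng.poisson(expected).astype(float)
    incidence = cases / config.person_years * 1e5
    return IncidenceTable(
        age_lo=lo,
        age_hi=hi,
        incidence=incidence,
        person_years=np.full(lo.size, config.person_years),
        cases=cases,
    )


def generate_locus_catalogue(
    n_loci: int,
    nu: OrDistribution,
    rho: RafDistribution,
    phi: float,
    seed: int = 0,
    max_rejections: int = 100_000,
) -> list:
    """Sample a synthetic locus catalogue: raf ~ rho, OR ~ nu, and the
    implied carrier MDP from the OR inversion. Draws whose (OR, raf) pair
    is incompatible with phi are rejected and resampled (count capped)."""
    rng = np.random.default_rng(seed)
    records = []
    rejections = 0
    i = 0
    while len(records) < n_loci:
        if rejections > max_rejections:
            raise ValueError(
                f"infeasible (nu, rho, phi): {rejections} rejected draws "
                f"before filling {n_loci} loci"
            )
        raf = float(rho.rvs(1, rng)[0])
        orv = float(nu.rvs(1, rng)[0])
        if not (0.0 < raf < 1.0) or orv <= 0:
            rejections += 1
            continue
        try:
            mdp = mdp_from_or(orv, raf, phi)
        except ValueError:
            rejections += 1
            continue
        records.append(
            LocusRecord(locus_id=f"locus_{i:04d}", raf=raf, or_value=orv, mdp=mdp)
        )
        i += 1
    return records
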