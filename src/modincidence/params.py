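"""Parameter containers for the modular-network disease-onset model.

The disease network consists of N functional modules. Each module starts
in a naive state, stabilizes into a mature state after an exponential
maturation time (mean ``tau`` years), and the mature state is
disease-permissive with probability ``F`` (the module disease propensity,
MDP) or protective with probability ``1 - F``. A mature protective module
may still fail to the permissive state at a slow exponential rate
(mean time ``T`` years, ``T >> tau``). Disease onset occurs when all N
modules are simultaneously permissive.

The homogenized (mean-field) model replaces the per-module parameters by
their geometric means, leaving four parameters: N, tau, T, Phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModuleSpec",
    "ModuleNetwork",
    "HomogenizedParams",
    "as_age_grid",
]

#: sentinel threshold above which T is treated as infinite relative to tau,
#: to avoid catastrophic cancellation in the (1 - tau/T) weights
_T_INF_RATIO = 1e12


@dataclass(frozen=True)
class ModuleSpec:
    """One functional module of the disease network.

    Parameters
    ----------
    tau : float
        Mean maturation time of the naive state, in years. Must be > 0.
    T : float
        Mean failure time of the stabilized state, in years. Must exceed
        ``tau``; ``numpy.inf`` is allowed (no late failure).
    F : float
        Module disease propensity: probability that the mature state is
        disease-permissive. In [0, 1].
    naive_state : {"protective", "permissive"}
        State of the module at birth. The pipeline default is
        "protective"; the "permissive" variant (naive state compatible
        with disease, mature permissive modules failing *to* protective)
        is provided for the more general network model.
    """

    tau: float
    T: float
    F: float
    naive_state: str = "protective"

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.T > self.tau:
            raise ValueError(
                f"T must exceed tau (got T={self.T}, tau={self.tau}); "
                "the 1 - tau/T weight degenerates otherwise"
            )
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F}")
        if self.naive_state not in ("protective", "permissive"):
            raise ValueError(
                f"naive_state must be 'protective' or 'permissive', got {self.naive_state!r}"
            )

    @property
    def effectively_infinite_T(self) -> bool:
        return not np.isfinite(self.T) or self.T / self.tau > _T_INF_RATIO


@dataclass(frozen=True)
class ModuleNetwork:
    """An ordered collection of heterogeneous modules (the general model).

    The probability that the disease has arisen by age x is the product of
    the per-module permissive probabilities; with all modules naive-
    protective this is a proper onset CDF (the permissive state is
    absorbing).
    """

    modules: tuple[ModuleSpec, ...]

    def __init__(self, modules: Iterable[ModuleSpec]):
        mods = tuple(modules)
        if len(mods) < 1:
            raise ValueError("a ModuleNetwork needs at least one module")
        object.__setattr__(self, "modules", mods)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def homogenize(self) -> "HomogenizedParams":
        """Mean-field reduction: geometric means of (tau, T, F) across modules."""
        taus = np.array([m.tau for m in self.modules])
        Ts = np.array([m.T for m in self.modules])
        Fs = np.array([m.F for m in self.modules])
        if np.any(Fs <= 0):
            raise ValueError("geometric mean of F undefined with F=0 modules")
        return HomogenizedParams(
            N=len(self.modules),
            tau=float(np.exp(np.mean(np.log(taus)))),
            T=float(np.exp(np.mean(np.log(Ts)))),
            Phi=float(np.exp(np.mean(np.log(Fs)))),
        )


@dataclass(frozen=True)
class HomogenizedParams:
    """Four-parameter homogenized model: (N, tau, T, Phi).

    N is the number of exchangeable modules; tau, T, Phi are the geometric
    means of the per-module maturation times, failure times and disease
    propensities. ``T = numpy.inf`` selects the no-late-failure limit, in
    which the lifetime disease risk plateaus at ``Phi**N``.
    """

    N: int
    tau: float
    T: float
    Phi: float

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.T > self.tau:
            raise ValueError(f"need T > tau, got T={self.T}, tau={self.tau}")
        if not 0.0 <= self.Phi <= 1.0:
            raise ValueError(f"Phi must lie in [0, 1], got {self.Phi}")

    @property
    def effectively_infinite_T(self) -> bool:
        return not np.isfinite(self.T) or self.T / self.tau > _T_INF_RATIO

    def as_module(self) -> ModuleSpec:
        return ModuleSpec(tau=self.tau, T=self.T, F=self.Phi)

    def expand(self) -> ModuleNetwork:
        """The equivalent general network of N identical modules."""
        return ModuleNetwork([self.as_module()] * self.N)

    def to_dict(self) -> dict:
        return {"N": int(self.N), "tau": float(self.tau), "T": float(self.T), "Phi": float(self.Phi)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "HomogenizedParams":
        return cls(N=int(d["N"]), tau=float(d["tau"]), T=float(d["T"]), Phi=float(d["Phi"]))

    def replace(self, **kw) -> "HomogenizedParams":
        d = self.to_dict()
        d.update(kw)
        return HomogenizedParams(**d)


def as_age_grid(ages: Sequence[float]) -> np.ndarray:
    """Validate and return a strictly increasing, nonnegative age grid (years)."""
    arr = np.asarray(ages, dtype=float)
    if arr.ndim != 1:
        raise ValueError("age grid must be one-dimensional")
    if arr.size and arr[0] < 0:
        raise ValueError("ages must be nonnegative")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError("ages must be strictly increasing")
    return arr
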