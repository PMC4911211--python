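"""Tables and file formats: binned incidence registries, locus catalogues,
parameter files.

All tabular I/O is tidy CSV (one observation per row); structured results
are JSON and configurations are YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .params import HomogenizedParams

__all__ = [
    "IncidenceTable",
    "read_incidence_csv",
    "write_incidence_csv",
    "read_locus_csv",
    "write_locus_csv",
    "load_params",
    "dump_params",
]

_INCIDENCE_COLUMNS = ["age_lo", "age_hi", "incidence_per_100k"]


@dataclass(frozen=True)
class IncidenceTable:
    """Binned age-specific incidence observations.

    Each row is one age bin [age_lo, age_hi) with an observed incidence
    rate per 100,000 person-years, optionally accompanied by the exposure
    denominator (person-years) and the raw case count.
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    incidence: np.ndarray  # per 100,000 person-years
    person_years: Optional[np.ndarray] = None
    cases: Optional[np.ndarray] = None

    def __post_init__(self):
        lo = np.asarray(self.age_lo, dtype=float)
        hi = np.asarray(self.age_hi, dtype=float)
        inc = np.asarray(self.incidence, dtype=float)
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "age_hi", hi)
        object.__setattr__(self, "incidence", inc)
        if self.person_years is not None:
            object.__setattr__(self, "person_years", np.asarray(self.person_years, dtype=float))
        if self.cases is not None:
            object.__setattr__(self, "cases", np.asarray(self.cases, dtype=float))
        if not (len(lo) == len(hi) == len(inc)):
            raise ValueError("column lengths differ")
        if len(lo) == 0:
            raise ValueError("empty incidence table")
        bad = np.nonzero(~(lo < hi))[0]
        if bad.size:
            raise ValueError(f"age_lo >= age_hi in rows {bad.tolist()}")
        order = np.argsort(lo)
        overlap = np.nonzero(hi[order][:-1] > lo[order][1:] + 1e-9)[0]
        if overlap.size:
            rows = [(int(order[i]), int(order[i + 1])) for i in overlap]
            raise ValueError(f"overlapping age bins in row pairs {rows}")
        if np.any(inc < 0):
            raise ValueError("negative incidence")
        if self.cases is not None and self.person_years is not None:
            implied = self.cases / self.person_years * 1e5
            # allow rounding of published rates to ~last printed digit
            if np.any(np.abs(implied - inc) > np.maximum(0.05, 5e-4 * np.abs(inc)) + 1e-9):
                raise ValueError("incidence inconsistent with cases/person_years")

    def __len__(self) -> int:
        return len(self.age_lo)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.age_lo + self.age_hi)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncidenceTable":
        missing = [c for c in _INCIDENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(
            age_lo=df["age_lo"].to_numpy(float),
            age_hi=df["age_hi"].to_numpy(float),
            incidence=df["incidence_per_100k"].to_numpy(float),
            person_years=df["person_years"].to_numpy(float) if "person_years" in df else None,
            cases=df["cases"].to_numpy(float) if "cases" in df else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "age_lo": self.age_lo,
            "age_hi": self.age_hi,
            "incidence_per_100k": self.incidence,
        }
        if self.person_years is not None:
            data["person_years"] = self.person_years
        if self.cases is not None:
            data["cases"] = self.cases
        return pd.DataFrame(data)


def read_incidence_csv(path) -> IncidenceTable:
    """Read and validate a binned incidence table from CSV."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot read incidence CSV {path}: {exc}") from exc
    try:
        return IncidenceTable.from_dataframe(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_incidence_csv(table: IncidenceTable, path) -> None:
    # repr-round-trip float formatting so read-back is bit-exact
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_locus_csv(path) -> pd.DataFrame:
    """Read a locus catalogue CSV (locus_id, raf, or[, mdp])."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("locus_id", "raf", "or"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if not ((df["raf"] > 0) & (df["raf"] < 1)).all():
        raise ValueError(f"{path}: raf must lie strictly in (0, 1)")
    if not (df["or"] > 0).all():
        raise ValueError(f"{path}: odds ratios must be positive")
    return df


def write_locus_csv(records, path) -> None:
    from .genetics import LocusRecord  # local import to avoid a cycle

    rows = [
        {"locus_id": r.locus_id, "raf": r.raf, "or": r.or_value, "mdp": r.mdp}
        for r in records
    ]
    pd.DataFrame(rows, columns=["locus_id", "raf", "or", "mdp"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_params(path) -> HomogenizedParams:
    """Load homogenized parameters from a flat YAML/JSON mapping {N, tau, T, Phi}."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping with keys N, tau, T, Phi")
    if isinstance(data.get("T"), str) and data["T"].lower() in (".inf", "inf", "infinity"):
        data["T"] = np.inf
    return HomogenizedParams.from_dict(data)


def dump_params(params: HomogenizedParams, path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(params.to_dict(), indent=2))
    else:
        p.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
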