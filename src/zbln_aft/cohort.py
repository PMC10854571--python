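"""Cohort data model: records, covariate specs, CSV I/O, dummy coding, splitting.

A cohort is one row per patient: follow-up time in months since diagnosis,
an event flag (1 = death from the index cancer, 0 = administratively
censored at the study horizon), and a fixed set of typed covariates.
Categorical covariates carry an explicit reference level; the design matrix
uses treatment (dummy) coding that omits the reference column, so fitted
coefficients read as contrasts against that level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "CohortFormatError",
    "CohortValidationError",
    "DegenerateDesignError",
    "CovariateSpec",
    "SurvivalRecord",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "encode_design",
    "split_cohort",
    "recensor",
    "specs_to_json",
    "specs_from_json",
    "lung_cancer_covariates",
]

VALID_HORIZONS = (36, 60)


class CohortError(ValueError):
    """Base class for cohort construction problems."""


class CohortFormatError(CohortError):
    """The input file does not have the expected columns/shape."""


class CohortValidationError(CohortError):
    """Rows violate the declared covariate specs or time/event invariants."""


class DegenerateDesignError(CohortError):
    """The requested design matrix would be rank deficient."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one covariate: its kind, levels and reference level."""

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise CohortError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise CohortError(f"{self.name}: categorical without levels")
            if len(set(self.levels)) != len(self.levels):
                raise CohortError(f"{self.name}: duplicate levels")
            if self.reference not in self.levels:
                raise CohortError(
                    f"{self.name}: reference {self.reference!r} not among levels"
                )
        else:
            if self.levels is not None or self.reference is not None:
                raise CohortError(f"{self.name}: continuous takes no levels")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time (months, > 0), event flag, covariates."""

    time: float
    event: int
    covariates: Mapping[str, object]

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise CohortValidationError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise CohortValidationError(f"event must be 0/1, got {self.event}")


@dataclass
class CohortTable:
    """A validated cohort: data frame + covariate metadata + censoring horizon.

    ``df`` holds columns ``time``, ``event`` and one column per covariate;
    validation happens on construction so downstream code can trust types,
    level membership and the administrative-censoring invariant
    (no time exceeds the horizon).
    """

    df: pd.DataFrame
    specs: tuple[CovariateSpec, ...]
    horizon: int

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        if self.horizon not in VALID_HORIZONS:
            raise CohortError(f"horizon must be one of {VALID_HORIZONS}")
        _validate_frame(self.df, self.specs, self.horizon)
        order = ["time", "event"] + [s.name for s in self.specs]
        self.df = self.df.loc[:, order].reset_index(drop=True)
        self.df["time"] = self.df["time"].astype(float)
        self.df["event"] = self.df["event"].astype(int)

    # -- convenience accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(int)

    @property
    def records(self) -> list[SurvivalRecord]:
        names = [s.name for s in self.specs]
        return [
            SurvivalRecord(row.time, int(row.event),
                           {n: getattr(row, n) for n in names})
            for row in self.df.itertuples(index=False)
        ]

    def spec(self, name: str) -> CovariateSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @classmethod
    def from_records(
        cls,
        records: Iterable[SurvivalRecord],
        specs: Sequence[CovariateSpec],
        horizon: int,
    ) -> "CohortTable":
        rows = [{"time": r.time, "event": r.event, **r.covariates} for r in records]
        return cls(pd.DataFrame(rows), tuple(specs), horizon)


def _validate_frame(
    df: pd.DataFrame, specs: Sequence[CovariateSpec], horizon: int
) -> None:
    required = ["time", "event"] + [s.name for s in specs]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing columns: {missing}")

    problems: list[str] = []
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    for i in np.flatnonzero(~(np.isfinite(time) & (time > 0))):
        problems.append(f"row {i}: time must be a positive number, got {df['time'].iloc[i]!r}")
    for i in np.flatnonzero(~event.isin([0, 1])):
        problems.append(f"row {i}: event must be 0 or 1, got {df['event'].iloc[i]!r}")
    over = np.flatnonzero(np.isfinite(time) & (time > horizon + 1e-9))
    for i in over:
        problems.append(
            f"row {i}: time {time.iloc[i]} exceeds the administrative horizon {horizon}"
        )
    for s in specs:
        col = df[s.name]
        if s.kind == "continuous":
            vals = pd.to_numeric(col, errors="coerce")
            for i in np.flatnonzero(~np.isfinite(vals)):
                problems.append(f"row {i}: {s.name} must be numeric, got {col.iloc[i]!r}")
        else:
            ok = col.astype(str).isin(s.levels)
            for i in np.flatnonzero(~ok):
                problems.append(
                    f"row {i}: unknown level {col.iloc[i]!r} for {s.name} "
                    f"(declared: {list(s.levels)})"
                )
    if problems:
        raise CohortValidationError("; ".join(problems[:20]) +
                                    ("" if len(problems) <= 20 else f"; … {len(problems)} total"))


def read_cohort(
    path,
    specs: Sequence[CovariateSpec],
    horizon: int,
    remap_zero_times: bool = False,
) -> CohortTable:
    """Read a cohort CSV (columns ``time``, ``event``, one per covariate).

    ``remap_zero_times=True`` maps recorded times of exactly 0 months
    (death in the month of diagnosis, a tie at the boundary under
    month-granularity registries) to 0.5 months before validation;
    otherwise non-positive times are rejected with row-indexed diagnostics.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message suffices
        raise CohortFormatError(str(exc)) from exc
    if remap_zero_times and "time" in df.columns:
        t = pd.to_numeric(df["time"], errors="coerce")
        df["time"] = t.where(t != 0, 0.5)
    return CohortTable(df, tuple(specs), horizon)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort as plain CSV, times with 6 decimals (round-trip safe)."""
    cohort.df.to_csv(path, index=False, float_format="%.6f")


def encode_design(
    cohort: CohortTable, covariates: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix (no intercept column).

    Continuous covariates pass through; a categorical with L levels yields
    L-1 indicator columns, omitting the reference level. Column order is
    deterministic: spec order, then declared level order. Column names are
    ``name`` (continuous) or ``name:level``.
    """
    if covariates is None:
        use = list(cohort.specs)
    else:
        use = [cohort.spec(name) for name in covariates]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for s in use:
        if s.kind == "continuous":
            cols.append(cohort.df[s.name].to_numpy(float))
            names.append(s.name)
        else:
            if len(s.levels) < 2:
                raise DegenerateDesignError(
                    f"{s.name}: categorical with a single level cannot be coded"
                )
            vals = cohort.df[s.name].astype(str).to_numpy()
            for lev in s.levels:
                if lev == s.reference:
                    continue
                cols.append((vals == lev).astype(float))
                names.append(f"{s.name}:{lev}")
    X = np.column_stack(cols) if cols else np.empty((cohort.n, 0))
    return X, names


def split_cohort(
    cohort: CohortTable, train_fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Random disjoint train/validation partition, train size round(n*f)."""
    if not 0 < train_fraction < 1:
        raise CohortError("train_fraction must be in (0, 1)")
    n = cohort.n
    if n < 2:
        raise CohortError("cannot split a cohort with fewer than 2 records")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr = cohort.df.iloc[np.sort(perm[:n_train])]
    te = cohort.df.iloc[np.sort(perm[n_train:])]
    return (
        CohortTable(tr, cohort.specs, cohort.horizon),
        CohortTable(te, cohort.specs, cohort.horizon),
    )


def recensor(cohort: CohortTable, horizon: int) -> CohortTable:
    """Re-apply administrative censoring at a shorter horizon."""
    if horizon > cohort.horizon:
        raise CohortError("cannot extend follow-up beyond the recorded horizon")
    df = cohort.df.copy()
    over = df["time"] > horizon
    df.loc[over, "time"] = float(horizon)
    df.loc[over, "event"] = 0
    return CohortTable(df, cohort.specs, horizon)


# -- JSON config ---------------------------------------------------------

def specs_to_json(specs: Sequence[CovariateSpec], horizon: int) -> str:
    payload = {
        "horizon": horizon,
        "covariates": [
            {
                "name": s.name,
                "kind": s.kind,
                **(
                    {"levels": list(s.levels), "reference": s.reference}
                    if s.kind == "categorical"
                    else {}
                ),
            }
            for s in specs
        ],
    }
    return json.dumps(payload, indent=2)


def specs_from_json(text: str) -> tuple[tuple[CovariateSpec, ...], int]:
    payload = json.loads(text)
    specs = tuple(
        CovariateSpec(
            name=c["name"],
            kind=c["kind"],
            levels=tuple(c["levels"]) if c.get("levels") else None,
            reference=c.get("reference"),
        )
        for c in payload["covariates"]
    )
    return specs, int(payload["horizon"])


def lung_cancer_covariates() -> tuple[CovariateSpec, ...]:
    """The study covariate set, with reference levels as reported.

    Order: age, race, gender, treatment, histology, primary site, grade,
    TISP (count of in situ/malignant tumors), metastasis pattern. Dummy
    coding this set yields 22 design columns.
    """
    return (
        CovariateSpec("age", "continuous"),
        CovariateSpec(
            "race", "categorical",
            ("American Indian", "Asian", "Black", "White"), "American Indian",
        ),
        CovariateSpec("gender", "categorical", ("Male", "Female"), "Male"),
        CovariateSpec(
            "treatment", "categorical",
            ("No Treatment", "Monotherapy", "Bimodal Therapy", "Trimodal Therapy"),
            "No Treatment",
        ),
        CovariateSpec(
            "histology", "categorical",
            (
                "Epithelial Neoplasms",
                "Squamous Cell Neoplasms",
                "Adenomas and Adenocarcinomas",
                "Others",
            ),
            "Epithelial Neoplasms",
        ),
        CovariateSpec(
            "primary_site", "categorical",
            (
                "Main Bronchus",
                "Upper Lobe",
                "Middle Lobe",
                "Lower Lobe",
                "Lung NOS",
                "Overlapping Lesion of Lung",
            ),
            "Main Bronchus",
        ),
        CovariateSpec(
            "grade", "categorical",
            (
                "Well-Differentiated",
                "Moderately Differentiated",
                "Poorly Differentiated",
                "Undifferentiated",
            ),
            "Well-Differentiated",
        ),
        CovariateSpec("tisp", "continuous"),
        CovariateSpec(
            "metastases", "categorical",
            ("Bone Only", "Bone and Brain", "Brain Only"), "Bone Only",
        ),
    )
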