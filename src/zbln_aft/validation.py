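"""Held-out performance: Harrell concordance, Kaplan-Meier, calibration, RMSE.

The concordance convention here is survival-time-oriented: scores are
"higher = predicted to live longer" (predicted median survival for AFT
models, the negated linear predictor for Cox), so concordance counts
pairs where the longer-lived patient also got the higher score. A pair is
comparable iff the smaller observed time is an event; tied scores earn
half credit (Harrell's estimator).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import CohortTable

__all__ = ["ConcordanceError", "harrell_c", "KMCurve", "km_estimate",
           "CalibrationBin", "calibration_table", "rmse_pred",
           "ValidationReport", "validate_model", "risk_scores"]


class ConcordanceError(ValueError):
    """No comparable pair exists: concordance is undefined."""


def harrell_c(scores, times, events) -> float:
    """Harrell's C over comparable pairs (vectorized O(n^2) enumeration).

    For each ordered pair with t_i < t_j and event_i = 1: concordant
    (score_i < score_j) counts 1, tied scores count 0.5, discordant 0.
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    if not (len(s) == len(t) == len(d)):
        raise ValueError("scores, times, events must have equal length")
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ConcordanceError("no comparable pair (check events and ties)")
    conc = (s[:, None] < s[None, :]) & comparable
    tied = (s[:, None] == s[None, :]) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    def __init__(self, times, events):
        t = np.asarray(times, float)
        d = np.asarray(events, int)
        if len(t) == 0:
            raise ValueError("need at least one observation")
        self._kmf = KaplanMeierFitter().fit(t, d)
        self.max_time = float(t.max())

    def __call__(self, t):
        out = np.atleast_1d(np.asarray(
            self._kmf.predict(np.atleast_1d(np.asarray(t, float)),
                              interpolate=False), float))
        return out if np.ndim(t) else float(out[0])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; S(0) = 1, steps at event times."""
    return KMCurve(times, events)


@dataclass
class CalibrationBin:
    mean_predicted: float
    km_observed: float
    n: int
    flagged: bool = False  # KM carried beyond the bin's last observed time


def calibration_table(model, cohort: CohortTable, horizon: float,
                      n_bins: int = 10) -> list[CalibrationBin]:
    """Equal-count calibration bins of predicted vs KM-observed S(horizon).

    Records are sorted by predicted S(horizon | x) and cut into ``n_bins``
    bins of equal count (+/- 1); each bin reports the mean predicted
    probability and the within-bin Kaplan-Meier estimate at the horizon.
    A bin whose follow-up ends before the horizon carries the last KM value
    with ``flagged=True``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pred = np.asarray(model.predict_survival(cohort, horizon), float)
    order = np.argsort(pred, kind="stable")
    t, d = cohort.times, cohort.events
    bins = []
    for idx in np.array_split(order, n_bins):
        km = km_estimate(t[idx], d[idx])
        bins.append(
            CalibrationBin(
                mean_predicted=float(pred[idx].mean()),
                km_observed=km(horizon),
                n=len(idx),
                flagged=bool(km.max_time < horizon),
            )
        )
    return bins


def rmse_pred(model, cohort: CohortTable) -> float:
    """RMSE of predicted median survival vs observed time, uncensored only."""
    d = cohort.events
    if int(d.sum()) == 0:
        raise ValueError("no uncensored records: RMSE undefined")
    unc = d == 1
    sub = CohortTable(cohort.df.loc[unc], cohort.specs, cohort.horizon)
    pred = np.asarray(model.predict_median(sub), float)
    return float(np.sqrt(np.mean((pred - sub.times) ** 2)))


def risk_scores(model, cohort: CohortTable) -> np.ndarray:
    """Survival-time-oriented scores: predicted median (AFT) or -lp (Cox)."""
    if hasattr(model, "ancillary"):  # parametric AFT fit
        return np.asarray(model.predict_median(cohort), float)
    return -np.asarray(model.linear_predictor(cohort), float)


@dataclass
class ValidationReport:
    c_index: float
    rmse: float | None
    calibration: list[CalibrationBin]
    rmse_definition: str = ("RMSE of predicted median survival time vs observed "
                            "time over uncensored records")

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "rmse": self.rmse,
            "rmse_definition": self.rmse_definition,
            "calibration": [asdict(b) for b in self.calibration],
        }


def validate_model(model, cohort: CohortTable, horizon: float,
                   n_bins: int = 10) -> ValidationReport:
    """C-index, RMSE (AFT only) and calibration bins on a held-out cohort."""
    c = harrell_c(risk_scores(model, cohort), cohort.times, cohort.events)
    rmse = rmse_pred(model, cohort) if hasattr(model, "ancillary") else None
    cal = calibration_table(model, cohort, horizon, n_bins)
    return ValidationReport(c_index=c, rmse=rmse, calibration=cal)
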