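"""Right-censored survival statistics shared by the signature pipeline.

The estimators here — Kaplan–Meier and Nelson–Aalen step functions, the
k-group log-rank test, the Cox proportional-hazards fit and Harrell's
concordance index — are backed by :mod:`lifelines`.  This module pins the
conventions the rest of the package relies on:

* tied event times in the Cox partial likelihood are handled with the
  Efron correction (lifelines' default), appropriate for the tie-heavy,
  year-granular survival records the pipeline consumes;
* the log-rank p-value is always taken from the chi-square reference with
  ``k - 1`` degrees of freedom;
* the concordance index is oriented so that *higher risk* scores are
  concordant with *shorter* survival, matching the forest's mortality
  predictions (OOB error = 1 - C);
* confidence intervals are reported at the 95% level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _ll_concordance

from .errors import EstimationError, InputError

__all__ = [
    "SurvivalData",
    "StepFunction",
    "km_estimate",
    "nelson_aalen",
    "logrank_test",
    "LogrankResult",
    "cox_fit",
    "CoxResult",
    "concordance_index",
]


def _as_time_event(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise InputError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise InputError("empty survival data")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise InputError("survival times must be finite and positive")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise InputError("event indicators must be 0/1")
    return time, ev.astype(np.int8)


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored outcomes: positive times, 0/1 event indicators.

    ``covariates`` is an optional patient-by-feature DataFrame aligned with
    ``time``/``event`` by position.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        time, event = _as_time_event(self.time, self.event)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if self.covariates is not None and len(self.covariates) != time.size:
            raise InputError("covariates must have one row per subject")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


class StepFunction:
    """Right-continuous piecewise-constant function on ascending knots.

    Value at ``t`` is ``y[i]`` for the largest knot ``x[i] <= t``; queries
    before the first knot return ``y_before``; queries after the last knot
    return the final value (constant extension).
    """

    __slots__ = ("x", "y", "y_before")

    def __init__(self, x, y, y_before: float):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise InputError("knots and values must be 1-d and equal length")
        if x.size and np.any(np.diff(x) < 0):
            raise InputError("knots must be ascending")
        self.x = x
        self.y = y
        self.y_before = float(y_before)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t_arr, side="right") - 1
        out = np.where(
            idx < 0,
            self.y_before,
            self.y[np.clip(idx, 0, max(len(self.y) - 1, 0))] if self.y.size else self.y_before,
        )
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"StepFunction({self.x.size} knots)"


def km_estimate(time, event) -> StepFunction:
    """Kaplan–Meier product-limit estimate of S(t); S(0) = 1."""
    time, event = _as_time_event(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return StepFunction(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float), y_before=1.0)


def nelson_aalen(time, event) -> StepFunction:
    """Nelson–Aalen cumulative-hazard estimate H(t); H(0) = 0."""
    time, event = _as_time_event(time, event)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(time, event_observed=event)
    ch = naf.cumulative_hazard_
    return StepFunction(ch.index.to_numpy(float), ch.iloc[:, 0].to_numpy(float), y_before=0.0)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(groups: Sequence) -> LogrankResult:
    """k-group log-rank test with hypergeometric variance.

    ``groups`` is a sequence of ``(time, event)`` pairs or
    :class:`SurvivalData`; the p-value comes from the chi-square reference
    with ``k - 1`` degrees of freedom.
    """
    parsed = []
    for g in groups:
        if isinstance(g, SurvivalData):
            parsed.append((g.time, g.event))
        else:
            parsed.append(_as_time_event(*g))
    parsed = [(t, e) for t, e in parsed if t.size]
    if len(parsed) < 2:
        raise InputError("log-rank test needs at least two non-empty groups")
    time = np.concatenate([t for t, _ in parsed])
    event = np.concatenate([e for _, e in parsed])
    label = np.concatenate([np.full(t.size, i) for i, (t, _) in enumerate(parsed)])
    if event.sum() == 0:
        raise InputError("log-rank test needs at least one event")
    res = multivariate_logrank_test(time, label, event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(parsed) - 1,
        p_value=float(res.p_value),
    )


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit (Efron ties, 95% CIs)."""

    names: tuple
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    def conf_int(self, z: float = 1.959963984540054):
        """(lower, upper) 95% CI on the hazard-ratio scale."""
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        return lo, hi


def cox_fit(covariates, time, event, names: Optional[Sequence[str]] = None) -> CoxResult:
    """Fit a Cox proportional-hazards model (Efron tie correction).

    ``covariates`` may be a DataFrame, a 1-d array (single covariate) or a
    2-d array with ``names``.  Raises :class:`EstimationError` on constant
    covariates, absent events or non-convergence (e.g. monotone likelihood
    under perfect separation).
    """
    time, event = _as_time_event(time, event)
    if event.sum() == 0:
        raise EstimationError("Cox fit requires at least one event")
    if isinstance(covariates, pd.DataFrame):
        X = covariates.reset_index(drop=True)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if names is None:
            names = [f"x{i}" for i in range(arr.shape[1])]
        X = pd.DataFrame(arr, columns=list(names))
    if len(X) != time.size:
        raise InputError("covariate rows must match survival records")
    stds = X.std(axis=0, ddof=0)
    constant = [c for c in X.columns if stds[c] == 0 or not np.isfinite(stds[c])]
    if constant:
        raise EstimationError(f"constant covariate(s): {constant}")
    df = X.copy()
    df["time__"] = time
    df["event__"] = event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cph.fit(df, duration_col="time__", event_col="event__",
                    fit_options={"precision": 1e-11, "max_steps": 500})
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise EstimationError(f"Cox fit did not converge: {exc}") from exc
    suspicious = [
        w for w in caught
        if issubclass(w.category, ConvergenceWarning)
        and ("separation" in str(w.message) or "determines whether" in str(w.message)
             or "norm(delta)" in str(w.message))
    ]
    if suspicious:
        raise EstimationError(
            "Cox fit degenerate (monotone likelihood / separation): "
            + str(suspicious[0].message).strip().splitlines()[0]
        )
    beta = cph.params_.to_numpy(float)
    se = cph.standard_errors_.to_numpy(float)
    if np.any(~np.isfinite(se)) or np.any(se > 1e4):
        raise EstimationError("Cox fit degenerate (unbounded standard errors); "
                              "likely monotone likelihood / separation")
    return CoxResult(
        names=tuple(X.columns),
        beta=beta,
        se=se,
        p=cph.summary["p"].to_numpy(float),
        loglik=float(cph.log_likelihood_),
    )


def concordance_index(risk, time, event) -> float:
    """Harrell's C for risk scores (higher risk ⇔ earlier event).

    Ties in risk count 1/2.  Returns NaN when no pair is comparable.
    """
    time, event = _as_time_event(time, event)
    risk = np.asarray(risk, dtype=float)
    if risk.shape != time.shape:
        raise InputError("risk scores must align with survival records")
    try:
        return float(_ll_concordance(time, -risk, event))
    except ZeroDivisionError:
        return float("nan")
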