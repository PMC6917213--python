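"""Gene signatures: representation, GMT I/O, scoring and risk calls.

A signature is a named gene set with per-gene direction weights (+1 for
genes expected up in the risk phenotype, −1 for down).  Samples are scored
as the weighted sum of per-gene standardized expression; scores are mapped
affinely onto [−1, +1]; samples are dichotomized so the high-risk fraction
matches the cohort's event fraction; multiple signatures combine by
majority vote; the prognostic value of a call set is summarized by a
univariate Cox hazard ratio with a 95% CI and a log-rank p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import survcore
from .errors import EstimationError, InputError, ScoringError

__all__ = [
    "GeneSignature",
    "read_gmt",
    "write_gmt",
    "score_samples",
    "normalize_scores",
    "dichotomize_by_event_percentile",
    "signature_correlation",
    "consensus_call",
    "group_hazard_ratio",
    "HazardRatioResult",
]


@dataclass(frozen=True)
class GeneSignature:
    """Named gene set with per-gene direction weights in {+1, −1}."""

    name: str
    members: Tuple[Tuple[str, int], ...]
    tag: Optional[str] = None  # e.g. "hypoxia" | "angiogenesis"

    def __post_init__(self):
        if not self.members:
            raise InputError(f"signature {self.name!r} has no members")
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            raise InputError(f"signature {self.name!r} has duplicate genes")
        if any(w not in (-1, 1) for _, w in self.members):
            raise InputError(f"signature {self.name!r} has weights outside {{+1, -1}}")

    @property
    def genes(self) -> List[str]:
        return [g for g, _ in self.members]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.members], dtype=float)

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path) -> List[GeneSignature]:
    """Read signatures from GMT; a ``GENE|-1`` token marks weight −1.

    The GMT description field doubles as an optional tag
    (``hypoxia``/``angiogenesis``); any other text is kept as-is.
    """
    sigs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed GMT line: {line[:60]!r}")
            name, desc = parts[0], parts[1]
            members = []
            for tok in parts[2:]:
                tok = tok.strip()
                if not tok:
                    continue
                if "|" in tok:
                    gene, w = tok.rsplit("|", 1)
                    members.append((gene, int(w)))
                else:
                    members.append((tok, 1))
            tag = desc if desc in ("hypoxia", "angiogenesis") else None
            sigs.append(GeneSignature(name=name, members=tuple(members), tag=tag))
    return sigs


def write_gmt(sigs: Iterable[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            toks = [g if w == 1 else f"{g}|{w}" for g, w in sig.members]
            desc = sig.tag or "na"
            fh.write("\t".join([sig.name, desc, *toks]) + "\n")


def score_samples(
    sig: GeneSignature,
    expr: pd.DataFrame,
    standardize: bool = True,
    agg: str = "sum",
) -> pd.Series:
    """Raw per-sample signature scores.

    ``expr`` is genes × samples on a normalized scale.  Each signature gene
    present in ``expr`` contributes ``weight * z`` where ``z`` is the gene's
    expression standardized across samples (``standardize=False`` uses the
    values as given).  Genes absent from ``expr`` are skipped with a
    warning; if none are present a :class:`ScoringError` is raised.
    ``agg`` is ``"sum"`` or ``"mean"`` over contributing genes.
    """
    if agg not in ("sum", "mean"):
        raise InputError("agg must be 'sum' or 'mean'")
    present = [(g, w) for g, w in sig.members if g in expr.index]
    missing = [g for g, _ in sig.members if g not in expr.index]
    if not present:
        raise ScoringError(f"no gene of signature {sig.name!r} present in expression")
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} gene(s) absent from expression",
            stacklevel=2,
        )
    sub = expr.loc[[g for g, _ in present]].to_numpy(float)
    if standardize:
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        sub = (sub - mu) / sd
    w = np.array([wt for _, wt in present], dtype=float)
    raw = w @ sub
    if agg == "mean":
        raw = raw / len(present)
    return pd.Series(raw, index=expr.columns, name=sig.name)


def normalize_scores(raw: pd.Series) -> pd.Series:
    """Affine map of raw scores onto [−1, +1] (min→−1, max→+1).

    A degenerate (constant) score vector maps to all zeros.
    """
    if len(raw) == 0:
        raise InputError("no samples to normalize")
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi == lo:
        return pd.Series(np.zeros(len(raw)), index=raw.index, name=raw.name)
    return (raw - lo) / (hi - lo) * 2.0 - 1.0


def dichotomize_by_event_percentile(scores: pd.Series, events) -> pd.Series:
    """High/low risk calls with the high-risk fraction ≈ the event fraction.

    The cutoff is the ``(1 − event_fraction)`` quantile of the score
    distribution; samples scoring strictly above it are called high-risk.
    """
    if len(scores) == 0:
        raise InputError("no samples to dichotomize")
    events = np.asarray(events)
    if events.shape[0] != len(scores):
        raise InputError("events must align with scores")
    frac = float(np.mean(events))
    if frac >= 1.0:
        calls = np.full(len(scores), "high")
    elif frac <= 0.0:
        calls = np.full(len(scores), "low")
    else:
        cutoff = float(np.quantile(scores.to_numpy(float), 1.0 - frac))
        calls = np.where(scores.to_numpy(float) > cutoff, "high", "low")
    return pd.Series(calls, index=scores.index, name=scores.name)


def signature_correlation(sigs: Sequence[GeneSignature], expr: pd.DataFrame,
                          standardize: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-sample signature scores.

    Degenerate (constant) score vectors yield NaN rows/columns; the
    diagonal is exactly 1 for non-degenerate signatures.
    """
    scoreable = []
    for sig in sigs:
        try:
            scoreable.append(score_samples(sig, expr, standardize=standardize))
        except ScoringError:
            continue
    if len(scoreable) < 2:
        raise InputError("need at least two scoreable signatures")
    mat = pd.concat(scoreable, axis=1)
    arr = mat.to_numpy(float).T
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=mat.columns, columns=mat.columns)


def consensus_call(calls: pd.DataFrame) -> pd.Series:
    """Majority vote over signatures (samples × signatures of high/low).

    Exact ties are called high-risk.
    """
    if calls.shape[1] < 1:
        raise InputError("need at least one signature's calls")
    bad = ~calls.isin(["high", "low"]).all(axis=None)
    if bad:
        raise InputError("calls must be 'high' or 'low'")
    n_high = (calls == "high").sum(axis=1)
    out = np.where(2 * n_high >= calls.shape[1], "high", "low")
    return pd.Series(out, index=calls.index, name="consensus")


@dataclass(frozen=True)
class HazardRatioResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_cox: float
    p_logrank: float
    n_high: int
    n_low: int


def group_hazard_ratio(calls: pd.Series, time, event) -> HazardRatioResult:
    """Univariate Cox HR of high- vs low-risk calls, with log-rank p.

    The CI is the normal approximation on the log-hazard scale at 95%.
    Raises :class:`EstimationError` if either group is empty or no event
    occurred.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    ind = (calls.to_numpy() == "high").astype(float)
    n_high = int(ind.sum())
    n_low = int(len(ind) - n_high)
    if n_high == 0 or n_low == 0:
        raise EstimationError("both risk groups must be non-empty")
    if np.sum(event) == 0:
        raise EstimationError("no events observed")
    fit = survcore.cox_fit(ind, time, event, names=["high_risk"])
    lo, hi = fit.conf_int()
    lr = survcore.logrank_test([
        (time[ind == 1], event[ind == 1]),
        (time[ind == 0], event[ind == 0]),
    ])
    return HazardRatioResult(
        hazard_ratio=float(fit.hazard_ratio[0]),
        ci_low=float(lo[0]),
        ci_high=float(hi[0]),
        p_cox=float(fit.p[0]),
        p_logrank=lr.p_value,
        n_high=n_high,
        n_low=n_low,
    )
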