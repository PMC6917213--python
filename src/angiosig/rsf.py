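"""Prognostic signature construction with a random survival forest.

The model-building procedure:

1. :func:`build_features` — for every candidate gene, a continuous
   expression feature and a binary copy dichotomized at the across-samples
   median (``GENE_D``, 1 iff expression strictly above the median), plus
   patient age and ordinal tumor stage (missing stage imputed with the
   cohort median);
2. :func:`univariate_filter` — per-feature univariate Cox models; features
   with p < alpha are kept and ranked by ascending p (age and stage are
   always offered to the ranking, appended if not retained on their own);
3. :func:`grow_forest` — a random survival forest with log-rank splitting
   and Nelson–Aalen terminal estimators; out-of-bag error is
   1 − Harrell's C of ensemble OOB mortality;
4. :func:`forward_select` — forests on the top-k ranked features for
   k = 1..K; the prefix with minimum OOB error wins (ties → smallest k);
5. :func:`stratify_risk` — three-tier calls from the predicted survival
   curve: low if S(15 y) > 0.5, else intermediate if S(7.5 y) > 0.5,
   else high.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import survcore
from ._rsf_kernel import grow_tree, predict_tree_chf
from .errors import ConfigurationError, EstimationError, InputError
from .survcore import StepFunction

__all__ = [
    "build_features",
    "FeatureInfo",
    "univariate_filter",
    "ForestConfig",
    "SurvivalForest",
    "grow_forest",
    "forward_select",
    "ForwardSelectResult",
    "predict_survival",
    "stratify_risk",
    "stratify_cohort",
    "RiskCall",
    "RISK_CLASSES",
]

RISK_CLASSES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class FeatureInfo:
    """Dichotomization cutoffs and stage imputation used to build features."""

    medians: pd.Series
    stage_fill: float
    stage_filled: Tuple[str, ...]

    def to_dict(self) -> dict:
        return {"medians": {k: float(v) for k, v in self.medians.items()},
                "stage_fill": float(self.stage_fill)}

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureInfo":
        return cls(medians=pd.Series(doc["medians"], dtype=float),
                   stage_fill=float(doc["stage_fill"]), stage_filled=())


def build_features(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: Sequence[str],
    info: Optional[FeatureInfo] = None,
) -> Tuple[pd.DataFrame, FeatureInfo]:
    """Patients × features table: continuous + median-dichotomized copies.

    ``expr`` is genes × patients; ``clinical`` must carry ``age`` and
    ``stage`` (NaN allowed) indexed by patient.  Binary copies are 1 iff
    expression is strictly above the median (ties to 0).  Pass the
    ``info`` returned from a training cohort to reuse its cutoffs and
    stage fill on new patients.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise InputError(f"genes absent from expression: {missing[:5]}")
    patients = list(expr.columns)
    if not set(patients).issubset(clinical.index):
        raise InputError("clinical table must cover every expression column")
    clin = clinical.loc[patients]

    sub = expr.loc[list(genes)]
    if info is None:
        medians = sub.median(axis=1)
        stage = clin["stage"]
        stage_fill = float(stage.median()) if stage.notna().any() else 0.0
        filled = tuple(stage.index[stage.isna()])
        info = FeatureInfo(medians=medians, stage_fill=stage_fill, stage_filled=filled)
    else:
        medians = info.medians.reindex(list(genes))
        if medians.isna().any():
            raise InputError("supplied FeatureInfo lacks medians for some genes")
        stage = clin["stage"]
        filled = tuple(stage.index[stage.isna()])
        info = FeatureInfo(medians=medians, stage_fill=info.stage_fill,
                           stage_filled=filled)

    cont = sub.T
    binary = (sub.gt(medians, axis=0)).astype(float).T
    binary.columns = [f"{g}_D" for g in genes]
    feats = pd.concat([cont, binary], axis=1)
    feats["age"] = clin["age"].to_numpy(float)
    feats["stage"] = clin["stage"].fillna(info.stage_fill).to_numpy(float)
    return feats, info


def univariate_filter(
    features: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    always_keep: Sequence[str] = ("age", "stage"),
) -> pd.DataFrame:
    """Univariate Cox screen: retained features ranked by ascending p.

    Features in ``always_keep`` are appended (in order) even when their
    own p ≥ alpha, so clinical covariates are always offered to forward
    selection.  Constant features are skipped.  Raises
    :class:`EstimationError` if nothing survives.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    if event.sum() == 0:
        raise EstimationError("univariate filter needs at least one event")
    pvals = {}
    for col in features.columns:
        x = features[col].to_numpy(float)
        if np.std(x) == 0 or not np.all(np.isfinite(x)):
            continue
        try:
            fit = survcore.cox_fit(x, time, event, names=[col])
        except EstimationError:
            continue
        pvals[col] = float(fit.p[0])
    ranked = sorted((c for c in pvals if pvals[c] < alpha), key=lambda c: pvals[c])
    for c in always_keep:
        if c in features.columns and c not in ranked:
            ranked.append(c)
    if not ranked:
        raise EstimationError("no feature passed the univariate filter")
    return pd.DataFrame(
        {"feature": ranked, "p": [pvals.get(c, np.nan) for c in ranked]}
    )


@dataclass(frozen=True)
class ForestConfig:
    """Random-survival-forest hyperparameters.

    ``mtry=None`` means ceil(sqrt(p)).  ``n_split=0`` scans every midpoint
    of distinct feature values; a positive value randomly subsamples that
    many candidate thresholds per feature (cheaper at cohort scale).
    ``grid_size`` caps the shared time grid (quantiles of event times).
    """

    ntree: int = 1000
    mtry: Optional[int] = None
    min_node_events: int = 3
    n_split: int = 0
    grid_size: int = 128
    horizons: Tuple[float, float] = (15.0, 7.5)

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return max(1, min(self.mtry, p))
        return max(1, math.ceil(math.sqrt(p)))


class SurvivalForest:
    """Ensemble of survival trees with log-rank splits and OOB error.

    Built by :func:`grow_forest`; predictions come from the ensemble mean
    cumulative hazard on the shared time grid, mortality is the sum of the
    CHF over the grid, and ``oob_error_`` is 1 − C of OOB mortality.
    """

    def __init__(self, feature_names, grid, trees, inbag_counts, config, seed,
                 oob_error, meta=None):
        self.feature_names = list(feature_names)
        self.grid = np.asarray(grid, float)
        self.trees = trees  # list of tuples (feat, thr, left, right, leaf_slot, leaf_chf)
        self.inbag_counts = inbag_counts  # (ntree, n_train) int matrix
        self.config = config
        self.seed = seed
        self.oob_error_ = oob_error
        #: free-form metadata serialized with the model (e.g. the
        #: dichotomization medians needed to rebuild features elsewhere)
        self.meta = dict(meta or {})

    # -- prediction -----------------------------------------------------
    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise InputError(f"features missing columns: {missing[:5]}")
            X = features[self.feature_names].to_numpy(float)
        else:
            X = np.asarray(features, float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_names):
                raise InputError("feature matrix does not match training schema")
        if not np.all(np.isfinite(X)):
            raise InputError("features must be finite")
        return np.ascontiguousarray(X)

    def predict_chf(self, features) -> np.ndarray:
        """Ensemble mean cumulative hazard, one row per patient."""
        X = self._matrix(features)
        out = np.zeros((X.shape[0], self.grid.size))
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            predict_tree_chf(X, *tree, rows, out)
        return out / len(self.trees)

    def predict_mortality(self, features) -> np.ndarray:
        """Ensemble mortality: CHF summed over the grid (higher = worse)."""
        return self.predict_chf(features).sum(axis=1)

    def predict_survival(self, features) -> List[StepFunction]:
        """Per-patient survival step functions S(t) = exp(−CHF(t))."""
        chf = self.predict_chf(features)
        return [StepFunction(self.grid, np.exp(-row), y_before=1.0) for row in chf]

    # -- serialization --------------------------------------------------
    def to_json(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "grid": self.grid.tolist(),
            "meta": self.meta,
            "seed": int(self.seed),
            "oob_error": None if self.oob_error_ is None or np.isnan(self.oob_error_)
            else float(self.oob_error_),
            "config": {
                "ntree": self.config.ntree,
                "mtry": self.config.mtry,
                "min_node_events": self.config.min_node_events,
                "n_split": self.config.n_split,
                "grid_size": self.config.grid_size,
                "horizons": list(self.config.horizons),
            },
            "trees": [
                {
                    "feat": t[0].tolist(),
                    "thr": t[1].tolist(),
                    "left": t[2].tolist(),
                    "right": t[3].tolist(),
                    "leaf_slot": t[4].tolist(),
                    "leaf_chf": t[5].tolist(),
                }
                for t in self.trees
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def from_json(cls, doc: dict) -> "SurvivalForest":
        cfgd = doc["config"]
        config = ForestConfig(
            ntree=cfgd["ntree"], mtry=cfgd["mtry"],
            min_node_events=cfgd["min_node_events"], n_split=cfgd["n_split"],
            grid_size=cfgd["grid_size"], horizons=tuple(cfgd["horizons"]),
        )
        trees = [
            (
                np.asarray(t["feat"], np.int64),
                np.asarray(t["thr"], float),
                np.asarray(t["left"], np.int64),
                np.asarray(t["right"], np.int64),
                np.asarray(t["leaf_slot"], np.int64),
                np.asarray(t["leaf_chf"], float),
            )
            for t in doc["trees"]
        ]
        oob = doc.get("oob_error")
        return cls(
            feature_names=doc["feature_names"],
            grid=np.asarray(doc["grid"], float),
            trees=trees,
            inbag_counts=None,
            config=config,
            seed=doc["seed"],
            oob_error=float("nan") if oob is None else float(oob),
            meta=doc.get("meta"),
        )

    @classmethod
    def load(cls, path) -> "SurvivalForest":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _time_grid(time, event, config: ForestConfig) -> np.ndarray:
    etimes = np.unique(np.asarray(time, float)[np.asarray(event) == 1])
    if etimes.size > config.grid_size:
        qs = np.linspace(0.0, 1.0, config.grid_size)
        etimes = np.unique(np.quantile(etimes, qs))
    horizons = [h for h in config.horizons if h > 0]
    return np.unique(np.concatenate([etimes, np.asarray(horizons, float)]))


def grow_forest(
    features: pd.DataFrame,
    time,
    event,
    config: Optional[ForestConfig] = None,
    seed: int = 0,
) -> SurvivalForest:
    """Grow a random survival forest; deterministic under ``seed``.

    Per tree: bootstrap with replacement; log-rank splitting over ``mtry``
    features drawn without replacement per node; Nelson–Aalen terminal
    estimators on a shared grid of event-time quantiles.  ``oob_error_``
    is 1 − C of the ensemble OOB mortality (NaN when no patient has an
    out-of-bag prediction).
    """
    config = config or ForestConfig()
    time = np.asarray(time, float)
    event = np.asarray(event).astype(np.int8)
    n, p = features.shape
    if p < 1:
        raise InputError("forest needs at least one feature")
    if event.sum() == 0:
        raise InputError("forest needs at least one event")
    if int(event.sum()) < config.min_node_events:
        raise InputError("fewer events than min_node_events")
    X = np.ascontiguousarray(features.to_numpy(float))
    if not np.all(np.isfinite(X)):
        raise InputError("features must be finite")
    grid = _time_grid(time, event, config)
    mtry = config.resolve_mtry(p)

    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=config.ntree)
    trees = []
    inbag = np.zeros((config.ntree, n), dtype=np.int32)
    oob_chf = np.zeros((n, grid.size))
    oob_ntrees = np.zeros(n, dtype=np.int64)
    for b in range(config.ntree):
        boot = rng.integers(0, n, size=n)
        np.add.at(inbag[b], boot, 1)
        Xb = np.ascontiguousarray(X[boot])
        tb = time[boot]
        db = event[boot]
        tree = grow_tree(Xb, tb, db, mtry, config.min_node_events,
                         config.n_split, grid, int(tree_seeds[b]))
        trees.append(tree)
        oob_rows = np.flatnonzero(inbag[b] == 0)
        if oob_rows.size:
            predict_tree_chf(X, *tree, oob_rows, oob_chf)
            oob_ntrees[oob_rows] += 1

    usable = oob_ntrees > 0
    if usable.sum() >= 2 and event[usable].sum() > 0:
        mortality = (oob_chf[usable] / oob_ntrees[usable, None]).sum(axis=1)
        c = survcore.concordance_index(mortality, time[usable], event[usable])
        oob_error = float("nan") if np.isnan(c) else 1.0 - c
    else:
        oob_error = float("nan")
    return SurvivalForest(
        feature_names=features.columns,
        grid=grid,
        trees=trees,
        inbag_counts=inbag,
        config=config,
        seed=seed,
        oob_error=oob_error,
    )


@dataclass(frozen=True)
class ForwardSelectResult:
    chosen: Tuple[str, ...]
    trace: pd.DataFrame  # columns: k, feature_added, oob_error
    forest: SurvivalForest


def forward_select(
    ranked: Sequence[str],
    features: pd.DataFrame,
    time,
    event,
    config: Optional[ForestConfig] = None,
    seed: int = 0,
) -> ForwardSelectResult:
    """Forward selection over a p-value-ranked feature list.

    Grows a forest on the top-k prefix for k = 1..K, records its OOB
    error, and returns the prefix with the minimum error (ties broken
    toward the smallest k) together with that forest and the error trace.
    """
    ranked = list(ranked)
    if not ranked:
        raise InputError("ranked feature list is empty")
    missing = [f for f in ranked if f not in features.columns]
    if missing:
        raise InputError(f"ranked features absent from table: {missing[:5]}")
    config = config or ForestConfig()
    rows = []
    best_err = np.inf
    best_k = 0
    best_forest = None
    for k in range(1, len(ranked) + 1):
        forest = grow_forest(features[ranked[:k]], time, event, config=config,
                             seed=seed + k)
        err = forest.oob_error_
        rows.append({"k": k, "feature_added": ranked[k - 1], "oob_error": err})
        if np.isfinite(err) and err < best_err:
            best_err = err
            best_k = k
            best_forest = forest
    if best_forest is None:
        raise EstimationError("no forest produced a finite OOB error")
    return ForwardSelectResult(
        chosen=tuple(ranked[:best_k]),
        trace=pd.DataFrame(rows),
        forest=best_forest,
    )


def predict_survival(forest: SurvivalForest, features) -> List[StepFunction]:
    """Per-patient predicted survival curves (see SurvivalForest)."""
    return forest.predict_survival(features)


@dataclass(frozen=True)
class RiskCall:
    risk_class: str
    s_long: float   # predicted S at the long horizon (15 y)
    s_short: float  # predicted S at the short horizon (7.5 y)


def stratify_risk(
    surv: StepFunction,
    horizons: Tuple[float, float] = (15.0, 7.5),
    cutoff: float = 0.5,
) -> RiskCall:
    """Sequential three-tier risk rule on a predicted survival curve.

    low if S(long) > cutoff; else intermediate if S(short) > cutoff; else
    high.  The curve is extended as constant beyond its last knot (the
    natural extension of the Nelson–Aalen estimator).
    """
    long_h, short_h = horizons
    if short_h >= long_h:
        raise ConfigurationError("short horizon must precede long horizon")
    s_long = float(surv(long_h))
    s_short = float(surv(short_h))
    if s_long > cutoff:
        cls = "low"
    elif s_short > cutoff:
        cls = "intermediate"
    else:
        cls = "high"
    return RiskCall(risk_class=cls, s_long=s_long, s_short=s_short)


def stratify_cohort(
    forest: SurvivalForest,
    features,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Risk class and horizon survival probabilities per patient."""
    curves = forest.predict_survival(features)
    horizons = forest.config.horizons
    index = features.index if isinstance(features, pd.DataFrame) else None
    rows = [stratify_risk(s, horizons=horizons, cutoff=cutoff) for s in curves]
    return pd.DataFrame(
        {
            "risk_class": [r.risk_class for r in rows],
            f"S_{horizons[0]:g}y": [r.s_long for r in rows],
            f"S_{horizons[1]:g}y": [r.s_short for r in rows],
        },
        index=index,
    )
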