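"""Synthetic study inputs with known ground truth.

Generators for every input the signature pipeline consumes:

* :func:`gen_counts` — negative-binomial RNA-seq counts from a retinal
  angiogenesis time course (normal vs oxygen-induced retinopathy, stages
  P12–P17) with planted differentially expressed genes;
* :func:`gen_cohort` — a breast-cancer-like survival cohort (normalized
  expression, age, ordinal tumor stage with missingness, PAM50-like
  subtype labels, Weibull survival with a log-linear hazard, independent
  censoring, 15-year truncation, disjoint train/validation split);
* :func:`gen_homology` — a mouse→human homology table with a requested
  unmapped / one-to-one / multi-mapping structure;
* :func:`gen_signatures` — gene signatures with requested sizes, pairwise
  overlaps and ±1 direction weights.

All generators are deterministic given their config seed.  Defaults mirror
the emulated study design: 21,390 active genes in 14 retina samples
(7 condition/stage groups × 2 replicates) with 153 planted DE genes, and a
1,988-patient cohort split 996 / 992 with survival truncated at 15 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .signatures import GeneSignature

__all__ = [
    "RetinaSimConfig",
    "CohortSimConfig",
    "HomologySpec",
    "Cohort",
    "gen_counts",
    "gen_cohort",
    "gen_homology",
    "gen_signatures",
]

#: condition/stage groups of the emulated retina time course.  "normal"
#: retinas at P12/P15/P17 develop physiologically; "OIR" retinas leave the
#: 75% oxygen chamber at P12 and undergo hypoxia-driven pathological
#: angiogenesis peaking at P17 (P12.5 = 12 h after return to room air).
DEFAULT_CONDITIONS: Tuple[Tuple[str, str], ...] = (
    ("normal", "P12"),
    ("normal", "P15"),
    ("normal", "P17"),
    ("OIR", "P12"),
    ("OIR", "P12.5"),
    ("OIR", "P15"),
    ("OIR", "P17"),
)


@dataclass(frozen=True)
class RetinaSimConfig:
    """Negative-binomial count simulation for the retina time course.

    ``lfc_magnitude`` is the absolute expected log2 fold change planted in
    OIR samples for the DE genes (random sign per gene); ``dispersion`` is
    the NB dispersion alpha in Var = mu + alpha * mu^2.
    """

    n_genes: int = 21390
    n_samples_per_group: int = 2
    conditions: Tuple[Tuple[str, str], ...] = DEFAULT_CONDITIONS
    n_de_genes: int = 153
    lfc_magnitude: float = 2.5
    dispersion: float = 0.05
    baseline_mean: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_de_genes > self.n_genes:
            raise ConfigurationError("n_de_genes cannot exceed n_genes")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")
        if self.n_samples_per_group < 1:
            raise ConfigurationError("need at least one sample per group")


def gen_counts(cfg: RetinaSimConfig):
    """Simulate a gene × sample count matrix with planted DE genes.

    Returns ``(counts, meta, truth)``: counts is a DataFrame (genes in
    rows, samples in columns), meta has one row per sample (sample,
    condition, stage, replicate), truth lists the planted genes with their
    signed log2 fold change (OIR vs normal).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"mGene{i:05d}" for i in range(cfg.n_genes)])
    samples, cond_labels = [], []
    for cond, stage in cfg.conditions:
        for r in range(1, cfg.n_samples_per_group + 1):
            samples.append(f"{cond}_{stage}_r{r}")
            cond_labels.append((cond, stage, r))
    meta = pd.DataFrame(
        cond_labels, columns=["condition", "stage", "replicate"],
        index=pd.Index(samples, name="sample"),
    )

    base_mu = rng.lognormal(mean=np.log(cfg.baseline_mean), sigma=1.0, size=cfg.n_genes)
    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de_genes)
    lfc = np.zeros(cfg.n_genes)
    lfc[de_idx] = signs * cfg.lfc_magnitude

    is_oir = (meta["condition"] == "OIR").to_numpy()
    mu = np.tile(base_mu[:, None], (1, len(samples)))
    mu[:, is_oir] *= 2.0 ** lfc[:, None]

    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    truth = pd.DataFrame({"gene": genes[de_idx], "lfc": lfc[de_idx]}).sort_values("gene")
    truth = truth.reset_index(drop=True)
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# survival cohort


#: ordinal tumor-stage distribution and PAM50-like subtype mix, matching the
#: clinical profile of the emulated training cohort.
STAGE_PROBS = (0.001, 0.339, 0.574, 0.076, 0.010)
SUBTYPES = ("Basal", "HER2", "LumA", "LumB", "Normal")
SUBTYPE_PROBS = (0.118, 0.086, 0.468, 0.269, 0.059)


@dataclass(frozen=True)
class CohortSimConfig:
    """Breast-cancer-like cohort with Weibull survival.

    Expression is generated directly on a normalized continuous scale
    (per-gene standard normal across patients).  The hazard is
    ``h0(t) * exp(sum(beta_g * x_g) + age_effect*(age-62) +
    stage_effect*(stage-2))`` with a Weibull baseline
    ``H0(t) = (t / baseline_scale) ** baseline_shape``.  Censoring is
    independent uniform on (0, truncate_years], thinned so the realized
    censored fraction approaches ``censor_rate``; event times past the
    horizon become censored at the horizon.
    """

    n_patients: int = 1988
    n_genes: int = 146
    prognostic_genes: Tuple[Tuple[str, float], ...] = ()
    age_effect: float = 0.02
    stage_effect: float = 0.3
    baseline_scale: float = 12.0
    baseline_shape: float = 1.2
    censor_rate: float = 0.3
    truncate_years: float = 15.0
    train_fraction: float = 996.0 / 1988.0
    stage_missing: float = 0.07
    genes: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        if self.truncate_years <= 0:
            raise ConfigurationError("truncate_years must be > 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.genes is not None and len(self.genes) != self.n_genes:
            raise ConfigurationError("genes list must have n_genes entries")
        names = self.genes if self.genes is not None else tuple(
            f"HGENE{i:04d}" for i in range(self.n_genes)
        )
        unknown = [g for g, _ in self.prognostic_genes if g not in names]
        if unknown:
            raise ConfigurationError(f"prognostic genes not in universe: {unknown}")

    @property
    def gene_names(self) -> Tuple[str, ...]:
        if self.genes is not None:
            return tuple(self.genes)
        return tuple(f"HGENE{i:04d}" for i in range(self.n_genes))


@dataclass(frozen=True)
class Cohort:
    """Expression (genes × patients) plus aligned clinical outcomes."""

    expr: pd.DataFrame
    clinical: pd.DataFrame  # index: patient; age, stage, subtype, time_years, event

    @property
    def patients(self):
        return self.clinical.index

    @property
    def time(self) -> np.ndarray:
        return self.clinical["time_years"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(int)


def gen_cohort(cfg: CohortSimConfig):
    """Simulate train/validation cohorts with planted prognostic genes.

    Returns ``(train, validation, truth)``; the split is disjoint and
    honors ``train_fraction``.  ``truth`` records the planted log-hazard
    coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    genes = list(cfg.gene_names)
    patients = [f"PT{i:05d}" for i in range(n)]

    expr = rng.standard_normal((cfg.n_genes, n))
    age = np.clip(rng.normal(61.5, 12.5, size=n), 25.0, 95.0)
    stage = rng.choice(np.arange(5), size=n, p=STAGE_PROBS).astype(float)
    subtype = rng.choice(SUBTYPES, size=n, p=SUBTYPE_PROBS)

    linpred = cfg.age_effect * (age - 62.0) + cfg.stage_effect * (stage - 2.0)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, beta in cfg.prognostic_genes:
        linpred = linpred + beta * expr[gene_pos[g]]

    # inverse-transform sampling from the Weibull proportional-hazards model
    u = rng.uniform(size=n)
    t_event = cfg.baseline_scale * (-np.log(u) / np.exp(linpred)) ** (1.0 / cfg.baseline_shape)

    # censoring: uniform on (0, horizon], thinned toward censor_rate
    c_all = rng.uniform(0.0, cfg.truncate_years, size=n)
    c_all[c_all == 0.0] = cfg.truncate_years
    censor_time = np.full(n, np.inf)
    would = np.flatnonzero(c_all < t_event)
    target = int(round(cfg.censor_rate * n))
    keep = would if would.size <= target else rng.choice(would, size=target, replace=False)
    censor_time[keep] = c_all[keep]

    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)
    over = time > cfg.truncate_years
    time[over] = cfg.truncate_years
    event[over] = 0

    stage_obs = stage.copy()
    missing = rng.uniform(size=n) < cfg.stage_missing
    stage_obs[missing] = np.nan

    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=patients)
    clin = pd.DataFrame(
        {
            "age": age,
            "stage": stage_obs,
            "subtype": subtype,
            "time_years": time,
            "event": event,
        },
        index=pd.Index(patients, name="patient"),
    )

    order = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train_ids = [patients[i] for i in sorted(order[:n_train])]
    valid_ids = [patients[i] for i in sorted(order[n_train:])]
    train = Cohort(expr_df[train_ids], clin.loc[train_ids])
    valid = Cohort(expr_df[valid_ids], clin.loc[valid_ids])
    truth = {
        "prognostic_genes": dict(cfg.prognostic_genes),
        "age_effect": cfg.age_effect,
        "stage_effect": cfg.stage_effect,
    }
    return train, valid, truth


# ---------------------------------------------------------------------------
# homology tables


@dataclass(frozen=True)
class HomologySpec:
    """Structure of a mouse→human homology table.

    ``multi_fanouts[i]`` is the number of distinct human partners of the
    i-th multi-mapping mouse gene; ``shared_pairs`` mouse-gene pairs map to
    a single shared human gene each.
    """

    n_unmapped: int = 10
    n_one_to_one: int = 140
    multi_fanouts: Tuple[int, ...] = (3, 3, 3)
    shared_pairs: int = 0
    mouse_genes: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_unmapped < 0 or self.n_one_to_one < 0 or self.shared_pairs < 0:
            raise ConfigurationError("counts must be non-negative")
        if any(f < 2 for f in self.multi_fanouts):
            raise ConfigurationError("multi-mapping fan-outs must be >= 2")
        if self.mouse_genes is not None and len(self.mouse_genes) != self.n_mouse:
            raise ConfigurationError(
                f"mouse_genes must list exactly {self.n_mouse} genes"
            )

    @property
    def n_mouse(self) -> int:
        return (self.n_unmapped + self.n_one_to_one + len(self.multi_fanouts)
                + 2 * self.shared_pairs)


def gen_homology(spec: HomologySpec) -> pd.DataFrame:
    """Build a homology table realizing exactly the requested structure.

    Returns a DataFrame with columns ``mouse_gene`` and ``human_gene``;
    an unmapped mouse gene appears once with a missing human partner.
    """
    if spec.mouse_genes is not None:
        mouse = list(spec.mouse_genes)
    else:
        mouse = [f"mGene{i:05d}" for i in range(spec.n_mouse)]
    rng = np.random.default_rng(spec.seed)
    mouse = [mouse[i] for i in rng.permutation(len(mouse))]

    rows = []
    it = iter(mouse)
    hid = 0

    def next_human():
        nonlocal hid
        hid += 1
        return f"HOM{hid:04d}"

    for _ in range(spec.n_unmapped):
        rows.append((next(it), pd.NA))
    for _ in range(spec.n_one_to_one):
        rows.append((next(it), next_human()))
    for fanout in spec.multi_fanouts:
        m = next(it)
        for _ in range(fanout):
            rows.append((m, next_human()))
    for _ in range(spec.shared_pairs):
        h = next_human()
        rows.append((next(it), h))
        rows.append((next(it), h))
    return pd.DataFrame(rows, columns=["mouse_gene", "human_gene"])


# ---------------------------------------------------------------------------
# gene signatures


def gen_signatures(
    sizes: Sequence[int],
    universe: Sequence[str],
    overlaps: Optional[Mapping[Tuple[int, int], int]] = None,
    down_fraction: float = 0.0,
    tags: Optional[Sequence[str]] = None,
    names: Optional[Sequence[str]] = None,
    seed: int = 0,
):
    """Draw signatures from ``universe`` with exact sizes and pairwise overlaps.

    ``overlaps[(i, j)]`` requests that signatures i and j share exactly
    that many genes; unconstrained pairs may overlap freely.
    ``down_fraction`` of each signature's genes receive weight −1 (the
    rest +1).  Raises :class:`ConfigurationError` on infeasible demands.
    """
    universe = list(dict.fromkeys(universe))
    rng = np.random.default_rng(seed)
    k = len(sizes)
    overlaps = {tuple(sorted(key)): v for key, v in (overlaps or {}).items()}
    if any(s > len(universe) for s in sizes):
        raise ConfigurationError("requested size exceeds universe")
    for (i, j), c in overlaps.items():
        if not (0 <= i < k and 0 <= j < k and i != j):
            raise ConfigurationError(f"overlap key {(i, j)} out of range")
        if c > min(sizes[i], sizes[j]):
            raise ConfigurationError(f"overlap {c} exceeds signature sizes for {(i, j)}")

    members = [set() for _ in range(k)]
    pool = list(universe)
    rng.shuffle(pool)
    cursor = 0

    def take(m):
        nonlocal cursor
        if cursor + m > len(pool):
            raise ConfigurationError("universe too small for requested overlap structure")
        out = pool[cursor:cursor + m]
        cursor += m
        return out

    # phase 1: dedicated shared genes per constrained pair
    for (i, j), c in overlaps.items():
        shared = take(c)
        members[i].update(shared)
        members[j].update(shared)
    # phase 2: fill each signature, avoiding genes held by constrained partners
    for i in range(k):
        if len(members[i]) > sizes[i]:
            raise ConfigurationError(f"overlap demands exceed size of signature {i}")
        partners = {j for (a, b) in overlaps for j in (a, b) if i in (a, b) and j != i}
        forbidden = set().union(*(members[j] for j in partners)) if partners else set()
        candidates = [g for g in universe if g not in members[i] and g not in forbidden]
        need = sizes[i] - len(members[i])
        if need > len(candidates):
            raise ConfigurationError(f"cannot fill signature {i} to size {sizes[i]}")
        pick = rng.choice(len(candidates), size=need, replace=False)
        members[i].update(candidates[p] for p in pick)

    out = []
    for i in range(k):
        genes = sorted(members[i])
        n_down = int(round(down_fraction * len(genes)))
        down = set(rng.choice(len(genes), size=n_down, replace=False)) if n_down else set()
        weighted = tuple((g, -1 if gi in down else 1) for gi, g in enumerate(genes))
        out.append(
            GeneSignature(
                name=names[i] if names else f"Sig{i + 1:02d}",
                members=weighted,
                tag=tags[i] if tags else None,
            )
        )
    return out
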