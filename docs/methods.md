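# Methods

This note documents the models, estimators and design choices behind
`angiosig`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Differential expression (`counts_de`)

Counts are normalized with median-of-ratios size factors: for sample *s*,
the factor is the median over genes expressed in every sample of
count(g,s) divided by gene *g*'s geometric mean. Genes with fewer than 10
reads in fewer than 2 samples fail the activity filter; they are reported
with undefined p/q and excluded from the multiple-testing family
(independent filtering), so selection counts are reproducible.

The test itself is a transparent negative-binomial Wald test. Per gene,
dispersion α in Var = μ + αμ² is estimated by method of moments from the
pooled within-group variance of normalized counts (truncated at 0). The
effect is the log₂ ratio of group means with a pseudo-count of 0.5; its
variance comes from the delta method, Var(log₂(m̄+½)) ≈
(μ + αμ²)/(n (μ+½)² ln²2) summed over the two groups. The Wald statistic
is referred to a **Student t with n₁+n₂−2 degrees of freedom** rather
than a normal: the moment dispersion estimate is itself noisy at the
n ≈ 8-per-group design this pipeline targets, and the t reference keeps
the type-I rate at the nominal 5% where a normal reference is measurably
anti-conservative. No shrinkage, covariates or multi-factor designs are
attempted — the pipeline's contribution is the thresholding and the
downstream use of the list, not the DE engine.

Selection applies |log₂FC| ≥ 2 (in at least one contrast, when several
are supplied) **and** p < 0.05 **and** BH q < 0.05. The fold-change
threshold is a single parameter; 2 is the default used for signature
construction (a 1.5-fold setting exists for landscape-style summaries).

The PCA summary filters to genes above a per-sample read floor
(default > 500 in all samples), ranks by variance, takes the top 500,
centers per gene and reports the first two components with their
explained-variance fractions.

## Homolog bookkeeping (`homology`)

Homology is consumed from static two-column tables (mouse_gene,
human_gene; empty = no homolog), never from live services, so analyses
are reproducible offline. `map_homologs` partitions the input into
unmapped / one-to-one / multi-mapped and returns the distinct union of
human partners in input order; paralogs are kept as independent genes
downstream (no averaging), which is why a 153-gene list with 10 unmapped
genes and three 3-way multi-mappers yields 143 mapped mouse genes and
149 human genes, and dropping 3 genes absent from the expression platform
leaves 146.

## Signature scoring (`signatures`)

A signature is a named gene set with per-gene weights in {+1, −1}. The
raw per-sample score is the weighted **sum of per-gene z-scores**
(expression standardized across samples); the aggregation (sum vs mean)
and the standardization are switchable, since published descriptions of
±1-weighted scoring rarely pin them down — z-scoring is the default
because it puts genes on a common scale and makes the ±1 weights
meaningful. Scores are mapped affinely onto [−1, +1] (degenerate constant
scores map to 0). Dichotomization matches the high-risk fraction to the
cohort's event fraction: the cutoff is the (1 − event fraction) score
quantile and samples strictly above it are called high risk. Consensus
over several signatures is a majority vote with ties called high risk
(the conservative side for a risk flag). Group prognostic value is a
univariate Cox hazard ratio of the high/low call with a 95% normal CI on
the log scale, plus a two-group log-rank p.

## Survival core (`survcore`)

Kaplan–Meier, Nelson–Aalen, the k-group log-rank test, the Cox model and
Harrell's C are provided by lifelines behind a thin, convention-fixing
surface; every estimator is verified in the test suite against an
independent brute-force oracle (direct product-limit accumulation,
observed-minus-expected log-rank with hypergeometric variance, generic
numerical maximization of the Efron partial likelihood, exhaustive pair
counting, and the defining BH formula). Conventions:

* Cox ties use the **Efron** correction — truncated year-scale survival
  data is tie-heavy — with the Newton solver run to tight precision so
  fits agree with the oracle optimum to ~1e-6; separation / monotone
  likelihood is converted into an estimation error.
* The log-rank p always comes from the χ² reference with k−1 df.
* The concordance index is oriented so higher risk ⇔ earlier event, and
  risk ties count ½; the forest's OOB error is 1 − C.
* Confidence intervals are 95% throughout.

## Random survival forest and signature construction (`rsf`)

**Features.** Each candidate gene contributes its continuous expression
and a binary copy (`GENE_D`) equal to 1 iff expression is strictly above
the across-samples median — values at the median go to 0, a deterministic
tie rule. Age (years) and ordinal tumor stage complete the table; missing
stage is imputed with the cohort median stage (and recorded per patient).
The pipeline computes dichotomization medians across all samples of the
dataset (training and validation pooled), and serialized models carry
their medians so predictions elsewhere reuse the training cutoffs. The
feature count is always derived from the inputs (2 × genes + 2).

**Screen.** Each feature gets a univariate Cox fit; features with
p < 0.05 are kept, ranked by ascending p. Age and stage are always
offered to the ranking stage even when their own p ≥ 0.05, because the
clinical covariates belong in the candidate model regardless of marginal
significance.

**Forest.** Trees are grown on bootstrap samples (with replacement, same
size). At each node, mtry = ⌈√p⌉ features (configurable) are drawn
without replacement; for each, candidate thresholds are the midpoints of
sorted distinct values (`n_split > 0` randomly subsamples that many
candidates — the knob used at cohort scale), and the split maximizing the
two-group log-rank statistic is taken. A split is admissible only if both
children receive ≥ `min_node_events` (default 3) events; nodes with fewer
than twice that many events become terminal, holding the Nelson–Aalen
cumulative hazard of their in-bag samples on a shared grid (event-time
quantiles capped at 128 knots, plus the two risk horizons). The ensemble
CHF is the mean over trees; S(t) = exp(−CHF(t)); mortality is the CHF
summed over the grid; OOB error is 1 − C of OOB mortality. The default
ntree is 1000 (error curves plateau well before that); tests and the
pipeline default to 100–200 trees, which sits on the same plateau at the
cohort sizes used here. All randomness flows from one seed; identical
seeds reproduce forests bit-for-bit. The split search runs in numba
kernels, which is what makes exhaustive threshold scans affordable.

**Forward selection.** For k = 1..K a forest is grown on the top-k ranked
features and its OOB error recorded; the prefix with minimum error wins,
ties going to the smallest k. Both representations of a gene (continuous
and `_D`) compete independently, so a final model may contain a gene
twice.

**Risk tiers.** From a predicted survival curve: low if S(15 y) > 0.5,
else intermediate if S(7.5 y) > 0.5, else high — 7.5 y being half the
truncation horizon; both horizons and the 0.5 cutoff are parameters. The
predicted curve is extended as a constant beyond its last knot (the
natural extension of a Nelson–Aalen step function), so horizon queries at
15 y are always defined for forests trained on 15-year-truncated data.

## Empirical null (`nulldist`)

Random feature sets are drawn uniformly without replacement, by default
10,000 per size for sizes 2–30 (290,000 sets); a fixed-size mode covers
the variant that permutes sets of exactly the chosen model's size. Each
set trains a forest (reduced to 100 trees in null mode — a documented
tractability knob), stratifies the validation cohort into the three risk
tiers, and records the k-group log-rank p (groups that fail to appear
reduce k; a single group records the placeholder p = 1) together with the
1 − OOB-error accuracy proxy (reported alongside, since "accuracy" for
such sweeps is ambiguous between OOB- and validation-based readings). The
percentile rank of a model is the fraction of null runs with p at least
as large, ties counting as larger. Desk-scale runs use reduced grids
(e.g. sizes 2–5, tens of sets per size); full scale is configuration, not
code. When checking calibration on effect-free cohorts, note that runs
sharing one cohort are positively dependent — uniformity checks should
pool several independent cohorts, and the placeholder p = 1 rows (no
stratification achieved) are bookkeeping, not p-value draws.

## Synthetic data (`syndata`)

`gen_counts` emulates the retina time course: 7 condition/stage groups
(normal P12/P15/P17; OIR P12/P12.5/P15/P17), two replicates per group by
default, 21,390 active genes, counts NB-distributed around log-normal
baseline means (default mean 50, dispersion 0.05), and 153 planted DE
genes at |log₂FC| = 2.5 with random sign applied to all OIR samples.
Power-style checks use more replicates per group, as two replicates
cannot identify single-gene effects.

`gen_cohort` emulates the breast-cancer cohort structure: 1,988 patients
split 996/992 by default, per-gene standard-normal expression (the
pipeline consumes normalized values; array-intensity preprocessing is out
of scope), age ≈ N(61.5, 12.5²) clipped to [25, 95], ordinal stage 0–4
with the observed stage mix and a configurable missing fraction (default
7%), and PAM50-like subtype labels. Survival follows a Weibull
proportional-hazards model, H(t) = (t/12)^1.2 · exp(β·x + 0.02·(age−62) +
0.3·(stage−2)) by default — scale and shape chosen so that median
survival sits near 9 years and roughly half the cohort experiences an
event within the 15-year horizon, matching the emulated cohort's
follow-up profile. Censoring is independent uniform on (0, 15], thinned
so the realized censored fraction approaches the configured rate
(default 0.3); event times beyond 15 years become censored at 15. What
this generator does **not** emulate: batch structure, probe-level noise,
correlated co-expression modules, non-proportional hazards, or informative
censoring — so green tests demonstrate the machinery's correctness and
statistical calibration, not robustness to those real-data features.

`gen_homology` realizes an exact unmapped / one-to-one / multi-mapping
structure; `gen_signatures` draws gene sets with exact sizes and exact
pairwise overlaps where requested (unconstrained pairs fill freely).

## Numerical and design notes

* Dichotomization ties go to 0; consensus ties go to high risk;
  forward-selection ties go to the smallest model — all deterministic.
* BH is statsmodels' step-up; PCA is scikit-learn's exact SVD.
* The forest's split statistic uses the hypergeometric variance with the
  (n−d)/(n−1) tie factor; thresholds are scanned exhaustively by default
  and subsampled (`n_split`, as in reference survival-forest
  implementations) at cohort scale.
* Stage seeds in the pipeline are derived from the master seed by hashing
  the stage name, so one integer reproduces a whole run; artifacts carry
  sha256 digests and unchanged stages are skipped on rerun.
* Desk-scale problem sizes used by the test suite (hundreds to a couple
  thousand patients, tens to ~150 genes, 50–100 trees, tens of null sets
  per size) were chosen so the full statistical battery — end-to-end risk
  separation, feature recovery across ten seeds, type-I and uniformity
  calibration — runs comfortably on a single CPU.

## Known limitations

* The DE engine is deliberately simple; it does not reproduce
  shrinkage-based DE tools numerically.
* No time-varying covariates, stratified or frailty survival models, and
  no competing risks.
* Forest variable importance is limited to the forward-selection error
  trace.
* The three-tier rule can produce empty tiers on weakly prognostic
  models; downstream tests then fall back to fewer groups (recorded per
  run).
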