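# angiosig

Prognostic gene signatures of pathological angiogenesis, built as a
tested, reusable pipeline.

## The problem

Genes that drive *pathological* angiogenesis — hypoxia- and VEGF-driven
vessel growth, as in tumors and proliferative retinopathies — differ from
those of normal vascular development. One way to isolate them is the
oxygen-induced retinopathy (OIR) mouse model: pups kept in 75% O₂ from
postnatal day P7–P12 suffer retinal vaso-obliteration, and on return to
room air the hypoxic retina mounts a pathological angiogenic response
peaking at P17. Genes differentially expressed between OIR and normally
developing retinas are candidate markers of pathological angiogenesis,
and — because angiogenesis is a hallmark of cancer — a candidate
prognostic signature for angiogenesis-dependent tumors such as breast
cancer.

`angiosig` implements that whole chain of analysis for computational
biologists who want to study, stress-test or reuse it:

1. **Differential expression** (`angiosig.counts_de`) — median-of-ratios
   normalization, an activity filter (≥ 10 reads in ≥ 2 samples), a
   negative-binomial Wald test, Benjamini–Hochberg correction, and the
   selection rule |log₂FC| ≥ 2 with p < 0.05 and FDR < 0.05; plus a
   top-variance PCA summary.
2. **Homolog bookkeeping** (`angiosig.homology`) — mapping a mouse DE
   list through a static mouse→human homology table (unmapped /
   one-to-one / multi-mapping partition), an expression-platform filter,
   and overlap counts against published hypoxia/angiogenesis signatures.
3. **Signature scoring** (`angiosig.signatures`) — ±1-weighted gene sets
   (GMT I/O), per-sample scores normalized to [−1, 1], dichotomization at
   the event percentile, Cox hazard ratios, and majority-vote consensus.
4. **Survival statistics** (`angiosig.survcore`) — Kaplan–Meier,
   Nelson–Aalen, k-group log-rank, Cox proportional hazards with Efron
   tie handling, and Harrell's concordance index.
5. **Model building** (`angiosig.rsf`) — for each candidate gene a
   continuous and a median-dichotomized feature plus age and tumor stage;
   a univariate Cox screen (p < 0.05) ranking features; a from-scratch
   random survival forest (log-rank splitting, Nelson–Aalen terminal
   hazards, out-of-bag error = 1 − C); forward selection choosing the
   prefix with minimum OOB error; and three-tier risk calls — low if
   predicted S(15 y) > 0.5, else intermediate if S(7.5 y) > 0.5, else
   high.
6. **Empirical null** (`angiosig.nulldist`) — random feature sets (sizes
   2–30, 10,000 per size at full scale), a forest per set, validation
   log-rank p per set, and the percentile rank of a chosen model.
7. **Synthetic data** (`angiosig.syndata`) — generators with known ground
   truth for every input above: NB retina counts with planted fold
   changes, a breast-cancer-like survival cohort (Weibull hazards,
   censoring, 15-year truncation, ~1000/1000 train–validation split),
   homology tables and signature compendia.

Everything is driven either as a library or through the `angiosig` CLI
(`simulate`, `de`, `homolog`, `sigscore`, `train`, `predict`, `null`,
`report`, or `run` for the whole pipeline under one YAML config and one
master seed).

## Worked example

```sh
cat > demo.yaml <<EOF
seed: 17
stages: [simulate, de, homolog, train, evaluate, "null", report]
simulate:
  retina: {n_genes: 2000, n_samples_per_group: 8, n_de_genes: 60,
           lfc_magnitude: 2.5, dispersion: 0.02}
  cohort: {n_patients: 600, n_prognostic: 4, effect: 0.9, n_extra_genes: 20}
train: {ntree: 100, n_split: 10}
"null": {sizes: [2, 3, 4], per_size: 10}
EOF
angiosig run --config demo.yaml --outdir demo_out
cat demo_out/report.txt
```

which prints (about 20 s on one CPU):

```
angiosig run report
===================
validation patients: 299
  low          n=120   KM median: not reached
  intermediate n=62    KM median: 13.93 y
  high         n=117   KM median: 3.13 y
log-rank p (3 groups): 7.36e-26
chosen model OOB error: 0.214
chosen features: HMGENE00295, HMGENE00751, HMGENE00377, HMGENE01104
null sweep: 30 random sets; model superior to 100.00% of them
```

Reading this: the simulated retina experiment planted 60 DE genes; the DE
stage recovered them, the homolog stage mapped them to human gene names,
and the forest trained on the ~300-patient training half chose a 4-feature
model (here the four planted prognostic genes). Applied to the held-out
validation half, the three risk tiers separate sharply (log-rank
p ≈ 7×10⁻²⁶; the high-risk tier's median survival is 3.1 years while the
low-risk tier's median is beyond the 15-year truncation horizon), and the
model beats all 30 random signatures of comparable size.

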