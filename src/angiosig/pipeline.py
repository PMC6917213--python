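"""End-to-end orchestration: simulate → DE → homologs → train → evaluate → null.

A single YAML config with per-stage sections and one master seed drives
the whole run; per-stage seeds are derived deterministically from the
master seed and the stage name, so one number reproduces the study
analog.  Every artifact is a TSV/GMT/JSON text file; a manifest records
the config snapshot, stage seeds, artifact digests and timings, and
stages are skipped on rerun when their inputs and outputs are unchanged
(digest match).
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, counts_de, homology, nulldist, rsf, signatures, survcore, syndata
from .errors import ConfigurationError
from .rsf import ForestConfig

__all__ = ["run_pipeline", "load_config", "derive_seed", "report_text", "STAGES"]

STAGES = ("simulate", "de", "homolog", "sigscore", "train", "evaluate", "null", "report")
DEFAULT_STAGES = ("simulate", "de", "homolog", "train", "evaluate", "report")


def derive_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    if None in cfg:
        # a bare `null` YAML key parses as None
        cfg["null"] = cfg.pop(None)
    if "stages" in cfg:
        # likewise for a bare `null` in the stage list
        cfg["stages"] = ["null" if s is None else s for s in cfg["stages"]]
    unknown = set(cfg.get("stages", [])) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    return cfg


# ---------------------------------------------------------------------------
# tabular I/O helpers (TSV with headers throughout)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gene_list(path) -> List[str]:
    return [line.strip() for line in open(path) if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    sim = cfg.get("simulate", {})
    retina_kw = dict(sim.get("retina", {}))
    retina_kw.setdefault("n_genes", 4000)
    retina_kw.setdefault("n_samples_per_group", 8)
    retina_kw.setdefault("n_de_genes", 153)
    retina = syndata.RetinaSimConfig(seed=seed, **retina_kw)
    counts, meta, truth_de = syndata.gen_counts(retina)

    # homology over the full mouse universe, human names derived from the
    # mouse gene so the table is coherent with any downstream DE list
    rng = np.random.default_rng(seed + 1)
    frac_unmapped = float(sim.get("homology", {}).get("frac_unmapped", 0.065))
    frac_multi = float(sim.get("homology", {}).get("frac_multi", 0.02))
    fanout = int(sim.get("homology", {}).get("fanout", 3))
    rows = []
    u = rng.uniform(size=len(counts.index))
    for g, ug in zip(counts.index, u):
        if ug < frac_unmapped:
            rows.append((g, ""))
        elif ug < frac_unmapped + frac_multi:
            for j in range(1, fanout + 1):
                rows.append((g, f"H{g.upper()}_{j}"))
        else:
            rows.append((g, f"H{g.upper()}"))
    hom = pd.DataFrame(rows, columns=["mouse_gene", "human_gene"])

    # cohort gene universe: human partners of the planted DE genes, minus a
    # few genes "not arrayed", plus extra measured genes
    mapped = hom[hom["human_gene"] != ""]
    partners = mapped.groupby("mouse_gene")["human_gene"].apply(list).to_dict()
    de_humans: List[str] = []
    for g in truth_de["gene"]:
        de_humans.extend(partners.get(g, []))
    de_humans = list(dict.fromkeys(de_humans))
    n_drop = int(sim.get("cohort", {}).get("n_not_arrayed", 3))
    drop = set(rng.choice(de_humans, size=min(n_drop, max(len(de_humans) - 1, 0)),
                          replace=False))
    arrayed = [h for h in de_humans if h not in drop]
    n_extra = int(sim.get("cohort", {}).get("n_extra_genes", 50))
    other = [h for h in mapped["human_gene"].unique() if h not in de_humans]
    extra = list(rng.choice(other, size=min(n_extra, len(other)), replace=False))
    cohort_genes = arrayed + extra

    ck = dict(sim.get("cohort", {}))
    n_prog = int(ck.pop("n_prognostic", 5))
    effect = float(ck.pop("effect", 0.8))
    ck.pop("n_not_arrayed", None)
    ck.pop("n_extra_genes", None)
    prog = [
        (g, effect)
        for g in rng.choice(arrayed, size=min(n_prog, len(arrayed)), replace=False)
    ]
    cohort_cfg = syndata.CohortSimConfig(
        n_genes=len(cohort_genes),
        genes=tuple(cohort_genes),
        prognostic_genes=tuple(prog),
        seed=seed + 2,
        **ck,
    )
    train, valid, truth_cohort = syndata.gen_cohort(cohort_cfg)

    sig_kw = sim.get("signatures", {})
    sizes = sig_kw.get("sizes", [62, 34, 100, 43, 9, 2, 3, 110, 32])
    sizes = [min(s, len(cohort_genes)) for s in sizes]
    tags = sig_kw.get("tags", ["angiogenesis"] * len(sizes))
    sigs = syndata.gen_signatures(sizes, cohort_genes, tags=tags, seed=seed + 3)

    paths = {}

    def emit(name, writer):
        p = out / name
        writer(p)
        paths[name] = p

    emit("counts.tsv", lambda p: counts.to_csv(p, sep="\t", index_label="gene"))
    emit("meta.tsv", lambda p: meta.to_csv(p, sep="\t"))
    emit("truth_de.tsv", lambda p: truth_de.to_csv(p, sep="\t", index=False))
    emit("homology.tsv", lambda p: hom.to_csv(p, sep="\t", index=False))
    emit("platform.txt", lambda p: write_gene_list(cohort_genes, p))
    emit("train_expr.tsv", lambda p: train.expr.to_csv(p, sep="\t", index_label="gene"))
    emit("train_clin.tsv", lambda p: train.clinical.to_csv(p, sep="\t"))
    emit("valid_expr.tsv", lambda p: valid.expr.to_csv(p, sep="\t", index_label="gene"))
    emit("valid_clin.tsv", lambda p: valid.clinical.to_csv(p, sep="\t"))
    emit("signatures.gmt", lambda p: signatures.write_gmt(sigs, p))
    emit(
        "truth_cohort.json",
        lambda p: Path(p).write_text(json.dumps(truth_cohort, indent=1)),
    )
    return paths


def _stage_de(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    de_cfg = cfg.get("de", {})
    counts = read_table(out / "counts.tsv")
    meta = read_table(out / "meta.tsv")
    table = counts_de.de_test(
        counts,
        meta,
        baseline=de_cfg.get("baseline", "normal"),
        contrast=de_cfg.get("contrast", "OIR"),
    )
    selected = counts_de.select_de(
        table,
        lfc_thresh=float(de_cfg.get("lfc", 2.0)),
        q_thresh=float(de_cfg.get("fdr", 0.05)),
        p_thresh=float(de_cfg.get("p", 0.05)),
    )
    table = table.assign(selected=table.index.isin(selected).astype(int))
    write_table(table, out / "de_table.tsv", index_label="gene")
    write_gene_list(selected, out / "de_genes.txt")
    return {"de_table.tsv": out / "de_table.tsv", "de_genes.txt": out / "de_genes.txt"}


def _stage_homolog(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    genes = read_gene_list(out / "de_genes.txt")
    hom = homology.load_homology(out / "homology.tsv")
    platform = read_gene_list(out / "platform.txt")
    report = homology.map_homologs(genes, hom)
    retained, dropped = homology.platform_filter(report.human_genes, platform)
    write_gene_list(retained, out / "human_genes.txt")
    doc = {
        "n_input": report.n_input,
        "n_unmapped": report.n_unmapped,
        "n_one_to_one": report.n_one_to_one,
        "n_multi": report.n_multi,
        "n_mapped": report.n_mapped,
        "n_human": report.n_human,
        "n_on_platform": len(retained),
        "dropped": dropped,
    }
    (out / "homolog_report.json").write_text(json.dumps(doc, indent=1))
    return {
        "human_genes.txt": out / "human_genes.txt",
        "homolog_report.json": out / "homolog_report.json",
    }


def _stage_sigscore(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    sigs = signatures.read_gmt(out / "signatures.gmt")
    expr = pd.concat(
        [read_table(out / "train_expr.tsv"), read_table(out / "valid_expr.tsv")], axis=1
    )
    clin = pd.concat(
        [read_table(out / "train_clin.tsv"), read_table(out / "valid_clin.tsv")]
    )
    events = clin["event"].to_numpy(int)
    score_rows, call_cols, hr_rows = {}, {}, []
    for sig in sigs:
        raw = signatures.score_samples(sig, expr)
        norm = signatures.normalize_scores(raw)
        calls = signatures.dichotomize_by_event_percentile(norm, events)
        score_rows[sig.name] = norm
        call_cols[sig.name] = calls
        try:
            hr = signatures.group_hazard_ratio(
                calls, clin["time_years"].to_numpy(float), events
            )
            hr_rows.append(
                {
                    "signature": sig.name,
                    "hazard_ratio": hr.hazard_ratio,
                    "ci_low": hr.ci_low,
                    "ci_high": hr.ci_high,
                    "p_cox": hr.p_cox,
                    "p_logrank": hr.p_logrank,
                }
            )
        except Exception:
            hr_rows.append({"signature": sig.name, "hazard_ratio": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan,
                            "p_cox": np.nan, "p_logrank": np.nan})
    calls_df = pd.DataFrame(call_cols)
    consensus = signatures.consensus_call(calls_df)
    scores_df = pd.DataFrame(score_rows)
    scores_df["consensus"] = consensus
    write_table(scores_df, out / "sig_scores.tsv", index_label="patient")
    pd.DataFrame(hr_rows).to_csv(out / "sig_hazard_ratios.tsv", sep="\t", index=False)
    return {
        "sig_scores.tsv": out / "sig_scores.tsv",
        "sig_hazard_ratios.tsv": out / "sig_hazard_ratios.tsv",
    }


def _forest_config(section: dict) -> ForestConfig:
    return ForestConfig(
        ntree=int(section.get("ntree", 200)),
        mtry=section.get("mtry"),
        min_node_events=int(section.get("min_node_events", 3)),
        n_split=int(section.get("n_split", 10)),
        grid_size=int(section.get("grid_size", 128)),
        horizons=tuple(section.get("horizons", (15.0, 7.5))),
    )


def _load_feature_info(out: Path, genes: List[str]) -> rsf.FeatureInfo:
    combined = pd.concat(
        [read_table(out / "train_expr.tsv"), read_table(out / "valid_expr.tsv")], axis=1
    )
    combined_clin = pd.concat(
        [read_table(out / "train_clin.tsv"), read_table(out / "valid_clin.tsv")]
    )
    _, info = rsf.build_features(combined, combined_clin, genes)
    return info


def _load_features(out: Path, genes: List[str]):
    train_expr = read_table(out / "train_expr.tsv")
    train_clin = read_table(out / "train_clin.tsv")
    valid_expr = read_table(out / "valid_expr.tsv")
    valid_clin = read_table(out / "valid_clin.tsv")
    # medians across all samples of the dataset (train + validation pooled)
    combined = pd.concat([train_expr, valid_expr], axis=1)
    combined_clin = pd.concat([train_clin, valid_clin])
    _, info = rsf.build_features(combined, combined_clin, genes)
    f_train, _ = rsf.build_features(train_expr, train_clin, genes, info=info)
    f_valid, _ = rsf.build_features(valid_expr, valid_clin, genes, info=info)
    return f_train, train_clin, f_valid, valid_clin


def _stage_train(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    section = cfg.get("train", {})
    genes = read_gene_list(out / "human_genes.txt")
    f_train, train_clin, _, _ = _load_features(out, genes)
    t = train_clin["time_years"].to_numpy(float)
    e = train_clin["event"].to_numpy(int)
    ranked = rsf.univariate_filter(f_train, t, e, alpha=float(section.get("alpha", 0.05)))
    config = _forest_config(section)
    result = rsf.forward_select(list(ranked["feature"]), f_train, t, e,
                                config=config, seed=seed)
    result.forest.meta["feature_info"] = _load_feature_info(out, genes).to_dict()
    result.forest.save(out / "model.json")
    ranked.to_csv(out / "ranked_features.tsv", sep="\t", index=False)
    result.trace.to_csv(out / "selection_trace.tsv", sep="\t", index=False)
    write_gene_list(result.chosen, out / "chosen_features.txt")
    return {
        "model.json": out / "model.json",
        "ranked_features.tsv": out / "ranked_features.tsv",
        "selection_trace.tsv": out / "selection_trace.tsv",
        "chosen_features.txt": out / "chosen_features.txt",
    }


def _stage_evaluate(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    genes = read_gene_list(out / "human_genes.txt")
    forest = rsf.SurvivalForest.load(out / "model.json")
    _, _, f_valid, valid_clin = _load_features(out, genes)
    calls = rsf.stratify_cohort(forest, f_valid[forest.feature_names])
    t = valid_clin["time_years"].to_numpy(float)
    e = valid_clin["event"].to_numpy(int)
    p, k = nulldist._logrank_on_classes(calls["risk_class"], t, e)
    group_sizes = calls["risk_class"].value_counts().to_dict()
    km_medians = {}
    for c in rsf.RISK_CLASSES:
        mask = (calls["risk_class"] == c).to_numpy()
        if mask.sum() == 0:
            continue
        sf = survcore.km_estimate(t[mask], e[mask])
        below = sf.x[sf.y <= 0.5]
        km_medians[c] = float(below[0]) if below.size else None
    doc = {
        "n_validation": int(len(calls)),
        "group_sizes": {c: int(group_sizes.get(c, 0)) for c in rsf.RISK_CLASSES},
        "km_median_years": km_medians,
        "logrank_p": p,
        "n_groups": k,
        "oob_error": None if forest.oob_error_ is None or np.isnan(forest.oob_error_)
        else float(forest.oob_error_),
    }
    (out / "evaluation.json").write_text(json.dumps(doc, indent=1))
    write_table(calls, out / "predictions.tsv", index_label="patient")
    return {"evaluation.json": out / "evaluation.json",
            "predictions.tsv": out / "predictions.tsv"}


def _stage_null(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    section = cfg.get("null", {})
    genes = read_gene_list(out / "human_genes.txt")
    f_train, train_clin, f_valid, valid_clin = _load_features(out, genes)
    sizes = section.get("sizes", [2, 3, 4, 5])
    per_size = int(section.get("per_size", 25))
    pool = list(f_train.columns)
    sets = nulldist.sample_feature_sets(pool, sizes=sizes, per_size=per_size, seed=seed)
    config = _forest_config(section) if "ntree" in section else ForestConfig(
        ntree=100, n_split=10)
    runs = nulldist.evaluate_null(
        sets,
        f_train,
        (train_clin["time_years"].to_numpy(float), train_clin["event"].to_numpy(int)),
        f_valid,
        (valid_clin["time_years"].to_numpy(float), valid_clin["event"].to_numpy(int)),
        config=config,
        seed=seed + 1,
    )
    runs.to_csv(out / "null_runs.tsv", sep="\t", index=False)
    evaluation = json.loads((out / "evaluation.json").read_text())
    model_p = evaluation["logrank_p"]
    rank = nulldist.percentile_rank(model_p, runs["p_value"].dropna())
    null_p = runs["p_value"].dropna()
    doc = {
        "n_sets": int(len(runs)),
        "model_logrank_p": model_p,
        "percentile_rank": rank,
        "frac_null_significant": float(np.mean(null_p < 0.05)) if len(null_p) else None,
    }
    (out / "null_summary.json").write_text(json.dumps(doc, indent=1))
    return {"null_runs.tsv": out / "null_runs.tsv",
            "null_summary.json": out / "null_summary.json"}


def report_text(doc: dict) -> str:
    lines = ["angiosig run report", "=" * 19]
    ev = doc.get("evaluation")
    if ev:
        lines.append(f"validation patients: {ev['n_validation']}")
        for c in rsf.RISK_CLASSES:
            med = ev["km_median_years"].get(c)
            med_s = f"{med:.2f} y" if med is not None else "not reached"
            lines.append(
                f"  {c:<12} n={ev['group_sizes'][c]:<5} KM median: {med_s}"
            )
        lines.append(f"log-rank p ({ev['n_groups']} groups): {ev['logrank_p']:.3g}")
        if ev.get("oob_error") is not None:
            lines.append(f"chosen model OOB error: {ev['oob_error']:.3f}")
    if doc.get("chosen_features"):
        lines.append("chosen features: " + ", ".join(doc["chosen_features"]))
    null = doc.get("null")
    if null:
        lines.append(
            f"null sweep: {null['n_sets']} random sets; model superior to "
            f"{100 * null['percentile_rank']:.2f}% of them"
        )
    else:
        lines.append("null sweep: absent")
    return "\n".join(lines) + "\n"


def _stage_report(cfg: dict, out: Path, seed: int) -> Dict[str, Path]:
    doc = {}
    if (out / "evaluation.json").exists():
        doc["evaluation"] = json.loads((out / "evaluation.json").read_text())
    if (out / "chosen_features.txt").exists():
        doc["chosen_features"] = read_gene_list(out / "chosen_features.txt")
    if (out / "null_summary.json").exists():
        doc["null"] = json.loads((out / "null_summary.json").read_text())
    (out / "report.json").write_text(json.dumps(doc, indent=1))
    (out / "report.txt").write_text(report_text(doc))
    return {"report.json": out / "report.json", "report.txt": out / "report.txt"}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "homolog": _stage_homolog,
    "sigscore": _stage_sigscore,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "null": _stage_null,
    "report": _stage_report,
}

#: artifacts each stage reads, for cache invalidation
_STAGE_INPUTS = {
    "simulate": (),
    "de": ("counts.tsv", "meta.tsv"),
    "homolog": ("de_genes.txt", "homology.tsv", "platform.txt"),
    "sigscore": ("signatures.gmt", "train_expr.tsv", "valid_expr.tsv",
                 "train_clin.tsv", "valid_clin.tsv"),
    "train": ("human_genes.txt", "train_expr.tsv", "train_clin.tsv",
              "valid_expr.tsv", "valid_clin.tsv"),
    "evaluate": ("human_genes.txt", "model.json", "valid_expr.tsv", "valid_clin.tsv"),
    "null": ("human_genes.txt", "evaluation.json", "train_expr.tsv",
             "train_clin.tsv", "valid_expr.tsv", "valid_clin.tsv"),
    "report": ("evaluation.json",),
}


def _stage_key(cfg: dict, stage: str, out: Path, seed: int) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(cfg.get(stage, {}), sort_keys=True, default=str).encode())
    h.update(str(seed).encode())
    for name in _STAGE_INPUTS[stage]:
        p = out / name
        if p.exists():
            h.update(name.encode())
            h.update(_digest(p).encode())
    return h.hexdigest()


def run_pipeline(config_path, outdir, log=print) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``<outdir>/manifest.json``).
    A stage is skipped when a previous manifest records the same config
    section, seed and input digests and its outputs are unchanged.
    """
    cfg = load_config(config_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    stages = [s for s in STAGES if s in cfg.get("stages", DEFAULT_STAGES)]

    prev = {}
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            prev = {}

    manifest = {
        "version": __version__,
        "config": cfg,
        "master_seed": master_seed,
        "stages": {},
    }
    for stage in stages:
        seed = derive_seed(master_seed, stage)
        key = _stage_key(cfg, stage, out, seed)
        cached = prev.get(stage)
        if (
            cached
            and cached.get("key") == key
            and all(
                (out / name).exists() and _digest(out / name) == dig
                for name, dig in cached.get("outputs", {}).items()
            )
        ):
            log(f"[{stage}] cached, skipping")
            manifest["stages"][stage] = cached
            continue
        log(f"[{stage}] running (seed={seed})")
        t0 = _time.perf_counter()
        outputs = _STAGE_FUNCS[stage](cfg, out, seed)
        elapsed = _time.perf_counter() - t0
        manifest["stages"][stage] = {
            "seed": seed,
            "key": key,
            "elapsed_s": round(elapsed, 3),
            "outputs": {name: _digest(p) for name, p in outputs.items()},
        }
        log(f"[{stage}] done in {elapsed:.1f}s")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
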