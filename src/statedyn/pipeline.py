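"""End-to-end pipeline driver.

Stages: simulate (optional) -> qc -> standardize/concatenate -> HMM fit ->
temporal metrics -> compositional PCA -> cross-sectional group statistics ->
longitudinal two-step prediction.  Every stage reads and writes only
declared plain-text files under the output directory, logs its seed, and is
deterministic given the config seed: a rerun with the same config produces
byte-identical result files (the run log additionally carries wall-clock
timestamps).
"""
from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpca, hmm, io, longitudinal, metrics as tmetrics, qc, stats, synthetic

__all__ = ["run_pipeline", "run_stage", "STAGES"]

STAGES = ("simulate", "qc", "fit", "metrics", "pca", "stats", "longitudinal")

FMT = io.FLOAT_FMT


class RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def write(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp} {msg}\n")


def _paths(config: io.PipelineConfig, workdir: Path) -> dict[str, Path]:
    out = workdir / config.output_dir
    return {
        "out": out,
        "tc_dir": workdir / config.timecourse_dir,
        "cohort": workdir / config.cohort_csv,
        "visits": workdir / config.visits_csv,
        "cohort_qc": out / "cohort_qc.csv",
        "exclusions": out / "exclusions.tsv",
        "model": out / "model.json",
        "metrics": out / "metrics.tsv",
        "loadings": out / "pca_loadings.tsv",
        "scores": out / "scores.tsv",
        "pca_summary": out / "pca_summary.tsv",
        "group_stats": out / "group_stats.tsv",
        "perm_test": out / "perm_test.tsv",
        "converter": out / "converter_stats.tsv",
        "longitudinal": out / "longitudinal.tsv",
        "log": out / "run_log.txt",
    }


def _stage_simulate(config, paths, log):
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", config.seed)
    spec = synthetic.CohortSpec(**overrides)
    cohort = synthetic.simulate_cohort(spec)
    synthetic.write_cohort(cohort, paths["tc_dir"].parent)
    log.write(f"simulate: {len(cohort.subjects)} subjects, seed={spec.seed}")


def _stage_qc(config, paths, log):
    cohort = io.read_cohort(paths["cohort"])
    thr = qc.QCThresholds(**config.qc_thresholds)
    annotated, excl = qc.apply_qc(cohort, thr)
    paths["out"].mkdir(parents=True, exist_ok=True)
    annotated.to_csv(paths["cohort_qc"], index=False, float_format=FMT)
    excl.to_csv(paths["exclusions"], sep="\t", index=False)
    log.write(f"qc: kept {int(annotated['qc_pass'].sum())}/{len(annotated)} scans")


def _passing(paths) -> pd.DataFrame:
    df = pd.read_csv(paths["cohort_qc"])
    df["converter"] = df["converter"].astype(bool)
    return df[df["qc_pass"]].reset_index(drop=True)


def _stage_fit(config, paths, log):
    cohort = _passing(paths)
    scans = [
        hmm.standardize_timecourse(io.read_timecourse(paths["tc_dir"] / f"{sid}.tsv"))
        for sid in cohort["scan_id"]
    ]
    stacked, bounds = hmm.concatenate_scans(scans)
    model = hmm.fit_hmm(
        stacked,
        bounds,
        config.n_states,
        n_restarts=config.hmm_n_restarts,
        max_iter=config.hmm_max_iter,
        tol=config.hmm_tol,
        seed=config.seed,
    )
    io.write_model(paths["model"], model)
    log.write(
        f"fit: K={config.n_states}, ll={model.log_likelihood:.6g}, "
        f"iters={model.n_iter}, converged={model.converged}, seed={config.seed}"
    )


def _stage_metrics(config, paths, log):
    cohort = _passing(paths)
    model = io.read_model(paths["model"])
    mlist = []
    for _, row in cohort.iterrows():
        X = hmm.standardize_timecourse(io.read_timecourse(paths["tc_dir"] / f"{row['scan_id']}.tsv"))
        post = hmm.forward_backward(model, X)
        mlist.append(tmetrics.scan_metrics(post, float(row["repetition_time"]), model))
    table = tmetrics.metrics_table(list(cohort["scan_id"].astype(str)), mlist)
    table.to_csv(paths["metrics"], sep="\t", index=False, float_format=FMT)
    log.write(f"metrics: {len(table)} scans")


def _cross_sectional(paths) -> pd.DataFrame:
    cohort = _passing(paths)
    latest = qc.select_scan(cohort, "latest")
    met = pd.read_csv(paths["metrics"], sep="\t")
    return latest.merge(met, on="scan_id", validate="1:1")


def _stage_pca(config, paths, log):
    cs = _cross_sectional(paths)
    K = config.n_states
    FO = cs[[f"FO_{k + 1}" for k in range(K)]].to_numpy(dtype=float)
    FO = FO / FO.sum(axis=1, keepdims=True)
    model = cpca.fit_composition_pca(FO, alpha=config.pca_alpha)
    scores = cpca.component_scores(FO, model)
    load = pd.DataFrame(
        model.state_space_loadings,
        columns=[f"component_{j + 1}" for j in range(model.n_selected)],
    )
    load.insert(0, "state", [f"state_{k + 1}" for k in range(K)])
    load.to_csv(paths["loadings"], sep="\t", index=False, float_format=FMT)
    sc = pd.DataFrame(
        scores, columns=[f"component_{j + 1}" for j in range(model.n_selected)]
    )
    sc.insert(0, "subject_id", cs["subject_id"].to_numpy())
    sc.insert(1, "scan_id", cs["scan_id"].to_numpy())
    sc.to_csv(paths["scores"], sep="\t", index=False, float_format=FMT)
    summary = pd.DataFrame(
        {
            "eigenvalue": model.eigenvalues,
            "variance_explained": model.variance_explained,
        }
    )
    summary.insert(0, "component", np.arange(1, K))
    summary["selected"] = summary["component"] <= model.n_selected
    summary.to_csv(paths["pca_summary"], sep="\t", index=False, float_format=FMT)
    log.write(
        f"pca: selected {model.n_selected} component(s), "
        f"var1={model.variance_explained[0]:.4f}, forced={model.selection_forced}"
    )


def _stage_stats(config, paths, log):
    cs = _cross_sectional(paths)
    scores = pd.read_csv(paths["scores"], sep="\t")
    cs = cs.merge(scores[["scan_id", "component_1"]], on="scan_id", validate="1:1")
    K = config.n_states
    sym_nc = cs[cs["group"].isin(["symptomatic", "noncarrier"])]
    results = []
    metric_cols = [f"FO_{k + 1}" for k in range(K)] + ["SR", "component_1"]
    for col in metric_cols:
        results.append(stats.fit_metric_model(sym_nc, col, effect_name=f"{col}:symptomatic_vs_noncarrier"))
    padj = stats.fdr_adjust([r.p_value for r in results])
    results = [r.adjusted(p) for r, p in zip(results, padj)]
    rows = [
        {
            "effect": r.effect,
            "F": r.f_stat,
            "df_num": r.df_num,
            "df_den": r.df_den,
            "p": r.p_value,
            "p_fdr": r.p_adjusted,
            "partial_eta2": r.effect_size,
            "estimate": r.estimate,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(paths["group_stats"], sep="\t", index=False, float_format=FMT)

    # permutation test on transition/persistence probabilities
    P = sym_nc[[f"P_{i + 1}_{j + 1}" for i in range(K) for j in range(K)]].to_numpy(dtype=float)
    mats = P.reshape(-1, K, K)
    cov = pd.DataFrame(
        {
            "age": sym_nc["age"].to_numpy(dtype=float),
            "sex": (sym_nc["sex"].astype(str).str.upper() == "M").astype(float).to_numpy(),
        }
    )
    perm = stats.permutation_test_transitions(
        mats,
        sym_nc["group"].to_numpy(),
        cov,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    prow = []
    for i in range(K):
        for j in range(K):
            prow.append(
                {
                    "cell": f"P_{i + 1}_{j + 1}",
                    "t": perm.t_obs[i, j],
                    "p_fwe": perm.p_fwe[i, j],
                    "significant": perm.p_fwe[i, j] <= config.fwe_level,
                }
            )
    pd.DataFrame(prow).to_csv(paths["perm_test"], sep="\t", index=False, float_format=FMT)

    # converters vs non-converting presymptomatic carriers
    conv_rows = []
    try:
        for col in ["component_1"] + [f"FO_{k + 1}" for k in range(K)]:
            r = stats.converter_contrast(cs, col)
            conv_rows.append(
                {
                    "effect": r.effect,
                    "F": r.f_stat,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p": r.p_value,
                    "estimate": r.estimate,
                }
            )
        cp = stats.fdr_adjust([r["p"] for r in conv_rows])
        for r, p in zip(conv_rows, cp):
            r["p_fdr"] = p
    except ValueError as e:
        log.write(f"stats: converter contrast skipped ({e})")
    pd.DataFrame(conv_rows).to_csv(paths["converter"], sep="\t", index=False, float_format=FMT)
    log.write(f"stats: {len(rows)} contrasts, perm n={perm.n_perm} exact={perm.exact}")


def _stage_longitudinal(config, paths, log):
    full = pd.read_csv(paths["cohort_qc"])
    visits = io.read_visits(paths["visits"], full)
    cohort = _passing(paths)
    visits = visits[visits["subject_id"].isin(set(cohort["subject_id"]))]
    scores = pd.read_csv(paths["scores"], sep="\t")
    baseline = qc.select_scan(cohort, "earliest")
    base = baseline.merge(scores[["scan_id", "component_1"]], on="scan_id", validate="1:1")
    floors = {
        k: longitudinal.FloorDefinition(**v) for k, v in config.floor_definitions.items()
    }
    outcomes = [c for c in visits.columns if c not in ("subject_id", "years_from_baseline")]
    rows = []
    for outcome in outcomes:
        fd = floors.get(outcome, longitudinal.FloorDefinition())
        filtered, _ = longitudinal.remove_floor(visits, {outcome: fd})
        slopes = longitudinal.estimate_slopes(filtered[outcome], outcome)
        merged = slopes.merge(
            base[["subject_id", "group", "age", "sex", "site", "component_1"]],
            on="subject_id",
        ).rename(columns={"component_1": "comp"})
        sym = merged[merged["group"] == "symptomatic"]
        if len(sym) >= 10:
            r = longitudinal.predict_decline(sym, "comp", outcome_name=outcome)
            rows.append(r)
        pre = merged[merged["group"].isin(["presymptomatic", "noncarrier"])]
        if len(pre) >= 20 and pre["group"].nunique() == 2:
            for form in longitudinal.PREDICTION_FORMS:
                rows.append(
                    longitudinal.predict_decline(pre, form, outcome_name=f"{outcome}:carriers")
                )
    if rows:
        padj = stats.fdr_adjust([r.p_value for r in rows])
    else:
        padj = []
    table = pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "form": r.form,
                "term": r.headline_term,
                "std_beta": r.std_beta,
                "t": r.t_stat,
                "p": r.p_value,
                "p_fdr": p,
                "n": r.n,
            }
            for r, p in zip(rows, padj)
        ]
    )
    table.to_csv(paths["longitudinal"], sep="\t", index=False, float_format=FMT)
    log.write(f"longitudinal: {len(table)} second-stage models")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "fit": _stage_fit,
    "metrics": _stage_metrics,
    "pca": _stage_pca,
    "stats": _stage_stats,
    "longitudinal": _stage_longitudinal,
}


def run_stage(stage: str, config: io.PipelineConfig, workdir: str | Path) -> None:
    workdir = Path(workdir)
    paths = _paths(config, workdir)
    paths["out"].mkdir(parents=True, exist_ok=True)
    log = RunLog(paths["log"])
    try:
        _STAGE_FN[stage](config, paths, log)
    except Exception as e:
        log.write(f"{stage}: FAILED ({e})")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


def run_pipeline(
    config: io.PipelineConfig, workdir: str | Path, *, skip_simulate: bool = False
) -> dict[str, Path]:
    """Run every stage in order; returns the output file paths."""
    workdir = Path(workdir)
    paths = _paths(config, workdir)
    stages = list(STAGES)
    if skip_simulate or config.simulate is None:
        stages.remove("simulate")
        if not paths["cohort"].exists() or not paths["tc_dir"].exists():
            raise FileNotFoundError(
                "inputs missing (cohort table or time-course directory) and simulation disabled"
            )
    paths["out"].mkdir(parents=True, exist_ok=True)
    log = RunLog(paths["log"])
    log.write(f"pipeline start: seed={config.seed}, K={config.n_states}")
    for stage in stages:
        run_stage(stage, config, workdir)
    log.write("pipeline done")
    return paths
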