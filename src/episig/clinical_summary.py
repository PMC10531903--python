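"""Clinical feature-frequency summaries and end-to-end pipeline
orchestration.

``summarize_features`` reproduces the familiar "k/n (p%)" cells of a
clinical case-series table from a +/− feature matrix (missing entries
excluded from the denominator).  ``run_pipeline`` drives the whole
synthetic study: simulate → QC → matching → differential methylation →
probe selection → clustering/MDS → leave-one-out CV → SVM training and
MVP scoring → DMR calling → genomic-context annotation → multi-cohort
comparison, writing every stage artifact plus a machine-readable run
manifest that captures all seeds and parameters.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotation as ann
from . import cohort_comparison as cc
from . import differential_methylation as dm
from . import dmr as dmr_mod
from . import episignature as es
from . import matching, preprocessing, synthetic_data as sd

POSITIVE = "+"
NEGATIVE = "-"
MISSING = ""

#: every tunable of the pipeline with its default; a config file or dict
#: overrides these keys
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "n_probes": 8000,
    "n_chroms": 3,
    "n_cases": 8,
    "n_control_pool": 60,
    "n_signature_probes": 100,
    "delta_beta": -0.10,
    "effect_sd": 0.02,
    "direction": "hypo",
    "confound_strength": 0.3,
    "detp_fail_fraction": 5e-4,
    "detection_p_max": 0.1,
    "sample_fail_fraction": 0.05,
    "match_ratio": 5,
    "logit_offset": 0.0,
    "pca_components": 2,
    "pca_z_threshold": 3.0,
    "top_k": 500,
    "auc_min": 0.9,
    "corr_max": 0.9,
    "svm_c": 1.0,
    "dmr_sig_alpha": 0.05,
    "dmr_max_gap": 1000,
    "dmr_min_probes": 5,
    "dmr_min_mean_delta": 0.05,
    "dmr_region_alpha": 0.01,
    "dmp_max_p_adjusted": 0.01,
    "dmp_min_abs_delta": 0.05,
    "tree_top_n": 500,
    "exclude_cases": [],
    "run_loo": True,
    "run_comparison": True,
    "comparison_n_cohorts": 3,
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ClinicalTable:
    """Features × cases matrix with entries '+', '-' or '' (missing).

    The Unicode minus often found in published tables is normalized to
    ASCII '-' on construction.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.entries.fillna(MISSING).astype(str)
        e = e.replace({"−": NEGATIVE, "–": NEGATIVE})
        e = e.apply(lambda col: col.str.strip())
        bad = ~e.isin([POSITIVE, NEGATIVE, MISSING])
        if bad.any().any():
            raise ValueError(
                f"entries must be '+', '-' or missing; offending values: "
                f"{sorted(set(e.values[bad.values]))}")
        self.entries = e

    @property
    def features(self) -> list[str]:
        return list(self.entries.index)

    @property
    def cases(self) -> list[str]:
        return list(self.entries.columns)


def format_percent(k: int, n: int) -> str:
    """'k/n (p%)' with a trailing .0 suppressed (75%, not 75.0%)."""
    if n == 0:
        return "0/0"
    pct = 100.0 * k / n
    rounded = round(pct, 1)
    if float(rounded).is_integer():
        return f"{k}/{n} ({int(rounded)}%)"
    return f"{k}/{n} ({rounded}%)"


def summarize_features(table: ClinicalTable) -> pd.DataFrame:
    """Per-feature positives, assessed count, percent and formatted cell."""
    if table.entries.size == 0:
        raise ValueError("empty clinical table")
    rows = []
    for feat in table.features:
        row = table.entries.loc[feat]
        n_pos = int((row == POSITIVE).sum())
        n_assessed = int((row != MISSING).sum())
        pct = 100.0 * n_pos / n_assessed if n_assessed else np.nan
        rows.append({"feature": feat, "n_pos": n_pos,
                     "n_assessed": n_assessed, "percent": pct,
                     "formatted": format_percent(n_pos, n_assessed)})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def load_config(source: dict | str | Path | None) -> dict:
    """Merge a config dict or YAML key-value file over the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            loaded = yaml.safe_load(fh) or {}
    else:
        loaded = dict(source)
    unknown = set(loaded) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage-named rewrap
                raise PipelineStageError(f"stage {name!r} failed: {exc}") \
                    from exc
        return inner
    return wrap


def run_pipeline(config: dict | str | Path | None,
                 out_dir: str | Path) -> Path:
    """Execute the full synthetic study end to end.

    Returns the run directory.  Every stage writes its artifact under
    ``out_dir``; ``run_manifest.json`` records the package version, the
    full parameter set and all derived seeds, sufficient to reproduce the
    run bit-identically.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    rng = np.random.default_rng(root_seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("manifest", "cohort", "svm", "panel")}

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        manifest, annotation = sd.simulate_manifest(
            cfg["n_probes"], cfg["n_chroms"], seed=seeds["manifest"])
        spec = sd.SignatureSpec(
            n_signature_probes=cfg["n_signature_probes"],
            delta_beta=cfg["delta_beta"], effect_sd=cfg["effect_sd"],
            direction=cfg["direction"])
        study = sd.simulate_cohort(
            manifest, cfg["n_cases"], cfg["n_control_pool"], spec,
            confound_strength=cfg["confound_strength"],
            seed=seeds["cohort"], annotation=annotation,
            detp_fail_fraction=cfg["detp_fail_fraction"])
        return study

    study = _simulate()
    study.write(out / "simulated")

    # -- qc ----------------------------------------------------------------
    @_stage("qc")
    def _qc():
        kept_samples, sample_report = preprocessing.filter_samples(
            study.detp, threshold=cfg["sample_fail_fraction"],
            detection_p_max=cfg["detection_p_max"])
        beta = study.beta[kept_samples]
        detp = study.detp[kept_samples]
        beta_f, probe_report = preprocessing.filter_probes(
            beta, detp, study.manifest,
            detection_p_max=cfg["detection_p_max"])
        report = preprocessing.QCReport(
            probes_removed=probe_report.probes_removed,
            samples_removed=sample_report.samples_removed,
            probes_remaining=probe_report.probes_remaining)
        return beta_f, report

    beta, qc_report = _qc()
    (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(),
                                                   indent=1))
    m = preprocessing.beta_to_m(beta, offset=cfg["logit_offset"])
    _, pca_scores = preprocessing.pca_outliers(
        m, n_components=cfg["pca_components"],
        z_threshold=cfg["pca_z_threshold"])
    pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")

    # -- match -------------------------------------------------------------
    exclude = set(cfg["exclude_cases"])
    sheet = study.samples[study.samples["sample_id"].isin(beta.columns)]
    cases = sheet[(sheet["group"] == "case")
                  & ~sheet["sample_id"].isin(exclude)]
    pool = sheet[sheet["group"] == "control_pool"]

    @_stage("match")
    def _match():
        return matching.match_controls(cases, pool, ratio=cfg["match_ratio"])

    match = _match()
    pd.DataFrame(
        [(c, ctrl) for c, lst in sorted(match.assignment.items())
         for ctrl in lst],
        columns=["case_id", "control_id"],
    ).to_csv(out / "matching.csv", index=False)
    case_ids = sorted(cases["sample_id"])
    control_ids = match.matched_control_ids

    # -- dmp ---------------------------------------------------------------
    @_stage("dmp")
    def _dmp():
        stats = dm.dmp_statistics(beta, m, study.samples, case_ids,
                                  control_ids)
        return es.attach_auc_scores(stats, beta, case_ids, control_ids)

    stats = _dmp()
    stats.to_csv(out / "dmp_table.tsv", sep="\t")

    # -- select / cluster / mds -------------------------------------------
    params = es.SelectionParams(top_k=cfg["top_k"], auc_min=cfg["auc_min"],
                                corr_max=cfg["corr_max"])

    @_stage("select")
    def _select():
        return es.select_probes(stats, beta[case_ids + control_ids], params)

    selected = _select()
    (out / "selected_probes.txt").write_text("\n".join(selected) + "\n")
    newick, _ = es.hierarchical_cluster(
        beta.loc[selected, case_ids + control_ids])
    (out / "dendrogram.nwk").write_text(newick + "\n")
    coords = es.mds_embedding(beta.loc[selected, case_ids + control_ids])
    coords.to_csv(out / "mds_coordinates.tsv", sep="\t")

    # -- loo ---------------------------------------------------------------
    if cfg["run_loo"]:
        @_stage("loo")
        def _loo():
            return es.loo_crossvalidate(beta, m, study.samples, case_ids,
                                        control_ids, params)

        rounds = _loo()
        pd.DataFrame([{k: (v if not isinstance(v, list) else len(v))
                       for k, v in r.items()} for r in rounds]) \
            .rename(columns={"selected_probes": "n_selected"}) \
            .to_csv(out / "loo_rounds.csv", index=False)

    # -- train / score -----------------------------------------------------
    @_stage("train")
    def _train():
        return es.train_classifier(beta.loc[selected], case_ids,
                                   control_ids, seed=seeds["svm"],
                                   c=cfg["svm_c"])

    model, mvp_report = _train()
    model.save(out / "model.json")
    mvp_report.to_csv(out / "mvp_scores.csv")
    if exclude:
        held = [s for s in exclude if s in beta.columns]
        if held:
            es.classify_samples(model, beta.loc[selected, held]) \
                .to_csv(out / "mvp_excluded_cases.csv")

    # -- dmr ---------------------------------------------------------------
    @_stage("dmr")
    def _dmr():
        return dmr_mod.call_dmrs(
            stats, study.manifest, sig_alpha=cfg["dmr_sig_alpha"],
            max_gap=cfg["dmr_max_gap"], min_probes=cfg["dmr_min_probes"],
            min_mean_delta=cfg["dmr_min_mean_delta"],
            region_alpha=cfg["dmr_region_alpha"])

    dmrs = _dmr()
    dmr_mod.write_bed(dmrs, out / "dmrs.bed")
    dmr_mod.dmrs_to_frame(dmrs).to_csv(out / "dmrs.tsv", sep="\t",
                                       index=False)

    # -- annotate ----------------------------------------------------------
    @_stage("annotate")
    def _annotate():
        positions = study.manifest[
            study.manifest["probe_id"].isin(beta.index)]
        ctx = ann.annotate_contexts(positions,
                                    study.annotation.cgi_intervals,
                                    study.annotation.genes)
        dmp_ids = stats[(stats["p_adjusted"] < cfg["dmp_max_p_adjusted"])
                        & (stats["delta_beta"].abs()
                           >= cfg["dmp_min_abs_delta"])].index
        result = {"background": {}, "dmp": {}, "tests": {}}
        for axis in ("cgi_context", "gene_context"):
            bg = ctx[axis].value_counts()
            obs = ctx.loc[ctx.index.isin(dmp_ids), axis].value_counts() \
                .reindex(bg.index, fill_value=0)
            result["background"][axis] = bg.to_dict()
            result["dmp"][axis] = obs.to_dict()
            if obs.sum() > 0:
                stat, p = ann.context_distribution_test(obs, bg)
                result["tests"][axis] = {"chi_square": stat, "p": p}
        return ctx, result

    ctx, ctx_result = _annotate()
    ctx.to_csv(out / "probe_contexts.tsv", sep="\t")
    (out / "context_counts.json").write_text(json.dumps(ctx_result, indent=1))

    # -- compare -----------------------------------------------------------
    if cfg["run_comparison"]:
        @_stage("compare")
        def _compare():
            n_sig = cfg["n_signature_probes"]
            names = [f"cohort_{chr(ord('A') + i)}"
                     for i in range(cfg["comparison_n_cohorts"])]
            plan = sd.OverlapPlan(
                sizes={n: n_sig for n in names},
                shared={(names[0], names[1]): max(1, n_sig // 5)})
            truth, _ = sd.simulate_disorder_panel(
                study.manifest, plan, seed=seeds["panel"],
                with_studies=False)
            sigs = [cc.CohortSignature(
                cohort_id=n,
                dmp_deltas={p: cfg["delta_beta"] for p in t})
                for n, t in sorted(truth.items())]
            return cc.overlap_matrix(sigs), cc.shared_counts(sigs)

        overlap, counts = _compare()
        overlap.to_csv(out / "cohort_overlap.tsv", sep="\t")
        counts.to_csv(out / "cohort_shared_counts.tsv", sep="\t")

    manifest_doc = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "config": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                   for k, v in cfg.items()},
        "derived_seeds": seeds,
        "n_selected_probes": len(selected),
        "n_dmrs": len(dmrs),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_doc, indent=1,
                                                      sort_keys=True))
    return out
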