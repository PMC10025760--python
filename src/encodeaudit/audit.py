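"""End-to-end audit orchestration.

``run_audit`` wires the stages together for one or two synthetic sites:
cohort generation, population summary, single-task and multitask training,
subgroup evaluation on original and resampled test sets, cross-site
evaluation, SPLIT panels for race and sex, unsupervised inspection with KS
tables, and a machine-readable verdict.  All stage seeds derive from one
master seed; identical configs produce byte-identical tables.

The verdict block is an interpretation aid layered on top of the raw
evidence: a chance-level probe is the scenario-A signature; a positive probe
with neither output-space group separation nor residual post-resampling
disparity is the scenario-B signature; a positive probe with either of those
is the scenario-C signature.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inspection import alignment_summary, inspect, marginal_ks_table
from .metrics import EvalConfig, calibrate_threshold, subgroup_performance
from .models import build_backbone, predict_proba, train_multitask, train_single_task
from .resampling import ResamplingSpec, resample_test_set, shift_diagnosis
from .split import split_panel
from .synthetic import (
    Cohort,
    CohortConfig,
    FOCAL_LABELS,
    GROUPS,
    make_cohort,
    summarize_population,
)

__all__ = ["AuditConfig", "run_audit", "ingest_predictions", "audit_verdict"]

log = logging.getLogger("encodeaudit")

SPLIT_NULL_BAND = (0.45, 0.55)
RESIDUAL_FPR_TOL = 0.03


@dataclass
class AuditConfig:
    sites: list[CohortConfig] = field(default_factory=lambda: [CohortConfig()])
    epochs: int = 20
    eval_cfg: EvalConfig = field(default_factory=EvalConfig)
    resampling: ResamplingSpec = field(default_factory=ResamplingSpec)
    run_split_panel: bool = True
    run_inspection: bool = True
    make_figures: bool = False
    plot_sample: int = 1000
    tsne_iter: int = 500
    out_dir: str = "audit_out"
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AuditConfig":
        d = dict(d)
        sites = [CohortConfig(**s) for s in d.pop("sites", [{}])]
        eval_cfg = EvalConfig(**d.pop("eval", {}))
        resampling = ResamplingSpec(**d.pop("resampling", {}))
        return cls(sites=sites, eval_cfg=eval_cfg, resampling=resampling, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AuditConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: AuditConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def audit_verdict(
    split_race_auc: float | None,
    logit_group_ks_significant: bool,
    residual_fpr_disparity: bool,
) -> dict:
    """Scenario signature from the three evidence streams (pure function)."""
    if split_race_auc is None:
        return {"scenario": "indeterminate", "reason": "no SPLIT result available"}
    lo, hi = SPLIT_NULL_BAND
    if lo <= split_race_auc <= hi:
        return {
            "scenario": "A",
            "reason": f"chance-level probe AUC {split_race_auc:.3f}: attribute not encoded",
        }
    if logit_group_ks_significant or residual_fpr_disparity:
        parts = []
        if logit_group_ks_significant:
            parts.append("group-separated logit marginals")
        if residual_fpr_disparity:
            parts.append("residual subgroup FPR disparity after resampling")
        return {
            "scenario": "C",
            "reason": f"positive probe AUC {split_race_auc:.3f} with " + " and ".join(parts),
        }
    return {
        "scenario": "B",
        "reason": (
            f"positive probe AUC {split_race_auc:.3f} but no output-level coupling: "
            "attribute encoded, not used"
        ),
    }


def _evaluate_site(
    bundle, cohort_test: Cohort, eval_cfg: EvalConfig, label: str,
    threshold: float | None = None,
) -> tuple[float, dict]:
    """Subgroup reports by race and by sex for one label.

    The decision threshold is calibrated on this cohort's pooled population
    unless an externally calibrated threshold is supplied (resampled test
    sets are always scored at the original population's threshold).
    """
    col = bundle.label_names.index(label)
    scores = predict_proba(bundle, cohort_test)[:, col]
    y = cohort_test.attr(label).astype(int)
    thr = (
        calibrate_threshold(scores, y, eval_cfg.target_fpr)
        if threshold is None
        else threshold
    )
    reports = {
        "race": subgroup_performance(
            scores, y, cohort_test.attr("group"), thr, eval_cfg, group_order=list(GROUPS)
        ),
        "sex": subgroup_performance(
            scores, y, cohort_test.attr("sex"), thr, eval_cfg,
            group_order=["female", "male"],
        ),
    }
    return thr, reports


def run_audit(config: AuditConfig) -> dict:
    """Execute the full audit; returns a dict of result objects and paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "audit.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.master_seed, 16)
    results: dict = {"sites": {}}
    stage = "init"
    try:
        bundles = {}
        cohorts = {}
        for si, cohort_cfg in enumerate(config.sites):
            site = cohort_cfg.site if cohort_cfg.site != "site0" or si == 0 else f"site{si}"
            cohort_cfg = dataclasses.replace(cohort_cfg, site=site)
            stage = f"cohort_generation[{site}]"
            log.info("stage %s", stage)
            cohort = make_cohort(cohort_cfg, seed=seeds[0] + si)
            cohorts[site] = cohort
            pop = summarize_population(cohort)
            pop.to_csv(out / f"population_{site}.csv", index=False)

            stage = f"training[{site}]"
            log.info("stage %s", stage)
            spec = {"input_dim": cohort.features.shape[1]}
            single = train_single_task(
                build_backbone("mlp", spec, seed=seeds[1] + si),
                cohort, epochs=config.epochs, seed=seeds[1] + si,
            )
            multi = train_multitask(
                build_backbone("mlp", spec, seed=seeds[2] + si),
                cohort, epochs=config.epochs, seed=seeds[2] + si,
            )
            bundles[site] = {"single": single, "multi": multi}

            stage = f"evaluation[{site}]"
            log.info("stage %s", stage)
            test = cohort.split("test")
            resampled = resample_test_set(
                test, dataclasses.replace(config.resampling, seed=seeds[3] + si)
            )
            site_res = {"reports": {}, "diagnosis": {}}
            residual_disparity = False
            for model_name, bundle in bundles[site].items():
                for label in FOCAL_LABELS:
                    thr, rep_orig = _evaluate_site(bundle, test, config.eval_cfg, label)
                    _, rep_res = _evaluate_site(
                        bundle, resampled, config.eval_cfg, label, threshold=thr
                    )
                    for attr in ("race", "sex"):
                        key = f"{model_name}_{label}_{attr}"
                        rep_orig[attr].table.to_csv(
                            out / f"subgroup_{site}_{key}_original.csv", index=False
                        )
                        rep_res[attr].table.to_csv(
                            out / f"subgroup_{site}_{key}_resampled.csv", index=False
                        )
                        diag = shift_diagnosis(rep_orig[attr], rep_res[attr])
                        diag.to_csv(out / f"shift_{site}_{key}.csv", index=False)
                        site_res["reports"][key] = {
                            "original": rep_orig[attr], "resampled": rep_res[attr]
                        }
                        site_res["diagnosis"][key] = diag
                    if model_name == "single":
                        fprs = rep_res["race"].table["fpr"].dropna()
                        if (abs(fprs - config.eval_cfg.target_fpr) > RESIDUAL_FPR_TOL).any():
                            residual_disparity = True

            split_tables = {}
            if config.run_split_panel:
                stage = f"split_panel[{site}]"
                log.info("stage %s", stage)
                for attribute in ("race", "sex"):
                    panel = split_panel(
                        cohort, attribute, seed=seeds[4] + si, epochs=config.epochs,
                        eval_cfg=config.eval_cfg,
                        single_task_bundle=single, multitask_bundle=multi,
                    )
                    panel.to_csv(out / f"split_panel_{site}_{attribute}.csv", index=False)
                    split_tables[attribute] = panel
                    if config.make_figures:
                        from .figures import plot_split_panel

                        plot_split_panel(panel, out / f"split_panel_{site}_{attribute}.png")

            ks_tables = {}
            logit_group_sig = False
            if config.run_inspection:
                stage = f"inspection[{site}]"
                log.info("stage %s", stage)
                insp = {}
                for model_name, bundle in bundles[site].items():
                    res = inspect(
                        bundle, test, plot_sample=config.plot_sample,
                        seed=seeds[5] + si, tsne_iter=config.tsne_iter,
                    )
                    insp[model_name] = res
                    kst = marginal_ks_table(res)
                    kst.to_csv(out / f"ks_{site}_{model_name}.csv", index=False)
                    ks_tables[model_name] = kst
                    if config.make_figures:
                        from .figures import plot_inspection

                        plot_inspection(res, out / f"inspection_{site}_{model_name}.png")
                align = alignment_summary(insp["single"], insp["multi"])
                align.to_csv(out / f"alignment_{site}.csv", index=False)
                site_res["alignment"] = align
                single_ks = ks_tables["single"]
                logit_rows = single_ks[
                    single_ks["axis"].str.startswith("logit")
                    & single_ks["pair"].isin(["g0/g1", "g1/g2", "g2/g0"])
                ]
                logit_group_sig = bool(logit_rows["significant"].any())

            stage = f"verdict[{site}]"
            split_auc = None
            if "race" in split_tables:
                t = split_tables["race"]
                sel = t[t["backbone_id"] == "all_data_disease"]["auc"].dropna()
                split_auc = float(sel.mean()) if len(sel) else None
            verdict = audit_verdict(split_auc, logit_group_sig, residual_disparity)
            verdict["evidence"] = {
                "split_race_auc_disease_backbone": split_auc,
                "logit_group_ks_significant": logit_group_sig,
                "residual_fpr_disparity": residual_disparity,
            }
            with open(out / f"verdict_{site}.json", "w") as fh:
                json.dump(verdict, fh, indent=2)
            site_res["verdict"] = verdict
            site_res["split_tables"] = split_tables
            site_res["ks_tables"] = ks_tables
            results["sites"][site] = site_res

        if len(config.sites) == 2:
            stage = "cross_site"
            log.info("stage %s", stage)
            names = list(cohorts)
            cross = {}
            for model_site in names:
                other = names[1] if model_site == names[0] else names[0]
                test = cohorts[other].split("test")
                for label in FOCAL_LABELS:
                    _, reports = _evaluate_site(
                        bundles[model_site]["single"], test, config.eval_cfg, label
                    )
                    for attr in ("race", "sex"):
                        key = f"model_{model_site}_on_{other}_{label}_{attr}"
                        reports[attr].table.to_csv(out / f"cross_{key}.csv", index=False)
                        cross[key] = reports[attr]
            results["cross_site"] = cross

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "master_seed": config.master_seed,
            "stage_seeds": seeds,
            "config_hash": _config_hash(config),
            "sites": [c.site for c in config.sites],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"audit stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


REQUIRED_PREDICTION_COLUMNS = ("sample_id", "group", "sex", "age")


def ingest_predictions(
    csv_path: str | Path,
    score_columns: dict[str, str] | None = None,
    label_columns: tuple[str, str] = FOCAL_LABELS,
    scores_are_probabilities: bool = True,
) -> pd.DataFrame:
    """Validate a user prediction table for audit-only mode.

    Expects per-sample identifier, attributes, the focal labels, and one score
    column per focal label (default ``score_<label>``).
    """
    df = pd.read_csv(csv_path)
    score_columns = score_columns or {lb: f"score_{lb}" for lb in label_columns}
    missing = [
        c
        for c in list(REQUIRED_PREDICTION_COLUMNS)
        + list(label_columns)
        + list(score_columns.values())
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"prediction table missing required columns: {missing}")
    if scores_are_probabilities:
        for col in score_columns.values():
            vals = df[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(
                    f"column {col!r} declared as probabilities but has values outside [0, 1]"
                )
    for col in label_columns:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            raise ValueError(f"label column {col!r} must be binary 0/1")
    return df
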