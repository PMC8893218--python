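"""Full analysis pipeline mirroring the standard reporting order.

run_pipeline: effect sizes -> overall three-level fit -> heterogeneity ->
publication bias -> outlier/influence diagnostics -> refit without flagged
effects -> moderator analyses on the cleaned set. Emits a JSON-serialisable
report plus CSV tables (forest, funnel, influence, power).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import trim_and_fill
from .dataset import AnalysisConfig, StudyDataset, read_dataset
from .effects import compute_effect_table
from .heterogeneity import heterogeneity_report
from .influence import influence_report
from .model import (ModelFit, fit_three_level, lrt_variance_component,
                    moderator_omnibus_test, subgroup_fits, wald_inference)
from .power import dataset_power_summary

log = logging.getLogger("metamem")

__all__ = ["run_pipeline", "forest_table"]

DEFAULT_MODERATORS = ("recovery_sleep", "memory_type", "task_type", "emotionality")


def forest_table(fit: ModelFit, ds: StudyDataset,
                 cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-effect rows (g, CI, normalized GLS weight) plus the pooled row.

    Weights are the row sums of the GLS weight matrix M^{-1} (normalised
    to 1): the contribution of each effect to the pooled estimate.
    """
    from scipy import stats
    from .model import _cluster_codes, _solve_m

    cfg = cfg or AnalysisConfig()
    y = np.array([r.g for r in ds.records], float)
    v = np.array([r.v for r in ds.records], float)
    codes = _cluster_codes(np.array([r.report_id for r in ds.records]))
    n_cl = int(codes.max()) + 1
    d = v + fit.tau2_within
    ones = np.ones_like(y)
    w = _solve_m(ones, d, fit.tau2_between, codes, n_cl)
    w = w / w.sum()
    q = stats.norm.ppf(1.0 - (1.0 - cfg.ci_level) / 2.0)
    se = np.sqrt(v)
    rows = pd.DataFrame({
        "effect_id": [r.effect_id for r in ds.records],
        "report_id": [r.report_id for r in ds.records],
        "g": y, "ci_low": y - q * se, "ci_high": y + q * se, "weight": w,
    })
    pooled = pd.DataFrame({
        "effect_id": ["POOLED"], "report_id": [""],
        "g": [fit.estimate],
        "ci_low": [fit.estimate - q * fit.se[0]],
        "ci_high": [fit.estimate + q * fit.se[0]],
        "weight": [np.nan],
    })
    return pd.concat([rows, pooled], ignore_index=True)


def _wald_dict(fit: ModelFit, cfg: AnalysisConfig) -> dict:
    inf = wald_inference(fit, cfg)
    return {
        "coefficients": [
            {"name": n, "estimate": float(b), "se": float(s), "z": float(z),
             "p": float(p), "ci_low": float(lo), "ci_high": float(hi)}
            for n, b, s, z, p, lo, hi in zip(inf.names, inf.estimate, inf.se,
                                             inf.z, inf.p, inf.ci_low, inf.ci_high)
        ],
        "tau2_between": fit.tau2_between,
        "tau2_within": fit.tau2_within,
        "loglik_reml": fit.loglik_reml,
        "k": fit.k, "n_clusters": fit.n_clusters,
        "Q": fit.Q, "Q_df": fit.Q_df, "Q_p": fit.Q_p,
    }


def _usable_moderators(ds: StudyDataset, min_per_level: int) -> list[str]:
    out = []
    for mod in DEFAULT_MODERATORS:
        counts: dict[str, int] = {}
        for rec in ds.records:
            lv = rec.moderators.get(mod, "")
            counts[lv] = counts.get(lv, 0) + 1
        levels = [lv for lv, c in counts.items() if lv]
        if len(levels) == 2 and all(counts[lv] >= min_per_level for lv in levels):
            out.append(mod)
    return out


def run_pipeline(data_path: str | Path, config_path: str | Path | None = None,
                 out_dir: str | Path | None = None,
                 remove_influential: bool = True,
                 min_subgroup_k: int = 6) -> dict:
    """Run the complete analysis and return the report as a dict.

    When out_dir is given, writes report.json plus forest/funnel/
    influence/power CSV tables there.
    """
    data_path = Path(data_path)
    cfg = AnalysisConfig.from_file(config_path) if config_path else AnalysisConfig()
    ds = read_dataset(data_path)
    ds = compute_effect_table(ds, cfg)

    log.info("dataset %s: %d effects in %d reports", ds.name, len(ds), ds.n_clusters)
    fit = fit_three_level(ds, None, cfg)
    het = heterogeneity_report(ds, fit, cfg)
    lrt_b = lrt_variance_component(ds, "between", cfg)
    lrt_w = lrt_variance_component(ds, "within", cfg)
    bias_rep = trim_and_fill(ds, cfg)
    infl = influence_report(ds, None, cfg)
    log.info("flagged effects: %s", infl.flagged or "none")

    cleaned = ds.drop(infl.flagged) if (remove_influential and infl.flagged
                                        and len(infl.flagged) < len(ds) - 1) else ds
    fit_clean = fit_three_level(cleaned, None, cfg) if cleaned is not ds else fit

    moderator_results = {}
    for mod in _usable_moderators(cleaned, 2):
        mfit = fit_three_level(cleaned, f"~ {mod}", cfg)
        omni = moderator_omnibus_test(mfit)
        subs = {}
        for level, sfit in subgroup_fits(cleaned, mod, cfg).items():
            w = wald_inference(sfit, cfg)
            subs[level] = {
                "g": sfit.estimate, "se": float(sfit.se[0]),
                "ci_low": float(w.ci_low[0]), "ci_high": float(w.ci_high[0]),
                "p": float(w.p[0]), "k": sfit.k,
                "low_k": sfit.k < min_subgroup_k,
            }
        moderator_results[mod] = {"omnibus": omni, "subgroups": subs}

    overall_w = wald_inference(fit, cfg)
    pw = dataset_power_summary(ds, abs(fit.estimate), cfg,
                               d_low=float(overall_w.ci_low[0]),
                               d_high=float(overall_w.ci_high[0]))

    cfg_json = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    report = {
        "version": __version__,
        "provenance": {
            "dataset": ds.name,
            "dataset_hash": hashlib.sha256(data_path.read_bytes()).hexdigest()[:16],
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "seed": cfg.seed,
        },
        "overall": _wald_dict(fit, cfg),
        "heterogeneity": het.to_dict(),
        "variance_lrt": {"between": lrt_b, "within": lrt_w},
        "bias": {
            "egger_z": bias_rep.egger_z, "egger_p": bias_rep.egger_p,
            "egger_slope": bias_rep.egger_slope,
            "n_imputed": bias_rep.n_imputed, "side": bias_rep.side,
            "g_adjusted": bias_rep.g_adjusted, "se_adjusted": bias_rep.se_adjusted,
            "ci_adjusted": list(bias_rep.ci_adjusted),
        },
        "influence": {
            "outliers": infl.outliers, "influential": infl.influential,
            "cooks_threshold": float(infl.cooks_threshold),
            "estimate_after_removal": fit_clean.estimate,
            "estimate_before_removal": fit.estimate,
        },
        "moderators": moderator_results,
        "power": {"d": pw.d, "d_low": pw.d_low, "d_high": pw.d_high,
                  "summary": pw.summary},
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
        forest_table(fit, ds, cfg).to_csv(out_dir / "forest.csv", index=False)
        bias_rep.funnel.to_csv(out_dir / "funnel.csv", index=False)
        infl.table.to_csv(out_dir / "influence.csv", index=False)
        pw.table.to_csv(out_dir / "power.csv", index=False)
        log.info("report written to %s", out_dir)
    return report
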