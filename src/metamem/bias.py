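"""Publication-bias assessment: funnel table, Egger test, trim-and-fill.

The Egger variant regresses each effect on its standard error inside the
three-level model (standard error entered as a continuous moderator), so
the asymmetry test respects the clustered structure. Trim-and-fill follows
Duval & Tweedie's rank-based algorithm and — deliberately — treats effects
as independent (a two-level approximation), because the method is defined
for independent effects; its adjusted estimate is a sensitivity analysis,
not a replacement for the multilevel fit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import AnalysisConfig, StudyDataset
from .model import fit_three_level, wald_inference, _extract_yvcl

__all__ = [
    "BiasReport",
    "funnel_table",
    "egger_multilevel",
    "trim_and_fill",
    "random_effects_dl",
]

_BANDS = ((0.01, "p<.01"), (0.05, ".01-.05"), (0.10, ".05-.10"))


@dataclass
class BiasReport:
    egger_z: float
    egger_p: float
    egger_slope: float
    egger_slope_se: float
    n_imputed: int
    side: str
    g_adjusted: float
    se_adjusted: float
    ci_adjusted: tuple[float, float]
    funnel: pd.DataFrame = field(repr=False, default=None)


def funnel_table(ds: StudyDataset, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-effect (g, se) with significance-contour band labels.

    Bands use the two-sided z = g/se: "p<.01", ".01-.05", ".05-.10",
    ">=.10". Every row gets exactly one band.
    """
    y, v, _ = _extract_yvcl(ds)
    se = np.sqrt(v)
    z = y / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    bands = []
    for pi in p:
        for cut, label in _BANDS:
            if pi < cut:
                bands.append(label)
                break
        else:
            bands.append(">=.10")
    return pd.DataFrame({
        "effect_id": [r.effect_id for r in ds.records],
        "g": y, "se": se, "p": p, "band": bands,
        "imputed": False,
    })


def egger_multilevel(ds: StudyDataset, cfg: AnalysisConfig | None = None) -> dict[str, float]:
    """Funnel-asymmetry test: se as a moderator in the three-level model.

    Returns the Wald z and p for the slope on the standard error. A
    positive slope means small (high-se) studies report larger effects.
    """
    cfg = cfg or AnalysisConfig()
    if len(ds) < 4:
        raise ValueError("Egger regression needs at least 4 effects")
    y, v, _ = _extract_yvcl(ds)
    se = np.sqrt(v)
    if np.ptp(se) == 0:
        raise ValueError("constant standard error: Egger slope undefined")
    # inject se as a numeric moderator without touching the input dataset
    recs = [dataclasses.replace(r, moderators={**r.moderators, "_se": repr(float(s))})
            for r, s in zip(ds.records, se)]
    ds_se = StudyDataset(recs, ds.name)
    fit = fit_three_level(ds_se, "~ _se", cfg)
    inf = wald_inference(fit, cfg)
    return {"z": float(inf.z[1]), "p": float(inf.p[1]),
            "slope": float(inf.estimate[1]), "slope_se": float(inf.se[1]),
            "intercept": float(inf.estimate[0])}


def random_effects_dl(y: np.ndarray, v: np.ndarray) -> dict[str, float]:
    """Two-level DerSimonian–Laird random-effects pooled estimate."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    w = 1.0 / v
    mu_fe = float((w * y).sum() / w.sum())
    Q = float((w * (y - mu_fe) ** 2).sum())
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (y.size - 1)) / c) if c > 0 else 0.0
    wr = 1.0 / (v + tau2)
    mu = float((wr * y).sum() / wr.sum())
    se = float(np.sqrt(1.0 / wr.sum()))
    return {"mu": mu, "se": se, "tau2": tau2, "Q": Q}


def _l0_k0(centered: np.ndarray, side: str) -> int:
    """Duval–Tweedie L0 estimator of the number of suppressed studies.

    Ranks |centered| over all n effects; T_n is the rank sum on the heavy
    side; L0 = (4 T_n - n(n+1)) / (2n - 1), floored at 0.
    """
    n = centered.size
    signed = centered if side == "right" else -centered
    ranks = stats.rankdata(np.abs(centered))
    T_n = float(ranks[signed > 0].sum())
    k0 = (4.0 * T_n - n * (n + 1)) / (2.0 * n - 1.0)
    return max(0, int(round(k0)))


def _r0_k0(centered: np.ndarray, side: str) -> int:
    """Rightmost-run estimator: length of the run of same-side effects
    among the largest |centered| values, minus 1."""
    signed = centered if side == "right" else -centered
    order = np.argsort(np.abs(centered))[::-1]
    run = 0
    for idx in order:
        if signed[idx] > 0:
            run += 1
        else:
            break
    return max(0, run - 1)


def trim_and_fill(ds: StudyDataset, cfg: AnalysisConfig | None = None,
                  max_iter: int = 50) -> BiasReport:
    """Duval–Tweedie trim-and-fill with an adjusted pooled estimate.

    Iteratively: centre effects at the fixed-effect mean of the retained
    set, estimate the number k0 of suppressed studies on the heavy side
    (L0 or R0 per config), trim the k0 most extreme same-side effects, and
    repeat until k0 stabilises. Trimmed effects are then mirrored about the
    final centre (g_imp = 2·centre - g, v_imp = v) and the adjusted
    estimate is a two-level DerSimonian–Laird fit on observed + imputed.
    Side "auto" trims opposite the Egger slope (missing studies are assumed
    on the side the slope points away from).
    """
    cfg = cfg or AnalysisConfig()
    y, v, _ = _extract_yvcl(ds)
    n = y.size
    if n < 3:
        raise ValueError("trim-and-fill needs at least 3 effects")

    side_missing = cfg.trimfill_side
    if side_missing == "auto":
        w = 1.0 / v
        mu_fe = (w * y).sum() / w.sum()
        se = np.sqrt(v)
        slope = np.polyfit(se, y - mu_fe, 1)[0] if np.ptp(se) > 0 else 0.0
        side_missing = "left" if slope >= 0 else "right"
    trim_side = "right" if side_missing == "left" else "left"
    estimator = _l0_k0 if cfg.trimfill_estimator == "L0" else _r0_k0

    k0 = 0
    for _ in range(max_iter):
        if side_missing == "left":
            order = np.argsort(y)            # ascending; trim from the top
            kept = order[: n - k0] if k0 else order
        else:
            order = np.argsort(y)[::-1]
            kept = order[: n - k0] if k0 else order
        w = 1.0 / v[kept]
        center = float((w * y[kept]).sum() / w.sum())
        k0_new = min(estimator(y - center, trim_side), n - 2)
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(f"trim-and-fill did not stabilise in {max_iter} iterations")

    funnel = funnel_table(ds, cfg)
    if k0 > 0:
        extreme = np.argsort(y)[-k0:] if side_missing == "left" else np.argsort(y)[:k0]
        y_imp = 2.0 * center - y[extreme]
        v_imp = v[extreme]
        y_all = np.concatenate([y, y_imp])
        v_all = np.concatenate([v, v_imp])
        imp_rows = pd.DataFrame({
            "effect_id": [f"imputed.{i + 1}" for i in range(k0)],
            "g": y_imp, "se": np.sqrt(v_imp),
            "p": 2.0 * stats.norm.sf(np.abs(y_imp) / np.sqrt(v_imp)),
            "band": "", "imputed": True,
        })
        funnel = pd.concat([funnel, imp_rows], ignore_index=True)
    else:
        y_all, v_all = y, v

    re = random_effects_dl(y_all, v_all)
    q = stats.norm.ppf(1.0 - (1.0 - cfg.ci_level) / 2.0)
    try:
        egger = egger_multilevel(ds, cfg)
    except ValueError:
        egger = {"z": np.nan, "p": np.nan, "slope": np.nan, "slope_se": np.nan}
    return BiasReport(
        egger_z=egger["z"], egger_p=egger["p"], egger_slope=egger["slope"],
        egger_slope_se=egger["slope_se"], n_imputed=int(k0), side=side_missing,
        g_adjusted=re["mu"], se_adjusted=re["se"],
        ci_adjusted=(re["mu"] - q * re["se"], re["mu"] + q * re["se"]),
        funnel=funnel,
    )
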