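"""Power and sample-size calculations for two-tailed t tests.

Achieved power uses the noncentral t distribution: for an
independent-groups test with per-group sizes (n1, n2) the noncentrality is
delta = d sqrt(n1 n2 / (n1 + n2)) on df = n1 + n2 - 2; for a paired test
with n pairs, delta = d_z sqrt(n) on df = n - 1. Both rejection tails are
counted. Sample-size solving also offers the large-sample normal
approximation n_per_group = 2 (z_{1-a/2} + z_{power})^2 / d^2 common in
quick planning formulas; the noncentral-t path is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import AnalysisConfig, StudyDataset

__all__ = ["PowerReport", "t_test_power", "required_n", "dataset_power_summary"]


@dataclass
class PowerReport:
    table: pd.DataFrame = field(repr=False)
    d: float = np.nan
    d_low: float = np.nan
    d_high: float = np.nan
    summary: dict[str, float] = field(default_factory=dict)


def t_test_power(d: float, design: str, n1: int, n2_or_pairs: int | None = None,
                 alpha: float = 0.05, tails: int = 2) -> float:
    """Achieved power of a t test for standardized effect d.

    design "between": n1, n2_or_pairs are the two group sizes;
    design "within": n1 is the number of pairs (d interpreted as d_z).
    """
    if n1 < 2:
        raise ValueError("need n >= 2")
    if design == "between":
        n2 = n2_or_pairs if n2_or_pairs is not None else n1
        if n2 < 2:
            raise ValueError("need n >= 2 in each group")
        df = n1 + n2 - 2
        ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    elif design == "within":
        df = n1 - 1
        ncp = d * np.sqrt(n1)
    else:
        raise ValueError(f"unknown design {design!r}")
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)
        # scipy's noncentral t loses the far tail for large ncp; the wrong
        # tail is then negligible and the main tail ~1
        if not np.isfinite(lower):
            lower = 0.0
        if not np.isfinite(upper):
            upper = float(stats.norm.sf(tcrit - ncp))
        return float(min(upper + lower, 1.0))
    if tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, ncp)
        if not np.isfinite(power):
            power = float(stats.norm.sf(tcrit - ncp))
        return float(min(power, 1.0))
    raise ValueError("tails must be 1 or 2")


def _normal_power(d: float, design: str, n: int, alpha: float, tails: int) -> float:
    ncp = d * np.sqrt(n / 2.0) if design == "between" else d * np.sqrt(n)
    z = stats.norm.ppf(1.0 - alpha / (2.0 if tails == 2 else 1.0))
    power = stats.norm.sf(z - ncp)
    if tails == 2:
        power += stats.norm.cdf(-z - ncp)
    return float(power)


def required_n(d: float, design: str, alpha: float = 0.05, tails: int = 2,
               target_power: float = 0.80,
               approximation: str = "noncentral_t") -> int:
    """Smallest sample size reaching the target power.

    Returns the total N (= 2 per-group n, equal groups) for between
    designs and the number of pairs for within designs. approximation
    "normal" uses the large-sample formula's power; "noncentral_t" solves
    the exact t-test power.
    """
    if d == 0:
        raise ValueError("no finite sample size can detect d = 0")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    d = abs(d)

    def power(n: int) -> float:
        if approximation == "normal":
            return _normal_power(d, design, n, alpha, tails)
        if design == "between":
            return t_test_power(d, "between", n, n, alpha, tails)
        return t_test_power(d, "within", n, None, alpha, tails)

    # bracket by doubling, then binary-search the smallest adequate n
    lo, hi = 2, 4
    while power(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise ValueError("required sample size exceeds 1e7")
    while lo < hi:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    n = lo if power(lo) >= target_power else hi
    return 2 * n if design == "between" else n


def dataset_power_summary(ds: StudyDataset, d: float,
                          cfg: AnalysisConfig | None = None,
                          d_low: float | None = None,
                          d_high: float | None = None) -> PowerReport:
    """Per-effect achieved power at d (and optionally at CI-bound effects).

    Records without sample sizes are skipped with a warning. Power is
    reported on the percent scale in the summary to match how per-study
    power is usually quoted.
    """
    import warnings
    cfg = cfg or AnalysisConfig()
    rows = []
    for rec in ds.records:
        if rec.n1 is None or (rec.design == "between" and rec.n2 is None):
            warnings.warn(f"effect {rec.effect_id}: missing sample size, skipped",
                          stacklevel=2)
            continue
        row = {
            "effect_id": rec.effect_id,
            "design": rec.design,
            "power_mean": t_test_power(d, rec.design, rec.n1, rec.n2, cfg.alpha),
        }
        if d_low is not None:
            row["power_low"] = t_test_power(d_low, rec.design, rec.n1, rec.n2, cfg.alpha)
        if d_high is not None:
            row["power_high"] = t_test_power(d_high, rec.design, rec.n1, rec.n2, cfg.alpha)
        rows.append(row)
    table = pd.DataFrame(rows)
    pw = table["power_mean"].to_numpy() if len(table) else np.array([np.nan])
    summary = {
        "mean_percent": float(100 * np.mean(pw)),
        "sd_percent": float(100 * np.std(pw, ddof=1)) if pw.size > 1 else 0.0,
        "min_percent": float(100 * np.min(pw)),
        "max_percent": float(100 * np.max(pw)),
    }
    return PowerReport(table=table, d=d,
                       d_low=np.nan if d_low is None else d_low,
                       d_high=np.nan if d_high is None else d_high,
                       summary=summary)
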