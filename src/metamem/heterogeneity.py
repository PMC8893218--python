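"""Heterogeneity statistics: Cochran Q, multilevel I², prediction intervals.

The I² decomposition follows the multilevel formulation: with a "typical"
within-study sampling variance ṽ computed from the weights, the total
variance τ²_within + τ²_between + ṽ is split into the percentage
attributable to sampling error, to within-report heterogeneity, and to
between-report heterogeneity. The three shares sum to 100 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import AnalysisConfig, StudyDataset
from .model import ModelFit, _cochran_q, design_matrix, _extract_yvcl

__all__ = [
    "HeterogeneityReport",
    "cochran_q",
    "typical_sampling_variance",
    "i2_decomposition",
    "prediction_interval",
    "heterogeneity_report",
]


@dataclass
class HeterogeneityReport:
    Q: float
    df: int
    p: float
    i2_sampling: float
    i2_within: float
    i2_between: float
    v_typical: float
    tau2_within: float
    tau2_between: float
    pi_low: float
    pi_high: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def cochran_q(y: np.ndarray, v: np.ndarray,
              X: np.ndarray | None = None) -> dict[str, float]:
    """Residual heterogeneity test Q = Σ w_i (y_i - ŷ_i)², w_i = 1/v_i.

    ŷ is the weighted least-squares fit on X (intercept-only when X is
    None); df = k - rank(X); p from the chi-square tail.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if X is None:
        X = np.ones((y.size, 1))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    if y.size <= np.linalg.matrix_rank(X):
        raise ValueError("need more effects than fitted coefficients")
    Q, df, p = _cochran_q(y, v, X)
    return {"Q": Q, "df": df, "p": p}


def typical_sampling_variance(v: np.ndarray) -> float:
    """Typical within-study sampling variance ṽ.

    ṽ = (k-1) Σw_i / ((Σw_i)² - Σw_i²) with w_i = 1/v_i: the harmonic-style
    summary used in the multilevel I² formula. Equals the common value when
    all v_i are identical, and always lies between min(v) and max(v).
    """
    v = np.asarray(v, float)
    if v.size < 2:
        raise ValueError("typical sampling variance needs k >= 2")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    return float((v.size - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def i2_decomposition(tau2_w: float, tau2_b: float,
                     v_typical: float) -> tuple[float, float, float]:
    """Percentage of total variance at each level (sums to exactly 100).

    Returns (i2_sampling, i2_within, i2_between).
    """
    if min(tau2_w, tau2_b, v_typical) < 0:
        raise ValueError("variance components must be non-negative")
    total = tau2_w + tau2_b + v_typical
    if total == 0:
        raise ValueError("all variance components are zero")
    return (100.0 * v_typical / total, 100.0 * tau2_w / total, 100.0 * tau2_b / total)


def prediction_interval(mu: float, se: float, tau2_total: float, k: int,
                        level: float = 0.95) -> tuple[float, float]:
    """t-based interval expected to contain the true effect of a new study.

    bounds = mu ± t_{k-2, (1+level)/2} sqrt(se² + τ²_total), with τ²_total
    the sum of both heterogeneity components since a new study draws both
    random terms. The k-2 degrees of freedom follow the Higgins-style
    convention.
    """
    if k < 3:
        raise ValueError("prediction interval needs k >= 3")
    tq = stats.t.ppf((1.0 + level) / 2.0, k - 2)
    half = tq * np.sqrt(se**2 + tau2_total)
    return (float(mu - half), float(mu + half))


def heterogeneity_report(ds: StudyDataset, fit: ModelFit,
                         cfg: AnalysisConfig | None = None) -> HeterogeneityReport:
    """Assemble the full heterogeneity summary for a fitted model."""
    cfg = cfg or AnalysisConfig()
    y, v, _ = _extract_yvcl(ds)
    X, _ = design_matrix(ds, None if fit.design_matrix_spec == "~ 1"
                         else fit.design_matrix_spec)
    q = cochran_q(y, v, X)
    vt = typical_sampling_variance(v)
    i2_s, i2_w, i2_b = i2_decomposition(fit.tau2_within, fit.tau2_between, vt)
    lo, hi = prediction_interval(fit.estimate, float(fit.se[0]),
                                 fit.tau2_within + fit.tau2_between,
                                 fit.k, cfg.ci_level)
    return HeterogeneityReport(Q=q["Q"], df=q["df"], p=q["p"],
                               i2_sampling=i2_s, i2_within=i2_w, i2_between=i2_b,
                               v_typical=vt, tau2_within=fit.tau2_within,
                               tau2_between=fit.tau2_between, pi_low=lo, pi_high=hi)
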