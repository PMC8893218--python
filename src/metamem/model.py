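"""Three-level random-effects meta-analysis fitted by REML.

Model: for effect i in report (cluster) j,

    y_ij = x_ij' beta + u_j + w_ij + e_ij,
    u_j  ~ N(0, tau2_between),   w_ij ~ N(0, tau2_within),
    e_ij ~ N(0, v_ij)            (known sampling variances),

so the marginal covariance is block-diagonal over clusters:
M_j = diag(v) + tau2_within I + tau2_between 11'. Level 1 is sampling
error, level 2 the within-report heterogeneity, level 3 the between-report
heterogeneity. Variance components are estimated by restricted maximum
likelihood with a non-negativity constraint (boundary solutions at zero
are legitimate and common); beta is the GLS solution at the optimum.

All linear algebra exploits the one-factor block structure through the
Sherman–Morrison identity, so a likelihood evaluation is O(k) in the
number of effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .dataset import AnalysisConfig, StudyDataset

__all__ = [
    "ModelFit",
    "WaldInference",
    "reml_loglik",
    "fit_three_level",
    "wald_inference",
    "lrt_variance_component",
    "moderator_omnibus_test",
    "subgroup_fits",
    "interaction_test",
    "design_matrix",
    "ConvergenceError",
    "RankDeficiencyError",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the best iterate found."""

    def __init__(self, message: str, best: tuple[float, float] | None = None):
        super().__init__(message)
        self.best = best


class RankDeficiencyError(ValueError):
    """Design matrix is rank-deficient (collinear moderators)."""


@dataclass
class ModelFit:
    """A fitted three-level meta-analytic model."""

    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    tau2_between: float
    tau2_within: float
    loglik_reml: float
    k: int
    n_clusters: int
    Q: float
    Q_df: int
    Q_p: float
    coef_names: list[str] = field(default_factory=list)
    design_matrix_spec: str = "~ 1"

    @property
    def estimate(self) -> float:
        """Intercept (pooled effect for an intercept-only model)."""
        return float(self.beta[0])


@dataclass
class WaldInference:
    """Per-coefficient Wald z tests and normal-quantile CIs."""

    names: list[str]
    estimate: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def _cluster_codes(clusters: np.ndarray) -> np.ndarray:
    _, codes = np.unique(np.asarray(clusters), return_inverse=True)
    return codes


def _solve_m(x: np.ndarray, d: np.ndarray, tau2_b: float, codes: np.ndarray,
             n_cl: int) -> np.ndarray:
    """Return M^{-1} x column-wise via Sherman–Morrison per cluster.

    d = v + tau2_within (diagonal part); the cluster block adds
    tau2_b * 11'. Works for 1-D or 2-D x.
    """
    x = np.atleast_2d(x.T).T  # ensure 2-D with columns
    xd = x / d[:, None]
    if tau2_b == 0.0:
        return xd if x.shape[1] > 1 else xd[:, 0]
    s = np.bincount(codes, weights=1.0 / d, minlength=n_cl)
    scale = tau2_b / (1.0 + tau2_b * s)  # per cluster
    out = np.empty_like(xd)
    for col in range(x.shape[1]):
        t = np.bincount(codes, weights=xd[:, col], minlength=n_cl)
        out[:, col] = xd[:, col] - (scale * t)[codes] / d
    return out if x.shape[1] > 1 else out[:, 0]


def _logdet_m(d: np.ndarray, tau2_b: float, codes: np.ndarray, n_cl: int) -> float:
    val = float(np.sum(np.log(d)))
    if tau2_b > 0.0:
        s = np.bincount(codes, weights=1.0 / d, minlength=n_cl)
        val += float(np.sum(np.log1p(tau2_b * s)))
    return val


def reml_loglik(tau2_b: float, tau2_w: float, y: np.ndarray, v: np.ndarray,
                clusters: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood of (tau2_between, tau2_within).

    -1/2 [ (k-p) log 2π + log|M| + log|X'M^{-1}X| + r'M^{-1}r ]
    with r the GLS residuals at the profiled beta-hat.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    codes = _cluster_codes(clusters)
    n_cl = int(codes.max()) + 1
    k, p = X.shape
    d = v + tau2_w
    if np.any(d <= 0):
        raise ValueError("marginal variances must be positive")
    Minv_X = np.atleast_2d(_solve_m(X, d, tau2_b, codes, n_cl).T).T
    XtMinvX = X.T @ Minv_X
    XtMinvy = Minv_X.T @ y
    try:
        L = np.linalg.cholesky(XtMinvX)
    except np.linalg.LinAlgError as err:
        raise RankDeficiencyError("X'M^{-1}X is singular") from err
    beta = np.linalg.solve(XtMinvX, XtMinvy)
    r = y - X @ beta
    Minv_r = _solve_m(r, d, tau2_b, codes, n_cl)
    quad = float(r @ Minv_r)
    logdet_xtmx = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * ((k - p) * _LOG_2PI + _logdet_m(d, tau2_b, codes, n_cl)
                   + logdet_xtmx + quad)


def design_matrix(ds: StudyDataset, moderators: str | None = None,
                  reference: dict[str, str] | None = None
                  ) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effects design matrix from a formula-like spec.

    ``moderators`` is e.g. ``"~ recovery_sleep + memory_type"`` or
    ``"~ recovery_sleep * memory_type"`` (main effects + interaction) or
    ``"~ recovery_sleep:memory_type"`` (the product term only). Categorical
    moderators get treatment coding with the alphabetically first level as
    reference (overridable via ``reference``); numeric moderator values are
    entered as-is (continuous).
    """
    k = len(ds)
    cols: list[np.ndarray] = [np.ones(k)]
    names: list[str] = ["intercept"]
    if moderators is None or moderators.strip() in ("", "~ 1", "~1"):
        return np.column_stack(cols), names
    spec = moderators.strip().lstrip("~").strip()
    terms: list[str] = []
    for raw in spec.split("+"):
        term = raw.strip()
        if not term:
            continue
        if "*" in term:
            a, b = (t.strip() for t in term.split("*", 1))
            terms.extend([a, b, f"{a}:{b}"])
        else:
            terms.append(term)

    def moderator_column(name: str) -> tuple[np.ndarray, str]:
        values = [rec.moderators.get(name, "") for rec in ds.records]
        try:
            return np.array([float(x) for x in values]), name
        except ValueError:
            pass
        levels = sorted(set(values))
        if len(levels) < 2:
            raise RankDeficiencyError(f"moderator {name!r} has a single level")
        if len(levels) > 2:
            raise RankDeficiencyError(
                f"moderator {name!r} has {len(levels)} levels; dichotomise or "
                "recode before fitting")
        ref = (reference or {}).get(name, levels[0])
        other = [lv for lv in levels if lv != ref][0]
        return (np.array(values) == other).astype(float), f"{name}[{other}]"

    for term in terms:
        if ":" in term:
            a, b = (t.strip() for t in term.split(":", 1))
            col_a, name_a = moderator_column(a)
            col_b, name_b = moderator_column(b)
            cols.append(col_a * col_b)
            names.append(f"{name_a}:{name_b}")
        else:
            col, name = moderator_column(term)
            cols.append(col)
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(f"collinear design for spec {moderators!r}")
    return X, names


def _extract_yvcl(ds: StudyDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = [rec.g for rec in ds.records]
    v = [rec.v for rec in ds.records]
    if any(x is None for x in g) or any(x is None for x in v):
        raise ValueError("dataset has records without (g, v); "
                         "run compute_effect_table first")
    clusters = np.array([rec.report_id for rec in ds.records])
    return np.asarray(g, float), np.asarray(v, float), clusters


def _cochran_q(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> tuple[float, int, float]:
    # residual (QE-style) Q with fixed-effect weights 1/v
    w = 1.0 / v
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ y)
    resid = y - X @ beta
    Q = float(np.sum(w * resid**2))
    df = int(y.size - np.linalg.matrix_rank(X))
    p = float(stats.chi2.sf(Q, df)) if df > 0 else float("nan")
    return Q, df, p


def fit_three_level(ds: StudyDataset, moderators: str | None = None,
                    cfg: AnalysisConfig | None = None,
                    fix_tau2_between: float | None = None,
                    fix_tau2_within: float | None = None) -> ModelFit:
    """Fit the three-level model by REML.

    ``fix_tau2_between`` / ``fix_tau2_within`` pin a component (used by the
    likelihood-ratio tests); leave None to estimate.
    """
    cfg = cfg or AnalysisConfig()
    y, v, clusters = _extract_yvcl(ds)
    if y.size < 2:
        raise ValueError("need at least 2 effects")
    X, names = design_matrix(ds, moderators)
    codes = _cluster_codes(clusters)
    n_cl = int(codes.max()) + 1

    free_b = fix_tau2_between is None
    free_w = fix_tau2_within is None

    def unpack(theta: np.ndarray) -> tuple[float, float]:
        it = iter(theta)
        t_b = next(it) if free_b else fix_tau2_between
        t_w = next(it) if free_w else fix_tau2_within
        return float(t_b), float(t_w)

    def negll(theta: np.ndarray) -> float:
        t_b, t_w = unpack(theta)
        return -reml_loglik(t_b, t_w, y, v, clusters, X)

    n_free = int(free_b) + int(free_w)
    if n_free == 0:
        tau2_b, tau2_w = float(fix_tau2_between), float(fix_tau2_within)
        ll = reml_loglik(tau2_b, tau2_w, y, v, clusters, X)
    else:
        # typical sampling variance sets the multi-start scale
        w = 1.0 / v
        vtyp = (y.size - 1) * w.sum() / (w.sum()**2 - (w**2).sum()) if y.size > 1 else v.mean()
        starts = [0.0, vtyp / 2.0, vtyp]
        best: tuple[float, np.ndarray] | None = None
        grids = [starts] * n_free
        from itertools import product
        for point in product(*grids):
            res = optimize.minimize(
                negll, x0=np.array(point), method="L-BFGS-B",
                bounds=[(0.0, None)] * n_free,
                options={"ftol": cfg.reml_tol, "gtol": 1e-10, "maxiter": 500})
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best[0] - 0.0:
                best = (float(res.fun), res.x.copy())
        if best is None:
            raise ConvergenceError("REML optimisation failed from every start")
        tau2_b, tau2_w = unpack(best[1])
        ll = -best[0]

    # GLS at the optimum
    d = v + tau2_w
    Minv_X = np.atleast_2d(_solve_m(X, d, tau2_b, codes, n_cl).T).T
    XtMinvX = X.T @ Minv_X
    vcov = np.linalg.inv(XtMinvX)
    beta = vcov @ (Minv_X.T @ y)
    se = np.sqrt(np.diag(vcov))
    Q, Q_df, Q_p = _cochran_q(y, v, X)
    return ModelFit(beta=beta, se=se, vcov=vcov,
                    tau2_between=float(tau2_b), tau2_within=float(tau2_w),
                    loglik_reml=float(ll), k=int(y.size), n_clusters=n_cl,
                    Q=Q, Q_df=Q_df, Q_p=Q_p, coef_names=names,
                    design_matrix_spec=moderators or "~ 1")


def wald_inference(fit: ModelFit, cfg: AnalysisConfig | None = None) -> WaldInference:
    """Normal-theory z tests and CIs for every coefficient."""
    cfg = cfg or AnalysisConfig()
    z = fit.beta / fit.se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    q = stats.norm.ppf(1.0 - (1.0 - cfg.ci_level) / 2.0)
    return WaldInference(names=list(fit.coef_names), estimate=fit.beta.copy(),
                         se=fit.se.copy(), z=z, p=p,
                         ci_low=fit.beta - q * fit.se,
                         ci_high=fit.beta + q * fit.se)


def lrt_variance_component(ds: StudyDataset, which_level: str,
                           cfg: AnalysisConfig | None = None,
                           moderators: str | None = None) -> dict[str, float]:
    """One-sided likelihood-ratio test of a variance component.

    ``which_level``: "between" tests tau2_between = 0 (reduced model keeps
    only within-report variance); "within" tests tau2_within = 0. Because
    the null value sits on the boundary of the parameter space the
    one-sided p uses the 50:50 chi-square mixture, p = 0.5 P(chi2_1 > LRT);
    the unhalved chi2_1 tail is also returned.
    """
    cfg = cfg or AnalysisConfig()
    full = fit_three_level(ds, moderators, cfg)
    if which_level == "between":
        reduced = fit_three_level(ds, moderators, cfg, fix_tau2_between=0.0)
    elif which_level == "within":
        reduced = fit_three_level(ds, moderators, cfg, fix_tau2_within=0.0)
    else:
        raise ValueError("which_level must be 'between' or 'within'")
    lrt = max(0.0, 2.0 * (full.loglik_reml - reduced.loglik_reml))
    p_two = float(stats.chi2.sf(lrt, 1))
    return {"lrt_stat": lrt, "p_onesided": 0.5 * p_two, "p_chi2_1": p_two,
            "loglik_full": full.loglik_reml, "loglik_reduced": reduced.loglik_reml}


def moderator_omnibus_test(fit: ModelFit) -> dict[str, float]:
    """Wald chi-square omnibus test of all non-intercept coefficients."""
    if len(fit.beta) < 2:
        raise ValueError("fit has no moderator coefficients")
    idx = np.arange(1, len(fit.beta))
    b = fit.beta[idx]
    V = fit.vcov[np.ix_(idx, idx)]
    try:
        Qm = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as err:
        raise RankDeficiencyError("singular moderator covariance") from err
    df = idx.size
    return {"Q_M": Qm, "df": df, "p": float(stats.chi2.sf(Qm, df))}


def subgroup_fits(ds: StudyDataset, moderator: str,
                  cfg: AnalysisConfig | None = None) -> dict[str, ModelFit]:
    """Independent intercept-only fits for each level of a moderator.

    Levels with fewer than 2 effects are skipped (reported as absent).
    """
    cfg = cfg or AnalysisConfig()
    levels: dict[str, list[str]] = {}
    for rec in ds.records:
        levels.setdefault(rec.moderators.get(moderator, ""), []).append(rec.effect_id)
    out: dict[str, ModelFit] = {}
    for level, ids in sorted(levels.items()):
        if len(ids) < 2:
            import warnings
            warnings.warn(f"moderator {moderator!r} level {level!r} has "
                          f"{len(ids)} effect(s); skipped", stacklevel=2)
            continue
        out[level] = fit_three_level(ds.subset(ids, name=f"{ds.name}[{moderator}={level}]"),
                                     None, cfg)
    return out


def interaction_test(ds: StudyDataset, mod_a: str, mod_b: str,
                     cfg: AnalysisConfig | None = None) -> dict[str, float]:
    """Wald test of the product term in a main-effects + interaction model.

    Requires both moderators binary with all four cells populated.
    """
    cfg = cfg or AnalysisConfig()
    cells: dict[tuple[str, str], int] = {}
    la = sorted({rec.moderators.get(mod_a, "") for rec in ds.records})
    lb = sorted({rec.moderators.get(mod_b, "") for rec in ds.records})
    if len(la) != 2 or len(lb) != 2:
        raise RankDeficiencyError(f"{mod_a!r} and {mod_b!r} must both be binary")
    for rec in ds.records:
        key = (rec.moderators.get(mod_a, ""), rec.moderators.get(mod_b, ""))
        cells[key] = cells.get(key, 0) + 1
    for a in la:
        for b in lb:
            if cells.get((a, b), 0) == 0:
                raise RankDeficiencyError(
                    f"empty design cell ({mod_a}={a}, {mod_b}={b})")
    fit = fit_three_level(ds, f"~ {mod_a} + {mod_b} + {mod_a}:{mod_b}", cfg)
    b_int = fit.beta[-1]
    se_int = fit.se[-1]
    Qi = float((b_int / se_int) ** 2)
    return {"Q_int": Qi, "df": 1, "p": float(stats.chi2.sf(Qi, 1))}
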