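"""Synthetic meta-analytic literatures with the three-level structure.

The generator emulates the shape of a sleep-deprivation memory literature:
reports contributing 1-5 effects each, a mix of between- and within-subject
designs, true effects drawn as theta_ij = mu + u_j + w_ij (+ moderator
shifts) with u_j ~ N(0, tau2_between) and w_ij ~ N(0, tau2_within), and
per-group raw scores simulated so that the observed summary statistics —
not injected g values — feed the effect-size module downstream. Optional
significance-based suppression models publication selection at the effect
level.

Defaults mirror the after-learning literature: 45 reports, ~130 effects,
mu = 0.277, tau2_between = 0.061, tau2_within = 0.026, 80% between-subject
designs, study total sample sizes centred near 32 with range 6-78.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import AnalysisConfig, EffectSizeRecord, StudyDataset
from .effects import compute_effect_table

__all__ = ["SimulationSpec", "ModeratorSpec", "simulate_dataset", "apply_selection"]


@dataclass
class ModeratorSpec:
    """Level probabilities and true effect shifts for one moderator."""

    levels: tuple[str, ...]
    probs: tuple[float, ...]
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must align")
        if not np.isclose(sum(self.probs), 1.0):
            raise ValueError("level probabilities must sum to 1")


_DEFAULT_MODERATORS: dict[str, ModeratorSpec] = {
    "recovery_sleep": ModeratorSpec(("yes", "no"), (85 / 130, 45 / 130)),
    "memory_type": ModeratorSpec(("declarative", "procedural"), (109 / 130, 21 / 130)),
    "task_type": ModeratorSpec(("recall", "recognition", "other"),
                               (42 / 130, 60 / 130, 28 / 130)),
    "emotionality": ModeratorSpec(("emotional", "neutral", "unreported"),
                                  (31 / 130, 20 / 130, 79 / 130)),
}


@dataclass
class SimulationSpec:
    """True parameters and structure of a simulated literature.

    n_total_range / n_total_mean / n_total_sd describe the study total
    sample size (split into two equal groups for between designs; the
    number of pairs for within designs), truncated-normal to match the
    observed 6-78 range with mean near 32.
    """

    n_reports: int = 45
    effects_per_report: tuple[int, int] = (1, 5)
    mu: float = 0.277
    tau2_between: float = 0.061
    tau2_within: float = 0.026
    n_total_range: tuple[int, int] = (6, 78)
    n_total_mean: float = 31.84
    n_total_sd: float = 13.15
    prop_between: float = 104 / 130
    moderators: dict[str, ModeratorSpec] = field(
        default_factory=lambda: dict(_DEFAULT_MODERATORS))
    r_within: float = 0.5
    selection: dict[str, float] | None = None  # {"p_threshold":…, "suppress_prob":…}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2_between < 0 or self.tau2_within < 0:
            raise ValueError("variance components must be non-negative")
        if not 0 <= self.prop_between <= 1:
            raise ValueError("prop_between must lie in [0, 1]")
        if self.effects_per_report[0] < 1 or self.effects_per_report[1] < self.effects_per_report[0]:
            raise ValueError("effects_per_report range is empty")
        if self.n_total_range[0] < 4:
            raise ValueError("smallest total sample size must be >= 4")


def _draw_total_n(spec: SimulationSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.n_total_range
    if lo == hi:
        return int(lo)
    a = (lo - spec.n_total_mean) / spec.n_total_sd
    b = (hi - spec.n_total_mean) / spec.n_total_sd
    val = stats.truncnorm.rvs(a, b, loc=spec.n_total_mean, scale=spec.n_total_sd,
                              random_state=rng)
    return int(round(val))


def simulate_dataset(spec: SimulationSpec,
                     compute_effects: bool = True) -> StudyDataset:
    """Generate one literature; reproducible for a given spec.seed.

    Summary statistics (means, SDs, group sizes) are simulated from raw
    normal scores so the effect-size computation path is exercised; when
    ``compute_effects`` is True the returned dataset already carries
    (g, v). True per-effect parameters are attached as ``ds.truth``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[EffectSizeRecord] = []
    truth_thetas: list[float] = []
    for j in range(spec.n_reports):
        report_id = f"r{j + 1:03d}"
        u_j = rng.normal(0.0, np.sqrt(spec.tau2_between))
        m_lo, m_hi = spec.effects_per_report
        n_eff = int(rng.integers(m_lo, m_hi + 1))
        design = "between" if rng.random() < spec.prop_between else "within"
        total_n = _draw_total_n(spec, rng)
        for i in range(n_eff):
            w_ij = rng.normal(0.0, np.sqrt(spec.tau2_within))
            mods = {}
            shift = 0.0
            for name, mspec in spec.moderators.items():
                level = str(rng.choice(mspec.levels, p=mspec.probs))
                mods[name] = level
                shift += mspec.shifts.get(level, 0.0)
            theta = spec.mu + u_j + w_ij + shift
            if design == "between":
                n1 = max(2, total_n // 2)
                n2 = max(2, total_n - n1)
                control = rng.normal(0.0, 1.0, n1)
                deprived = rng.normal(-theta, 1.0, n2)
                rec = EffectSizeRecord(
                    report_id=report_id, effect_id=f"{report_id}.{i + 1}",
                    design="between",
                    m1=float(control.mean()), sd1=float(control.std(ddof=1)), n1=n1,
                    m2=float(deprived.mean()), sd2=float(deprived.std(ddof=1)), n2=n2,
                    direction="higher_better", moderators=mods)
            else:
                n = max(2, total_n)
                r = spec.r_within
                cov = np.array([[1.0, r], [r, 1.0]])
                scores = rng.multivariate_normal([0.0, -theta], cov, size=n)
                rec = EffectSizeRecord(
                    report_id=report_id, effect_id=f"{report_id}.{i + 1}",
                    design="within",
                    m1=float(scores[:, 0].mean()), sd1=float(scores[:, 0].std(ddof=1)),
                    n1=n,
                    m2=float(scores[:, 1].mean()), sd2=float(scores[:, 1].std(ddof=1)),
                    r_within=r,
                    direction="higher_better", moderators=mods)
            records.append(rec)
            truth_thetas.append(theta)
    ds = StudyDataset(records, name=f"sim(seed={spec.seed})")
    if compute_effects:
        ds = compute_effect_table(ds, AnalysisConfig(default_r_within=spec.r_within))
    ds.truth = {  # type: ignore[attr-defined]
        "mu": spec.mu, "tau2_between": spec.tau2_between,
        "tau2_within": spec.tau2_within, "theta": truth_thetas,
        "seed": spec.seed,
    }
    if spec.selection is not None:
        ds = apply_selection(ds, spec.selection["p_threshold"],
                             spec.selection["suppress_prob"],
                             seed=spec.seed + 1)
    return ds


def apply_selection(ds: StudyDataset, p_threshold: float, suppress_prob: float,
                    seed: int = 0) -> StudyDataset:
    """Significance-based publication selection at the effect level.

    Each effect whose two-sided p (z = g/sqrt(v)) is >= p_threshold is
    independently removed with probability suppress_prob; reports whose
    effects all vanish drop out of the dataset.
    """
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for rec in ds.records:
        if rec.g is None or rec.v is None:
            raise ValueError("apply_selection requires computed (g, v); "
                             "run compute_effect_table first")
        p = 2.0 * stats.norm.sf(abs(rec.g) / np.sqrt(rec.v))
        if p >= p_threshold and rng.random() < suppress_prob:
            continue
        keep.append(rec.effect_id)
    if not keep:
        raise ValueError("selection suppressed every effect")
    out = ds.subset(keep, name=f"{ds.name}+selection")
    if hasattr(ds, "truth"):
        out.truth = dict(ds.truth)  # type: ignore[attr-defined]
    return out
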