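"""Standardized mean differences and their sampling variances.

Between-subjects designs use Cohen's d_s (pooled-SD standardisation);
within-subject designs use Cohen's d_av (standardised by the average of the
two condition SDs), whose sampling variance depends on the cross-condition
correlation r. Both are bias-corrected to Hedges' g with the usual
small-sample factor J = 1 - 3/(4·df - 1).

Sign convention: a positive g always means sleep deprivation worsened
performance relative to the sleep control. For "lower is better" outcomes
(e.g. reaction time) the raw difference is flipped during orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import AnalysisConfig, EffectSizeRecord, StudyDataset

__all__ = [
    "ComputedEffect",
    "cohens_d_between",
    "cohens_d_within_av",
    "hedges_correct",
    "select_outcome",
    "orient_sign",
    "compute_effect",
    "compute_effect_table",
    "DegenerateInputError",
    "OutcomeSelectionError",
]


class DegenerateInputError(ValueError):
    """Raised when summary statistics cannot yield an effect size."""


class OutcomeSelectionError(ValueError):
    """Raised when no candidate outcome has a recognised label."""


@dataclass(frozen=True)
class ComputedEffect:
    """An effect size with its variance and bias-correction bookkeeping.

    g is the (possibly corrected) effect; before `hedges_correct` is
    applied, g equals d_raw and J is 1.
    """

    g: float
    v: float
    d_raw: float
    J: float
    df: float


def cohens_d_between(m1: float, sd1: float, n1: int,
                     m2: float, sd2: float, n2: int) -> ComputedEffect:
    """Cohen's d_s for two independent groups, pre-bias-correction.

    d_s = (m1 - m2) / s_pooled with the df-weighted pooled SD, and
    v_d = (n1 + n2)/(n1 n2) + d_s² / (2 (n1 + n2)).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise DegenerateInputError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("each group needs n >= 2")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise DegenerateInputError("pooled SD is zero")
    d = (m1 - m2) / s_pooled
    v = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
    return ComputedEffect(g=d, v=v, d_raw=d, J=1.0, df=n1 + n2 - 2)


def cohens_d_within_av(m_diff: float, sd1: float, sd2: float,
                       n: int, r: float) -> ComputedEffect:
    """Cohen's d_av for a paired design, pre-bias-correction.

    d_av = m_diff / ((sd1 + sd2)/2); the variance uses the
    Morris–DeShon-style form v_d = (1/n + d_av²/(2n)) · 2(1 - r), which
    reduces to the independent-groups per-observation variance at r = 0.5.
    """
    if n < 2:
        raise DegenerateInputError("need at least 2 pairs")
    if not -1.0 <= r <= 1.0:
        raise DegenerateInputError(f"correlation r={r} outside [-1, 1]")
    s_av = (sd1 + sd2) / 2.0
    if s_av <= 0:
        raise DegenerateInputError("average SD is zero")
    d = m_diff / s_av
    v = (1.0 / n + d**2 / (2.0 * n)) * 2.0 * (1.0 - r)
    return ComputedEffect(g=d, v=v, d_raw=d, J=1.0, df=n - 1)


def hedges_correct(effect: ComputedEffect) -> ComputedEffect:
    """Apply the small-sample bias correction J = 1 - 3/(4 df - 1).

    Both the point estimate and (to first order) its variance shrink:
    g = J·d, v_g = J²·v_d.
    """
    if effect.df < 2:
        raise DegenerateInputError("bias correction requires df >= 2")
    J = 1.0 - 3.0 / (4.0 * effect.df - 1.0)
    return ComputedEffect(g=J * effect.d_raw, v=J**2 * effect.v,
                          d_raw=effect.d_raw, J=J, df=effect.df)


# Outcome-measure preference: accuracy before reaction time, retention
# (change from training to test) before test-only; within recognition
# tasks, signal-detection measures before proportion correct.
_OUTCOME_RANK = {
    "accuracy-retention": 0,
    "accuracy-at-test": 1,
    "rt-retention": 2,
    "rt-at-test": 3,
}
_RECOGNITION_RANK = {"d-prime": 0, "signal-detection": 0, "proportion-correct": 1}


def _outcome_label(candidate: object) -> str:
    if isinstance(candidate, str):
        return candidate
    if isinstance(candidate, (tuple, list)) and candidate:
        return str(candidate[0])
    label = getattr(candidate, "label", None)
    if label is not None:
        return str(label)
    raise OutcomeSelectionError(f"cannot extract an outcome label from {candidate!r}")


def select_outcome(candidates: Sequence[object]) -> object:
    """Pick the single outcome to meta-analyse when a task reports several.

    Candidates may be labels, ``(label, payload)`` pairs, or objects with a
    ``label`` attribute. Preference order: accuracy-retention >
    accuracy-at-test > rt-retention > rt-at-test; recognition-task labels
    rank signal-detection measures (d-prime) above proportion correct.
    Ties keep the earliest candidate.
    """
    if not candidates:
        raise OutcomeSelectionError("no candidate outcomes supplied")
    scored: list[tuple[int, int, object]] = []
    for pos, cand in enumerate(candidates):
        label = _outcome_label(cand).lower().replace("_", "-")
        if label in _OUTCOME_RANK:
            scored.append((_OUTCOME_RANK[label], pos, cand))
        elif label in _RECOGNITION_RANK:
            # signal-detection vs proportion-correct sits inside the
            # accuracy tier; rank below accuracy-retention labels.
            scored.append((10 + _RECOGNITION_RANK[label], pos, cand))
    if not scored:
        raise OutcomeSelectionError(
            f"no recognised outcome label among {[_outcome_label(c) for c in candidates]}")
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]


def orient_sign(effect: ComputedEffect, direction: str) -> ComputedEffect:
    """Orient the effect so positive g = deprivation impaired performance.

    Summary statistics are entered control-first (m1 = sleep control,
    m2 = deprivation, or m_diff = control - deprivation). On tasks where
    higher scores are better that raw difference is already positive when
    deprivation hurts; on "lower is better" outcomes such as reaction time
    the sign must be flipped. Variance is unchanged.
    """
    if direction == "higher_better":
        return effect
    if direction == "lower_better":
        return dataclasses.replace(effect, g=-effect.g, d_raw=-effect.d_raw)
    raise ValueError(f"unknown direction {direction!r}")


def compute_effect(rec: EffectSizeRecord, cfg: AnalysisConfig) -> ComputedEffect:
    """Full effect-size path for one record: d -> Hedges' g -> orientation."""
    if rec.has_precomputed():
        return ComputedEffect(g=rec.g, v=rec.v, d_raw=rec.g, J=1.0, df=np.inf)
    if rec.design == "between":
        eff = cohens_d_between(rec.m1, rec.sd1, rec.n1, rec.m2, rec.sd2, rec.n2)
    else:
        r = rec.r_within if rec.r_within is not None else cfg.default_r_within
        eff = cohens_d_within_av(rec.m1 - rec.m2, rec.sd1, rec.sd2, rec.n1, r)
    return orient_sign(hedges_correct(eff), rec.direction)


def compute_effect_table(ds: StudyDataset, cfg: AnalysisConfig | None = None) -> StudyDataset:
    """Fill (g, v) for every record; precomputed records pass through.

    Per-record errors are re-raised annotated with the effect_id.
    """
    cfg = cfg or AnalysisConfig()
    out: list[EffectSizeRecord] = []
    for rec in ds.records:
        if rec.has_precomputed():
            out.append(rec)
            continue
        try:
            eff = compute_effect(rec, cfg)
        except (DegenerateInputError, ValueError) as err:
            raise DegenerateInputError(f"effect {rec.effect_id}: {err}") from err
        out.append(dataclasses.replace(rec, g=float(eff.g), v=float(eff.v),
                                       moderators=dict(rec.moderators)))
    return StudyDataset(out, ds.name)
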