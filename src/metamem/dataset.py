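"""Dataset schema, validation and CSV round-trip for effect-size tables.

A study-level meta-analytic dataset is a flat table with one row per
observed effect. Effects are clustered by report (``report_id``): a single
publication typically contributes several correlated effects (multiple
tasks, conditions, or test sessions), which is what the three-level model
downstream accounts for. Each row carries either the per-group summary
statistics needed to compute a standardized mean difference, or a
precomputed effect size ``g`` with its sampling variance ``v``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "EffectSizeRecord",
    "StudyDataset",
    "AnalysisConfig",
    "DatasetValidationError",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "CSV_COLUMNS",
]

MODERATOR_NAMES = ("recovery_sleep", "memory_type", "task_type", "emotionality")
QUALITY_COLUMNS = tuple(f"q{i:02d}" for i in range(1, 23))

CSV_COLUMNS = (
    "report_id",
    "effect_id",
    "design",
    "m1",
    "sd1",
    "n1",
    "m2",
    "sd2",
    "n2",
    "r_within",
    "g",
    "v",
    "direction",
    *MODERATOR_NAMES,
    *QUALITY_COLUMNS,
)


class SchemaError(ValueError):
    """Raised when a CSV is missing mandatory columns."""


class DatasetValidationError(ValueError):
    """Raised when one or more rows violate record invariants.

    Carries ``errors``: a list of ``(row_label, message)`` pairs so the
    offending rows can be reported together rather than one at a time.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        lines = "; ".join(f"{label}: {msg}" for label, msg in errors)
        super().__init__(f"{len(errors)} invalid record(s): {lines}")


@dataclass
class EffectSizeRecord:
    """One observed effect with its provenance.

    Exactly one of two parameterisations must be complete: the per-group
    summary statistics (``m1, sd1, n1, m2, sd2`` and, for between designs,
    ``n2``), or a precomputed ``(g, v)`` pair. For within designs ``n1`` is
    the number of pairs and ``n2`` is ignored; ``r_within`` is the
    correlation between the two conditions (may be absent — the analysis
    config supplies a default).
    """

    report_id: str
    effect_id: str
    design: str  # "between" | "within"
    m1: float | None = None
    sd1: float | None = None
    n1: int | None = None
    m2: float | None = None
    sd2: float | None = None
    n2: int | None = None
    r_within: float | None = None
    g: float | None = None
    v: float | None = None
    direction: str = "higher_better"  # or "lower_better"
    moderators: dict[str, str] = field(default_factory=dict)
    quality_items: list[int] | None = None

    def has_summary_stats(self) -> bool:
        base = all(x is not None for x in (self.m1, self.sd1, self.n1, self.m2, self.sd2))
        if self.design == "between":
            return base and self.n2 is not None
        return base

    def has_precomputed(self) -> bool:
        return self.g is not None and self.v is not None

    def validate(self) -> list[str]:
        """Return a list of invariant-violation messages (empty if valid)."""
        errs: list[str] = []
        if self.design not in ("between", "within"):
            errs.append(f"unknown design {self.design!r}")
        if self.direction not in ("higher_better", "lower_better"):
            errs.append(f"unknown direction {self.direction!r}")
        if not (self.has_summary_stats() or self.has_precomputed()):
            errs.append("neither complete summary statistics nor (g, v) supplied")
        if self.v is not None and not self.v > 0:
            errs.append(f"sampling variance v={self.v} must be > 0")
        if self.g is not None and self.v is None:
            errs.append("g supplied without its sampling variance v")
        for label, sd in (("sd1", self.sd1), ("sd2", self.sd2)):
            if sd is not None and not sd > 0:
                errs.append(f"{label}={sd} must be > 0")
        for label, n in (("n1", self.n1), ("n2", self.n2)):
            if n is not None and n < 2:
                errs.append(f"{label}={n} must be >= 2")
        if self.r_within is not None and not -1.0 <= self.r_within <= 1.0:
            errs.append(f"r_within={self.r_within} outside [-1, 1]")
        if self.quality_items is not None:
            if len(self.quality_items) != 22:
                errs.append("quality_items must have exactly 22 entries")
            elif any(q not in (0, 1) for q in self.quality_items):
                errs.append("quality_items must be binary")
        # moderator names beyond the canonical four are allowed: continuous
        # covariates (quality clusters, per-study power) travel the same way
        return errs


@dataclass
class StudyDataset:
    """An ordered collection of effect-size records with a name."""

    records: list[EffectSizeRecord]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not self.records:
            raise DatasetValidationError([("dataset", "must contain at least one record")])
        seen: set[str] = set()
        errors: list[tuple[str, str]] = []
        for rec in self.records:
            if rec.effect_id in seen:
                errors.append((rec.effect_id, "duplicate effect_id"))
            seen.add(rec.effect_id)
            for msg in rec.validate():
                errors.append((rec.effect_id, msg))
        if errors:
            raise DatasetValidationError(errors)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EffectSizeRecord]:
        return iter(self.records)

    @property
    def n_clusters(self) -> int:
        return len({r.report_id for r in self.records})

    @property
    def cluster_ids(self) -> list[str]:
        """Distinct report ids in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.report_id not in seen:
                seen.add(r.report_id)
                out.append(r.report_id)
        return out

    def subset(self, keep: Iterable[str], name: str | None = None) -> "StudyDataset":
        keep = set(keep)
        recs = [dataclasses.replace(r, moderators=dict(r.moderators),
                                    quality_items=None if r.quality_items is None
                                    else list(r.quality_items))
                for r in self.records if r.effect_id in keep]
        return StudyDataset(recs, name or self.name)

    def drop(self, remove: Iterable[str], name: str | None = None) -> "StudyDataset":
        remove = set(remove)
        return self.subset([r.effect_id for r in self.records if r.effect_id not in remove],
                           name)


@dataclass
class AnalysisConfig:
    """Tunable analysis settings with conventional defaults.

    alpha / ci_level: significance level and CI coverage used everywhere.
    default_r_within: cross-condition correlation assumed for within-subject
        designs when a study does not report one (0.5 makes the within-design
        sampling variance equal the between-design per-observation variance).
    reml_tol: convergence tolerance for the REML variance-component search.
    trimfill_estimator / trimfill_side: Duval–Tweedie variant selection;
        side "auto" trims opposite the Egger slope sign.
    cooks_threshold_rule: "iqr" (median + 6·IQR heuristic) or a number for
        an absolute Cook's distance cutoff.
    """

    alpha: float = 0.05
    ci_level: float = 0.95
    default_r_within: float = 0.5
    reml_tol: float = 1e-8
    trimfill_estimator: str = "L0"
    trimfill_side: str = "auto"
    cooks_threshold_rule: str | float = "iqr"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.reml_tol <= 0:
            raise ValueError("reml_tol must be positive")
        if self.trimfill_estimator not in ("L0", "R0"):
            raise ValueError("trimfill_estimator must be 'L0' or 'R0'")
        if self.trimfill_side not in ("left", "right", "auto"):
            raise ValueError("trimfill_side must be 'left', 'right' or 'auto'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**(data or {}))


def _parse_float(cell: object) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    return float(cell)


def _parse_int(cell: object) -> int | None:
    val = _parse_float(cell)
    return None if val is None else int(val)


def read_dataset(path: str | Path, schema: Mapping[str, str] | None = None,
                 name: str | None = None) -> StudyDataset:
    """Read a CSV effect-size table into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row (UTF-8, comma-separated, "." decimals,
        empty cells for missing values).
    schema:
        Optional map from canonical column names to the names actually used
        in the file, for deposits with different headers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in CSV_COLUMNS}
    if schema:
        colmap.update(schema)
    mandatory = ("report_id", "design")
    missing = [c for c in mandatory if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    def get(row: pd.Series, col: str) -> object:
        actual = colmap[col]
        return row[actual] if actual in df.columns else ""

    records: list[EffectSizeRecord] = []
    per_report_counter: dict[str, int] = {}
    for idx, row in df.iterrows():
        report_id = str(get(row, "report_id"))
        effect_id = str(get(row, "effect_id"))
        if not effect_id:
            per_report_counter[report_id] = per_report_counter.get(report_id, 0) + 1
            effect_id = f"{report_id}.{per_report_counter[report_id]}"
        moderators = {m: str(get(row, m)) for m in MODERATOR_NAMES if str(get(row, m))}
        qvals = [get(row, q) for q in QUALITY_COLUMNS]
        quality = None if all(q == "" for q in qvals) else [int(float(q)) for q in qvals]
        rec = EffectSizeRecord(
            report_id=report_id,
            effect_id=effect_id,
            design=str(get(row, "design")),
            m1=_parse_float(get(row, "m1")),
            sd1=_parse_float(get(row, "sd1")),
            n1=_parse_int(get(row, "n1")),
            m2=_parse_float(get(row, "m2")),
            sd2=_parse_float(get(row, "sd2")),
            n2=_parse_int(get(row, "n2")),
            r_within=_parse_float(get(row, "r_within")),
            g=_parse_float(get(row, "g")),
            v=_parse_float(get(row, "v")),
            direction=str(get(row, "direction")) or "higher_better",
            moderators=moderators,
            quality_items=quality,
        )
        records.append(rec)
    try:
        return StudyDataset(records, name or path.stem)
    except DatasetValidationError as err:
        rownums = {r.effect_id: i + 2 for i, r in enumerate(records)}  # header = line 1
        annotated = [(f"row {rownums.get(label, '?')} ({label})", msg)
                     for label, msg in err.errors]
        raise DatasetValidationError(annotated) from None


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_dataset(ds: StudyDataset, path: str | Path) -> None:
    """Write a dataset as CSV with the stable canonical column order."""
    rows = []
    for rec in ds.records:
        row = {
            "report_id": rec.report_id,
            "effect_id": rec.effect_id,
            "design": rec.design,
            "m1": _fmt(rec.m1),
            "sd1": _fmt(rec.sd1),
            "n1": _fmt(rec.n1),
            "m2": _fmt(rec.m2),
            "sd2": _fmt(rec.sd2),
            "n2": _fmt(rec.n2),
            "r_within": _fmt(rec.r_within),
            "g": _fmt(rec.g),
            "v": _fmt(rec.v),
            "direction": rec.direction,
        }
        for m in MODERATOR_NAMES:
            row[m] = rec.moderators.get(m, "")
        for j, q in enumerate(QUALITY_COLUMNS):
            row[q] = "" if rec.quality_items is None else str(rec.quality_items[j])
        rows.append(row)
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
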