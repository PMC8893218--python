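"""Methodological-quality scoring: totals, normalisation, cluster subscores.

Each study is rated 0/1 on 22 checklist items. The total is normalised by
the maximum total achieved in the dataset (so the best-scoring study gets
1.0 and scores rank studies on a common scale), and items aggregate into
four cluster proportions — reporting, bias, confounding, power — used as
continuous moderators. The power cluster is computed but excluded from the
default moderator set, since most studies score zero on it.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset import StudyDataset, QUALITY_COLUMNS

__all__ = ["load_checklist", "default_cluster_map", "normalize_scores",
           "cluster_scores", "dataset_quality", "CLUSTERS"]

CLUSTERS = ("reporting", "bias", "confounding", "power")


def load_checklist(path: str | Path | None = None) -> list[dict[str, str]]:
    """Load the checklist definition (id, cluster, text) from YAML."""
    if path is None:
        text = resources.files("metamem").joinpath("data/checklist.yaml").read_text()
    else:
        text = Path(path).read_text()
    items = yaml.safe_load(text)["items"]
    ids = [it["id"] for it in items]
    if len(items) != 22 or ids != list(QUALITY_COLUMNS):
        raise ValueError("checklist must define items q01..q22 in order")
    return items


def default_cluster_map(path: str | Path | None = None) -> dict[str, str]:
    """item id -> cluster name, from the checklist definition."""
    return {it["id"]: it["cluster"] for it in load_checklist(path)}


def normalize_scores(totals: Sequence[int]) -> np.ndarray:
    """Divide each total by the dataset maximum (best study scores 1.0)."""
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ValueError("no totals supplied")
    if np.any((totals < 0) | (totals > 22)):
        raise ValueError("totals must lie in [0, 22]")
    top = totals.max()
    if top == 0:
        raise ValueError("all totals are zero: normalisation undefined")
    return totals / top


def cluster_scores(items: Sequence[int],
                   cluster_map: Mapping[str, str] | None = None) -> dict[str, float]:
    """Per-cluster pass proportion for one study's 22 binary items."""
    cluster_map = cluster_map or default_cluster_map()
    if len(items) != 22:
        raise ValueError("expected 22 binary items")
    unmapped = [q for q in QUALITY_COLUMNS if q not in cluster_map]
    if unmapped:
        raise ValueError(f"items without a cluster: {unmapped}")
    bad = sorted(set(cluster_map.values()) - set(CLUSTERS))
    if bad:
        raise ValueError(f"unknown cluster name(s): {bad}")
    out: dict[str, float] = {}
    for cl in CLUSTERS:
        members = [i for i, q in enumerate(QUALITY_COLUMNS) if cluster_map[q] == cl]
        out[cl] = float(np.mean([items[i] for i in members])) if members else np.nan
    return out


def dataset_quality(ds: StudyDataset,
                    cluster_map: Mapping[str, str] | None = None) -> dict[str, dict]:
    """Quality summary per effect: total, normalised total, cluster scores.

    Effects without quality items are omitted. Normalisation uses the
    maximum total among the scored effects in this dataset.
    """
    cluster_map = cluster_map or default_cluster_map()
    scored = [(r.effect_id, r.quality_items) for r in ds.records
              if r.quality_items is not None]
    if not scored:
        return {}
    totals = [sum(q) for _, q in scored]
    normed = normalize_scores(totals)
    out: dict[str, dict] = {}
    for (eid, items), total, norm in zip(scored, totals, normed):
        out[eid] = {"total": int(total), "normalized": float(norm),
                    "clusters": cluster_scores(items, cluster_map)}
    return out
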