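"""Selecting the best rule or combination of rules per quality.

A *combination* is a disjunction of up to 12 rules for one quality: a
molecule is described if it falls in the union of the member coverages.
Each combination is a point in the (error, recall) plane with
``error = 1 - precision``; the winner is the combination closest (Euclidean
distance) to the ideal point (error 0, recall 1).  Candidates within one
mining run are ranked by precision and combined as nested prefixes of that
ranking (the default, O(pool x 12) strategy); an exhaustive all-subsets
search is available as an oracle for small pools.

Qualities are then grouped by the half-plane conventions
(error < 0.5 vs >= 0.5, recall >= 0.5 vs < 0.5) and binned into quartiles
of the distance distribution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import OdorantDataset
from .measures import RuleMetrics, SORule, coverage_mask, evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "RuleCombination",
    "SelectionResult",
    "combination_metrics",
    "select_best",
    "classify_group",
    "assign_quartiles",
    "selection_report",
]

_DISTANCE_TIE_TOL = 1e-12


@dataclass
class RuleCombination:
    quality: frozenset[str]
    rules: tuple[SORule, ...]
    union_coverage: tuple[str, ...]
    precision: float
    recall: float
    error: float
    distance: float
    source_min_supp: int | None = None
    flags: tuple[str, ...] = ()


@dataclass
class SelectionResult:
    quality: frozenset[str]
    best: list[RuleCombination]
    group: int | None = None
    quartile: str | None = None
    flags: tuple[str, ...] = ()

    @property
    def distance(self) -> float:
        return self.best[0].distance if self.best else math.inf


def combination_metrics(
    rules: Sequence[SORule],
    qualities: Iterable[str],
    dataset: OdorantDataset,
    source_min_supp: int | None = None,
) -> RuleCombination:
    """Precision/recall/error/distance of a disjunction of rules on Q.

    Positives are molecules carrying every quality of Q; precision and
    recall are computed on the union of the member coverages.
    """
    rules = tuple(rules)
    if not (1 <= len(rules) <= 12):
        raise ValueError(f"a combination holds 1..12 rules, got {len(rules)}")
    q = frozenset(qualities)
    mask = np.zeros(dataset.n_molecules, dtype=bool)
    for rule in rules:
        mask |= coverage_mask(rule.description, dataset)
    pos = dataset.positives_mask(q)
    covered = int(mask.sum())
    hits = int((mask & pos).sum())
    support_q = int(pos.sum())
    flags: list[str] = []
    if covered:
        precision = hits / covered
    else:
        precision, flags = 0.0, ["empty_union_coverage"]
    recall = hits / support_q if support_q else 0.0
    if not support_q:
        flags.append("zero_support_q")
    error = 1.0 - precision
    distance = math.hypot(error, 1.0 - recall)
    ids = tuple(m for m, ok in zip(dataset.molecule_ids, mask) if ok)
    return RuleCombination(
        quality=q,
        rules=rules,
        union_coverage=ids,
        precision=precision,
        recall=recall,
        error=error,
        distance=distance,
        source_min_supp=source_min_supp,
        flags=tuple(flags),
    )


def _precision_order(
    rules: Sequence[SORule], q: frozenset[str], dataset: OdorantDataset
) -> list[SORule]:
    scored = []
    for rule in rules:
        m = evaluate(rule, dataset)
        scored.append((-m.precision, -m.support_d, len(rule.description), rule))
    scored.sort(key=lambda t: (t[0], t[1], t[2], t[3].description.sort_key()))
    return [t[3] for t in scored]


def select_best(
    candidates_per_run: Mapping[int, Sequence[SORule]],
    qualities: Iterable[str],
    dataset: OdorantDataset,
    max_rules: int = 12,
    strategy: str = "prefix",
) -> SelectionResult:
    """Pick the combination(s) with minimal distance to the ideal point.

    ``candidates_per_run`` maps a run identifier (typically its minSupp) to
    that run's candidate rules; combinations never mix rules from different
    runs.  ``strategy="prefix"`` evaluates nested prefixes of the
    precision-ranked candidates; ``"exhaustive"`` additionally evaluates all
    subsets (up to ``max_rules`` members) when a run's pool has <= 15 rules.
    All ties at the minimal distance are kept.
    """
    if strategy not in ("prefix", "exhaustive"):
        raise ValueError(f"strategy must be 'prefix' or 'exhaustive', got {strategy!r}")
    q = frozenset(qualities)
    combos: list[RuleCombination] = []
    for run_key in sorted(candidates_per_run):
        pool = list(candidates_per_run[run_key])
        if not pool:
            continue
        ordered = _precision_order(pool, q, dataset)
        for k in range(1, min(max_rules, len(ordered)) + 1):
            combos.append(
                combination_metrics(ordered[:k], q, dataset, source_min_supp=run_key)
            )
        if strategy == "exhaustive" and len(ordered) <= 15:
            for k in range(1, min(max_rules, len(ordered)) + 1):
                for subset in itertools.combinations(ordered, k):
                    combos.append(
                        combination_metrics(subset, q, dataset, source_min_supp=run_key)
                    )
    if not combos:
        logger.warning("no candidate rules for %s", sorted(q))
        return SelectionResult(quality=q, best=[], flags=("no_candidates",))
    best_d = min(c.distance for c in combos)
    best, seen = [], set()
    for c in combos:
        if c.distance <= best_d + _DISTANCE_TIE_TOL:
            sig = (c.source_min_supp, tuple(sorted(r.description.sort_key() for r in c.rules)))
            if sig not in seen:
                seen.add(sig)
                best.append(c)
    group = classify_group(best[0].error, best[0].recall)
    return SelectionResult(quality=q, best=best, group=group)


def classify_group(error: float, recall: float) -> int:
    """Half-plane group of an (error, recall) point.

    Group 1: error < 0.5 and recall >= 0.5 (good rules);
    group 2: error < 0.5, recall < 0.5; group 3: error >= 0.5,
    recall >= 0.5; group 4: error >= 0.5, recall < 0.5.
    """
    if not (0.0 <= error <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError(f"error/recall must lie in [0,1], got ({error}, {recall})")
    if error < 0.5:
        return 1 if recall >= 0.5 else 2
    return 3 if recall >= 0.5 else 4


def assign_quartiles(results: Sequence[SelectionResult]) -> dict[frozenset[str], str]:
    """Bin qualities into distance quartiles Q1 (closest to ideal) .. Q4.

    Thresholds are the 25/50/75 linear-interpolation percentiles of the
    best distances; a quality is assigned the lowest quartile whose
    threshold its distance does not exceed, so exact ties share a bin.
    """
    if len(results) < 4:
        logger.warning("fewer than 4 qualities: assigning all to Q1")
        for r in results:
            r.quartile = "Q1"
        return {r.quality: "Q1" for r in results}
    distances = np.array([r.distance for r in results])
    t25, t50, t75 = np.percentile(distances, [25, 50, 75])
    out = {}
    for r in results:
        d = r.distance
        r.quartile = "Q1" if d <= t25 else "Q2" if d <= t50 else "Q3" if d <= t75 else "Q4"
        out[r.quality] = r.quartile
    return out


def selection_report(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Flat per-quality table of the best combination (first of any ties)."""
    rows = []
    for r in results:
        if not r.best:
            rows.append({"quality": "+".join(sorted(r.quality)), "n_rules": 0})
            continue
        c = r.best[0]
        rows.append(
            {
                "quality": "+".join(sorted(r.quality)),
                "n_rules": len(c.rules),
                "precision": c.precision,
                "recall": c.recall,
                "error": c.error,
                "distance": c.distance,
                "group": r.group,
                "quartile": r.quartile,
                "source_minSupp": c.source_min_supp,
                "n_ties": len(r.best),
            }
        )
    return pd.DataFrame(rows)
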