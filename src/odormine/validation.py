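"""External validation of rulesets on independently rated odorant panels.

A rated panel is a set of novel molecules with the same descriptor schema
plus continuous per-quality ratings (e.g. 0-100 applicability scores).
For a quality's selected ruleset we split the panel into molecules that
satisfy the rules (Rule(1)) and those that do not (Rule(0)) and run a
one-way fixed-effects ANOVA on the ratings, reporting F, p and the effect
size eta-squared = SS_between / SS_total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import OdorantDataset
from .measures import SORule, coverage_mask
from .selection import RuleCombination

logger = logging.getLogger(__name__)

__all__ = [
    "RatedPanel",
    "AnovaResult",
    "load_panel",
    "apply_ruleset",
    "one_way_anova",
    "validate_panel",
]

RATING_PREFIX = "rating:"


@dataclass
class RatedPanel:
    """Novel odorants: descriptor matrix + continuous quality ratings."""

    dataset: OdorantDataset
    ratings: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for q, scores in self.ratings.items():
            scores = np.asarray(scores, dtype=float)
            if scores.shape != (self.dataset.n_molecules,):
                raise ValueError(
                    f"ratings for {q!r} must have one score per molecule"
                )
            self.ratings[q] = scores

    @property
    def molecule_ids(self) -> list[str]:
        return self.dataset.molecule_ids


@dataclass
class AnovaResult:
    quality: str
    n_rule1: int
    n_rule0: int
    mean_rule1: float
    mean_rule0: float
    F: float
    df: tuple[int, int]
    p: float
    eta_squared: float


def load_panel(path: str | Path) -> RatedPanel:
    """Load a panel CSV: an ``id`` column, descriptor columns, and one
    ``rating:<quality>`` column per rated quality."""
    df = pd.read_csv(path)
    id_col = df.columns[0]
    rating_cols = [c for c in df.columns if str(c).startswith(RATING_PREFIX)]
    desc_cols = [c for c in df.columns[1:] if c not in rating_cols]
    ids = [str(v) for v in df[id_col]]
    dataset = OdorantDataset(
        molecule_ids=ids,
        descriptor_names=[str(c) for c in desc_cols],
        values=df[desc_cols].to_numpy(dtype=float),
        labels={m: frozenset() for m in ids},
    )
    ratings = {
        str(c)[len(RATING_PREFIX):]: df[c].to_numpy(dtype=float) for c in rating_cols
    }
    return RatedPanel(dataset=dataset, ratings=ratings)


def _descriptions(ruleset) -> list:
    if isinstance(ruleset, RuleCombination):
        return [r.description for r in ruleset.rules]
    out = []
    for r in ruleset:
        out.append(r.description if isinstance(r, SORule) else r)
    return out


def apply_ruleset(ruleset, panel: RatedPanel | OdorantDataset) -> tuple[np.ndarray, list[str]]:
    """Rule(1)/Rule(0) membership of each panel molecule.

    A molecule is Rule(1) iff it lies in the union coverage of the ruleset.
    Missing descriptor *values* make a molecule Rule(0) (reported in the
    returned flag list); a missing descriptor *column* is a hard error.
    """
    dataset = panel.dataset if isinstance(panel, RatedPanel) else panel
    descs = _descriptions(ruleset)
    needed = {c.descriptor for d in descs for c in d.conditions}
    gap = sorted(needed - set(dataset.descriptor_names))
    if gap:
        raise KeyError(f"panel is missing descriptor column(s): {gap}")
    mask = np.zeros(dataset.n_molecules, dtype=bool)
    for d in descs:
        mask |= coverage_mask(d, dataset)
    # flag molecules excluded while missing a value on a restricted descriptor
    flagged = []
    if needed:
        idx = [dataset.descriptor_index(n) for n in sorted(needed)]
        has_nan = np.isnan(dataset.values[:, idx]).any(axis=1)
        flagged = [
            m for m, ok, nan in zip(dataset.molecule_ids, mask, has_nan)
            if (not ok) and nan
        ]
    return mask, flagged


def one_way_anova(
    scores: Sequence[float], membership: Sequence[bool], quality: str = ""
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of ratings across Rule(1)/Rule(0).

    ``F = (SS_between / 1) / (SS_within / (n - 2))`` with p from the
    F(1, n-2) distribution and ``eta_squared = SS_between / SS_total``.
    Zero within-group variance with unequal means reports F = inf, p = 0.
    """
    scores = np.asarray(scores, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    if scores.shape != membership.shape:
        raise ValueError("scores and membership must align")
    g1, g0 = scores[membership], scores[~membership]
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both Rule(1) and Rule(0) groups must be non-empty")
    n = scores.size
    grand = scores.mean()
    ss_between = g1.size * (g1.mean() - grand) ** 2 + g0.size * (g0.mean() - grand) ** 2
    ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g0 - g0.mean()) ** 2).sum()
    ss_total = ss_between + ss_within
    df = (1, n - 2)
    if ss_within == 0:
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = ss_between / (ss_within / df[1])
        p = float(stats.f.sf(f_stat, *df))
    eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
    return AnovaResult(
        quality=quality,
        n_rule1=int(g1.size),
        n_rule0=int(g0.size),
        mean_rule1=float(g1.mean()),
        mean_rule0=float(g0.mean()),
        F=float(f_stat),
        df=df,
        p=p,
        eta_squared=float(eta_sq),
    )


def validate_panel(
    rulesets: Mapping[str, object],
    panel: RatedPanel,
    min_rule1: int = 5,
    alias: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Apply each quality's ruleset to the panel and ANOVA its ratings.

    ``alias`` optionally maps a ruleset quality name to the panel's rated
    quality name (vocabularies rarely align across atlases).  Qualities
    with fewer than ``min_rule1`` Rule(1) molecules are skipped (logged),
    matching the usual minimum-group-size practice.  Returns a tidy table
    with one row per tested quality, including group means and SEMs for
    plotting.
    """
    alias = dict(alias or {})
    rows = []
    for rq, ruleset in rulesets.items():
        pq = alias.get(rq, rq)
        if pq not in panel.ratings:
            logger.info("quality %r not rated in panel; skipped", pq)
            continue
        mask, flagged = apply_ruleset(ruleset, panel)
        n1 = int(mask.sum())
        if flagged:
            logger.info("%d molecule(s) Rule(0) due to missing values: %s", len(flagged), flagged)
        if n1 < min_rule1:
            logger.warning(
                "quality %r: only %d Rule(1) molecule(s) (< %d); skipped", pq, n1, min_rule1
            )
            continue
        if n1 == panel.dataset.n_molecules:
            logger.warning("quality %r: every molecule is Rule(1); skipped", pq)
            continue
        scores = panel.ratings[pq]
        res = one_way_anova(scores, mask, quality=pq)
        g1, g0 = scores[mask], scores[~mask]
        rows.append(
            {
                "quality": rq,
                "panel_quality": pq,
                "n_rule1": res.n_rule1,
                "n_rule0": res.n_rule0,
                "mean_rule1": res.mean_rule1,
                "mean_rule0": res.mean_rule0,
                "sem_rule1": float(g1.std(ddof=1) / math.sqrt(g1.size)) if g1.size > 1 else np.nan,
                "sem_rule0": float(g0.std(ddof=1) / math.sqrt(g0.size)) if g0.size > 1 else np.nan,
                "F": res.F,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "eta_squared": res.eta_squared,
            }
        )
    if not rows:
        logger.warning("no shared qualities between rulesets and panel ratings")
    return pd.DataFrame(rows)
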