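"""Bootstrap confidence-interval significance of a selected ruleset.

A ruleset for quality Q covers X molecules.  The null model asks: how good
an F-measure would a *random* set of X molecules achieve for Q?  We draw X
molecule IDs uniformly with replacement from the whole dataset, compute
the F-measure of each resample, and build an empirical percentile
confidence interval (99% by default).  The ruleset is significant when its
observed F-measure exceeds the upper CI bound (one-sided, as only
better-than-chance matters).

Under resampling with replacement the recall numerator uses *distinct*
drawn positives (capped at 1); a duplicate-counting variant is available
behind ``duplicate_recall=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import OdorantDataset
from .measures import SORule, beta_weight, coverage_mask, f_beta_combine
from .selection import RuleCombination, SelectionResult

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "bootstrap_ci", "batch_significance"]


@dataclass
class BootstrapResult:
    quality: frozenset[str]
    coverage_size_x: int
    n_resamples: int
    ci_level: float
    ci_low: float
    ci_high: float
    observed_f: float
    significant: bool
    seed: int
    measure: str


def _union_mask(ruleset, dataset: OdorantDataset) -> np.ndarray:
    if isinstance(ruleset, RuleCombination):
        ids = set(ruleset.union_coverage)
        return np.array([m in ids for m in dataset.molecule_ids], dtype=bool)
    mask = np.zeros(dataset.n_molecules, dtype=bool)
    for rule in ruleset:
        desc = rule.description if isinstance(rule, SORule) else rule
        mask |= coverage_mask(desc, dataset)
    return mask


def null_f_samples(
    pos_mask: np.ndarray,
    x: int,
    support_q: int,
    n_resamples: int,
    rng: np.random.Generator,
    beta: float,
    duplicate_recall: bool = False,
    batch_size: int = 20_000,
) -> np.ndarray:
    """F-measures of random with-replacement samples of ``x`` molecules."""
    n = pos_mask.size
    out = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        b = min(batch_size, n_resamples - done)
        draws = rng.integers(0, n, size=(b, x))
        hit = pos_mask[draws]
        k = hit.sum(axis=1)  # multiset positive count
        if duplicate_recall:
            numer = k
        else:
            # distinct positive IDs per row: sort positives, count transitions
            s = np.sort(np.where(hit, draws, -1), axis=1)
            numer = (s[:, 0] >= 0).astype(np.int64)
            if x > 1:
                numer += ((s[:, 1:] != s[:, :-1]) & (s[:, 1:] >= 0)).sum(axis=1)
        precision = k / x
        recall = np.minimum(numer / support_q, 1.0)
        denom = beta * precision + recall
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, (1.0 + beta) * precision * recall / denom, 0.0)
        out[done : done + b] = f
        done += b
    return out


def bootstrap_ci(
    dataset: OdorantDataset,
    ruleset,
    qualities: Iterable[str],
    n_resamples: int = 100_000,
    ci_level: float = 0.99,
    seed: int = 0,
    measure: str = "fbeta",
    x_beta: float = 110.0,
    l_beta: float = 20.0,
    duplicate_recall: bool = False,
) -> BootstrapResult:
    """Percentile-CI significance test of one ruleset's F-measure.

    ``ruleset`` may be a :class:`RuleCombination`, a sequence of rules, or
    a sequence of bare descriptions; the union of their coverages defines
    X.  ``measure`` is ``"fbeta"`` (the adaptive F-beta used in mining,
    with beta taken at support(Q)) or ``"f1"``.
    """
    if measure not in ("fbeta", "f1"):
        raise ValueError(f"measure must be 'fbeta' or 'f1', got {measure!r}")
    if not (0.0 < ci_level < 1.0):
        raise ValueError(f"ci_level must be in (0,1), got {ci_level}")
    if n_resamples < 100:
        logger.warning("n_resamples=%d is very small; CI will be noisy", n_resamples)
    q = frozenset(qualities)
    pos = dataset.positives_mask(q)
    support_q = int(pos.sum())
    if support_q == 0:
        raise ValueError(f"quality {sorted(q)} has zero support in the dataset")
    mask = _union_mask(ruleset, dataset)
    x = int(mask.sum())
    if x == 0:
        raise ValueError("ruleset union coverage is empty")

    beta = beta_weight(support_q, x_beta, l_beta) if measure == "fbeta" else 1.0
    hits = int((mask & pos).sum())
    obs_p = hits / x
    obs_r = min(hits / support_q, 1.0)
    observed_f = f_beta_combine(obs_p, obs_r, beta)

    rng = np.random.default_rng(seed)
    samples = null_f_samples(
        pos, x, support_q, n_resamples, rng, beta, duplicate_recall
    )
    alpha = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.percentile(samples, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(
        quality=q,
        coverage_size_x=x,
        n_resamples=n_resamples,
        ci_level=ci_level,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        observed_f=observed_f,
        significant=bool(observed_f > ci_high),
        seed=seed,
        measure=measure,
    )


def batch_significance(
    results: Sequence[SelectionResult],
    dataset: OdorantDataset,
    n_resamples: int = 100_000,
    ci_level: float = 0.99,
    seed: int = 0,
    measure: str = "fbeta",
    x_beta: float = 110.0,
    l_beta: float = 20.0,
) -> pd.DataFrame:
    """Run :func:`bootstrap_ci` per selected quality (first best combination).

    Per-quality seeds are derived deterministically from the master seed;
    per-quality failures are logged and reported as NaN rows rather than
    aborting the batch.
    """
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=len(results))
    rows = []
    for res, sub_seed in zip(results, seeds):
        name = "+".join(sorted(res.quality))
        if not res.best:
            logger.warning("no selected combination for %s; skipping", name)
            continue
        try:
            b = bootstrap_ci(
                dataset,
                res.best[0],
                res.quality,
                n_resamples=n_resamples,
                ci_level=ci_level,
                seed=int(sub_seed),
                measure=measure,
                x_beta=x_beta,
                l_beta=l_beta,
            )
            rows.append(
                {
                    "quality": name,
                    "X": b.coverage_size_x,
                    "observed_F": b.observed_f,
                    "ci_low": b.ci_low,
                    "ci_high": b.ci_high,
                    "significant": b.significant,
                    "seed": b.seed,
                    "n_resamples": b.n_resamples,
                    "measure": b.measure,
                }
            )
        except ValueError as exc:
            logger.warning("bootstrap failed for %s: %s", name, exc)
            rows.append({"quality": name, "X": np.nan, "observed_F": np.nan})
    return pd.DataFrame(rows)
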