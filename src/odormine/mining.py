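"""Beam-search mining of interval-pattern structure-odor rules.

For each target quality set Q the miner searches the space of interval
descriptions (axis-aligned boxes over descriptor columns), scoring each
candidate by the adaptive F-beta of the rule D -> Q.  The search is a
breadth-limited beam over a refinement lattice:

* the root is the unrestricted description (covers every molecule);
* a refinement minimally shrinks one bound of one descriptor to the next
  grid value inside the current coverage (introducing a condition on a new
  descriptor counts toward ``max_properties``);
* candidates below ``min_supp`` coverage are pruned, candidates whose
  coverage set was already visited are deduplicated, and the ``beam_width``
  best (by F-beta, with deterministic tie-breaking) seed the next level;
* the search ends when the beam can produce no coverage set not seen
  before — every refinement strictly shrinks coverage, so this always
  terminates.  ``max_stall`` optionally stops earlier after that many
  consecutive levels without improving the best score (useful at corpus
  scale).

The refinement grid is either every observed value of a descriptor
(``"observed"``, exact but fine-grained) or the descriptor's empirical
quantiles (``"quantiles:K"``, coarser and faster on large data).

The miner uses no randomness: results are a deterministic function of the
dataset content and the configuration, and invariant to row order.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .dataset import OdorantDataset
from .measures import (
    Condition,
    Description,
    RuleMetrics,
    SORule,
    beta_weight,
    coverage_mask,
    evaluate,
    f_beta_combine,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MinerConfig",
    "MiningRun",
    "enumerate_targets",
    "refinements",
    "mine",
    "mine_all",
    "ruleset_to_json",
    "ruleset_from_json",
    "save_runs",
    "load_runs",
]

#: printed-parameter-name aliases accepted in YAML config files
_YAML_ALIASES = {
    "maxoutput": "max_output",
    "beamwidth": "beam_width",
    "maxqual": "max_qual",
    "maxproperties": "max_properties",
    "maxprop": "max_properties",
    "maxsupp": "max_supp",
    "minsupp": "min_supp",
    "xbeta": "x_beta",
    "lbeta": "l_beta",
    "ibeta": "l_beta",  # common transcription of lBeta
}


@dataclass(frozen=True)
class MinerConfig:
    """Mining parameters.

    Defaults are the reference study settings: ``max_output=100``,
    ``beam_width=30``, ``max_qual=1``, ``max_properties=8``,
    ``max_supp=700``, ``x_beta=110``, ``l_beta=20``, ``min_supp=5``.
    """

    min_supp: int = 5
    max_supp: int = 700
    max_qual: int = 1
    max_properties: int = 8
    beam_width: int = 30
    max_output: int = 100
    x_beta: float = 110.0
    l_beta: float = 20.0
    beta_direction: str = "increasing"
    refinement_grid: str = "observed"
    max_stall: int | None = None
    seed: int = 0  # reserved for stochastic extensions; unused by the miner

    def __post_init__(self) -> None:
        if not (0 < self.min_supp <= self.max_supp):
            raise ValueError("need 0 < min_supp <= max_supp")
        for name in ("max_qual", "max_properties", "beam_width", "max_output"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.refinement_grid != "observed" and not self.refinement_grid.startswith(
            "quantiles:"
        ):
            raise ValueError(
                "refinement_grid must be 'observed' or 'quantiles:<k>', "
                f"got {self.refinement_grid!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MinerConfig":
        """Load a config whose keys may use the printed parameter spellings
        (maxoutput, beamwidth, MaxQual, MaxProperties, maxSupp, XBeta, lBeta,
        minSupp) or the pythonic field names."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        for key, value in raw.items():
            norm = str(key).strip()
            pythonic = norm.lower().replace("-", "_")
            target = _YAML_ALIASES.get(pythonic.replace("_", ""), None)
            if target is None:
                target = pythonic if pythonic in valid else None
            if target is None:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[target] = value
        return cls(**kwargs)

    def provenance(self) -> tuple[tuple[str, object], ...]:
        return tuple(sorted(asdict(self).items()))


@dataclass
class MiningRun:
    """Result of one mining call: ranked rules plus a per-level trace."""

    config: MinerConfig
    target: frozenset[str]
    rules: list[tuple[SORule, RuleMetrics]]
    trace: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Target enumeration


def enumerate_targets(
    dataset: OdorantDataset, max_qual: int = 1, min_supp: int = 1
) -> list[frozenset[str]]:
    """All non-empty quality sets Q with |Q| <= max_qual and support >= min_supp,
    in lexicographic order of the sorted label tuples."""
    if max_qual < 1:
        raise ValueError("max_qual must be >= 1")
    vocab = sorted(dataset.quality_vocabulary)
    out: list[frozenset[str]] = []
    for size in range(1, max_qual + 1):
        for combo in itertools.combinations(vocab, size):
            q = frozenset(combo)
            if dataset.support(q) >= min_supp:
                out.append(q)
    out.sort(key=lambda q: (len(q), tuple(sorted(q))))
    return out


# ---------------------------------------------------------------------------
# Refinement operator


def _build_grids(dataset: OdorantDataset, refinement_grid: str) -> list[np.ndarray]:
    grids = []
    for j in range(dataset.n_descriptors):
        col = dataset.values[:, j]
        finite = col[~np.isnan(col)]
        if finite.size == 0:
            grids.append(np.empty(0))
            continue
        if refinement_grid == "observed":
            grids.append(np.unique(finite))
        else:
            k = int(refinement_grid.split(":", 1)[1])
            qs = np.nanquantile(finite, np.linspace(0.0, 1.0, k + 1))
            grids.append(np.unique(qs))
    return grids


def _candidate_conditions(
    values: np.ndarray,
    mask: np.ndarray,
    conds: dict[int, tuple[float, float]],
    grids: list[np.ndarray],
    max_properties: int,
) -> list[tuple[int, float, float]]:
    """Minimal one-step shrinks of the description with condition map `conds`.

    Returns (descriptor index, new lo, new hi) triples.  Each emitted
    candidate strictly shrinks the coverage: the rows attaining the current
    covered minimum (resp. maximum) of the touched descriptor fall out.
    """
    out: list[tuple[int, float, float]] = []
    n_desc = values.shape[1]
    covered = values[mask]
    for j in range(n_desc):
        restricted = j in conds
        if not restricted and len(conds) >= max_properties:
            continue
        col = covered[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        cmin, cmax = float(col.min()), float(col.max())
        if cmin == cmax:
            continue  # single distinct value: nothing to shrink
        grid = grids[j]
        lo_cur, hi_cur = conds.get(j, (cmin, cmax))
        # shrink the lower bound up to the next grid value
        i = int(np.searchsorted(grid, cmin, side="right"))
        if i < grid.size and grid[i] <= cmax:
            out.append((j, float(grid[i]), hi_cur if restricted else cmax))
        # shrink the upper bound down to the previous grid value
        i = int(np.searchsorted(grid, cmax, side="left")) - 1
        if i >= 0 and grid[i] >= cmin:
            out.append((j, lo_cur if restricted else cmin, float(grid[i])))
    return out


def refinements(
    description: Description,
    dataset: OdorantDataset,
    max_properties: int = 8,
    refinement_grid: str = "observed",
) -> list[Description]:
    """All minimal one-step specializations of a description.

    For each descriptor, either the lower bound is raised to the next grid
    value inside the current coverage or the upper bound is lowered to the
    previous one; a condition on a previously unrestricted descriptor counts
    toward ``max_properties``.  No refinement empties the coverage.
    """
    grids = _build_grids(dataset, refinement_grid)
    mask = coverage_mask(description, dataset)
    conds = {
        dataset.descriptor_index(c.descriptor): (c.lo, c.hi)
        for c in description.conditions
    }
    out = []
    for j, lo, hi in _candidate_conditions(
        dataset.values, mask, conds, grids, max_properties
    ):
        name = dataset.descriptor_names[j]
        new = {c.descriptor: (c.lo, c.hi) for c in description.conditions}
        new[name] = (lo, hi)
        out.append(
            Description(tuple(Condition(d, *b) for d, b in sorted(new.items())))
        )
    return out


# ---------------------------------------------------------------------------
# Beam search


def _conds_sort_key(
    conds: dict[int, tuple[float, float]], names: Sequence[str]
) -> tuple:
    return tuple(sorted((names[j], lo, hi) for j, (lo, hi) in conds.items()))


def mine(
    dataset: OdorantDataset,
    qualities: Iterable[str],
    config: MinerConfig = MinerConfig(),
) -> MiningRun:
    """Beam-search the best rules D -> Q under the configured constraints.

    Returns up to ``max_output`` rules with ``min_supp <= support(D) <=
    max_supp`` and at most ``max_properties`` restricted descriptors, ranked
    by F-beta descending (ties: larger support, fewer conditions, then
    lexicographic on the condition triples).  ``max_supp`` is enforced on
    emitted rules only; broad intermediate candidates stay in the beam.
    """
    q = frozenset(str(s) for s in qualities)
    unknown = q - dataset.quality_vocabulary
    if unknown:
        raise KeyError(f"qualities {sorted(unknown)} not in the dataset vocabulary")

    values = dataset.values
    n = dataset.n_molecules
    names = dataset.descriptor_names
    pos = dataset.positives_mask(q)
    support_q = int(pos.sum())
    beta = beta_weight(support_q, config.x_beta, config.l_beta, config.beta_direction)
    grids = _build_grids(dataset, config.refinement_grid)

    def score(mask: np.ndarray) -> tuple[float, int, int]:
        supp = int(mask.sum())
        hits = int((mask & pos).sum())
        p = hits / supp if supp else 0.0
        r = hits / support_q if support_q else 0.0
        return f_beta_combine(p, r, beta), supp, hits

    def cov_key(mask: np.ndarray) -> bytes:
        return np.packbits(mask).tobytes()

    # beam entries: (conds dict, mask, fbeta, supp, hits)
    root_mask = np.ones(n, dtype=bool)
    root_f, root_supp, root_hits = score(root_mask)
    beam = [({}, root_mask, root_f, root_supp, root_hits)]
    visited = {cov_key(root_mask)}
    # pool of emitted candidates keyed by coverage (one description per
    # distinct coverage — the first, which the tie-break ranked highest)
    pool: list[tuple[dict, float, int, int]] = []
    if config.min_supp <= root_supp <= config.max_supp:
        pool.append(({}, root_f, root_supp, root_hits))

    best_f = root_f
    stall = 0
    trace: list[dict] = []
    while beam:
        level: list[tuple[dict, np.ndarray, float, int, int]] = []
        for conds, mask, _, _, _ in beam:
            for j, lo, hi in _candidate_conditions(
                values, mask, conds, grids, config.max_properties
            ):
                col = values[:, j]
                with np.errstate(invalid="ignore"):
                    new_mask = mask & (col >= lo) & (col <= hi)
                supp = int(new_mask.sum())
                if supp < config.min_supp:
                    continue
                key = cov_key(new_mask)
                if key in visited:
                    continue
                visited.add(key)
                new_conds = dict(conds)
                new_conds[j] = (lo, hi)
                f, supp, hits = score(new_mask)
                level.append((new_conds, new_mask, f, supp, hits))
        if not level:
            break
        level.sort(
            key=lambda e: (-e[2], -e[3], len(e[0]), _conds_sort_key(e[0], names))
        )
        for conds, mask, f, supp, hits in level:
            if supp <= config.max_supp:
                pool.append((conds, f, supp, hits))
        beam = level[: config.beam_width]
        level_best = level[0][2]
        trace.append(
            {
                "candidates": len(level),
                "beam": len(beam),
                "best_f_beta": level_best,
            }
        )
        if level_best > best_f:
            best_f = level_best
            stall = 0
        else:
            stall += 1
            if config.max_stall is not None and stall >= config.max_stall:
                break

    pool.sort(key=lambda e: (-e[1], -e[2], len(e[0]), _conds_sort_key(e[0], names)))
    rules: list[tuple[SORule, RuleMetrics]] = []
    for conds, f, supp, hits in pool[: config.max_output]:
        desc = Description(
            tuple(
                Condition(names[j], lo, hi)
                for j, (lo, hi) in sorted(conds.items(), key=lambda kv: names[kv[0]])
            )
        )
        rule = SORule(desc, q, provenance=config.provenance())
        p = hits / supp if supp else 0.0
        r = hits / support_q if support_q else 0.0
        metrics = RuleMetrics(
            support_d=supp,
            positives_in_coverage=hits,
            support_q=support_q,
            precision=p,
            recall=r,
            f1=f_beta_combine(p, r, 1.0),
            f_beta=f,
            beta=beta,
            flags=() if support_q else ("zero_support_q",),
        )
        rules.append((rule, metrics))
    return MiningRun(config=config, target=q, rules=rules, trace=trace)


def mine_all(
    dataset: OdorantDataset, config: MinerConfig = MinerConfig()
) -> dict[frozenset[str], MiningRun]:
    """Mine every eligible target quality set; per-target errors are logged
    and skipped rather than aborting the batch."""
    runs: dict[frozenset[str], MiningRun] = {}
    for q in enumerate_targets(dataset, config.max_qual, config.min_supp):
        try:
            runs[q] = mine(dataset, q, config)
            logger.info(
                "mined %s: %d rule(s)", "+".join(sorted(q)), len(runs[q].rules)
            )
        except Exception:  # pragma: no cover - defensive batch behavior
            logger.exception("mining failed for target %s", sorted(q))
    return runs


# ---------------------------------------------------------------------------
# Serialization (rule JSON schema)


def ruleset_to_json(rules: Sequence[tuple[SORule, RuleMetrics]]) -> list[dict]:
    out = []
    for rule, m in rules:
        out.append(
            {
                "quality": sorted(rule.qualities),
                "conditions": [
                    {"descriptor": c.descriptor, "lo": c.lo, "hi": c.hi}
                    for c in rule.description.conditions
                ],
                "metrics": {
                    "support": m.support_d,
                    "positives": m.positives_in_coverage,
                    "support_q": m.support_q,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "f_beta": m.f_beta,
                    "beta": m.beta,
                },
                "provenance": {k: v for k, v in rule.provenance},
            }
        )
    return out


def ruleset_from_json(data: Sequence[Mapping]) -> list[tuple[SORule, RuleMetrics]]:
    out = []
    for entry in data:
        desc = Description(
            tuple(
                Condition(c["descriptor"], float(c["lo"]), float(c["hi"]))
                for c in entry["conditions"]
            )
        )
        rule = SORule(
            desc,
            frozenset(entry["quality"]),
            provenance=tuple(sorted(entry.get("provenance", {}).items())),
        )
        m = entry["metrics"]
        metrics = RuleMetrics(
            support_d=int(m["support"]),
            positives_in_coverage=int(m["positives"]),
            support_q=int(m["support_q"]),
            precision=float(m["precision"]),
            recall=float(m["recall"]),
            f1=float(m["f1"]),
            f_beta=float(m["f_beta"]),
            beta=float(m["beta"]),
        )
        out.append((rule, metrics))
    return out


def save_runs(runs: Mapping[frozenset[str], MiningRun], path: str | Path) -> None:
    payload = {
        "+".join(sorted(q)): ruleset_to_json(run.rules) for q, run in runs.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_runs(path: str | Path) -> dict[frozenset[str], list[tuple[SORule, RuleMetrics]]]:
    payload = json.loads(Path(path).read_text())
    return {
        frozenset(key.split("+")): ruleset_from_json(entries)
        for key, entries in payload.items()
    }
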