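"""Interval-pattern descriptions and rule quality measures.

A *description* D is a conjunction of closed intervals over descriptor
columns; its *coverage* is the set of molecules whose values fall inside
every interval.  A *structure-odor rule* D -> Q pairs a description with a
target set of olfactory qualities Q and is scored by precision, recall and
their combinations.

A molecule counts as a positive for Q iff it carries every quality of Q
(Q is a subset of the molecule's label set).  Because qualities are very
unevenly frequent, the headline measure is an adaptive F-beta whose weight

    beta(x) = (0.5 * (1 + tanh((x - x_beta) / l_beta)))**2

is a squared sigmoid of the target's support x: rare qualities get
beta ~ 0 (F-beta ~ precision), frequent ones beta ~ 1 and beyond
(recall-favoring).  The combination uses the (1 + beta) form:

    F_beta = (1 + beta) * P * R / (beta * P + R)

which equals P at beta = 0 and the harmonic mean F1 at beta = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .dataset import OdorantDataset

__all__ = [
    "Condition",
    "Description",
    "SORule",
    "RuleMetrics",
    "matches",
    "coverage",
    "coverage_mask",
    "beta_weight",
    "f_beta_combine",
    "evaluate",
]


@dataclass(frozen=True)
class Condition:
    """A closed interval restriction ``lo <= descriptor <= hi``."""

    descriptor: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(
                f"empty interval [{self.lo}, {self.hi}] on {self.descriptor!r}"
            )


@dataclass(frozen=True)
class Description:
    """Conjunction of closed intervals, at most one per descriptor."""

    conditions: tuple[Condition, ...] = ()

    def __post_init__(self) -> None:
        conds = tuple(
            c if isinstance(c, Condition) else Condition(*c) for c in self.conditions
        )
        names = [c.descriptor for c in conds]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate descriptor restriction in {names}")
        object.__setattr__(self, "conditions", conds)

    @property
    def restricted_descriptors(self) -> tuple[str, ...]:
        return tuple(c.descriptor for c in self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    def sort_key(self) -> tuple:
        return tuple((c.descriptor, c.lo, c.hi) for c in sorted(
            self.conditions, key=lambda c: c.descriptor
        ))


@dataclass(frozen=True)
class SORule:
    """A structure-odor rule D -> Q with the mining parameters it came from."""

    description: Description
    qualities: frozenset[str]
    provenance: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", frozenset(self.qualities))
        if not self.qualities:
            raise ValueError("a rule needs at least one target quality")
        if not isinstance(self.provenance, tuple):
            object.__setattr__(self, "provenance", tuple(dict(self.provenance).items()))


@dataclass
class RuleMetrics:
    support_d: int
    positives_in_coverage: int
    support_q: int
    precision: float
    recall: float
    f1: float
    f_beta: float
    beta: float
    flags: tuple[str, ...] = ()


def matches(label_set: Iterable[str], qualities: Iterable[str]) -> bool:
    """True iff the molecule carries every quality of Q."""
    return frozenset(qualities) <= frozenset(label_set)


def coverage_mask(description: Description, dataset: OdorantDataset) -> np.ndarray:
    """Boolean row mask of the description's coverage.

    Both interval bounds are inclusive.  A missing (NaN) value on a
    restricted descriptor makes the molecule not covered.
    """
    mask = np.ones(dataset.n_molecules, dtype=bool)
    for cond in description.conditions:
        col = dataset.column(cond.descriptor)  # raises KeyError if unknown
        with np.errstate(invalid="ignore"):
            mask &= (col >= cond.lo) & (col <= cond.hi)
    return mask


def coverage(description: Description, dataset: OdorantDataset) -> list[str]:
    """IDs of covered molecules, in dataset row order."""
    mask = coverage_mask(description, dataset)
    return [m for m, ok in zip(dataset.molecule_ids, mask) if ok]


def beta_weight(
    x: float, x_beta: float = 110.0, l_beta: float = 20.0, direction: str = "increasing"
) -> float:
    """Squared-sigmoid support weight ``(0.5 * (1 + tanh((x - x_beta)/l_beta)))**2``.

    Strictly increasing in x with ``beta(x_beta) = 0.25``; limits 0 and 1 at
    -inf/+inf.  ``direction="decreasing"`` mirrors the sigmoid for the
    opposite convention.
    """
    if l_beta <= 0:
        raise ValueError(f"l_beta must be > 0, got {l_beta}")
    z = (x - x_beta) / l_beta
    if direction == "decreasing":
        z = -z
    elif direction != "increasing":
        raise ValueError(f"direction must be 'increasing' or 'decreasing', got {direction!r}")
    return (0.5 * (1.0 + math.tanh(z))) ** 2


def f_beta_combine(precision: float, recall: float, beta: float) -> float:
    """``(1 + beta) * P * R / (beta * P + R)``; 0 when the denominator is 0.

    Equals P at beta = 0 and the harmonic mean (F1) at beta = 1.
    """
    denom = beta * precision + recall
    if denom == 0:
        return 0.0
    return (1.0 + beta) * precision * recall / denom


def evaluate(
    rule: SORule,
    dataset: OdorantDataset,
    x_beta: float = 110.0,
    l_beta: float = 20.0,
    beta_direction: str = "increasing",
) -> RuleMetrics:
    """Score a rule on a dataset: support, P, R, F1 and adaptive F-beta.

    Zero denominators never raise: the affected measure is reported as 0
    with an explanatory entry in ``flags``.
    """
    mask = coverage_mask(rule.description, dataset)
    pos = dataset.positives_mask(rule.qualities)
    support_d = int(mask.sum())
    support_q = int(pos.sum())
    positives = int((mask & pos).sum())
    flags: list[str] = []

    if support_d > 0:
        precision = positives / support_d
    else:
        precision, flags = 0.0, flags + ["empty_coverage"]
    if support_q > 0:
        recall = positives / support_q
    else:
        recall = 0.0
        flags.append("zero_support_q")

    f1 = f_beta_combine(precision, recall, 1.0)
    beta = beta_weight(support_q, x_beta, l_beta, beta_direction)
    f_beta = f_beta_combine(precision, recall, beta)
    return RuleMetrics(
        support_d=support_d,
        positives_in_coverage=positives,
        support_q=support_q,
        precision=precision,
        recall=recall,
        f1=f1,
        f_beta=f_beta,
        beta=beta,
        flags=tuple(flags),
    )
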