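"""Synthetic odorant datasets with planted interval-box rules.

The generator emulates the statistical shape the miner assumes: a numeric
descriptor matrix, multi-label annotations with a strongly unbalanced
frequency profile, and axis-aligned descriptor boxes whose members carry a
quality with probability ``p_inside`` (vs ``p_outside`` elsewhere).  Since
the planted box and its realized coverage are known exactly, mining runs
can be scored against ground truth (coverage Jaccard).

Planted boxes live in the same hypothesis class the miner searches
(axis-aligned, few descriptors), so recovery is an oracle test of the
search, not a misspecification test; ``rotate=True`` on a planted rule
plants a rotated (correlated) box instead for robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dataset import OdorantDataset
from .measures import Description, SORule, coverage_mask

__all__ = [
    "PlantedRule",
    "SyntheticSpec",
    "generate",
    "recovery_score",
    "benchmark_spec",
]


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth box -> label association.

    ``p_inside``/``p_outside`` are the label probabilities for molecules
    inside/outside the box; a recoverable rule needs p_inside > p_outside.
    ``rotate`` plants the box in a randomly rotated coordinate frame of its
    restricted descriptors (outside the miner's hypothesis class).
    """

    quality: str
    box: Description
    p_inside: float = 1.0
    p_outside: float = 0.0
    rotate: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_inside, self.p_outside):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probabilities must lie in [0,1], got {p}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Background labels follow a geometric frequency profile: label j is
    assigned to each molecule independently with probability
    ``background_label_rate * background_decay**j``, giving the unbalanced
    few-to-many support spectrum seen in real odor atlases.  When
    ``mean_labels_per_molecule`` is set, extra background labels are
    sprinkled (weighted by the same profile) to reach that average, and
    label-free molecules receive one background label so the dataset loads
    in annotated mode.
    """

    n_molecules: int = 500
    n_descriptors: int = 5
    distribution: str = "uniform"  # uniform(0,1) or normal(0,1)
    planted_rules: tuple[PlantedRule, ...] = ()
    background_label_rate: float = 0.3
    background_decay: float = 0.8
    n_background_labels: int = 10
    mean_labels_per_molecule: float | None = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(
                f"distribution must be 'uniform' or 'normal', got {self.distribution!r}"
            )
        if not (0.0 <= self.background_label_rate <= 1.0):
            raise ValueError("background_label_rate must lie in [0,1]")
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))


def _descriptor_names(k: int) -> list[str]:
    return [f"d{j + 1}" for j in range(k)]


def generate(spec: SyntheticSpec) -> tuple[OdorantDataset, dict]:
    """Sample a dataset from the spec; fully reproducible from its seed.

    Returns the dataset and a ground-truth report holding, per planted
    rule, the realized coverage, support, precision and recall.
    """
    rng = np.random.default_rng(spec.seed)
    names = _descriptor_names(spec.n_descriptors)
    if spec.distribution == "uniform":
        values = rng.uniform(0.0, 1.0, size=(spec.n_molecules, spec.n_descriptors))
        support_lo, support_hi = 0.0, 1.0
    else:
        values = rng.standard_normal((spec.n_molecules, spec.n_descriptors))
        support_lo, support_hi = -np.inf, np.inf
    ids = [str(i + 1) for i in range(spec.n_molecules)]
    labels: dict[str, set[str]] = {m: set() for m in ids}
    dataset = OdorantDataset(
        molecule_ids=ids,
        descriptor_names=names,
        values=values,
        labels={m: frozenset() for m in ids},
    )

    report: dict = {"planted": {}}
    for rule in spec.planted_rules:
        for cond in rule.box.conditions:
            if cond.descriptor not in names:
                raise ValueError(f"box descriptor {cond.descriptor!r} not generated")
            if cond.lo < support_lo or cond.hi > support_hi:
                raise ValueError(
                    f"box [{cond.lo}, {cond.hi}] on {cond.descriptor!r} lies outside "
                    f"the {spec.distribution} descriptor support"
                )
        if rule.rotate:
            idx = [dataset.descriptor_index(c.descriptor) for c in rule.box.conditions]
            sub = values[:, idx]
            rot = np.linalg.qr(rng.standard_normal((len(idx), len(idx))))[0]
            rotated = (sub - sub.mean(axis=0)) @ rot + sub.mean(axis=0)
            inside = np.ones(spec.n_molecules, dtype=bool)
            for col, cond in zip(rotated.T, rule.box.conditions):
                inside &= (col >= cond.lo) & (col <= cond.hi)
        else:
            inside = coverage_mask(rule.box, dataset)
        u = rng.random(spec.n_molecules)
        assigned = np.where(inside, u < rule.p_inside, u < rule.p_outside)
        for m, a in zip(ids, assigned):
            if a:
                labels[m].add(rule.quality)
        cov_ids = [m for m, i in zip(ids, inside) if i]
        hits = int((inside & assigned).sum())
        support_q = int(assigned.sum())
        report["planted"][rule.quality] = {
            "coverage": cov_ids,
            "support_d": len(cov_ids),
            "support_q": support_q,
            "precision": hits / len(cov_ids) if cov_ids else 0.0,
            "recall": hits / support_q if support_q else 0.0,
        }

    # geometric-profile background labels
    bg_names = [f"bg{j + 1}" for j in range(spec.n_background_labels)]
    probs = np.array(
        [spec.background_label_rate * spec.background_decay**j for j in range(len(bg_names))]
    )
    if bg_names:
        draws = rng.random((spec.n_molecules, len(bg_names))) < probs
        for i, m in enumerate(ids):
            for j, name in enumerate(bg_names):
                if draws[i, j]:
                    labels[m].add(name)

    if spec.mean_labels_per_molecule is not None and bg_names:
        # sprinkle (molecule, label) pairs until the average label count is
        # reached; draws colliding with existing labels add nothing, so loop
        target = int(round(spec.mean_labels_per_molecule * spec.n_molecules))
        w = probs / probs.sum()
        for _ in range(200):
            need = target - sum(len(s) for s in labels.values())
            if need <= 0:
                break
            mol_idx = rng.integers(0, spec.n_molecules, size=need)
            lab_idx = rng.choice(len(bg_names), size=need, p=w)
            for i, j in zip(mol_idx, lab_idx):
                labels[ids[i]].add(bg_names[j])

    if bg_names:
        w = probs / probs.sum()
        for m in ids:
            if not labels[m]:
                labels[m].add(bg_names[int(rng.choice(len(bg_names), p=w))])

    out = OdorantDataset(
        molecule_ids=ids,
        descriptor_names=names,
        values=values,
        labels={m: frozenset(s) for m, s in labels.items()},
    )
    return out, report


def recovery_score(
    mined_rules: Sequence, planted: PlantedRule, dataset: OdorantDataset
) -> float:
    """Best coverage Jaccard between any mined rule and the planted box."""
    target = set(
        m for m, ok in zip(dataset.molecule_ids, coverage_mask(planted.box, dataset)) if ok
    )
    best = 0.0
    for entry in mined_rules:
        rule = entry[0] if isinstance(entry, tuple) else entry
        desc = rule.description if isinstance(rule, SORule) else rule
        cov = set(
            m for m, ok in zip(dataset.molecule_ids, coverage_mask(desc, dataset)) if ok
        )
        union = target | cov
        if union:
            best = max(best, len(target & cov) / len(union))
    return best


def benchmark_spec(seed: int) -> SyntheticSpec:
    """The standard planted-box recovery benchmark.

    One quality planted in a two-descriptor box covering ~16% of 500
    uniform molecules, with 90% label probability inside the box and 2%
    outside, plus geometric background labels averaging ~3 per molecule.
    """
    box = Description(
        (
            ("d1", 0.30, 0.70),
            ("d2", 0.20, 0.60),
        )
    )
    return SyntheticSpec(
        n_molecules=500,
        n_descriptors=5,
        distribution="uniform",
        planted_rules=(PlantedRule("planted", box, p_inside=0.9, p_outside=0.02),),
        background_label_rate=0.3,
        background_decay=0.8,
        n_background_labels=10,
        mean_labels_per_molecule=3.0,
        seed=seed,
    )
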