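"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's optimized code paths: plain loops
and exhaustive enumeration only, so they can arbitrate the real
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from odormine.measures import beta_weight, f_beta_combine


def brute_force_metrics(dataset, conditions, qualities):
    """Recount support/positives/P/R by looping molecules in pure Python."""
    q = set(qualities)
    covered = []
    for i, mid in enumerate(dataset.molecule_ids):
        ok = True
        for name, lo, hi in conditions:
            v = dataset.values[i, dataset.descriptor_names.index(name)]
            if math.isnan(v) or not (lo <= v <= hi):
                ok = False
                break
        if ok:
            covered.append(mid)
    positives = [m for m in covered if q <= set(dataset.labels[m])]
    support_q = sum(1 for m in dataset.molecule_ids if q <= set(dataset.labels[m]))
    p = len(positives) / len(covered) if covered else 0.0
    r = len(positives) / support_q if support_q else 0.0
    return len(covered), len(positives), support_q, p, r


def exhaustive_best_f_beta(
    dataset,
    qualities,
    min_supp: int = 1,
    max_supp: int = 10**9,
    max_properties: int = 3,
    x_beta: float = 110.0,
    l_beta: float = 20.0,
):
    """Best F-beta over every interval box with bounds on observed values."""
    pos = dataset.positives_mask(qualities)
    support_q = int(pos.sum())
    beta = beta_weight(support_q, x_beta, l_beta)
    options = []
    for name in dataset.descriptor_names:
        col = dataset.column(name)
        vs = sorted(set(v for v in col if not math.isnan(v)))
        opts = [None]
        for i, lo in enumerate(vs):
            for hi in vs[i:]:
                opts.append((lo, hi))
        options.append(opts)
    best = 0.0
    n = dataset.n_molecules
    for combo in itertools.product(*options):
        conds = [(j, b) for j, b in enumerate(combo) if b is not None]
        if len(conds) > max_properties:
            continue
        mask = np.ones(n, dtype=bool)
        for j, (lo, hi) in conds:
            col = dataset.values[:, j]
            with np.errstate(invalid="ignore"):
                mask &= (col >= lo) & (col <= hi)
        supp = int(mask.sum())
        if not (min_supp <= supp <= max_supp):
            continue
        hits = int((mask & pos).sum())
        p = hits / supp
        r = hits / support_q if support_q else 0.0
        best = max(best, f_beta_combine(p, r, beta))
    return best


def random_small_dataset(rng, n_molecules=None, n_descriptors=None, n_qualities=2):
    """A tiny random annotated dataset for enumeration-scale oracles."""
    from odormine.dataset import OdorantDataset

    n = n_molecules or int(rng.integers(4, 9))
    d = n_descriptors or int(rng.integers(1, 4))
    values = np.round(rng.uniform(0, 10, size=(n, d)), 1)
    vocab = [f"q{i}" for i in range(n_qualities)]
    labels = {}
    for i in range(n):
        picked = [q for q in vocab if rng.random() < 0.5]
        if not picked:
            picked = [vocab[int(rng.integers(0, n_qualities))]]
        labels[str(i + 1)] = frozenset(picked)
    return OdorantDataset(
        molecule_ids=[str(i + 1) for i in range(n)],
        descriptor_names=[f"d{j + 1}" for j in range(d)],
        values=values,
        labels=labels,
    )
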