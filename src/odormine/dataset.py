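"""Loading, validation and summary of odorant datasets.

An odorant dataset couples a numeric descriptor table (molecules x
physicochemical descriptors, e.g. MW, nAT, MLOGP) with a multi-label
annotation mapping each molecule to a set of olfactory qualities
(``fruity``, ``woody``, ...).  Datasets are multi-labeled and strongly
unbalanced: a quality may annotate anywhere from a couple to several
hundred molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OdorantDataset",
    "DatasetSummary",
    "FilterReport",
    "load_dataset",
    "write_dataset",
    "toy_dataset",
    "filter_descriptors",
    "variance_retained",
    "summarize",
]


@dataclass
class OdorantDataset:
    """Molecules x descriptors matrix plus per-molecule quality labels.

    Parameters
    ----------
    molecule_ids : sequence of str
        Unique molecule identifiers (e.g. PubChem CIDs), one per matrix row.
    descriptor_names : sequence of str
        Descriptor column names.
    values : ndarray of float, shape (n_molecules, n_descriptors)
        Descriptor values; missing entries are NaN.
    labels : mapping id -> frozenset of str
        Olfactory-quality label sets.  May be empty sets in panel mode.
    quality_vocabulary : frozenset of str
        Union of all labels seen (extended automatically on construction).
    """

    molecule_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    labels: dict[str, frozenset[str]]
    quality_vocabulary: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.molecule_ids = [str(m) for m in self.molecule_ids]
        self.descriptor_names = list(self.descriptor_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("molecule_ids must be unique")
        if self.values.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.molecule_ids)} molecules x {len(self.descriptor_names)} descriptors"
            )
        self.labels = {
            str(m): frozenset(self.labels.get(str(m), frozenset()))
            for m in self.molecule_ids
        }
        seen = frozenset().union(*self.labels.values()) if self.labels else frozenset()
        self.quality_vocabulary = frozenset(self.quality_vocabulary) | seen

    # -- basic accessors -------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def descriptor_index(self, name: str) -> int:
        try:
            return self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown descriptor {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_index(name)]

    def label_set(self, molecule_id: str) -> frozenset[str]:
        return self.labels[str(molecule_id)]

    def positives_mask(self, qualities: Iterable[str]) -> np.ndarray:
        """Boolean row mask of molecules carrying *every* quality in Q."""
        q = frozenset(qualities)
        return np.array([q <= self.labels[m] for m in self.molecule_ids], dtype=bool)

    def support(self, qualities: Iterable[str]) -> int:
        """Number of molecules carrying every quality of Q."""
        return int(self.positives_mask(qualities).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.molecule_ids, columns=self.descriptor_names
        )

    def subset_descriptors(self, names: Sequence[str]) -> "OdorantDataset":
        idx = [self.descriptor_index(n) for n in names]
        return OdorantDataset(
            molecule_ids=list(self.molecule_ids),
            descriptor_names=list(names),
            values=self.values[:, idx].copy(),
            labels=dict(self.labels),
            quality_vocabulary=self.quality_vocabulary,
        )


@dataclass
class DatasetSummary:
    n_molecules: int
    n_qualities: int
    mean_labels_per_molecule: float
    per_quality_support: dict[str, int]
    min_labels_per_molecule: int
    max_labels_per_molecule: int


@dataclass
class FilterReport:
    """Names of dropped descriptor columns, keyed by the reason."""

    constant: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    correlated: list[tuple[str, str, float]] = field(default_factory=list)
    """(dropped column, kept column it correlates with, |r|)."""

    @property
    def dropped(self) -> list[str]:
        return self.constant + self.missing + [c for c, _, _ in self.correlated]


# ---------------------------------------------------------------------------
# I/O


def _parse_label_file(path: Path) -> dict[str, set[str]]:
    """Parse a label CSV, auto-detecting the dialect from its header.

    Long form: header ``id,quality`` with one row per (molecule, label).
    Wide form: header ``id,qualities`` with ``;``-separated label lists.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    labels: dict[str, set[str]] = {}
    if len(df.columns) >= 2 and cols[1] == "qualities":
        for mid, cell in zip(df.iloc[:, 0], df.iloc[:, 1]):
            parts = [p.strip() for p in str(cell).split(";") if p.strip()]
            labels.setdefault(str(mid).strip(), set()).update(parts)
    elif len(df.columns) >= 2 and cols[1] == "quality":
        for mid, quality in zip(df.iloc[:, 0], df.iloc[:, 1]):
            quality = str(quality).strip()
            labels.setdefault(str(mid).strip(), set())
            if quality:
                labels[str(mid).strip()].add(quality)
    else:
        raise ValueError(
            f"label file {path}: second column must be 'quality' (long form) "
            f"or 'qualities' (wide form); got header {list(df.columns)!r}"
        )
    return labels


def load_dataset(
    descriptor_file: str | Path,
    label_file: str | Path | None,
    mode: str = "annotated",
) -> OdorantDataset:
    """Load descriptors + labels into a validated :class:`OdorantDataset`.

    ``mode="annotated"`` requires every kept molecule to carry at least one
    label; molecules present in only one of the two files are dropped with a
    warning.  ``mode="panel"`` keeps label-free molecules (validation panels
    carry continuous ratings instead of labels).
    """
    if mode not in ("annotated", "panel"):
        raise ValueError(f"mode must be 'annotated' or 'panel', got {mode!r}")
    descriptor_file = Path(descriptor_file)
    df = pd.read_csv(descriptor_file, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    ids = [str(v).strip() for v in df[id_col]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule IDs in {descriptor_file}: {dupes}")
    descriptor_names = [str(c) for c in df.columns[1:]]

    values = np.empty((len(ids), len(descriptor_names)), dtype=float)
    for j, name in enumerate(descriptor_names):
        for i, cell in enumerate(df[df.columns[j + 1]]):
            cell = str(cell).strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric descriptor value {cell!r} at molecule "
                    f"{ids[i]!r}, column {name!r}"
                ) from None

    labels = _parse_label_file(Path(label_file)) if label_file is not None else {}

    if mode == "annotated":
        if label_file is None:
            raise ValueError("annotated mode requires a label file")
        keep = [i for i, m in enumerate(ids) if labels.get(m)]
        dropped = [m for m in ids if not labels.get(m)]
        orphan_labels = sorted(set(labels) - set(ids))
        if dropped:
            logger.warning(
                "dropping %d molecule(s) without labels: %s", len(dropped), dropped
            )
        if orphan_labels:
            logger.warning(
                "ignoring %d labeled molecule(s) absent from the descriptor file: %s",
                len(orphan_labels),
                orphan_labels,
            )
        if not keep:
            raise ValueError(
                "empty intersection between descriptor and label files"
            )
        ids = [ids[i] for i in keep]
        values = values[keep]
        label_map = {m: frozenset(labels[m]) for m in ids}
    else:
        label_map = {m: frozenset(labels.get(m, set())) for m in ids}

    return OdorantDataset(
        molecule_ids=ids,
        descriptor_names=descriptor_names,
        values=values,
        labels=label_map,
    )


def write_dataset(
    dataset: OdorantDataset,
    descriptor_file: str | Path,
    label_file: str | Path,
    label_form: str = "long",
) -> None:
    """Write a dataset back to the descriptor/label CSV dialects."""
    frame = dataset.to_frame()
    frame.index.name = "id"
    frame.to_csv(descriptor_file)
    rows = []
    if label_form == "long":
        for m in dataset.molecule_ids:
            for q in sorted(dataset.labels[m]):
                rows.append({"id": m, "quality": q})
        pd.DataFrame(rows, columns=["id", "quality"]).to_csv(label_file, index=False)
    elif label_form == "wide":
        for m in dataset.molecule_ids:
            rows.append({"id": m, "qualities": ";".join(sorted(dataset.labels[m]))})
        pd.DataFrame(rows, columns=["id", "qualities"]).to_csv(label_file, index=False)
    else:
        raise ValueError(f"label_form must be 'long' or 'wide', got {label_form!r}")


_TOY_ROWS = [
    # (id, MW, nAT, nC, labels)
    ("1", 150, 21, 11, {"vanillin", "woody"}),
    ("2", 128, 29, 9, {"fruity"}),
    ("3", 136, 24, 10, {"fruity", "woody"}),
    ("4", 152, 23, 11, {"woody"}),
    ("5", 151, 27, 12, {"fruity", "vanillin"}),
    ("6", 142, 27, 10, {"fruity", "vanillin"}),
]


def toy_dataset() -> OdorantDataset:
    """The six-molecule worked-example dataset (MW, nAT, nC; three qualities)."""
    return OdorantDataset(
        molecule_ids=[r[0] for r in _TOY_ROWS],
        descriptor_names=["MW", "nAT", "nC"],
        values=np.array([[r[1], r[2], r[3]] for r in _TOY_ROWS], dtype=float),
        labels={r[0]: frozenset(r[4]) for r in _TOY_ROWS},
    )


# ---------------------------------------------------------------------------
# Descriptor filtering


def filter_descriptors(
    dataset: OdorantDataset,
    drop_constant: bool = True,
    drop_missing: bool = True,
    correlation_threshold: float = 0.85,
) -> tuple[OdorantDataset, FilterReport]:
    """Drop constant, incomplete and highly correlated descriptor columns.

    Order of operations: constant columns, then columns with any missing
    value (when flagged), then greedy correlation pruning: columns are
    visited in file order and a column is dropped if its absolute Pearson
    correlation (over complete pairs) with any already-kept column exceeds
    the threshold — i.e. the earlier column of a correlated pair survives.
    """
    if not (0.0 < correlation_threshold <= 1.0):
        raise ValueError(
            f"correlation_threshold must be in (0, 1], got {correlation_threshold}"
        )
    report = FilterReport()
    kept = list(dataset.descriptor_names)

    if drop_constant:
        remaining = []
        for name in kept:
            col = dataset.column(name)
            finite = col[~np.isnan(col)]
            if finite.size == 0 or np.all(finite == finite[0]):
                report.constant.append(name)
            else:
                remaining.append(name)
        kept = remaining

    if drop_missing:
        remaining = []
        for name in kept:
            if np.isnan(dataset.column(name)).any():
                report.missing.append(name)
            else:
                remaining.append(name)
        kept = remaining

    surviving: list[str] = []
    for name in kept:
        col = dataset.column(name)
        partner = None
        for other in surviving:
            oc = dataset.column(other)
            ok = ~np.isnan(col) & ~np.isnan(oc)
            if ok.sum() < 2:
                continue
            a, b = col[ok], oc[ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r = abs(float(np.corrcoef(a, b)[0, 1]))
            if r > correlation_threshold:
                partner = (other, r)
                break
        if partner is None:
            surviving.append(name)
        else:
            report.correlated.append((name, partner[0], partner[1]))

    return dataset.subset_descriptors(surviving), report


def variance_retained(
    dataset: OdorantDataset, subset: Iterable[str], ddof: int = 1
) -> float:
    """Fraction of total per-column variance carried by a descriptor subset.

    Computed on raw (unstandardized) values as
    ``sum(var(col) for col in subset) / sum(var(col) for all cols)``.
    This summed-column-variance reading is one concrete choice for an
    otherwise underdetermined "retained variance" figure; see the methods
    note.
    """
    subset = list(subset)
    if dataset.n_molecules == 0 or dataset.n_descriptors == 0:
        raise ValueError("variance_retained requires a non-empty dataset")
    unknown = [n for n in subset if n not in dataset.descriptor_names]
    if unknown:
        raise KeyError(f"unknown descriptors {unknown}")
    if not subset:
        return 0.0
    variances = {
        n: float(np.nanvar(dataset.column(n), ddof=ddof))
        for n in dataset.descriptor_names
    }
    total = sum(variances.values())
    if total == 0:
        return 0.0
    return sum(variances[n] for n in subset) / total


def summarize(dataset: OdorantDataset) -> DatasetSummary:
    """Descriptive statistics of the label structure."""
    counts = [len(dataset.labels[m]) for m in dataset.molecule_ids]
    support: dict[str, int] = {q: 0 for q in sorted(dataset.quality_vocabulary)}
    for m in dataset.molecule_ids:
        for q in dataset.labels[m]:
            support[q] += 1
    return DatasetSummary(
        n_molecules=dataset.n_molecules,
        n_qualities=len(dataset.quality_vocabulary),
        mean_labels_per_molecule=float(np.mean(counts)) if counts else 0.0,
        per_quality_support=support,
        min_labels_per_molecule=min(counts) if counts else 0,
        max_labels_per_molecule=max(counts) if counts else 0,
    )
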