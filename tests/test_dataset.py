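"""Dataset loading, filtering and summary statistics."""

import logging

import numpy as np
import pytest

from odormine import (
    OdorantDataset,
    filter_descriptors,
    load_dataset,
    summarize,
    toy_dataset,
    variance_retained,
    write_dataset,
)


class TestToyFixture:
    def test_molecule_one(self, toy):
        assert toy.to_frame().loc["1"].tolist() == [150.0, 21.0, 11.0]
        assert toy.label_set("1") == {"vanillin", "woody"}

    def test_shape_and_vocabulary(self, toy):
        s = summarize(toy)
        assert s.n_molecules == 6
        assert s.n_qualities == 3
        assert toy.quality_vocabulary == {"fruity", "vanillin", "woody"}

    @pytest.mark.parametrize(
        "quality,support", [("vanillin", 3), ("fruity", 4), ("woody", 3)]
    )
    def test_per_quality_support(self, toy, quality, support):
        assert summarize(toy).per_quality_support[quality] == support
        assert toy.support({quality}) == support

    def test_mean_labels_per_molecule(self, toy):
        assert summarize(toy).mean_labels_per_molecule == pytest.approx(10 / 6)


class TestLoadWrite:
    @pytest.mark.parametrize("form", ["long", "wide"])
    def test_round_trip(self, toy, tmp_path, form):
        d, l = tmp_path / "desc.csv", tmp_path / "lab.csv"
        write_dataset(toy, d, l, label_form=form)
        back = load_dataset(d, l, mode="annotated")
        assert back.molecule_ids == toy.molecule_ids
        assert back.descriptor_names == toy.descriptor_names
        np.testing.assert_array_equal(back.values, toy.values)
        assert back.labels == toy.labels

    def test_round_trip_preserves_missing_values(self, tmp_path):
        ds = OdorantDataset(
            ["a", "b"], ["x", "y"], [[1.0, np.nan], [3.0, 4.0]],
            {"a": frozenset({"q"}), "b": frozenset({"q"})},
        )
        write_dataset(ds, tmp_path / "d.csv", tmp_path / "l.csv")
        back = load_dataset(tmp_path / "d.csv", tmp_path / "l.csv")
        np.testing.assert_array_equal(back.values, ds.values)

    def test_unlabeled_molecule_dropped_with_warning(self, tmp_path, caplog):
        (tmp_path / "d.csv").write_text("id,MW\n1,10\n2,20\n")
        (tmp_path / "l.csv").write_text("id,quality\n1,fruity\n")
        with caplog.at_level(logging.WARNING):
            ds = load_dataset(tmp_path / "d.csv", tmp_path / "l.csv", mode="annotated")
        assert ds.molecule_ids == ["1"]
        assert "2" in caplog.text

    def test_panel_mode_keeps_label_free_molecules(self, tmp_path):
        (tmp_path / "d.csv").write_text("id,MW\n1,10\n2,20\n")
        (tmp_path / "l.csv").write_text("id,quality\n1,fruity\n")
        ds = load_dataset(tmp_path / "d.csv", tmp_path / "l.csv", mode="panel")
        assert ds.molecule_ids == ["1", "2"]
        assert ds.label_set("2") == frozenset()

    def test_new_quality_extends_vocabulary(self, tmp_path):
        (tmp_path / "d.csv").write_text("id,MW\n1,10\n")
        (tmp_path / "l.csv").write_text("id,quality\n1,uncatalogued-smell\n")
        ds = load_dataset(tmp_path / "d.csv", tmp_path / "l.csv")
        assert "uncatalogued-smell" in ds.quality_vocabulary

    def test_duplicate_ids_rejected(self, tmp_path):
        (tmp_path / "d.csv").write_text("id,MW\n1,10\n1,20\n")
        (tmp_path / "l.csv").write_text("id,quality\n1,fruity\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_dataset(tmp_path / "d.csv", tmp_path / "l.csv")

    def test_non_numeric_cell_named(self, tmp_path):
        (tmp_path / "d.csv").write_text("id,MW\n1,ten\n")
        (tmp_path / "l.csv").write_text("id,quality\n1,fruity\n")
        with pytest.raises(ValueError, match=r"'ten'.*'1'.*'MW'"):
            load_dataset(tmp_path / "d.csv", tmp_path / "l.csv")

    def test_empty_intersection_rejected(self, tmp_path):
        (tmp_path / "d.csv").write_text("id,MW\n1,10\n")
        (tmp_path / "l.csv").write_text("id,quality\n9,fruity\n")
        with pytest.raises(ValueError, match="intersection"):
            load_dataset(tmp_path / "d.csv", tmp_path / "l.csv")


def _dataset(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"c{j}" for j in range(values.shape[1])]
    ids = [str(i) for i in range(values.shape[0])]
    return OdorantDataset(ids, names, values, {m: frozenset({"q"}) for m in ids})


class TestFilterDescriptors:
    def test_constant_column_dropped(self):
        ds = _dataset([[1, 5, 2], [2, 5, 3], [3, 5, 1]])
        out, report = filter_descriptors(ds)
        assert out.descriptor_names == ["c0", "c2"]
        assert report.constant == ["c1"]

    def test_missing_column_dropped_when_flagged(self):
        ds = _dataset([[1, np.nan], [2, 3.0], [3, 9.0], [5, 4.0]])
        out, report = filter_descriptors(ds, drop_missing=True)
        assert out.descriptor_names == ["c0"]
        assert report.missing == ["c1"]
        out2, _ = filter_descriptors(ds, drop_missing=False)
        assert "c1" in out2.descriptor_names

    def test_identical_columns_later_dropped(self):
        ds = _dataset([[1, 1], [2, 2], [3, 3]])
        out, report = filter_descriptors(ds, correlation_threshold=0.85)
        assert out.descriptor_names == ["c0"]
        assert report.correlated[0][0] == "c1"
        assert report.correlated[0][2] == pytest.approx(1.0)

    def test_planted_correlated_pair_matches_brute_force(self):
        rng = np.random.default_rng(42)
        values = rng.normal(size=(60, 5))
        # plant exactly one strongly correlated pair (c3 ~ c1)
        values[:, 3] = values[:, 1] + 0.2 * rng.normal(size=60)
        ds = _dataset(values)
        out, report = filter_descriptors(ds, correlation_threshold=0.85)
        # brute-force all-pairs scan as the oracle
        over = [
            (i, j)
            for i in range(5)
            for j in range(i + 1, 5)
            if abs(np.corrcoef(values[:, i], values[:, j])[0, 1]) > 0.85
        ]
        assert over == [(1, 3)]
        assert [c for c, _, _ in report.correlated] == ["c3"]
        assert out.descriptor_names == ["c0", "c1", "c2", "c4"]

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(40, 6))
        values[:, 5] = values[:, 0]
        values[:, 2] = 3.14
        ds = _dataset(values)
        once, _ = filter_descriptors(ds, correlation_threshold=0.9)
        twice, report = filter_descriptors(once, correlation_threshold=0.9)
        assert twice.descriptor_names == once.descriptor_names
        assert report.dropped == []

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_validated(self, bad):
        with pytest.raises(ValueError):
            filter_descriptors(_dataset([[1, 2], [3, 4]]), correlation_threshold=bad)


class TestVarianceRetained:
    def test_identity_and_empty_subset(self, toy):
        assert variance_retained(toy, toy.descriptor_names) == pytest.approx(1.0)
        assert variance_retained(toy, []) == 0.0

    def test_hand_computed_ratio(self):
        # columns with sample variances exactly 1, 2 and 7
        cols = np.array(
            [[0, 0, 0], [1, np.sqrt(2), np.sqrt(7)], [2, 2 * np.sqrt(2), 2 * np.sqrt(7)]]
        )
        ds = _dataset(cols)
        assert variance_retained(ds, ["c0", "c1"]) == pytest.approx(3 / 10)

    def test_monotone_under_subset_growth(self):
        rng = np.random.default_rng(3)
        ds = _dataset(rng.normal(size=(30, 6)))
        names = ds.descriptor_names
        fracs = [variance_retained(ds, names[:k]) for k in range(len(names) + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_empty_dataset_rejected(self):
        ds = OdorantDataset([], [], np.empty((0, 0)), {})
        with pytest.raises(ValueError):
            variance_retained(ds, [])


def test_summary_of_label_free_panel():
    ds = OdorantDataset(["a"], ["x"], [[1.0]], {"a": frozenset()})
    s = summarize(ds)
    assert s.mean_labels_per_molecule == 0
    assert s.min_labels_per_molecule == 0
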