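import math

import numpy as np
import pandas as pd
import pytest

from wci.preprocess import (
    low_count_filter,
    low_variance_filter,
    preprocess,
    read_count_table,
    remove_contaminants,
    tss_normalize,
    write_count_table,
)
from wci.reference import DEFAULT_CONTAMINANT_BLACKLIST
from wci.simulate import make_cohort, table1_spec
from wci.tables import FormatError, TaxaCountTable, ValidationError

from conftest import random_count_table


class TestReadWrite:
    def test_round_trip_fixture(self, small_table, tmp_path):
        write_count_table(small_table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.equals(small_table)

    def test_round_trip_synthetic_cohort(self, tmp_path):
        table = make_cohort(table1_spec("genus", seed=7))
        write_count_table(table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.equals(table)

    def test_samples_rows_orientation(self, small_table, tmp_path):
        write_count_table(
            small_table, tmp_path / "c.tsv", tmp_path / "m.tsv", orientation="samples_rows"
        )
        back = read_count_table(
            tmp_path / "c.tsv", tmp_path / "m.tsv", orientation="samples_rows"
        )
        assert back.equals(small_table)

    def test_metadata_sample_missing_from_counts(self, small_table, tmp_path):
        write_count_table(small_table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        meta = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        meta.loc[len(meta)] = ["ghost", "HC"]
        meta.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="ghost"):
            read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_non_integer_cell_rejected(self, small_table, tmp_path):
        write_count_table(small_table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        text = (tmp_path / "c.tsv").read_text().replace("\t2\t", "\t2.5\t", 1)
        (tmp_path / "c.tsv").write_text(text)
        with pytest.raises(FormatError, match="non-integer"):
            read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_age_covariate_loaded(self, small_table, tmp_path):
        write_count_table(small_table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        meta = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        meta["age"] = [71.0, 65.0, 58.0, 62.0]
        meta.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        back = read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert list(back.covariates["age"]) == [71.0, 65.0, 58.0, 62.0]


class TestTableInvariants:
    def test_zero_depth_sample_rejected(self):
        counts = pd.DataFrame(
            [[1, 2], [0, 0], [3, 4], [5, 6]],
            index=list("abcd"),
            columns=["t1", "t2"],
        )
        labels = pd.Series(["BCa", "BCa", "HC", "HC"], index=counts.index)
        with pytest.raises(ValidationError, match="zero total"):
            TaxaCountTable(counts=counts, labels=labels)

    def test_single_class_rejected(self):
        counts = pd.DataFrame([[1], [2], [3]], index=list("abc"), columns=["t"])
        labels = pd.Series(["BCa"] * 3, index=counts.index)
        with pytest.raises(ValidationError, match="two classes"):
            TaxaCountTable(counts=counts, labels=labels)


class TestContaminantRemoval:
    def test_default_blacklist_removes_ralstonia(self, small_table):
        out, report = remove_contaminants(small_table, DEFAULT_CONTAMINANT_BLACKLIST)
        assert "Ralstonia" not in out.taxon_ids
        assert report.removed_taxa == ["Ralstonia"]
        assert set(report.kept_taxa) == {"TaxA", "TaxB", "TaxC"}

    def test_match_is_case_insensitive(self, small_table):
        out, _ = remove_contaminants(small_table, ["rAlStOnIa"])
        assert "Ralstonia" not in out.taxon_ids

    def test_empty_blacklist_is_identity(self, small_table):
        out, report = remove_contaminants(small_table, [])
        assert out.equals(small_table)
        assert report.removed_taxa == []

    def test_unmatched_entry_warns_not_errors(self, small_table):
        with pytest.warns(UserWarning, match="not present"):
            out, _ = remove_contaminants(small_table, ["Ralstonia", "NotATaxon"])
        assert len(out.taxon_ids) == 3

    def test_spiked_contaminant_count(self):
        rng = np.random.default_rng(3)
        table = random_count_table(rng, 10, 30)
        from wci.simulate import spike_contaminants

        spiked = spike_contaminants(table, ["ContamA", "Ralstonia"], ra=0.01)
        assert len(spiked.taxon_ids) == 32
        out, _ = remove_contaminants(spiked, ["ContamA", "Ralstonia"])
        assert len(out.taxon_ids) == 30


class TestLowCountFilter:
    def test_single_qualifying_sample_suffices(self):
        # ceil(0.1 * 10) = 1 sample with >= 20 counts keeps the taxon
        counts = pd.DataFrame(
            {"sparse": [25] + [0] * 9, "anchor": [30] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["BCa"] * 5 + ["HC"] * 5, index=counts.index)
        table = TaxaCountTable(counts=counts, labels=labels)
        out, _ = low_count_filter(table)
        assert "sparse" in out.taxon_ids

    def test_nineteen_everywhere_removed(self):
        counts = pd.DataFrame(
            {"weak": [19] * 10, "anchor": [30] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["BCa"] * 5 + ["HC"] * 5, index=counts.index)
        table = TaxaCountTable(counts=counts, labels=labels)
        out, report = low_count_filter(table)
        assert report.removed_taxa == ["weak"]

    def test_all_zero_taxon_removed(self):
        counts = pd.DataFrame(
            {"zero": [0] * 6, "anchor": [30] * 6}, index=[f"s{i}" for i in range(6)]
        )
        labels = pd.Series(["BCa"] * 3 + ["HC"] * 3, index=counts.index)
        table = TaxaCountTable(counts=counts, labels=labels)
        out, _ = low_count_filter(table, min_count=1)
        assert "zero" not in out.taxon_ids

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(5, 50)), int(rng.integers(2, 50))
        table = random_count_table(rng, n, p)
        min_count, min_prev = int(rng.integers(1, 40)), float(rng.uniform(0.05, 0.9))
        try:
            out, _ = low_count_filter(table, min_count, min_prev)
            kept = set(out.taxon_ids)
        except ValidationError:
            kept = set()
        expected = set()
        for taxon in table.taxon_ids:
            hits = sum(1 for c in table.counts[taxon] if c >= min_count)
            if hits >= math.ceil(min_prev * n):
                expected.add(taxon)
        assert kept == expected or (not expected and not kept)

    def test_removing_everything_is_an_error(self, small_table):
        with pytest.raises(ValidationError, match="min_count=1000"):
            low_count_filter(small_table, min_count=1000, min_prevalence=1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        table = random_count_table(rng, 20, 30)
        once, _ = low_count_filter(table)
        twice, report = low_count_filter(once)
        assert twice.equals(once) and report.removed_taxa == []


class TestLowVarianceFilter:
    @staticmethod
    def _table_with_iqrs():
        # taxon j takes values {0, j} alternating -> IQR j (for even n)
        rng = np.random.default_rng(0)
        cols = {}
        for j in range(1, 11):
            vals = np.array([0, j] * 6)
            rng.shuffle(vals)
            cols[f"iqr{j}"] = vals
        counts = pd.DataFrame(cols, index=[f"s{i}" for i in range(12)])
        counts["iqr1"] += 1  # keep depths positive
        labels = pd.Series(["BCa"] * 6 + ["HC"] * 6, index=counts.index)
        return TaxaCountTable(counts=counts, labels=labels)

    def test_smallest_iqr_removed_at_p10(self):
        table = self._table_with_iqrs()
        arr = table.counts.to_numpy(float)
        iqrs = np.percentile(arr, 75, axis=0) - np.percentile(arr, 25, axis=0)
        cutoff = np.percentile(iqrs, 10)
        expected_removed = set(np.array(table.taxon_ids)[iqrs < cutoff])
        out, report = low_variance_filter(table, percentile=10)
        assert set(report.removed_taxa) == expected_removed
        assert np.argmin(iqrs) == list(table.taxon_ids).index(report.removed_taxa[0])

    def test_percentile_zero_is_identity(self, small_table):
        out, report = low_variance_filter(small_table, percentile=0)
        assert out.equals(small_table) and report.removed_taxa == []

    def test_constant_taxon_removed(self):
        rng = np.random.default_rng(5)
        table = random_count_table(rng, 12, 9)
        counts = table.counts.copy()
        counts["flat"] = 7
        table = TaxaCountTable(counts=counts, labels=table.labels)
        out, _ = low_variance_filter(table, percentile=10)
        assert "flat" not in out.taxon_ids

    def test_single_taxon_noop_with_warning(self):
        counts = pd.DataFrame({"only": [1, 2, 3, 4]}, index=list("abcd"))
        labels = pd.Series(["BCa", "BCa", "HC", "HC"], index=counts.index)
        table = TaxaCountTable(counts=counts, labels=labels)
        with pytest.warns(UserWarning, match="fewer than two"):
            out, _ = low_variance_filter(table)
        assert out.equals(table)


class TestTss:
    def test_forced_arithmetic(self):
        counts = pd.DataFrame(
            [[2, 3, 5]] * 4, index=list("abcd"), columns=["x", "y", "z"]
        )
        labels = pd.Series(["BCa", "BCa", "HC", "HC"], index=counts.index)
        ab = tss_normalize(TaxaCountTable(counts=counts, labels=labels))
        assert list(ab.ra.iloc[0]) == [0.2, 0.3, 0.5]

    def test_one_taxon_gives_ones(self):
        counts = pd.DataFrame({"only": [5, 9, 2, 4]}, index=list("abcd"))
        labels = pd.Series(["BCa", "BCa", "HC", "HC"], index=counts.index)
        ab = tss_normalize(TaxaCountTable(counts=counts, labels=labels))
        assert (ab.ra["only"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng, int(rng.integers(4, 30)), int(rng.integers(2, 40)))
        ab = tss_normalize(table)
        assert np.allclose(ab.ra.sum(axis=1), 1.0, atol=1e-12, rtol=0)


class TestComposition:
    def test_stage_outputs_chain(self):
        table = make_cohort(table1_spec("genus", seed=5))
        ab, reports = preprocess(table, blacklist=DEFAULT_CONTAMINANT_BLACKLIST)
        # each report's kept set is exactly the next stage's input taxon set
        assert set(reports[0].kept_taxa) == set(
            reports[1].kept_taxa + reports[1].removed_taxa
        )
        assert set(reports[1].kept_taxa) == set(
            reports[2].kept_taxa + reports[2].removed_taxa
        )
        assert set(reports[2].kept_taxa) == set(ab.taxon_ids)
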