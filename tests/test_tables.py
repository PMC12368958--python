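import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from soilmerge import tables

from conftest import random_counts


# ---------------------------------------------------------------------------
# I/O


class TestCountTableIO:
    def test_round_trip_preserves_values_and_bytes(self, small_counts, tmp_path):
        p = tmp_path / "counts.tsv"
        tables.write_count_table(small_counts, p)
        back = tables.read_count_table(p)
        pd.testing.assert_frame_equal(back, small_counts.rename_axis("sample_id"))
        p2 = tmp_path / "again.tsv"
        tables.write_count_table(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_biom_tsv_layout_is_detected_and_transposed(self, tmp_path):
        p = tmp_path / "table.tsv"
        p.write_text(
            "# Constructed from biom file\n"
            "#OTU ID\ts1\ts2\n"
            "a1\t1\t5\n"
            "a2\t2\t0\n"
        )
        df = tables.read_count_table(p)
        assert df.shape == (2, 2)
        assert df.loc["s1", "a2"] == 2 and df.loc["s2", "a1"] == 5

    @pytest.mark.parametrize(
        "cell, message",
        [("-3", "negative count"), ("2.5", "non-integer"), ("abc", "non-numeric")],
    )
    def test_malformed_cells_are_rejected_with_location(self, tmp_path, cell, message):
        p = tmp_path / "bad.tsv"
        p.write_text(f"sample_id\ta1\ta2\ns1\t1\t{cell}\ns2\t1\t1\n")
        with pytest.raises(ValueError, match=message) as err:
            tables.read_count_table(p)
        assert "s1" in str(err.value) and "a2" in str(err.value)

    def test_duplicate_identifiers_rejected(self, small_counts):
        dup = pd.concat([small_counts, small_counts.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate sample"):
            tables.validate_count_table(dup)


# ---------------------------------------------------------------------------
# relative abundance


class TestRelativeAbundance:
    def test_simple_rows(self, small_counts):
        rel = tables.relative_abundance(small_counts)
        assert rel.loc["s1"].tolist() == [0.25, 0.25, 0.5]
        assert rel.loc["s2"].tolist() == [1.0, 0.0, 0.0]

    def test_empty_sample_is_named(self, small_counts):
        small_counts.loc["s2"] = 0
        with pytest.raises(ValueError, match="s2"):
            tables.relative_abundance(small_counts)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(1, 6), st.integers(1, 8)),
            elements=st.integers(0, 1000),
        )
    )
    def test_rows_always_sum_to_one(self, counts):
        counts[:, 0] += 1
        df = pd.DataFrame(counts).rename_axis("sample_id")
        sums = tables.relative_abundance(df).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# rarefaction


class TestRarefy:
    def test_exact_depth_and_no_inflation(self):
        rng = np.random.default_rng(0)
        counts = random_counts(rng, n_samples=4, n_taxa=30, high=12_000)
        out = tables.rarefy(counts, 100_000, seed=1)
        assert (out.sum(axis=1) == 100_000).all()
        assert (out.to_numpy() <= counts.loc[out.index].to_numpy()).all()

    def test_depth_equal_to_row_sum_returns_row_unchanged(self, small_counts):
        out = tables.rarefy(small_counts.iloc[[0]], int(small_counts.iloc[0].sum()), seed=0)
        assert out.iloc[0].tolist() == small_counts.iloc[0].tolist()

    def test_single_taxon_row_is_deterministic(self):
        df = pd.DataFrame({"only": [500]}, index=pd.Index(["s"], name="sample_id"))
        for seed in (0, 1, 99):
            assert tables.rarefy(df, 100, seed=seed).iloc[0, 0] == 100

    def test_same_seed_reproduces_and_seeds_differ(self):
        rng = np.random.default_rng(1)
        counts = random_counts(rng, n_samples=3, n_taxa=40, high=500)
        a = tables.rarefy(counts, 1000, seed=5)
        b = tables.rarefy(counts, 1000, seed=5)
        c = tables.rarefy(counts, 1000, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_subsampling_is_independent_of_table_subset(self):
        rng = np.random.default_rng(2)
        counts = random_counts(rng, n_samples=4, n_taxa=25, high=400)
        full = tables.rarefy(counts, 800, seed=3)
        solo = tables.rarefy(counts.iloc[[2]], 800, seed=3)
        pd.testing.assert_frame_equal(full.iloc[[2]], solo)

    def test_shallow_samples_dropped_with_warning(self, small_counts):
        with pytest.warns(UserWarning, match="below rarefaction depth"):
            out = tables.rarefy(small_counts, 6, seed=0)
        assert list(out.index) == ["s3"]

    def test_nonpositive_depth_rejected(self, small_counts):
        with pytest.raises(ValueError, match="depth"):
            tables.rarefy(small_counts, 0)


# ---------------------------------------------------------------------------
# rank aggregation


class TestAggregateToRank:
    def test_genus_sums(self, small_counts, small_taxonomy):
        out = tables.aggregate_to_rank(small_counts, small_taxonomy, "genus")
        assert out.loc["s1", "G1"] == 2 and out.loc["s1", "G2"] == 2
        assert out.loc["s3", "G1"] == 7

    def test_unassigned_pooled_into_own_column(self, small_counts, small_taxonomy):
        small_taxonomy.loc["a3", "genus"] = tables.UNASSIGNED
        out = tables.aggregate_to_rank(small_counts, small_taxonomy, "genus")
        assert tables.UNASSIGNED in out.columns
        assert out[tables.UNASSIGNED].tolist() == small_counts["a3"].tolist()

    def test_missing_taxonomy_names_asv(self, small_counts, small_taxonomy):
        with pytest.raises(KeyError, match="a3"):
            tables.aggregate_to_rank(small_counts, small_taxonomy.drop("a3"), "genus")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_per_sample_totals_conserved(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_counts(rng, n_samples=4, n_taxa=10)
        tax = pd.DataFrame(
            {
                "genus": rng.choice(["G1", "G2", "G3"], size=10),
                "phylum": rng.choice(["P1", "P2"], size=10),
            },
            index=counts.columns.rename("asv_id"),
        )
        out = tables.aggregate_to_rank(counts, tax, "genus")
        assert (out.sum(axis=1) == counts.sum(axis=1)).all()


# ---------------------------------------------------------------------------
# shared taxa


class TestSharedTaxaFraction:
    def _table(self, totals: dict) -> pd.DataFrame:
        return pd.DataFrame([totals], index=pd.Index(["s"], name="sample_id"))

    def test_half_shared(self):
        a = self._table({"G1": 5, "G2": 5, "G3": 5, "G4": 5})
        b = self._table({"G2": 9, "G3": 2})
        assert tables.shared_taxa_fraction(a, b) == 0.5

    def test_disjoint_and_identity(self):
        a = self._table({"G1": 4, "G2": 4})
        b = self._table({"G3": 4})
        assert tables.shared_taxa_fraction(a, b) == 0.0
        assert tables.shared_taxa_fraction(a, a) == 1.0

    def test_direction_is_the_first_argument(self):
        a = self._table({"G1": 5, "G2": 5, "G3": 5, "G4": 5})
        b = self._table({"G2": 9, "G3": 2})
        assert tables.shared_taxa_fraction(b, a) == 1.0

    def test_singletons_and_unassigned_removed(self):
        a = self._table({"G1": 5, "G2": 1, tables.UNASSIGNED: 10})
        b = self._table({"G1": 3})
        # only G1 survives filtering in a: the singleton G2 and unassigned drop
        assert tables.shared_taxa_fraction(a, b) == 1.0
        assert tables.shared_taxa_fraction(a, b, remove_singletons=False) == 0.5

    def test_genus_rank_aggregates_through_taxonomy(self, small_counts, small_taxonomy):
        frac = tables.shared_taxa_fraction(
            small_counts, small_counts, rank="genus", taxonomy=small_taxonomy
        )
        assert frac == 1.0
        with pytest.raises(ValueError, match="taxonomy"):
            tables.shared_taxa_fraction(small_counts, small_counts, rank="genus")

    def test_empty_after_filtering_is_an_error(self):
        a = self._table({"G1": 1})
        with pytest.raises(ValueError, match="no taxa left"):
            tables.shared_taxa_fraction(a, a)
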