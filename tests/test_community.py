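import numpy as np
import pytest
from hypothesis import given, strategies as st

from thorlink import (
    OtuTable,
    SampleRecord,
    ValidationError,
    aggregate_taxonomy,
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    rarefy,
    richness,
    surface_derived_fraction,
    unique_otu_fraction,
    vertical_dissimilarity,
)
from thorlink.model import TaxonomyMap, Lineage, metadata_by_sample
from thorlink.simulate import (
    SyntheticConfig,
    generate_dataset,
    generate_endmembers,
    reduced_config,
)


class TestRarefy:
    def test_single_otu_forced_to_depth(self):
        t = OtuTable(["S1", "S2"], ["A", "B"], np.array([[8000, 0], [0, 100]]))
        rt = rarefy(t, depth=5000, seed=0)
        assert rt.table.sample_counts("S1").sum() == 5000
        assert rt.table.counts[rt.table.sample_index("S1"), rt.table.otu_ids.index("A")] == 5000

    def test_samples_at_or_below_depth_unchanged(self):
        t = OtuTable(["S1"], ["A", "B"], np.array([[1000, 2000]]))
        rt = rarefy(t, depth=5000, seed=0)
        np.testing.assert_array_equal(rt.table.counts, [[1000, 2000]])
        assert rt.dropped_samples == []

    def test_drop_below_depth_option(self):
        t = OtuTable(["S1", "S2"], ["A", "B"], np.array([[1000, 2000], [4000, 4000]]))
        rt = rarefy(t, depth=5000, seed=0, drop_below_depth=True)
        assert rt.dropped_samples == ["S1"]
        assert rt.table.sample_ids == ["S2"]

    def test_totals_equal_min_depth_total_across_seeds(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 800, size=(6, 40))
        counts[0] = 0
        counts[0, 0] = 3000  # below depth
        t = OtuTable([f"S{i}" for i in range(6)], [f"O{j}" for j in range(40)], counts)
        expected = np.minimum(t.totals(), 5000)
        for seed in range(20):
            rt = rarefy(t, depth=5000, seed=seed)
            np.testing.assert_array_equal(rt.table.totals(), expected)

    def test_all_zero_otus_dropped(self):
        t = OtuTable(["S1"], ["A", "B"], np.array([[6000, 1]]))
        # B may be lost during subsampling; if so its column must vanish
        rt = rarefy(t, depth=100, seed=1)
        assert (rt.table.counts.sum(axis=0) > 0).all()

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        t = OtuTable(
            ["S1", "S2"], [f"O{j}" for j in range(30)],
            rng.integers(0, 1000, size=(2, 30)) + 1,
        )
        a = rarefy(t, depth=5000, seed=7)
        b = rarefy(t, depth=5000, seed=7)
        np.testing.assert_array_equal(a.table.counts, b.table.counts)

    def test_marginal_counts_are_hypergeometric(self):
        """Rarefying [6000, 6000] to 5000 matches hypergeometric moments."""
        n_rep = 1000
        t = OtuTable([f"S{i}" for i in range(n_rep)], ["A", "B"],
                     np.tile([6000, 6000], (n_rep, 1)))
        rt = rarefy(t, depth=5000, seed=3)
        a = rt.table.counts[:, rt.table.otu_ids.index("A")]
        mean_exp = 2500.0
        var_exp = 5000 * 0.5 * 0.5 * (12000 - 5000) / (12000 - 1)  # ~729.2
        assert a.mean() == pytest.approx(mean_exp, abs=5 * np.sqrt(var_exp / n_rep))
        assert a.var() == pytest.approx(var_exp, rel=0.15)


class TestRichness:
    def test_counts_nonzero_otus(self, toy_table):
        r = richness(toy_table)
        assert r.tolist() == [4, 4, 3]

    def test_single_otu_sample(self):
        t = OtuTable(["S"], ["A", "B", "C"], np.array([[0, 7, 0]]))
        assert richness(t).tolist() == [1]

    def test_warns_on_unrarefied(self, toy_table):
        with pytest.warns(UserWarning):
            richness(toy_table, rarefied=False)


class TestAggregateTaxonomy:
    def _taxmap(self):
        tm = TaxonomyMap()
        tm.lineages["OTU1"] = Lineage.from_parts(["Bacteria", "P1", "ClassA"])
        tm.lineages["OTU2"] = Lineage.from_parts(["Bacteria", "P1", "ClassA"])
        tm.lineages["OTU3"] = Lineage.from_parts(["Bacteria", "P2", "ClassB"])
        return tm

    def test_same_class_rows_are_summed(self, toy_table):
        agg = aggregate_taxonomy(toy_table, self._taxmap(), rank="class")
        assert agg.counts.loc["ClassA", "S1"] == 3  # OTU1 + OTU2
        assert "unclassified" in agg.counts.index  # OTU4 has no lineage

    def test_per_sample_relative_abundances_sum_to_one(self, toy_table):
        agg = aggregate_taxonomy(toy_table, self._taxmap(), rank="class")
        np.testing.assert_allclose(agg.relative.sum(axis=0), 1.0)
        assert agg.overall.sum() == pytest.approx(1.0)

    def test_generator_class_share_recovered(self):
        """A composition built with 55% of mass in one class yields ~55% of reads."""
        cfg = SyntheticConfig(seed=5)
        rng = np.random.default_rng(5)
        em = generate_endmembers(cfg, rng)
        comp = em.surface[("ST1", 53.0)]
        reads = rng.multinomial(1_000_000, comp)
        classes = np.asarray(em.otu_class)
        share = reads[classes == "Alphaproteobacteria"].sum() / reads.sum()
        # private pool dilutes the 0.55 class weight by (1-q) plus its own draw
        assert share == pytest.approx(0.55, abs=0.04)


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis([5, 0, 0], [0, 2, 7]) == 1.0

    def test_worked_value_five_sevenths(self):
        assert bray_curtis([2, 1, 0], [0, 1, 3]) == pytest.approx(5 / 7)

    def test_both_all_zero_errors(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
        st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
    )
    def test_symmetry_and_range(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert d == bray_curtis(y, x)
        assert 0.0 <= d <= 1.0


def _stratum_meta(n_depths=6):
    depths = [5, 25, 100, 300, 550, 700][:n_depths]
    return [
        SampleRecord(f"S{z}", "A", float(z), 53.0, 5.0) for z in depths
    ]


class TestVerticalDissimilarity:
    def test_identical_deep_sample_gives_zero(self):
        recs = _stratum_meta(2)
        t = OtuTable([r.sample_id for r in recs], ["A", "B"], np.array([[3, 4], [3, 4]]))
        out = vertical_dissimilarity(t, metadata_by_sample(recs))
        assert len(out) == 1 and out[0].bray_curtis == 0.0

    def test_six_depth_stratum_yields_five_records(self):
        recs = _stratum_meta(6)
        rng = np.random.default_rng(0)
        t = OtuTable(
            [r.sample_id for r in recs], [f"O{j}" for j in range(10)],
            rng.integers(1, 50, size=(6, 10)),
        )
        out = vertical_dissimilarity(t, metadata_by_sample(recs))
        assert len(out) == 5
        assert all(r.depth_surface == 5 for r in out)

    def test_single_sample_stratum_warns(self):
        recs = _stratum_meta(1)
        t = OtuTable(["S5"], ["A"], np.array([[3]]))
        with pytest.warns(UserWarning):
            assert vertical_dissimilarity(t, metadata_by_sample(recs)) == []

    def test_mean_dissimilarity_nondecreasing_with_depth(self):
        """Monotone depth-mixing makes surface distance grow with depth."""
        sums = {}
        for seed in range(100):
            ds = generate_dataset(reduced_config(seed=seed))
            meta = metadata_by_sample(ds.metadata)
            for r in vertical_dissimilarity(ds.table, meta):
                if r.fraction == 53.0:
                    sums.setdefault(r.depth_deep, []).append(r.bray_curtis)
        means = [np.mean(sums[z]) for z in sorted(sums)]
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))


class TestAnosim:
    def _separated(self):
        # two tight groups, all between-distances exceed within-distances
        d = np.array(
            [
                [0.0, 0.1, 0.2, 0.9, 0.8, 0.95],
                [0.1, 0.0, 0.15, 0.85, 0.9, 0.9],
                [0.2, 0.15, 0.0, 0.8, 0.85, 0.9],
                [0.9, 0.85, 0.8, 0.0, 0.1, 0.2],
                [0.8, 0.9, 0.85, 0.1, 0.0, 0.15],
                [0.95, 0.9, 0.9, 0.2, 0.15, 0.0],
            ]
        )
        return d, ["a", "a", "a", "b", "b", "b"]

    def test_perfect_separation_gives_r_one(self):
        d, g = self._separated()
        res = anosim(d, g, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.method == "exact"  # 20 labelings -> enumerated
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings reach R=1

    def test_structureless_matrix_r_near_zero(self):
        rng = np.random.default_rng(1)
        n = 16
        x = rng.random((n, 5))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        rs = [
            anosim(d, rng.permutation(["a"] * 8 + ["b"] * 8), n_permutations=99, seed=i).R
            for i in range(30)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_degenerate_grouping_errors(self):
        d, _ = self._separated()
        with pytest.raises(ValidationError):
            anosim(d, ["a"] * 6)
        with pytest.raises(ValidationError):
            anosim(d, ["a", "b", "b", "b", "b", "b"])

    def test_matches_scikit_bio(self):
        """Cross-check R against the independent skbio implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        x = rng.random((12, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = anosim(d, groups, n_permutations=99, seed=0)
        theirs = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d), grouping=list(groups), permutations=99
        )
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)


class TestSurfaceDerived:
    def _table_meta(self):
        recs = [
            SampleRecord("surf", "A", 5.0, 53.0, 5.0),
            SampleRecord("meso", "A", 550.0, 53.0, 5.0),
        ]
        # meso OTUs A:50 B:30 C:20; surface contains A and C only
        t = OtuTable(
            ["surf", "meso"],
            ["A", "B", "C"],
            np.array([[10, 0, 5], [50, 30, 20]]),
        )
        return t, metadata_by_sample(recs)

    def test_worked_percentages(self):
        t, meta = self._table_meta()
        (rec,) = surface_derived_fraction(t, meta)
        assert rec.pct_otus_surface_derived == pytest.approx(100 * 2 / 3)
        assert rec.pct_seqs_surface_derived == pytest.approx(70.0)

    def test_all_and_none_present(self):
        recs = [
            SampleRecord("surf", "A", 5.0, 53.0, 5.0),
            SampleRecord("meso", "A", 550.0, 53.0, 5.0),
        ]
        t_all = OtuTable(["surf", "meso"], ["A", "B"], np.array([[1, 1], [5, 5]]))
        (r_all,) = surface_derived_fraction(t_all, metadata_by_sample(recs))
        assert (r_all.pct_otus_surface_derived, r_all.pct_seqs_surface_derived) == (100, 100)
        t_none = OtuTable(["surf", "meso"], ["A", "B"], np.array([[9, 0], [0, 5]]))
        (r_none,) = surface_derived_fraction(t_none, metadata_by_sample(recs))
        assert (r_none.pct_otus_surface_derived, r_none.pct_seqs_surface_derived) == (0, 0)

    def test_invariant_to_column_and_sample_order(self):
        t, meta = self._table_meta()
        perm_otus = ["C", "A", "B"]
        idx = [t.otu_ids.index(o) for o in perm_otus]
        t2 = OtuTable(["meso", "surf"], perm_otus, t.counts[::-1][:, idx])
        (a,) = surface_derived_fraction(t, meta)
        (b,) = surface_derived_fraction(t2, meta)
        assert a == b

    def test_inclusive_vs_strict_surface_boundary(self):
        """A 100 m sample counts as surface only under the inclusive rule."""
        recs = [
            SampleRecord("s100", "A", 100.0, 53.0, 5.0),
            SampleRecord("s5", "A", 5.0, 53.0, 5.0),
            SampleRecord("meso", "A", 550.0, 53.0, 5.0),
        ]
        meta = metadata_by_sample(recs)
        t = OtuTable(
            ["s100", "s5", "meso"], ["A", "B"],
            np.array([[4, 1], [5, 0], [1, 9]]),
        )
        (inc,) = surface_derived_fraction(t, meta, surface_inclusive=True)
        (strict,) = surface_derived_fraction(t, meta, surface_inclusive=False)
        assert inc.pct_otus_surface_derived == 100.0  # B seen at 100 m
        assert strict.pct_otus_surface_derived == 50.0


class TestUniqueOtus:
    def _two_station_table(self):
        recs = [
            SampleRecord("A5", "A", 5.0, 53.0, 5.0),
            SampleRecord("A300", "A", 300.0, 0.2, 5.0),
            SampleRecord("B5", "B", 5.0, 53.0, 5.0),
        ]
        #         O1  O2  O3
        # A5       5   1   0
        # A300     0   2   0   (O2 unique to A via 300 m presence pooling)
        # B5       9   0   3
        t = OtuTable(
            ["A5", "A300", "B5"], ["O1", "O2", "O3"],
            np.array([[5, 1, 0], [0, 2, 0], [9, 0, 3]]),
        )
        return t, metadata_by_sample(recs)

    def test_unique_pools_all_depths_and_fractions(self):
        t, meta = self._two_station_table()
        recs = {(r.station, r.depth): r for r in unique_otu_fraction(t, meta)}
        a5 = recs[("A", 5.0)]
        assert a5.pct_otus_unique == pytest.approx(50.0)  # O2 of {O1, O2}
        assert a5.pct_seqs_unique == pytest.approx(100 * 1 / 6)
        b5 = recs[("B", 5.0)]
        assert b5.pct_otus_unique == pytest.approx(50.0)  # O3 of {O1, O3}

    def test_shared_otu_not_unique(self):
        t, meta = self._two_station_table()
        recs = {(r.station, r.depth): r for r in unique_otu_fraction(t, meta)}
        # O1 occurs in both stations: it never contributes
        assert recs[("A", 5.0)].pct_seqs_unique < 100
        assert recs[("B", 5.0)].pct_seqs_unique < 100

    def test_needs_two_stations(self):
        recs = [SampleRecord("A5", "A", 5.0, 53.0, 5.0), SampleRecord("A9", "A", 9.0, 53.0, 5.0)]
        t = OtuTable(["A5", "A9"], ["O1"], np.array([[1], [2]]))
        with pytest.raises(ValidationError):
            unique_otu_fraction(t, metadata_by_sample(recs))

    def test_private_share_recovered_from_generator(self):
        """Station-private endmember taxa at share q appear as ~q of surface reads."""
        q = 0.1
        vals = []
        for seed in range(5):
            ds = generate_dataset(SyntheticConfig(seed=seed, private_taxon_share=q))
            meta = metadata_by_sample(ds.metadata)
            uniq = unique_otu_fraction(ds.table, meta)
            vals.extend(u.pct_seqs_unique for u in uniq if u.depth == 5.0)
        # chance-unique shared OTUs add a small positive bias on top of q
        assert np.mean(vals) == pytest.approx(100 * q, abs=5.0)

    def test_unique_sequence_share_much_below_otu_share(self, rarefied_default):
        """Station-unique OTUs are numerous but rare."""
        rt, meta = rarefied_default
        uniq = unique_otu_fraction(rt.table, meta)
        mean_otus = np.mean([u.pct_otus_unique for u in uniq])
        mean_seqs = np.mean([u.pct_seqs_unique for u in uniq])
        assert mean_seqs < 0.6 * mean_otus
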