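import numpy as np
import pytest

from metacomm.community import (
    bray_curtis,
    env_distance,
    occupancy,
    rarefy,
    relative_abundance,
    spatial_distance,
    subset_by_taxon,
)
from metacomm.io_formats import OtuTable

from .conftest import make_metadata


def single_sample_table(counts, otus=None):
    otus = otus or [f"O{i}" for i in range(len(counts))]
    return OtuTable(
        ["s1"], otus, np.array([counts]), {o: "Unclassified" for o in otus}
    )


class TestRarefy:
    def test_exact_depth_is_identity(self):
        t = single_sample_table([1500, 1000])
        out = rarefy(t, 2500, seed=0)
        np.testing.assert_array_equal(out.counts, [[1500, 1000]])

    def test_single_otu_sample(self):
        t = single_sample_table([10, 0], otus=["A", "B"])
        out = rarefy(t, 5, seed=0)
        assert out.otu_ids == ["A"]  # B empty after rarefaction -> dropped
        np.testing.assert_array_equal(out.counts, [[5]])

    def test_hypergeometric_support_and_mean(self):
        # sample {A:6, B:4} at depth 5: A count must be in {1..5};
        # hypergeometric expectation is 5*6/10 = 3.0
        t = single_sample_table([6, 4], otus=["A", "B"])
        draws = []
        for seed in range(10_000):
            out = rarefy(t, 5, seed=seed)
            a = out.counts[0][out.otu_ids.index("A")] if "A" in out.otu_ids else 0
            draws.append(a)
        draws = np.array(draws)
        assert draws.min() >= 1 and draws.max() <= 5
        assert abs(draws.mean() - 3.0) < 0.05

    def test_depth_preserved_and_deterministic(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(5, 20))
        counts[0] *= 10  # ensure one deep sample
        ids = [f"s{i}" for i in range(5)]
        t = OtuTable(ids, [f"O{j}" for j in range(20)], counts,
                     {f"O{j}": "X" for j in range(20)})
        a = rarefy(t, 200, seed=42)
        b = rarefy(t, 200, seed=42)
        assert np.array_equal(a.counts, b.counts) and a.sample_ids == b.sample_ids
        assert np.all(a.sample_totals() == 200)

    def test_shallow_samples_dropped(self):
        t = OtuTable(["deep", "shallow"], ["A", "B"],
                     np.array([[100, 100], [1, 1]]),
                     {"A": "X", "B": "X"})
        out = rarefy(t, 50, seed=0)
        assert out.sample_ids == ["deep"]

    def test_all_below_depth_errors(self):
        t = single_sample_table([3, 2])
        with pytest.raises(ValueError, match="no samples survive"):
            rarefy(t, 100, seed=0)


class TestRelativeAbundance:
    def test_simple_rows(self):
        t = OtuTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[1, 1, 2], [2500, 0, 0]]),
                     {o: "X" for o in "ABC"})
        rel = relative_abundance(t)
        np.testing.assert_allclose(rel[0], [0.25, 0.25, 0.5])
        np.testing.assert_allclose(rel[1], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_mean_relative_abundance_hand_computed(self):
        t = OtuTable(["s1", "s2", "s3"], ["A", "B", "C"],
                     np.array([[1, 1, 2], [2, 2, 0], [0, 5, 5]]),
                     {o: "X" for o in "ABC"})
        rel = relative_abundance(t)
        # per-OTU mean relative abundance x100
        expected_a = 100 * (0.25 + 0.5 + 0.0) / 3
        assert 100 * rel[:, 0].mean() == pytest.approx(expected_a, abs=1e-12)

    def test_zero_sum_sample_errors(self):
        t = OtuTable(["s1"], ["A"], np.array([[0]]), {"A": "X"})
        with pytest.raises(ValueError, match="zero-sum"):
            relative_abundance(t)


class TestSubsetByTaxon:
    def test_matching_otus(self, toy_otu_table):
        sub = subset_by_taxon(toy_otu_table, "Cyanobacteria")
        assert sub.otu_ids == ["A", "B"]

    def test_class_level_proteobacteria(self, toy_otu_table):
        sub = subset_by_taxon(toy_otu_table, "Alphaproteobacteria")
        assert sub.otu_ids == ["C"]

    def test_absent_label_gives_nf_marker(self, toy_otu_table):
        assert subset_by_taxon(toy_otu_table, "Euryarchaeota") is None

    def test_no_substring_match(self, toy_otu_table):
        # "Proteobacteria" is a distinct token from "Alphaproteobacteria"
        sub = subset_by_taxon(toy_otu_table, "Proteobacteria")
        assert sub.otu_ids == ["C"]
        assert subset_by_taxon(toy_otu_table, "bacteria") is None

    def test_groups_partition_fixture(self, toy_otu_table):
        groups = ["Cyanobacteria", "Alphaproteobacteria", "Unclassified"]
        seen = []
        for g in groups:
            sub = subset_by_taxon(toy_otu_table, g)
            if sub is not None:
                seen.extend(sub.otu_ids)
        assert sorted(seen) == sorted(toy_otu_table.otu_ids)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = OtuTable(["a", "b"], ["A", "B"], np.array([[3, 4], [3, 4]]),
                     {"A": "X", "B": "X"})
        assert bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        t = OtuTable(["a", "b"], ["A", "B"], np.array([[1, 0], [0, 1]]),
                     {"A": "X", "B": "X"})
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated(self):
        t = OtuTable(["a", "b"], ["A", "B", "C"],
                     np.array([[1, 2, 3], [3, 2, 1]]), {o: "X" for o in "ABC"})
        assert bray_curtis(t).values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(6, 10))
        counts[:, 0] += 1  # no all-zero rows
        t = OtuTable([f"s{i}" for i in range(6)], [f"O{j}" for j in range(10)],
                     counts, {f"O{j}": "X" for j in range(10)})
        d = bray_curtis(t)
        for i in range(6):
            for j in range(6):
                num = sum(abs(counts[i, k] - counts[j, k]) for k in range(10))
                den = sum(counts[i, k] + counts[j, k] for k in range(10))
                expected = num / den if den else 0.0
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 9, size=(8, 12)) + 1
        t = OtuTable([f"s{i}" for i in range(8)], [f"O{j}" for j in range(12)],
                     counts, {f"O{j}": "X" for j in range(12)})
        d = bray_curtis(t)
        assert np.all((d.values >= 0) & (d.values <= 1))
        np.testing.assert_array_equal(d.values, d.values.T)

    def test_two_all_zero_samples_error(self):
        t = OtuTable(["a", "b"], ["A"], np.array([[0], [0]]), {"A": "X"})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(t)


class TestEnvDistance:
    def test_identical_samples_zero(self):
        md = make_metadata(["a", "b", "c"], env={"salinity": [7, 7, 8]})
        d = env_distance(md, ["salinity"])
        assert d.values[0, 1] == 0.0

    def test_unstandardized_single_variable(self):
        md = make_metadata(["a", "b"], env={"salinity": [0.0, 3.0]})
        d = env_distance(md, ["salinity"], standardize=False)
        assert d.values[0, 1] == pytest.approx(3.0)

    def test_zscored_hand_computed(self):
        sal = np.array([1.0, 2.0, 3.0, 4.0])
        tem = np.array([10.0, 10.0, 20.0, 20.0])
        md = make_metadata(list("abcd"), env={"salinity": sal, "temperature": tem})
        d = env_distance(md, ["salinity", "temperature"])
        zs = (sal - sal.mean()) / sal.std()
        zt = (tem - tem.mean()) / tem.std()
        expected = np.hypot(zs[0] - zs[2], zt[0] - zt[2])
        assert d.values[0, 2] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_named(self):
        md = make_metadata(["a", "b"], env={"salinity": [7.0, 7.0]})
        with pytest.raises(ValueError, match="salinity"):
            env_distance(md, ["salinity"])


class TestSpatialDistance:
    def test_same_point_zero(self):
        md = make_metadata(["a", "b"], latitudes=[56, 56], longitudes=[16, 16])
        assert spatial_distance(md).values[0, 1] == 0.0

    def test_three_four_five(self):
        md = make_metadata(["a", "b"], latitudes=[0, 3], longitudes=[0, 4])
        assert spatial_distance(md).values[0, 1] == pytest.approx(5.0)

    def test_great_circle_quarter(self):
        md = make_metadata(["a", "b"], latitudes=[0, 0], longitudes=[0, 90])
        d = spatial_distance(md, mode="great-circle")
        assert d.values[0, 1] == pytest.approx(6371.0 * np.pi / 2, rel=1e-9)

    def test_unknown_mode(self):
        md = make_metadata(["a", "b"])
        with pytest.raises(ValueError, match="mode"):
            spatial_distance(md, mode="chebyshev")


class TestOccupancy:
    def test_everywhere(self):
        t = OtuTable(["a", "b"], ["A"], np.array([[1], [2]]), {"A": "X"})
        assert 100 * occupancy(t)[0] == 100.0

    def test_nowhere(self):
        t = OtuTable(["a", "b"], ["A", "B"], np.array([[0, 1], [0, 1]]),
                     {"A": "X", "B": "X"})
        assert occupancy(t)[0] == 0.0

    def test_fraction(self):
        counts = np.zeros((63, 1), dtype=int)
        counts[:31, 0] = 1
        t = OtuTable([f"s{i}" for i in range(63)], ["A"], counts, {"A": "X"})
        assert 100 * occupancy(t)[0] == pytest.approx(49.2, abs=0.02)


class TestReorderingInvariance:
    def test_distances_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 20, size=(5, 8))
        ids = [f"s{i}" for i in range(5)]
        t = OtuTable(ids, [f"O{j}" for j in range(8)], counts,
                     {f"O{j}": "X" for j in range(8)})
        perm = [3, 1, 4, 0, 2]
        t2 = t.select_samples([ids[i] for i in perm])
        d1 = bray_curtis(t)
        d2 = bray_curtis(t2)
        np.testing.assert_allclose(
            d2.subset(ids).values, d1.values, atol=1e-12
        )
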