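"""Alpha/beta diversity, ordination, permutation ADONIS and paired tests."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from lungdecontam import SampleMeta, ZeroTotalSampleError
from lungdecontam.diversity import (
    bray_curtis,
    dna_yield_per_gram,
    paired_ttest,
    paired_wilcoxon,
    pcoa,
    permanova,
    shannon,
    shapiro_wilk,
)

from conftest import build_table


class TestShannon:
    def test_single_otu_zero(self):
        assert shannon([0, 42, 0]) == 0.0

    def test_uniform_four_otus_ln4(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))

    def test_direct_formula(self):
        p = np.array([1, 2, 3]) / 6
        assert shannon([1, 2, 3]) == pytest.approx(float(-(p * np.log(p)).sum()))

    def test_uniform_is_maximal(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            c = rng.integers(1, 50, 6)
            assert shannon(c) <= math.log(6) + 1e-12
        assert shannon([7] * 6) == pytest.approx(math.log(6))

    def test_zero_total_rejected(self):
        with pytest.raises(ZeroTotalSampleError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        t = build_table({"A": [3, 1], "B": [3, 1]}, ["x", "y"])
        assert bray_curtis(t)["A", "B"] == pytest.approx(0.0)

    def test_disjoint_support_distance_one(self):
        t = build_table({"A": [3, 0], "B": [0, 7]}, ["x", "y"])
        for weighted in (True, False):
            assert bray_curtis(t, weighted=weighted)["A", "B"] == pytest.approx(1.0)

    def test_unweighted_hand_case(self):
        t = build_table({"A": [2, 0, 1], "B": [1, 1, 0]}, ["x", "y", "z"])
        # presence vectors [1,0,1] vs [1,1,0] -> sum|diff| / sum(total) = 2/4
        assert bray_curtis(t, weighted=False)["A", "B"] == pytest.approx(0.5)

    def test_unweighted_equals_weighted_on_indicators(self):
        rng = np.random.default_rng(3)
        counts = (rng.integers(0, 5, (4, 7))).astype(int)
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = build_table({f"S{i}": list(counts[i]) for i in range(4)},
                        [f"o{j}" for j in range(7)])
        unw = bray_curtis(t, weighted=False)
        ind = (counts > 0).astype(float)
        expected = squareform(pdist(ind, metric="braycurtis"))
        assert np.allclose(unw.data, expected)

    def test_values_in_unit_interval(self, small_study):
        table, _ = small_study
        dm = bray_curtis(table.subset(sample_type="control"))
        assert ((dm.data >= 0) & (dm.data <= 1 + 1e-12)).all()
        assert np.allclose(dm.data, dm.data.T, atol=1e-12)


class TestPcoa:
    def test_two_points_embed_at_plus_minus_half_distance(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        res = pcoa(dm)
        coords = sorted(res.coordinates.iloc[:, 0].tolist())
        assert coords == pytest.approx([-0.5, 0.5])

    def test_equilateral_three_points_two_equal_eigenvalues(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        emb = res.coordinates.to_numpy()
        d_emb = squareform(pdist(emb))
        assert np.allclose(d_emb, d, atol=1e-9)

    def test_agrees_with_skbio_on_random_distances(self, small_study):
        table, _ = small_study
        dm = bray_curtis(table.subset(sample_type="control"))
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=0)
        n_pos = ours.coordinates.shape[1]
        ref_eigs = np.sort(np.asarray(ref.eigvals))[::-1][:n_pos]
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1][:n_pos], ref_eigs, atol=1e-8
        )
        # coordinates match up to per-axis sign
        ref_coords = ref.samples.to_numpy()[:, :2]
        for axis in range(2):
            a = ours.coordinates.iloc[:, axis].to_numpy()
            b = ref_coords[:, axis]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix([[0.0]], ids=["a"]))


def _block_dm():
    """4 samples, two groups, within-distance 0, between-distance 1."""
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    return DistanceMatrix(d, ids=list("abcd"))


class TestPermanova:
    def test_two_block_toy_exhaustive(self):
        res = permanova(_block_dm(), ["g1", "g1", "g2", "g2"], exhaustive=True)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pseudo_F == math.inf
        # 8 of the 24 relabelings reproduce the two-block split
        assert res.p_value == pytest.approx(2 / 6)

    def test_two_block_toy_exhaustive_matches_enumeration_oracle(self):
        dm = _block_dm()
        groups = np.array(["g1", "g1", "g2", "g2"])
        d2 = dm.data ** 2

        def pseudo_f(g):
            n = 4
            sst = sum(d2[i, j] for i, j in itertools.combinations(range(n), 2)) / n
            ssw = 0.0
            for lab in set(g):
                idx = [i for i in range(n) if g[i] == lab]
                ssw += sum(d2[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
            ssb = sst - ssw
            return math.inf if ssw == 0 else (ssb / 1) / (ssw / 2)

        f_obs = pseudo_f(groups)
        exceed = sum(
            pseudo_f(groups[list(p)]) >= f_obs
            for p in itertools.permutations(range(4))
        )
        assert exceed / 24 == pytest.approx(2 / 6)
        assert permanova(dm, groups, exhaustive=True).p_value == pytest.approx(exceed / 24)

    def test_seeded_run_is_reproducible_and_respects_b_plus_one(self):
        res1 = permanova(_block_dm(), ["g1", "g1", "g2", "g2"],
                         permutations=99, seed=5)
        res2 = permanova(_block_dm(), ["g1", "g1", "g2", "g2"],
                         permutations=99, seed=5)
        assert res1 == res2
        assert res1.p_value >= 1 / 100

    def test_sample_reordering_invariance(self, small_study):
        table, _ = small_study
        controls = table.subset(sample_type="control")
        dm = bray_curtis(controls)
        groups = list(controls.meta["extraction_kit"])
        res = permanova(dm, groups, permutations=99, seed=1)
        order = np.random.default_rng(2).permutation(len(groups))
        ids = [dm.ids[i] for i in order]
        dm_p = DistanceMatrix(dm.data[np.ix_(order, order)], ids=ids)
        res_p = permanova(dm_p, [groups[i] for i in order],
                          permutations=99, seed=1)
        assert res_p.pseudo_F == pytest.approx(res.pseudo_F)
        assert res_p.r_squared == pytest.approx(res.r_squared)

    def test_agrees_with_skbio_pseudo_f(self, small_study):
        table, _ = small_study
        controls = table.subset(sample_type="control")
        dm = bray_curtis(controls)
        groups = list(controls.meta["extraction_kit"])
        ours = permanova(dm, groups, permutations=99, seed=0)
        ref = skbio_permanova(dm, grouping=groups, permutations=99)
        assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]))

    def test_r_squared_in_unit_interval_under_random_labels(self):
        rng = np.random.default_rng(11)
        d = squareform(pdist(rng.normal(size=(8, 3))))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        for seed in range(5):
            g = np.random.default_rng(seed).choice(["x", "y"], 8)
            if len(set(g)) < 2:
                continue
            res = permanova(dm, g, permutations=49, seed=seed)
            assert 0 <= res.r_squared <= 1
            assert 0 < res.p_value <= 1


class TestPairedTests:
    def test_wilcoxon_n5_same_sign_is_exact_two_over_thirty_two(self):
        # the smallest two-sided exact p at n=5: 2/2^5
        p = paired_wilcoxon([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)

    def test_wilcoxon_single_informative_pair_p_one(self):
        p = paired_wilcoxon([1, 2, 3, 4, 5.5], [1, 2, 3, 4, 5])
        assert p == pytest.approx(1.0)

    def test_wilcoxon_swap_symmetry(self):
        a = [1.2, 3.4, 2.2, 5.0, 4.1]
        b = [2.0, 3.0, 2.5, 4.0, 4.4]
        assert paired_wilcoxon(a, b) == pytest.approx(paired_wilcoxon(b, a))

    def test_wilcoxon_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2, 3], [1, 2, 3])

    def test_ttest_matches_closed_form(self):
        a = np.array([3.1, 4.2, 5.0, 3.9, 4.4])
        b = np.array([2.5, 4.4, 4.1, 3.0, 4.0])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        from scipy import stats
        expected = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert paired_ttest(a, b) == pytest.approx(expected, abs=1e-9)

    def test_ttest_power_grows_with_shift(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 0.05, 8)
        noise = rng.normal(0, 0.01, 8)
        p_small = paired_ttest(b + 0.1 + noise, b)
        p_large = paired_ttest(b + 2.0 + noise, b)
        assert p_large < p_small

    def test_ttest_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1, 2, 3], [1, 2, 3])

    def test_shapiro_returns_probability(self):
        assert 0 < shapiro_wilk(np.random.default_rng(1).normal(size=20)) <= 1


class TestDnaYield:
    def test_worked_example(self):
        assert dna_yield_per_gram(50, 600, 1.0) == pytest.approx(30_000)

    def test_doubling_mass_halves_yield(self):
        assert dna_yield_per_gram(50, 600, 2.0) == pytest.approx(15_000)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dna_yield_per_gram(0, 600, 1.0)
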