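"""Distances, NJ trees, PCA, AMOVA, permutation tests, Fst."""

import io

import numpy as np
import pandas as pd
import pytest

from targetsnp import (
    ConfigError,
    amova,
    global_fst,
    nj_tree,
    pairwise_fst,
    pca,
    randomization_test,
    simple_matching_distance,
    simulate_structured_genotypes,
)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# simple matching distance
# ---------------------------------------------------------------------------


class TestSimpleMatchingDistance:
    def test_hand_example(self):
        gm = make_matrix([[0, 1, 2, 0], [0, 1, 0, 0]])
        D = simple_matching_distance(gm)
        assert D.iloc[0, 1] == pytest.approx(0.25)

    def test_identical_and_discordant(self):
        gm = make_matrix([[0, 1], [0, 1], [1, 2]])
        D = simple_matching_distance(gm)
        assert D.iloc[0, 1] == 0.0
        assert D.iloc[0, 2] == 1.0

    def test_missing_shrinks_denominator(self):
        gm = make_matrix([[0, 1, -1], [0, 2, 0]])
        # one mismatch of two shared loci
        assert simple_matching_distance(gm).iloc[0, 1] == pytest.approx(0.5)

    def test_no_shared_loci_flagged(self):
        gm = make_matrix([[0, -1], [-1, 0]])
        with pytest.warns(UserWarning, match="share no scored loci"):
            D = simple_matching_distance(gm)
        assert D.iloc[0, 1] == 1.0

    def test_metric_properties_on_complete_data(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        D = simple_matching_distance(make_matrix(codes)).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _parse_with_skbio(newick):
    from skbio import TreeNode

    return TreeNode.read(io.StringIO(newick))


class TestNjTree:
    def test_three_taxa_closed_form(self):
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = _parse_with_skbio(nj_tree(D))
        lengths = {t.name: t.length for t in tree.tips()}
        # la = (dab + dac - dbc)/2 etc.
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(7.0)

    def test_additive_four_taxon_split_recovered(self):
        # tree ((A,B),(C,D)) with internal branch 3
        #   A-1-x, B-2-x, x-3-y, C-4-y, D-5-y
        D = pd.DataFrame(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = _parse_with_skbio(nj_tree(D))
        # A and B must form a cherry
        a = tree.find("A")
        siblings = {t.name for t in a.parent.tips()}
        assert siblings == {"A", "B"}
        # total path lengths reproduce the additive metric
        for x, y in [("A", "B"), ("A", "C"), ("C", "D"), ("B", "D")]:
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(D.loc[x, y])

    def test_clone_pair_zero_cherry(self):
        D = pd.DataFrame(
            [[0, 0, 4], [0, 0, 4], [4, 4, 0]],
            index=list("XYZ"), columns=list("XYZ"), dtype=float,
        )
        tree = _parse_with_skbio(nj_tree(D))
        assert tree.find("X").length == pytest.approx(0.0)
        assert tree.find("Y").length == pytest.approx(0.0)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        codes = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        gm = make_matrix(codes)
        D = simple_matching_distance(gm)
        ours = _parse_with_skbio(nj_tree(D))
        theirs = skbio_nj(DistanceMatrix(D.to_numpy(), ids=list(D.index)))
        assert ours.compare_rfd(theirs) == 0.0

    def test_needs_three_taxa(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            nj_tree(D)

    def test_all_labels_present_exactly_once(self):
        gm, _ = simulate_structured_genotypes(sizes=(10,), n_loci=20, seed=3)
        newick = nj_tree(simple_matching_distance(gm))
        tree = _parse_with_skbio(newick)
        assert sorted(t.name for t in tree.tips()) == sorted(gm.samples)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_two_clusters_on_pc1(self):
        codes = np.array([[0] * 6] * 5 + [[2] * 6] * 5, dtype=np.int8)
        res = pca(make_matrix(codes), n_components=2)
        pc1 = res.coordinates["PC1"].to_numpy()
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert len(set(np.sign(pc1[:5]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[-1])

    def test_planted_rank_two_structure(self):
        # loci 0-2 separate group 1, loci 3-5 separate group 2 (orthogonal)
        codes = np.zeros((9, 6), dtype=np.int8)
        codes[3:6, :3] = 2
        codes[6:9, 3:] = 2
        res = pca(make_matrix(codes), n_components=3)
        assert res.explained_variance_ratio[:2].sum() == pytest.approx(1.0)
        assert res.explained_variance_ratio[2] == pytest.approx(0.0, abs=1e-9)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, size=(12, 15)).astype(np.int8)
        gm = make_matrix(codes)
        perm = rng.permutation(12)
        gm_p = make_matrix(codes[perm], samples=[gm.samples[i] for i in perm])
        a = pca(gm, 3).coordinates
        b = pca(gm_p, 3).coordinates
        # same coordinates per sample, up to component sign
        for pc in a.columns:
            col_a = a[pc].reindex(b.index).to_numpy()
            col_b = b[pc].to_numpy()
            assert np.allclose(col_a, col_b, atol=1e-8) or np.allclose(
                col_a, -col_b, atol=1e-8
            )

    def test_constant_matrix_warns(self):
        gm = make_matrix(np.ones((4, 4), dtype=np.int8))
        with pytest.warns(UserWarning, match="constant"):
            res = pca(gm, 2)
        assert not res.coordinates.to_numpy().any()


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def amova_oracle(codes, groups):
    """Direct-summation AMOVA from the haplotype distance-matrix definition.

    Expands every diploid sample into two haplotypes, computes squared
    distances as allele mismatch counts, and forms each SS as
    sum_{i<j in S} d2_ij / |S| over the relevant haplotype sets.
    """
    n, _ = codes.shape
    hap = np.zeros((2 * n, codes.shape[1]))
    for i in range(n):
        for j, c in enumerate(codes[i]):
            if c == 1:
                hap[2 * i, j], hap[2 * i + 1, j] = 0, 1
            else:
                hap[2 * i, j] = hap[2 * i + 1, j] = c / 2
    d2 = ((hap[:, None, :] != hap[None, :, :]).sum(axis=2)).astype(float)

    def ss(idx):
        idx = list(idx)
        tot = sum(d2[a, b] for x, a in enumerate(idx) for b in idx[x + 1:])
        return tot / len(idx)

    all_idx = range(2 * n)
    ss_total = ss(all_idx)
    labels = np.unique(groups)
    ss_within_groups = sum(
        ss([h for i in np.nonzero(groups == g)[0] for h in (2 * i, 2 * i + 1)])
        for g in labels
    )
    ss_wi = sum(ss([2 * i, 2 * i + 1]) for i in range(n))
    ss_ai = ss_within_groups - ss_wi
    ss_ag = ss_total - ss_within_groups
    a = len(labels)
    ms_ag, ms_ai, ms_wi = ss_ag / (a - 1), ss_ai / (n - a), ss_wi / n
    sizes = np.array([(groups == g).sum() for g in labels], dtype=float)
    n_cc = (2 * n - np.sum((2 * sizes) ** 2) / (2 * n)) / (a - 1)
    sigma_wi = ms_wi
    sigma_ai = (ms_ai - ms_wi) / 2
    sigma_ag = (ms_ag - ms_ai) / n_cc
    return ss_ag, ss_ai, ss_wi, sigma_ag, sigma_ai, sigma_wi


class TestAmova:
    def test_total_fixation_between_pops(self):
        codes = np.array([[0] * 5] * 4 + [[2] * 5] * 4, dtype=np.int8)
        gm = make_matrix(codes)
        strata = {s: ("A" if i < 4 else "B") for i, s in enumerate(gm.samples)}
        res = amova(gm, strata)
        assert res.table.loc["among_groups", "percent"] == pytest.approx(100.0)
        assert res.table.loc["within_samples", "percent"] == pytest.approx(0.0)
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_percentages_sum_to_100(self, structured):
        gm, truth = structured
        res = amova(gm, truth.population_labels)
        assert res.table.loc[
            ["among_groups", "among_samples_within_groups", "within_samples"],
            "percent",
        ].sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(31)
        for trial in range(5):
            codes = rng.integers(0, 3, size=(20, 12)).astype(np.int8)
            sizes = [6, 5, 9]
            groups = np.repeat(["A", "B", "C"], sizes)
            gm = make_matrix(codes)
            strata = dict(zip(gm.samples, groups))
            res = amova(gm, strata)
            exp = amova_oracle(codes, groups)
            got = (
                res.table.loc["among_groups", "sum_of_squares"],
                res.table.loc["among_samples_within_groups", "sum_of_squares"],
                res.table.loc["within_samples", "sum_of_squares"],
                res.table.loc["among_groups", "variance_component"],
                res.table.loc["among_samples_within_groups", "variance_component"],
                res.table.loc["within_samples", "variance_component"],
            )
            assert got == pytest.approx(exp, abs=1e-9)

    def test_identical_samples_degenerate(self):
        codes = np.zeros((6, 4), dtype=np.int8)
        gm = make_matrix(codes)
        strata = {s: ("A" if i < 3 else "B") for i, s in enumerate(gm.samples)}
        with pytest.warns(UserWarning, match="zero total variance"):
            res = amova(gm, strata)
        assert res.degenerate
        assert np.isnan(res.table.loc["among_groups", "percent"])

    def test_single_group_rejected(self):
        gm = make_matrix([[0], [1]])
        with pytest.raises(ConfigError):
            amova(gm, {"s1": "A", "s2": "A"})


class TestRandomizationTest:
    def test_fixed_case_min_p(self):
        codes = np.array([[0] * 8] * 4 + [[2] * 8] * 4, dtype=np.int8)
        gm = make_matrix(codes)
        strata = {s: ("A" if i < 4 else "B") for i, s in enumerate(gm.samples)}
        res = randomization_test(gm, strata, n_perm=99, seed=1)
        # permutations that recreate the exact split (or its mirror) tie the
        # observed statistic, so p is small but bounded below by 1/100
        assert res.p_value >= 1 / 100
        assert res.p_value <= 0.1
        assert len(res.permuted) == 99

    def test_label_invariant_statistic_p_near_one(self):
        # no structure at all: every sample identical except noise-free split
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
        gm = make_matrix(codes)
        # statistic computed on a constant relabeling of one group vs itself:
        # permuting identical labels cannot change sigma among
        strata = {s: ("A" if i % 2 else "B") for i, s in enumerate(gm.samples)}
        res = randomization_test(gm, strata, n_perm=199, seed=3)
        # under no true structure p should not be extreme
        assert res.p_value > 0.01

    def test_seed_reproducibility_and_mc_stability(self):
        gm, truth = simulate_structured_genotypes(sizes=(10, 10), n_loci=20,
                                                  fst_star=0.3, seed=6)
        a = randomization_test(gm, truth.population_labels, n_perm=99, seed=5)
        b = randomization_test(gm, truth.population_labels, n_perm=99, seed=5)
        assert np.array_equal(a.permuted, b.permuted)
        c = randomization_test(gm, truth.population_labels, n_perm=199, seed=5)
        assert abs(a.p_value - c.p_value) < 0.05


class TestFst:
    def test_total_fixation_gives_one(self):
        codes = np.array([[0] * 6] * 4 + [[2] * 6] * 4, dtype=np.int8)
        gm = make_matrix(codes)
        pops = {s: ("A" if i < 4 else "B") for i, s in enumerate(gm.samples)}
        assert pairwise_fst(gm, pops).raw.loc["A", "B"] == pytest.approx(1.0)

    def test_null_near_zero(self):
        gm, truth = simulate_structured_genotypes(sizes=(60, 60), n_loci=80,
                                                  fst_star=0.0, seed=12)
        fst = pairwise_fst(gm, truth.population_labels)
        assert abs(fst.raw.iloc[0, 1]) < 0.02

    def test_wc_recovers_divergence_parameter(self):
        gm, truth = simulate_structured_genotypes(sizes=(100, 100), n_loci=100,
                                                  fst_star=0.2, seed=14)
        fst = pairwise_fst(gm, truth.population_labels, estimator="wc")
        assert fst.raw.iloc[0, 1] == pytest.approx(0.2, abs=0.05)
        assert global_fst(gm, truth.population_labels) == pytest.approx(0.2, abs=0.05)

    def test_monotone_in_divergence(self):
        values = []
        for f in (0.05, 0.2, 0.5):
            gm, truth = simulate_structured_genotypes(sizes=(60, 60), n_loci=80,
                                                      fst_star=f, seed=100)
            values.append(pairwise_fst(gm, truth.population_labels).raw.iloc[0, 1])
        assert values[0] < values[1] < values[2]

    def test_monomorphic_pair_undefined(self):
        codes = np.zeros((6, 3), dtype=np.int8)
        gm = make_matrix(codes)
        pops = {s: ("A" if i < 3 else "B") for i, s in enumerate(gm.samples)}
        with pytest.warns(UserWarning, match="undefined"):
            fst = pairwise_fst(gm, pops)
        assert np.isnan(fst.raw.loc["A", "B"])
        assert fst.undefined_pairs == [("A", "B")]

    def test_small_population_rejected(self):
        gm = make_matrix([[0], [1], [2]])
        with pytest.raises(ConfigError):
            pairwise_fst(gm, {"s1": "A", "s2": "A", "s3": "B"})

    def test_symmetry_and_zero_diagonal(self, structured):
        gm, truth = structured
        fst = pairwise_fst(gm, truth.population_labels)
        M = fst.raw.to_numpy()
        assert np.allclose(M, M.T, equal_nan=True)
        assert np.allclose(np.diag(M), 0)
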