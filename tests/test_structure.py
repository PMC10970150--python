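"""Gst/Nst, Hudson Fst and AMOVA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import haplogeo as hg
from haplogeo import structure as st

from conftest import make_sample_table, random_alignment


def table_from_counts(counts: dict, seqs: dict) -> hg.HaplotypeTable:
    """Build a HaplotypeTable directly from {pop: {label: count}}."""
    labels = sorted({l for row in counts.values() for l in row},
                    key=lambda l: int(l[1:]))
    df = pd.DataFrame(0, index=list(counts), columns=labels, dtype=int)
    for pop, row in counts.items():
        for l, c in row.items():
            df.loc[pop, l] = c
    return hg.HaplotypeTable(
        tuple(labels), tuple(seqs[l] for l in labels), df, pd.Series(dtype=object)
    )


def pons_petit_oracle(counts: np.ndarray, d: np.ndarray):
    """Independent, loop-based Pons & Petit estimator of (vS, vT, stat)."""
    n = counts.sum(axis=1).astype(float)
    k = counts.shape[0]
    n_tilde = k / sum(1.0 / x for x in n)
    within = []
    for p in range(k):
        freq = counts[p] / n[p]
        acc = 0.0
        for i in range(counts.shape[1]):
            for j in range(counts.shape[1]):
                acc += d[i, j] * freq[i] * freq[j]
        within.append(acc)
    vS = n_tilde / (n_tilde - 1) * np.mean(within)
    xbar = (counts / n[:, None]).mean(axis=0)
    vT = 0.0
    for i in range(counts.shape[1]):
        for j in range(counts.shape[1]):
            vT += d[i, j] * xbar[i] * xbar[j]
    vT += vS / (n_tilde * k)
    return (vT - vS) / vT


class TestPairwiseDifferences:
    def test_trivial_pairs(self):
        a = hg.Alignment.from_sequences("x", ["a", "b", "c"], ["AAAA", "AAAA", "AATT"])
        m = hg.pairwise_difference_matrix(a)
        assert m.loc("a", "b") == 0 and m.loc("a", "c") == 2

    def test_matches_hamming_oracle(self, rng):
        a = random_alignment(rng, 10, 25)
        m = hg.pairwise_difference_matrix(a)
        for i, j in itertools.combinations(range(10), 2):
            d = sum(x != y for x, y in zip(a.sequences[i], a.sequences[j]))
            assert m.values[i, j] == d


class TestGstNst:
    def test_fixed_populations_give_one(self):
        t = table_from_counts(
            {"P1": {"H1": 10}, "P2": {"H2": 10}}, {"H1": "AAAA", "H2": "TTTT"}
        )
        assert hg.gst(t) == pytest.approx(1.0)
        assert hg.nst(t, hg.haplotype_distance_matrix(t)) == pytest.approx(1.0)

    def test_identical_composition_near_zero(self):
        t = table_from_counts(
            {"P1": {"H1": 500, "H2": 500}, "P2": {"H1": 500, "H2": 500}},
            {"H1": "AAAA", "H2": "TTTT"},
        )
        assert hg.gst(t) == pytest.approx(0.0, abs=1e-3)

    def test_equal_distances_make_nst_equal_gst(self, rng):
        counts = {
            "P1": {"H1": 5, "H2": 3, "H3": 1},
            "P2": {"H1": 1, "H2": 6, "H3": 4},
            "P3": {"H1": 2, "H2": 2, "H3": 7},
        }
        t = table_from_counts(counts, {"H1": "AA", "H2": "AT", "H3": "TA"})
        k = 3
        const = st.DistanceMatrix(t.haplotype_ids, 7.5 * (1 - np.eye(k)))
        assert hg.nst(t, const) == pytest.approx(hg.gst(t), abs=1e-12)

    def test_random_tables_match_independent_oracle(self, rng):
        for _ in range(5):
            counts = rng.integers(0, 12, size=(3, 4))
            counts[:, 0] += 2  # ensure n >= 2 everywhere
            d = rng.integers(1, 9, size=(4, 4)).astype(float)
            d = np.triu(d, 1)
            d = d + d.T
            t = table_from_counts(
                {f"P{i}": {f"H{j+1}": int(counts[i, j]) for j in range(4)}
                 for i in range(3)},
                {f"H{j+1}": "A" * j + "T" * (4 - j) for j in range(4)},
            )
            dm = st.DistanceMatrix(t.haplotype_ids, d)
            assert hg.nst(t, dm) == pytest.approx(
                pons_petit_oracle(counts.astype(float), d)
            )
            identity = 1.0 - np.eye(4)
            assert hg.gst(t) == pytest.approx(
                pons_petit_oracle(counts.astype(float), identity)
            )


class TestNstGstPermutation:
    def test_equal_distance_matrix_gives_p_near_one(self):
        t = table_from_counts(
            {"P1": {"H1": 5, "H2": 2}, "P2": {"H1": 2, "H2": 5}},
            {"H1": "AA", "H2": "TT"},
        )
        const = st.DistanceMatrix(t.haplotype_ids, 3.0 * (1 - np.eye(2)))
        nst_v, gst_v, p = hg.nst_gst_permutation_test(t, const, n_perm=199, seed=5)
        assert nst_v == pytest.approx(gst_v)
        assert p > 0.9

    def test_phylogeographic_signal_gives_small_p(self):
        # three demes, each carrying its own cluster of three one-step
        # haplotypes; the clusters are many steps apart, so randomly
        # reassigning distances to labels rarely keeps similar haplotypes
        # co-occurring
        core = {"A": "AAAAAAAAAA", "B": "TTTTTTTTTT", "C": "GGGGGGGGGG"}
        seqs, counts = {}, {}
        for k, (pop, base) in enumerate(core.items()):
            labels = [f"H{3 * k + j + 1}" for j in range(3)]
            for j, l in enumerate(labels):
                s = list(base)
                if j:
                    s[j - 1] = "C"
                seqs[l] = "".join(s)
            counts[f"P{k+1}"] = {l: 4 for l in labels}
        t = table_from_counts(counts, seqs)
        _, _, p = hg.nst_gst_permutation_test(
            t, hg.haplotype_distance_matrix(t), n_perm=499, seed=11
        )
        assert p < 0.05

    def test_seed_reproducibility(self):
        t = table_from_counts(
            {"P1": {"H1": 4, "H2": 2, "H3": 3}, "P2": {"H1": 1, "H2": 5, "H3": 2}},
            {"H1": "AAAA", "H2": "ATTT", "H3": "TTTT"},
        )
        d = hg.haplotype_distance_matrix(t)
        r1 = hg.nst_gst_permutation_test(t, d, n_perm=199, seed=42)
        r2 = hg.nst_gst_permutation_test(t, d, n_perm=199, seed=42)
        assert r1 == r2
        assert 0.0 <= r1[2] <= 1.0


class TestHudsonFst:
    def test_fixed_demes_give_one(self, two_pop_fixed):
        aln, samples = two_pop_fixed
        assert hg.hudson_fst(aln, samples) == pytest.approx(1.0)

    def test_identical_composition_at_most_zero(self):
        # with identical compositions Hw >= Hb slightly (sampling without
        # replacement), so the estimate is ~0 from below and shrinks with n
        samples = make_sample_table({"P1": 30, "P2": 30})
        seqs = (["AAAA", "TTTT", "AATT"] * 10) * 2
        aln = hg.Alignment.from_sequences("x", samples["sample_id"], seqs)
        fst = hg.hudson_fst(aln, samples)
        assert -0.05 < fst <= 1e-12

    def test_matches_brute_force_sums(self, rng):
        samples = make_sample_table({"P1": 7, "P2": 5})
        aln = random_alignment(rng, 12, 20, ids=list(samples["sample_id"]))
        pops = dict(zip(samples["sample_id"], samples["population"]))
        hw, cw, hb, cb = 0, 0, 0, 0
        for (i1, s1), (i2, s2) in itertools.combinations(
            zip(aln.sample_ids, aln.sequences), 2
        ):
            d = sum(a != b for a, b in zip(s1, s2))
            if pops[i1] == pops[i2]:
                hw, cw = hw + d, cw + 1
            else:
                hb, cb = hb + d, cb + 1
        assert hg.hudson_fst(aln, samples) == pytest.approx(
            1 - (hw / cw) / (hb / cb)
        )

    def test_pairwise_matrix_consistent_with_two_pop_call(self, rng):
        samples = make_sample_table({"P1": 5, "P2": 6, "P3": 4})
        aln = random_alignment(rng, 15, 30, ids=list(samples["sample_id"]),
                               alphabet="AG")
        pw = hg.pairwise_hudson_fst(aln, samples)
        sub_samples = samples[samples.population.isin(["P1", "P3"])]
        sub = aln.subset(list(sub_samples["sample_id"]))
        assert pw.loc("P1", "P3") == pytest.approx(hg.hudson_fst(sub, sub_samples))


class TestAmova:
    def test_hand_computed_three_population_toy(self):
        # n = 2,2,2; distances chosen for easy hand algebra
        samples = make_sample_table({"A": 2, "B": 2, "C": 2})
        ids = tuple(samples["sample_id"])
        d = np.array(
            [
                [0, 1, 4, 4, 9, 9],
                [1, 0, 4, 4, 9, 9],
                [4, 4, 0, 2, 9, 9],
                [4, 4, 2, 0, 9, 9],
                [9, 9, 9, 9, 0, 3],
                [9, 9, 9, 9, 3, 0],
            ],
            dtype=float,
        )
        dm = st.DistanceMatrix(ids, d)
        res = hg.amova(dm, samples, n_perm=100, seed=0)
        # hand solution: SS_total = sum upper/6, SS_within = (1+2+3)/2
        ss_total = d[np.triu_indices(6, 1)].sum() / 6
        ss_within = (1 + 2 + 3) / 2
        assert res.ss_within == pytest.approx(ss_within)
        assert res.ss_among == pytest.approx(ss_total - ss_within)
        ms_within = ss_within / 3
        ms_among = (ss_total - ss_within) / 2
        n0 = (6 - (4 + 4 + 4) / 6) / 2
        sigma_a = (ms_among - ms_within) / n0
        assert res.sigma2_b == pytest.approx(ms_within)
        assert res.sigma2_a == pytest.approx(sigma_a)
        assert res.phi_st == pytest.approx(sigma_a / (sigma_a + ms_within))
        assert res.df_among == 2 and res.df_within == 3

    def test_two_fixed_demes_all_variance_among(self, two_pop_fixed):
        aln, samples = two_pop_fixed
        res = hg.amova(
            hg.pairwise_difference_matrix(aln), samples, n_perm=100, seed=3
        )
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.p_value <= 1 / 101 + 1e-12

    def test_matches_hudson_on_balanced_two_deme_design(self, rng):
        samples = make_sample_table({"P1": 8, "P2": 8})
        aln = random_alignment(rng, 16, 40, ids=list(samples["sample_id"]),
                               alphabet="ACG")
        res = hg.amova(
            hg.pairwise_difference_matrix(aln), samples, n_perm=100, seed=1
        )
        assert res.phi_st == pytest.approx(hg.hudson_fst(aln, samples), abs=1e-6)

    def test_permutation_seed_reproducible(self, rng):
        samples = make_sample_table({"P1": 5, "P2": 5})
        aln = random_alignment(rng, 10, 15, ids=list(samples["sample_id"]))
        dm = hg.pairwise_difference_matrix(aln)
        r1 = hg.amova(dm, samples, n_perm=150, seed=9)
        r2 = hg.amova(dm, samples, n_perm=150, seed=9)
        assert r1 == r2
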