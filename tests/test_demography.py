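"""Neutrality statistics, mismatch spectra and sudden-expansion fitting."""

import math
from fractions import Fraction

import numpy as np
import pytest

import haplogeo as hg
from haplogeo import demography as dem

from conftest import random_alignment


def stirling_row(n):
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (m - 1) * (
                row[k] if k < len(row) else 0
            )
        row = new
    return row


class TestTajimasD:
    def test_monomorphic_is_nan(self):
        a = hg.Alignment.from_sequences("x", ["a", "b", "c", "d"], ["ACGT"] * 4)
        assert math.isnan(hg.tajimas_d(a))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dendropy_oracle(self, seed):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import popgenstat

        rng = np.random.default_rng(seed)
        a = random_alignment(rng, 8, 50, p=[0.7, 0.1, 0.1, 0.1])
        fasta = "".join(f">{i}\n{s}\n" for i, s in zip(a.sample_ids, a.sequences))
        dmat = dendropy.DnaCharacterMatrix.get(data=fasta, schema="fasta")
        assert hg.tajimas_d(a) == pytest.approx(popgenstat.tajimas_d(dmat))

    def test_star_genealogy_excess_singletons_negative(self):
        # every variant private to one sequence: classic expansion signature
        n, L = 10, 60
        seqs = []
        base = "A" * L
        for i in range(n):
            s = list(base)
            for j in range(3):
                s[i * 5 + j] = "T"
            seqs.append("".join(s))
        a = hg.Alignment.from_sequences("x", [f"s{i}" for i in range(n)], seqs)
        assert hg.tajimas_d(a) < 0

    def test_brute_force_formula_small_instance(self, rng):
        a = random_alignment(rng, 5, 30, alphabet="AT", p=[0.85, 0.15])
        n = 5
        s = dem.segregating_sites(a)
        k_hat = dem.mean_pairwise_differences(a)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        expected = (k_hat - s / a1) / math.sqrt(
            (c1 / a1) * s + (c2 / (a1**2 + a2)) * s * (s - 1)
        )
        assert hg.tajimas_d(a) == pytest.approx(expected)


class TestFuFs:
    @pytest.mark.parametrize("n", [2, 5, 10, 20])
    @pytest.mark.parametrize("theta", [0.3, 1.0, 4.7])
    def test_ewens_pmf_normalises(self, n, theta):
        assert sum(np.exp(dem.ewens_log_pmf(n, theta))) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,khat,kobs", [(5, 1.4, 3), (8, 2.25, 5), (6, 0.9, 2)])
    def test_matches_exact_fraction_oracle(self, n, khat, kobs):
        th = Fraction(khat).limit_denominator(10**9)
        s1 = stirling_row(n)
        denom = math.prod(th + i for i in range(n))
        probs = [Fraction(s1[k]) * th**k / denom for k in range(n + 1)]
        sp = float(sum(probs[kobs:]))
        expected = math.log(sp / (1 - sp))
        assert dem.fu_fs_from_summary(n, khat, kobs) == pytest.approx(expected)

    def test_many_unique_haplotypes_strongly_negative(self):
        # 12 distinct haplotypes at modest k_hat: expansion signature
        assert dem.fu_fs_from_summary(12, 1.5, 12) < -5

    def test_monomorphic_is_nan(self):
        a = hg.Alignment.from_sequences("x", ["a", "b", "c"], ["ACGT"] * 3)
        assert math.isnan(hg.fu_fs(a))


class TestNeutralityPValues:
    def test_null_median_gives_half(self):
        rng = np.random.default_rng(3)
        sims = []
        for _ in range(300):
            muts = dem._simulate_sample(10, 2.0, rng)
            s, k_hat, _ = dem._summaries_from_mutsets(muts)
            d = dem.tajimas_d_from_summary(10, s, k_hat)
            sims.append(0.0 if not math.isfinite(d) else d)
        med = float(np.median(sims))
        p = dem.neutrality_p_value("D", med, 10, 2.0, n_reps=500, seed=9)
        assert 0.35 < p < 0.65

    def test_seed_reproducible_and_bounded(self):
        p1 = dem.neutrality_p_value("Fs", -1.2, 8, 1.5, n_reps=200, seed=4)
        p2 = dem.neutrality_p_value("Fs", -1.2, 8, 1.5, n_reps=200, seed=4)
        assert p1 == p2 and 0.0 <= p1 <= 1.0

    def test_degenerate_statistic_gives_one(self):
        assert dem.neutrality_p_value("D", float("nan"), 10, 1.0, 200, 1) == 1.0

    def test_expansion_samples_give_small_p_for_d(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 15
        for _ in range(reps):
            muts = dem._simulate_sample(25, 60.0, rng, tau=6.0, theta_anc=0.3)
            s, k_hat, _ = dem._summaries_from_mutsets(muts)
            d = dem.tajimas_d_from_summary(25, s, k_hat)
            a1 = sum(1 / i for i in range(1, 25))
            p = dem.neutrality_p_value(
                "D", d, 25, s / a1, n_reps=200, seed=int(rng.integers(2**31))
            )
            hits += p < 0.10
        assert hits >= reps // 2


class TestMismatchObserved:
    def test_monomorphic_point_mass(self):
        a = hg.Alignment.from_sequences("x", ["a", "b", "c"], ["AAAA"] * 3)
        assert list(hg.mismatch_observed(a)) == [1.0]

    def test_two_haplotype_enumeration(self):
        # two haplotypes at distance 2 with counts (3, 2):
        # within-class pairs C(3,2)+C(2,2) = 4 of 10 at distance 0,
        # cross pairs 3*2 = 6 of 10 at distance 2.
        a = hg.Alignment.from_sequences(
            "x", list("abcde"), ["AAAA"] * 3 + ["TTAA"] * 2
        )
        spec = hg.mismatch_observed(a)
        assert spec == pytest.approx([0.4, 0.0, 0.6])

    def test_matches_pair_enumeration(self, rng):
        import itertools

        a = random_alignment(rng, 8, 20)
        diffs = [
            sum(x != y for x, y in zip(s1, s2))
            for s1, s2 in itertools.combinations(a.sequences, 2)
        ]
        expected = np.bincount(diffs) / len(diffs)
        assert hg.mismatch_observed(a) == pytest.approx(expected)


class TestExpansionSpectrum:
    def test_stationary_limit_is_geometric(self):
        theta = 2.5
        spec = hg.expansion_expected_spectrum(theta, theta, 0.0, 25)
        i = np.arange(26)
        geom = theta**i / (1 + theta) ** (i + 1)
        assert spec == pytest.approx(geom / geom.sum())

    @pytest.mark.parametrize("params", [(1, 100, 5), (0, 50, 12), (3, 3, 2)])
    def test_normalisation(self, params):
        t0, t1, tau = params
        assert hg.expansion_expected_spectrum(t0, t1, tau, 40).sum() == pytest.approx(1.0)

    def test_large_tau_zero_theta0_is_poisson_peak(self):
        tau = 15.0
        spec = hg.expansion_expected_spectrum(0.0, 5000.0, tau, 60)
        from scipy import stats

        pois = stats.poisson.pmf(np.arange(61), tau)
        assert spec == pytest.approx(pois / pois.sum(), abs=5e-3)
        assert abs(int(np.argmax(spec)) - tau) <= 1


class TestRaggedness:
    def test_point_mass_is_two(self):
        assert hg.raggedness([1.0]) == pytest.approx(2.0)

    @pytest.mark.parametrize("d", [1, 4, 9])
    def test_uniform_closed_form(self, d):
        assert hg.raggedness([1 / (d + 1)] * (d + 1)) == pytest.approx(2 / (d + 1) ** 2)

    def test_matches_direct_summation(self, rng):
        x = rng.dirichlet(np.ones(12))
        padded = np.r_[0.0, x, 0.0]
        expected = sum((padded[i] - padded[i - 1]) ** 2 for i in range(1, 14))
        assert hg.raggedness(x) == pytest.approx(expected)


class TestFitExpansion:
    def test_self_consistency_recovery(self):
        spec = hg.expansion_expected_spectrum(1.0, 100.0, 5.0, 35)
        fit = hg.fit_expansion(spec)
        assert fit.ssd < 1e-8
        assert fit.theta0 == pytest.approx(1.0, abs=0.1)
        assert fit.tau == pytest.approx(5.0, abs=0.2)

    def test_off_grid_recovery(self):
        spec = hg.expansion_expected_spectrum(0.8, 73.0, 4.4, 30)
        fit = hg.fit_expansion(spec)
        assert fit.ssd < 1e-8

    def test_point_mass_boundary_fit(self):
        fit = hg.fit_expansion(np.array([1.0]))
        assert fit.ssd < 1e-12
        assert fit.tau == pytest.approx(0.0, abs=1e-6) or fit.theta0 == pytest.approx(
            0.0, abs=1e-6
        )


class TestBootstrapMismatch:
    def test_p_values_bounded_and_reproducible(self):
        spec = hg.expansion_expected_spectrum(0.5, 50.0, 4.0, 20)
        fit = hg.fit_expansion(spec)
        b1 = hg.bootstrap_mismatch_tests(fit, n=20, n_reps=100, seed=21)
        b2 = hg.bootstrap_mismatch_tests(fit, n=20, n_reps=100, seed=21)
        assert (b1.p_ssd, b1.p_rag) == (b2.p_ssd, b2.p_rag)
        assert 0.0 <= b1.p_ssd <= 1.0 and 0.0 <= b1.p_rag <= 1.0
        # the observed spectrum IS the model expectation: it should not be
        # flagged as a poor fit
        assert b1.p_ssd > 0.5

    def test_sawtooth_spectrum_rejected(self):
        obs = np.zeros(21)
        obs[[0, 7, 14, 20]] = 0.25  # strongly multimodal
        fit = hg.fit_expansion(obs)
        b = hg.bootstrap_mismatch_tests(fit, n=25, n_reps=100, seed=5)
        assert b.p_ssd < 0.1


def test_expansion_sign_pattern_majority():
    """Sudden growth leaves both D and Fs negative in most replicates."""
    rng = np.random.default_rng(99)
    both_negative = 0
    reps = 20
    for _ in range(reps):
        muts = dem._simulate_sample(30, 80.0, rng, tau=5.0, theta_anc=0.5)
        s, k_hat, k = dem._summaries_from_mutsets(muts)
        d = dem.tajimas_d_from_summary(30, s, k_hat)
        fs = dem.fu_fs_from_summary(30, k_hat, k)
        both_negative += (d < 0) and (fs < 0)
    assert both_negative > reps / 2
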