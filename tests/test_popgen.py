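"""Polymorphism, neutrality and differentiation statistics against
independent brute-force oracles."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from introdiv import popgen
from introdiv.alignments import filter_sites

from conftest import make_alignment


# ---------------------------------------------------------------------------
# oracles: explicit pair enumeration and textbook formulas


def pair_diffs(seqs, sites):
    return [
        sum(a[i] != b[i] for i in sites) for a, b in combinations(seqs, 2)
    ]


def cross_pair_diffs(seqsA, seqsB, sites):
    return [sum(a[i] != b[i] for i in sites) for a in seqsA for b in seqsB]


def oracle_tajimas_d(n, s, pi_tot):
    """Independent implementation of the 1989 constants-and-formula chain."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_tot - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def oracle_stirling_tail(n, k_obs, theta):
    """Direct summation of |s(n,k)| theta^k / theta^(n) over k >= k_obs."""
    table = {(0, 0): 1}
    for m in range(1, n + 1):
        for k in range(0, m + 1):
            table[(m, k)] = (m - 1) * table.get((m - 1, k), 0) + table.get((m - 1, k - 1), 0)
    th = Fraction(theta)
    rising = Fraction(1)
    for i in range(n):
        rising *= th + i
    return sum(Fraction(table[(n, k)]) * th**k for k in range(k_obs, n + 1)) / rising


def random_two_pop(rng, n_max=8, L_max=12):
    nA = int(rng.integers(2, n_max // 2 + 1))
    nB = int(rng.integers(2, n_max // 2 + 1))
    L = int(rng.integers(2, L_max + 1))
    seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(nA + nB)]
    aln = make_alignment(seqs, pops=("A",) * nA + ("B",) * nB)
    return aln.subset_population("A"), aln.subset_population("B")


# ---------------------------------------------------------------------------


class TestSegregatingSites:
    def test_invariant_alignment(self):
        s, _ = popgen.segregating_sites(make_alignment(["ACGT"] * 4))
        assert s == 0

    def test_hand_enumerated_columns(self):
        # columns 1 and 4 (1-based) vary across {ACGT, ACGA, ACGT, CCGT}
        s, sites = popgen.segregating_sites(
            make_alignment(["ACGT", "ACGA", "ACGT", "CCGT"])
        )
        assert s == 2
        assert list(sites) == [0, 3]

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            popgen.segregating_sites(make_alignment(["ACGT"]))


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert popgen.nucleotide_diversity(make_alignment(["ACGTACGTAC"] * 3)) == 0.0

    def test_single_pair_single_difference(self):
        aln = make_alignment(["ACGTACGTAC", "ACGTACGTAA"])
        assert popgen.nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_three_sequences_brute_force(self):
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATA"])
        # pairwise diffs {1, 1, 2} over 10 sites
        assert popgen.nucleotide_diversity(aln) == pytest.approx((4 / 3) / 10)

    def test_empty_kept_sites_signalled(self):
        aln = make_alignment(["NN", "AC"])
        with pytest.warns(UserWarning):
            filtered = filter_sites(aln)
        with pytest.raises(ValueError):
            popgen.nucleotide_diversity(filtered)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, _ = random_two_pop(rng)
        sites = list(a.kept_sites)
        expected = np.mean(pair_diffs(a.sequences, sites)) / len(sites)
        assert popgen.nucleotide_diversity(a) == pytest.approx(expected, abs=1e-12)


class TestTajimasD:
    def test_undefined_for_no_segregating_sites(self):
        assert math.isnan(popgen.tajimas_d(make_alignment(["ACGT"] * 5)))

    def test_all_singletons_negative(self):
        base = "A" * 10
        seqs = [base] + [base[:i] + "T" + base[i + 1:] for i in range(5)]
        assert popgen.tajimas_d(make_alignment(seqs)) < 0

    def test_matches_independent_formula_chain(self):
        rng = np.random.default_rng(42)
        seqs = ["".join(rng.choice(list("AT"), size=30)) for _ in range(10)]
        aln = make_alignment(seqs)
        s, _ = popgen.segregating_sites(aln)
        pi_tot = popgen.pi_total(aln)
        assert s > 0
        assert popgen.tajimas_d(aln) == pytest.approx(
            oracle_tajimas_d(10, s, pi_tot), abs=1e-12
        )

    def test_zero_exactly_when_pi_equals_watterson(self):
        # synthetic (n, S, pi_tot) combinations on the boundary
        a1 = sum(1 / i for i in range(1, 8))
        assert popgen._tajimas_d_from(8, 5, 5 / a1) == pytest.approx(0.0, abs=1e-12)


class TestFusFs:
    def test_single_haplotype_clamps(self):
        res = popgen._fus_fs_from(5, 1, 2.0)
        assert res.s_prime == 1.0
        assert res.clamped
        assert res.fs > 0

    def test_maximal_haplotype_diversity_negative(self):
        # every sequence its own haplotype, low theta: strong excess
        res = popgen._fus_fs_from(8, 8, 0.5)
        assert res.fs < 0

    def test_matches_stirling_summation_oracle(self):
        sp = popgen.ewens_k_tail(5, 3, 1.0)
        assert sp == oracle_stirling_tail(5, 3, 1.0)
        res = popgen._fus_fs_from(5, 3, 1.0)
        expected = oracle_stirling_tail(5, 3, 1.0)
        assert res.fs == pytest.approx(math.log(expected / (1 - expected)), abs=1e-12)

    def test_float_path_agrees_with_exact(self):
        for n, k, th in [(10, 4, 2.3), (20, 12, 5.0), (42, 30, 8.1)]:
            exact = popgen._fus_fs_from(n, k, th, exact=True).fs
            fast = popgen._fus_fs_from(n, k, th, exact=False).fs
            assert fast == pytest.approx(exact, rel=1e-9)

    def test_undefined_for_s_zero(self):
        with pytest.raises(ValueError):
            popgen.fus_fs(make_alignment(["ACGT"] * 5))


class TestR2:
    def test_two_sequence_case(self):
        aln = make_alignment(["AAAAAAAAAA", "TAAAAAAAAA"])
        # U = {1, 1}, pi_tot = 1, S = 1 -> sqrt(mean((1-0.5)^2))/1 = 0.5
        assert popgen.ramos_onsins_r2(aln) == pytest.approx(0.5)

    def test_no_singletons_closed_form(self):
        # 4 sequences, one site with 2/2 split: pi_tot = 4*1/6*2 ... compute directly
        aln = make_alignment(["AT", "AT", "AA", "AA"])
        s, _ = popgen.segregating_sites(aln)
        pi_tot = popgen.pi_total(aln)
        u = popgen.singleton_counts(aln)
        assert list(u) == [0, 0, 0, 0]
        expected = math.sqrt(np.mean((u - pi_tot / 2) ** 2)) / s
        assert popgen.ramos_onsins_r2(aln) == pytest.approx(expected, abs=1e-12)

    def test_undefined_for_s_zero(self):
        assert math.isnan(popgen.ramos_onsins_r2(make_alignment(["ACGT"] * 3)))


class TestDxy:
    def test_reciprocally_fixed(self):
        a = make_alignment(["A" * 100] * 3)
        b = make_alignment(["T" + "A" * 99] * 3)
        assert popgen.dxy(a, b) == pytest.approx(0.01)

    def test_identical_populations_equals_pi(self):
        seqs = ["ACGTACGTAC", "ACGAACGTAC", "ACGTACGTAT"]
        a = make_alignment(seqs)
        b = make_alignment(seqs)
        # between two copies of the same pool, dxy >= pi (self-pairs excluded in pi)
        expected = np.mean(cross_pair_diffs(seqs, seqs, range(10))) / 10
        assert popgen.dxy(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cross_pair_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_two_pop(rng)
        sites = list(a.kept_sites)
        expected = np.mean(cross_pair_diffs(a.sequences, b.sequences, sites)) / len(sites)
        assert popgen.dxy(a, b) == pytest.approx(expected, abs=1e-12)

    def test_kept_sites_mismatch_rejected(self):
        a = make_alignment(["ACGT", "ACGA"])
        b = filter_sites(make_alignment(["AC-T", "ACGA"]))
        with pytest.raises(ValueError, match="kept_sites"):
            popgen.dxy(a, b)


class TestClassifyPolymorphisms:
    def test_fixed_difference(self):
        a = make_alignment(["AAAA"] * 3)
        b = make_alignment(["TAAA"] * 3)
        assert popgen.classify_polymorphisms(a, b) == popgen.SiteClasses(0, 1, 0, 0)

    def test_shared_polymorphism(self):
        a = make_alignment(["AAAA", "TAAA"])
        b = make_alignment(["AAAA", "TAAA"])
        assert popgen.classify_polymorphisms(a, b).ss == 1

    def test_exclusive_polymorphism(self):
        a = make_alignment(["AAAA", "TAAA"])
        b = make_alignment(["AAAA", "AAAA"])
        c = popgen.classify_polymorphisms(a, b)
        assert (c.sx1, c.sx2) == (1, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b = random_two_pop(rng)
        c = popgen.classify_polymorphisms(a, b)
        not_mono_identical = 0
        for col in a.kept_sites:
            residues = {s[col] for s in a.sequences} | {s[col] for s in b.sequences}
            if len(residues) > 1:
                not_mono_identical += 1
        assert c.ss + c.sf + c.sx1 + c.sx2 == not_mono_identical


class TestHudsonFst:
    def test_reciprocally_fixed_is_one(self):
        a = make_alignment(["AAAA"] * 3)
        b = make_alignment(["TTTT"] * 3)
        assert popgen.hudson_fst(a, b) == pytest.approx(1.0)

    def test_no_variation_undefined(self):
        a = make_alignment(["AAAA"] * 3)
        b = make_alignment(["AAAA"] * 3)
        assert math.isnan(popgen.hudson_fst(a, b))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        a, b = random_two_pop(rng)
        sites = list(a.kept_sites)
        hw = 0.5 * (
            np.mean(pair_diffs(a.sequences, sites))
            + np.mean(pair_diffs(b.sequences, sites))
        )
        hb = np.mean(cross_pair_diffs(a.sequences, b.sequences, sites))
        if hb == 0:
            assert math.isnan(popgen.hudson_fst(a, b))
        else:
            assert popgen.hudson_fst(a, b) == pytest.approx(1 - hw / hb, abs=1e-12)

    def test_invariant_under_sequence_reordering(self):
        rng = np.random.default_rng(7)
        a, b = random_two_pop(rng, n_max=8, L_max=10)
        perm = rng.permutation(a.n)
        a2 = a.subset_indices(list(perm))
        assert popgen.hudson_fst(a2, b) == pytest.approx(
            popgen.hudson_fst(a, b), abs=1e-12
        )
        assert popgen.pi_total(a2) == pytest.approx(popgen.pi_total(a), abs=1e-12)


class TestFstPermutation:
    def test_maximal_differentiation_minimal_p(self):
        a = make_alignment(["AAAA"] * 5)
        b = make_alignment(["TTTT"] * 5)
        res = popgen.fst_permutation_test(a, b, n_perm=200, seed=1)
        assert res.fst == pytest.approx(1.0)
        assert res.p <= 5 / 201

    def test_null_p_uniform_mean(self):
        # labels assigned at random within one pool: p should be ~U, mean ~0.5
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(40):
            seqs = ["".join(rng.choice(list("AT"), size=12)) for _ in range(10)]
            aln = make_alignment(seqs, pops=("A",) * 5 + ("B",) * 5)
            res = popgen.fst_permutation_test(
                aln.subset_population("A"), aln.subset_population("B"),
                n_perm=99, seed=int(rng.integers(2**31)),
            )
            ps.append(res.p)
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_zero_permutations_rejected(self):
        a = make_alignment(["AAAA", "AATA"])
        b = make_alignment(["TTTT", "TTAT"])
        with pytest.raises(ValueError):
            popgen.fst_permutation_test(a, b, n_perm=0)

    def test_seeded_determinism(self):
        a = make_alignment(["AAAA", "AATA", "ATAA"])
        b = make_alignment(["TTAT", "TTTT", "TATT"])
        r1 = popgen.fst_permutation_test(a, b, n_perm=100, seed=5)
        r2 = popgen.fst_permutation_test(a, b, n_perm=100, seed=5)
        assert r1 == r2


class TestNeutralNull:
    def test_null_mean_d_slightly_negative(self):
        null = popgen.simulate_neutral_stats(15, 10, n_reps=2000, seed=3)
        # conditional-on-S D has mean a bit below 0 in finite samples
        assert -0.5 < np.mean(null["D"]) < 0.2

    def test_pvalues_reasonable_for_neutral_data(self):
        rng = np.random.default_rng(4)
        import msprime

        ts = msprime.sim_ancestry(10, population_size=0.5, ploidy=1, random_seed=9)
        from introdiv.im import _drop_mutations, genotypes_to_alignment, SimLocusSpec

        g = _drop_mutations(ts, np.random.default_rng(9))
        aln = genotypes_to_alignment(g, SimLocusSpec(5, 5, 200), rng)
        p = popgen.neutrality_pvalues(aln, n_reps=500, seed=21)
        assert all(0 < v <= 1 for v in p.values())


# ---------------------------------------------------------------------------
# hypothesis property tests


from hypothesis import given, settings, strategies as st


@st.composite
def random_alignment_strategy(draw, min_n=2, max_n=6, min_L=2, max_L=10, alphabet="ACGT"):
    n = draw(st.integers(min_n, max_n))
    L = draw(st.integers(min_L, max_L))
    seqs = [
        "".join(draw(st.sampled_from(alphabet)) for _ in range(L)) for _ in range(n)
    ]
    return make_alignment(seqs)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(random_alignment_strategy())
def test_diversity_invariant_under_reordering(aln):
    """pi and theta_W do not depend on sequence order."""
    rev = aln.subset_indices(list(range(aln.n))[::-1])
    assert popgen.pi_total(rev) == pytest.approx(popgen.pi_total(aln), abs=1e-12)
    assert popgen.watterson_theta(rev) == pytest.approx(
        popgen.watterson_theta(aln), abs=1e-12
    )


@settings(max_examples=40, derandomize=True, deadline=None)
@given(random_alignment_strategy(min_n=4, alphabet="ACGT-N"))
def test_filter_sites_idempotent_property(aln):
    once = filter_sites(aln)
    twice = filter_sites(once)
    assert np.array_equal(once.kept_sites, twice.kept_sites)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(random_alignment_strategy(min_n=4, max_n=8))
def test_site_class_partition_property(aln):
    """Shared + fixed + exclusive columns = all non-monomorphic-identical
    columns, for any split of the sequences into two populations."""
    half = aln.n // 2
    a = aln.subset_indices(range(half))
    b = aln.subset_indices(range(half, aln.n))
    c = popgen.classify_polymorphisms(a, b)
    non_identical = sum(
        1 for col in aln.kept_sites
        if len({s[col] for s in aln.sequences}) > 1
    )
    assert c.ss + c.sf + c.sx1 + c.sx2 == non_identical


class TestNeutralCalibration:
    def test_tajimas_d_mean_and_rejection_under_neutral_model(self):
        """On loci simulated under the neutral constant-size coalescent,
        mean D sits near its slightly negative finite-sample value and the
        5% conditional-null test rejects at close to the nominal rate."""
        from introdiv.im import IMParams, SimLocusSpec, simulate_im_genotypes_batch

        n, theta = 10, 3.0
        p = IMParams(theta, theta, theta, 1e6, 0.0, 0.0)
        d_values = []
        s_values = []
        for g in simulate_im_genotypes_batch(p, SimLocusSpec(n, 0, 10**6), 500, seed=99):
            s = g.shape[0]
            if s == 0:
                continue
            counts = g.sum(axis=1)
            pi_tot = float(np.sum(2 * counts * (n - counts)) / (n * (n - 1)))
            d_values.append(popgen._tajimas_d_from(n, s, pi_tot))
            s_values.append(s)
        d_values = np.asarray(d_values)
        se = d_values.std() / math.sqrt(len(d_values))
        # finite-sample E[D] is slightly below zero
        assert -0.15 - 3 * se < d_values.mean() < 0.0 + 3 * se

        # empirical two-sided 5% rejection via conditional-on-S nulls
        null_cache = {}
        rejections = 0
        rng = np.random.default_rng(7)
        for d, s in zip(d_values, s_values):
            if s not in null_cache:
                null = popgen.simulate_neutral_stats(n, s, n_reps=400, seed=rng)["D"]
                null_cache[s] = (np.quantile(null, 0.025), np.quantile(null, 0.975))
            lo, hi = null_cache[s]
            if d < lo or d > hi:
                rejections += 1
        rate = rejections / len(d_values)
        assert rate < 0.10  # nominal 5% plus Monte-Carlo slack
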