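import itertools

import numpy as np
import pytest

from amplihap.core import SegmentGenotype
from amplihap.diversity import frequency_table, pic
from amplihap.identity import (
    capacity,
    cumulative_discrimination,
    fingerprint_code,
    genotype_match_probs,
    minimal_marker_set,
    pi_random,
    pi_sib,
    profile_match_probs,
)
from amplihap.phasing import collapse_genotypes

from conftest import make_profile

# ---------------------------------------------------------------------------
# Enumeration oracles under HWE and Mendelian segregation
# ---------------------------------------------------------------------------


def hwe_genotypes(p):
    """Unordered genotypes (i, j) with their HWE probabilities."""
    k = len(p)
    out = {}
    for i in range(k):
        for j in range(i, k):
            out[(i, j)] = p[i] ** 2 if i == j else 2 * p[i] * p[j]
    return out


def transmit(genotype, allele):
    i, j = genotype
    return ((allele == i) + (allele == j)) / 2


def child_dist(gm, gf, k):
    """Distribution of an offspring's unordered genotype given parents."""
    dist = {}
    for a in range(k):
        ta = transmit(gm, a)
        if ta == 0:
            continue
        for b in range(k):
            tb = transmit(gf, b)
            if tb == 0:
                continue
            g = tuple(sorted((a, b)))
            dist[g] = dist.get(g, 0.0) + ta * tb
    return dist


def pi_random_oracle(p):
    return sum(prob**2 for prob in hwe_genotypes(p).values())


def pi_sib_oracle(p):
    """P(two full sibs identical) = sum over parent pairs of
    sum_g P(g | parents)^2."""
    genos = hwe_genotypes(p)
    total = 0.0
    for gm, pm in genos.items():
        for gf, pf in genos.items():
            dist = child_dist(gm, gf, len(p))
            total += pm * pf * sum(v**2 for v in dist.values())
    return total


def sib_match_oracle(g0, p):
    """P(a sibling of an individual with genotype g0 also has g0),
    conditioning the parents on the first sib."""
    genos = hwe_genotypes(p)
    num = den = 0.0
    for gm, pm in genos.items():
        for gf, pf in genos.items():
            pg0 = child_dist(gm, gf, len(p)).get(g0, 0.0)
            num += pm * pf * pg0**2
            den += pm * pf * pg0
    return num / den


def par_off_match_oracle(g0, p):
    """P(an offspring of g0 and a random HWE mate has genotype g0)."""
    total = 0.0
    for m in set(g0):
        tm = transmit(g0, m)
        for f in range(len(p)):
            if tuple(sorted((m, f))) == g0:
                total += tm * p[f]
    return total


def random_freq_vectors(n, max_k, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        k = int(rng.integers(2, max_k + 1))
        p = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 2.0))
        p = np.maximum(p, 1e-4)
        yield p / p.sum()


def as_freqs(p):
    return {i + 1: float(x) for i, x in enumerate(p)}


# ---------------------------------------------------------------------------


class TestPiFormulas:
    def test_monomorphic_is_one(self):
        assert pi_random({1: 1.0}) == pytest.approx(1.0)
        assert pi_sib({1: 1.0}) == pytest.approx(1.0)

    def test_biallelic_half(self):
        freqs = {1: 0.5, 2: 0.5}
        assert pi_random(freqs) == pytest.approx(0.375)
        assert pi_sib(freqs) == pytest.approx(0.59375)

    def test_formulas_match_enumeration_oracles(self):
        for p in random_freq_vectors(25, 5, seed=11):
            assert pi_random(as_freqs(p)) == pytest.approx(
                pi_random_oracle(p), abs=1e-12
            )
            assert pi_sib(as_freqs(p)) == pytest.approx(
                pi_sib_oracle(p), abs=1e-12
            )

    def test_sibs_harder_to_distinguish_than_random(self):
        for p in random_freq_vectors(25, 8, seed=12):
            assert pi_sib(as_freqs(p)) >= pi_random(as_freqs(p))


class TestGenotypeMatchProbs:
    def test_fixed_allele_matches_everyone(self):
        m = genotype_match_probs(SegmentGenotype("S", (1, 1)), {1: 1.0})
        assert (m.random, m.par_off, m.sib) == (1.0, 1.0, 1.0)

    def test_biallelic_heterozygote(self):
        m = genotype_match_probs(SegmentGenotype("S", (1, 2)), {1: 0.5, 2: 0.5})
        assert (m.random, m.par_off, m.sib) == pytest.approx((0.5, 0.5, 0.625))

    def test_absent_allele_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            genotype_match_probs(SegmentGenotype("S", (1, 3)), {1: 0.5, 2: 0.5})

    def test_match_probs_against_mendelian_oracles(self):
        for p in random_freq_vectors(10, 4, seed=13):
            freqs = as_freqs(p)
            for g0 in hwe_genotypes(p):
                g = SegmentGenotype("S", (g0[0] + 1, g0[1] + 1))
                m = genotype_match_probs(g, freqs)
                assert m.random == pytest.approx(
                    hwe_genotypes(p)[g0], abs=1e-12
                )
                assert m.par_off == pytest.approx(
                    par_off_match_oracle(g0, p), abs=1e-12
                )
                assert m.sib == pytest.approx(sib_match_oracle(g0, p), abs=1e-12)

    def test_expected_match_probs_recover_pi(self):
        """Averaging per-genotype match probabilities over the HWE
        genotype distribution gives back PI and PI_sib."""
        for p in random_freq_vectors(10, 4, seed=14):
            freqs = as_freqs(p)
            e_random = e_sib = 0.0
            for g0, pg in hwe_genotypes(p).items():
                m = genotype_match_probs(
                    SegmentGenotype("S", (g0[0] + 1, g0[1] + 1)), freqs
                )
                e_random += pg * m.random
                e_sib += pg * m.sib
            assert e_random == pytest.approx(pi_random(freqs), abs=1e-12)
            assert e_sib == pytest.approx(pi_sib(freqs), abs=1e-12)


class TestCapacity:
    def test_pi_value_one_leaves_single_individual(self):
        assert capacity(1.0) == 1

    def test_capacity_monotonic(self):
        pis = [1e-2, 1e-4, 1e-6, 1e-8]
        caps = [capacity(v) for v in pis]
        assert caps == sorted(caps)
        assert capacity(1e-4, alpha=0.01) <= capacity(1e-4, alpha=0.10)

    def test_bound_is_tight(self):
        for v in (6.4e-10, 1.5e-4, 3.3e-7):
            n = capacity(v)
            assert n * (n - 1) / 2 * v <= 0.05
            assert (n + 1) * n / 2 * v > 0.05


class TestCumulativeDiscrimination:
    def test_products_shrink_and_counts_grow(self, study_skewed):
        reps = study_skewed.base_profiles
        table = frequency_table(reps)
        curve = cumulative_discrimination(reps, table)
        assert (np.diff(curve["cum_pi"]) <= 1e-18).all()
        assert (np.diff(curve["cum_pi_sib"]) <= 1e-18).all()
        assert (np.diff(curve["n_distinct"]) >= 0).all()

    def test_full_prefix_matches_collapse(self, study_skewed):
        reps = study_skewed.base_profiles
        table = frequency_table(reps)
        curve = cumulative_discrimination(reps, table)
        assert curve["n_distinct"].iloc[-1] == len(collapse_genotypes(reps))

    def test_single_monomorphic_segment(self):
        profiles = [make_profile(f"g{i}", {"S": (1, 1)}) for i in range(4)]
        table = frequency_table(profiles)
        curve = cumulative_discrimination(profiles, table, ["S"])
        assert curve["n_distinct"].iloc[0] == 1
        assert curve["cum_pi"].iloc[0] == pytest.approx(1.0)

    def test_pic_order_dominates_reverse_order(self, study_skewed):
        """Adding segments in descending-PIC order accumulates
        discrimination at least as fast as the reverse order."""
        reps = study_skewed.base_profiles
        table = frequency_table(reps)
        order = sorted(table.segment_ids, key=lambda s: (-pic(table[s]), s))
        fwd = cumulative_discrimination(reps, table, order)
        rev = cumulative_discrimination(reps, table, order[::-1])
        assert (fwd["cum_pi"].to_numpy() <= rev["cum_pi"].to_numpy() + 1e-18).all()
        assert (fwd["n_distinct"].to_numpy() >= rev["n_distinct"].to_numpy()).all()


class TestMinimalMarkerSet:
    def test_single_separating_segment(self):
        profiles = [
            make_profile(f"g{i}", {"S1": (i + 1, i + 1), "S2": (1, 1)})
            for i in range(4)
        ]
        size, subsets = minimal_marker_set(profiles)
        assert size == 1
        assert subsets == [("S1",)]

    def test_all_alternative_minimal_sets_returned(self):
        # every single segment leaves one pair merged; every 2-subset separates
        profiles = [
            make_profile("A", {"S1": (1, 1), "S2": (1, 1), "S3": (1, 1)}),
            make_profile("B", {"S1": (2, 2), "S2": (1, 1), "S3": (2, 2)}),
            make_profile("C", {"S1": (1, 1), "S2": (2, 2), "S3": (2, 2)}),
        ]
        size, subsets = minimal_marker_set(profiles)
        assert size == 2
        assert subsets == [("S1", "S2"), ("S1", "S3"), ("S2", "S3")]

    def test_matches_exhaustive_search(self, study):
        """Pruned exact search agrees with unpruned brute force."""
        reps = study.base_profiles[:24]
        segs = reps[0].segment_ids
        size, subsets = minimal_marker_set(reps)
        n = len(reps)
        brute = None
        for s in range(1, len(segs) + 1):
            hits = [
                sub
                for sub in itertools.combinations(segs, s)
                if len({p.key(sub) for p in reps}) == n
            ]
            if hits:
                brute = (s, hits)
                break
        assert (size, subsets) == brute

    def test_inseparable_profiles_rejected(self):
        profiles = [make_profile(x, {"S1": (1, 1)}) for x in "ab"]
        with pytest.raises(ValueError, match="indistinguishable"):
            minimal_marker_set(profiles)


class TestFingerprintCode:
    def test_token_format(self):
        p = make_profile("g", {"SEG6": (5, 2), "SEG9": (1, 1)})
        assert fingerprint_code(p, ["SEG6", "SEG9"]) == "SEG6:2/5;SEG9:1/1"

    def test_identical_profiles_identical_codes(self):
        pairs = {"S1": (1, 2), "S2": (3, 3)}
        a, b = make_profile("a", pairs), make_profile("b", pairs)
        assert fingerprint_code(a, ["S1", "S2"]) == fingerprint_code(b, ["S1", "S2"])

    def test_missing_segment_rejected(self):
        p = make_profile("g", {"S1": None})
        with pytest.raises(ValueError, match="missing"):
            fingerprint_code(p, ["S1"])

    def test_codes_distinct_on_minimal_subset(self, study):
        reps = study.base_profiles
        size, subsets = minimal_marker_set(reps)
        codes = {fingerprint_code(p, subsets[0]) for p in reps}
        assert len(codes) == len(reps)


def test_profile_match_probs_multiply_across_segments():
    profiles = [
        make_profile("a", {"S1": (1, 2), "S2": (1, 1)}),
        make_profile("b", {"S1": (1, 1), "S2": (1, 2)}),
    ]
    table = frequency_table(profiles)
    m = profile_match_probs(profiles[0], table)
    m1 = genotype_match_probs(profiles[0].genotypes["S1"], table["S1"])
    m2 = genotype_match_probs(profiles[0].genotypes["S2"], table["S2"])
    assert m.random == pytest.approx(m1.random * m2.random)
    assert m.sib == pytest.approx(m1.sib * m2.sib)
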