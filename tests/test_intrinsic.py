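"""Intrinsic (category-1) indices: anchors, oracles and invariances."""

import math

import numpy as np
import pytest

from rarecodon.codes import STANDARD_CODE
from rarecodon.core import CodonCounts
from rarecodon.intrinsic import (cdc, codon_preference_p, enc, ew, icdi, mcb,
                                 milc, rcbs_dcbs, rscu, scuo)
from rarecodon.reference import CodonUsageTable
from rarecodon.codes import CODONS

CODE = STANDARD_CODE


def counts_of(codons):
    return CodonCounts.from_codons(list(codons))


def random_codons(seed, n):
    rng = np.random.default_rng(seed)
    sense = CODE.sense_codons
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


def relabel_within_families(codons, seed=0):
    """Permute codon identities within each synonymous family."""
    rng = np.random.default_rng(seed)
    mapping = {}
    for fam in CODE.families.values():
        perm = list(fam)
        rng.shuffle(perm)
        mapping.update(dict(zip(fam, perm)))
    return [mapping[c] for c in codons]


class TestRscu:
    def test_two_fold_family_3_to_1(self):
        counts = counts_of(["AAA"] * 3 + ["AAG"])
        values = rscu(counts)
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_uniform_usage_gives_all_ones(self, uniform_counts):
        assert all(v == pytest.approx(1.0) for v in rscu(uniform_counts).values())

    def test_family_sums_equal_family_size(self):
        values = rscu(counts_of(random_codons(1, 400)))
        for aa, fam in CODE.families.items():
            observed = [values[c] for c in fam if c in values]
            if observed:
                assert sum(observed) == pytest.approx(len(fam))

    def test_unobserved_amino_acids_absent_not_zero(self):
        values = rscu(counts_of(["AAA", "AAG"]))
        assert "GGG" not in values


class TestEnc:
    def test_single_codon_per_family_is_20(self, single_codon_counts):
        assert enc(single_codon_counts) == pytest.approx(20.0)

    def test_uniform_long_gene_approaches_61(self):
        counts = counts_of([c for c in CODE.sense_codons for _ in range(200)])
        assert enc(counts) == pytest.approx(61.0, abs=0.5)

    def test_cap_at_61(self, uniform_counts):
        # 10 uses per codon: F-hat = 9/(10k-1) per k-fold family, and the
        # raw estimator 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 = 21 + 401/9 > 61
        raw = 2.0
        for k, n_fam in ((2, 9), (3, 1), (4, 5), (6, 3)):
            raw += n_fam / (9 / (10 * k - 1))
        assert raw > 61
        assert enc(uniform_counts) == 61.0

    def test_missing_three_fold_class_imputed(self):
        # no Ile codons at all: F3 borrowed from (F2+F4)/2, value still finite
        codons = [c for c in CODE.sense_codons
                  if CODE.codon_to_aa[c] != "I" for _ in range(5)]
        assert 20.0 <= enc(counts_of(codons)) <= 61.0

    def test_relabeling_invariance(self):
        codons = random_codons(7, 300)
        assert enc(counts_of(codons)) == pytest.approx(
            enc(counts_of(relabel_within_families(codons))))


class TestScuoEw:
    def test_uniform_extremes(self, uniform_counts, single_codon_counts):
        assert scuo(uniform_counts) == pytest.approx(0.0, abs=1e-12)
        assert ew(uniform_counts) == pytest.approx(1.0)
        assert scuo(single_codon_counts) == pytest.approx(1.0)
        assert ew(single_codon_counts) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_complement_identity_and_bounds(self, seed):
        counts = counts_of(random_codons(seed, 250))
        s, e = scuo(counts), ew(counts)
        assert 0.0 <= s <= 1.0 and 0.0 <= e <= 1.0
        assert s + e == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        codons = random_codons(8, 300)
        relabeled = relabel_within_families(codons)
        assert scuo(counts_of(codons)) == pytest.approx(scuo(counts_of(relabeled)))
        assert ew(counts_of(codons)) == pytest.approx(ew(counts_of(relabeled)))


class TestIcdi:
    def test_extremes(self, uniform_counts, single_codon_counts):
        assert icdi(uniform_counts) == pytest.approx(0.0, abs=1e-12)
        # S = ((n-1)^2 + (n-1)) / (n(n-1)) = 1 for every family size
        assert icdi(single_codon_counts) == pytest.approx(1.0)

    def test_monotone_in_two_fold_family(self):
        # exhaustively: moving one count from minor to major codon in a
        # 2-fold family never decreases ICDI
        for total in range(2, 21):
            values = []
            for major in range((total + 1) // 2, total + 1):
                codons = ["AAA"] * major + ["AAG"] * (total - major)
                values.append(icdi(counts_of(codons)))
            assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_relabeling_invariance(self):
        codons = random_codons(9, 300)
        assert icdi(counts_of(codons)) == pytest.approx(
            icdi(counts_of(relabel_within_families(codons))))


def oracle_rcbs_dcbs(codons):
    """Direct one-pass evaluation over sequence positions."""
    L = len(codons)
    f1 = {b: sum(c[0] == b for c in codons) / L for b in "ACGT"}
    f2 = {b: sum(c[1] == b for c in codons) / L for b in "ACGT"}
    f3 = {b: sum(c[2] == b for c in codons) / L for b in "ACGT"}
    freq = {c: codons.count(c) / L for c in set(codons)}
    prod = 1.0
    dcbs_total = 0.0
    for c in codons:
        e = f1[c[0]] * f2[c[1]] * f3[c[2]]
        d = freq[c] / e
        prod *= d ** (1.0 / L)
        dcbs_total += max(d, 1.0 / d)
    return prod - 1.0, dcbs_total / L


class TestRcbsDcbs:
    def test_factorizing_gene_anchors(self):
        # 16 codons of the form (A|C)(A|C)(A|C)? use 8 codons covering all
        # combos of {A,G}x{C,T}x{A,G}: frequencies factorize exactly
        codons = [a + b + c for a in "AG" for b in "CT" for c in "AG"]
        counts = counts_of(codons)
        r, d = rcbs_dcbs(counts)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert d == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_bruteforce_oracle(self, seed):
        codons = random_codons(seed, 300)
        r, d = rcbs_dcbs(counts_of(codons))
        r0, d0 = oracle_rcbs_dcbs(codons)
        assert r == pytest.approx(r0, abs=1e-9)
        assert d == pytest.approx(d0, abs=1e-9)


class TestCdc:
    def test_composition_expected_usage_gives_zero(self):
        # single-base-class gene: GGG only -> observed equals expected
        assert cdc(counts_of(["GGG"] * 30)) == pytest.approx(0.0, abs=1e-12)

    def test_toy_two_codon_gene_matches_hand_cosine(self):
        codons = ["AAA"] * 3 + ["GGG"]
        counts = counts_of(codons)
        # positions identical: GC=1/4, purine=1 at each position
        # p(G)=1/4, p(A)=3/4, p(C)=p(T)=0 per position
        exp = {"AAA": (3 / 4) ** 3, "GGG": (1 / 4) ** 3,
               "AAG": (3 / 4) ** 2 * (1 / 4), "AGA": (3 / 4) ** 2 * (1 / 4),
               "GAA": (3 / 4) ** 2 * (1 / 4), "AGG": (3 / 4) * (1 / 4) ** 2,
               "GAG": (3 / 4) * (1 / 4) ** 2, "GGA": (3 / 4) * (1 / 4) ** 2}
        obs = {"AAA": 3 / 4, "GGG": 1 / 4}
        num = sum(obs.get(c, 0) * exp.get(c, 0) for c in CODE.sense_codons)
        no = math.sqrt(sum(v * v for v in obs.values()))
        ne = math.sqrt(sum(exp.get(c, 0) ** 2 for c in CODE.sense_codons))
        assert cdc(counts) == pytest.approx(1 - num / (no * ne), abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_bounds(self, seed):
        assert 0.0 <= cdc(counts_of(random_codons(seed, 200))) <= 1.0


def oracle_milc(codons):
    """Brute-force log-likelihood-ratio evaluation against uniform usage."""
    L = len(codons)
    m_sum = 0.0
    corr = 0.0
    for aa, fam in CODE.families.items():
        xs = {c: codons.count(c) for c in fam}
        n = sum(xs.values())
        if n == 0:
            continue
        corr += len(fam) - 1
        for c, x in xs.items():
            if x:
                m_sum += 2 * x * math.log((x / n) * len(fam))
    return m_sum / L - (corr / L - 0.5)


class TestMilc:
    def test_uniform_observed_equals_minus_correction(self, uniform_counts):
        L = uniform_counts.total
        corr = sum(len(f) - 1 for f in CODE.families.values()) / L - 0.5
        assert milc(uniform_counts) == pytest.approx(-corr)

    def test_doubling_counts_preserves_per_length_deviance(self):
        # M/L is scale-free; only the finite-length correction C changes
        codons = random_codons(5, 150)
        a, b = counts_of(codons), counts_of(codons * 2)

        def correction(counts):
            fams = sum(len(CODE.families[aa]) for aa in counts.aa_counts)
            return (fams - len(counts.aa_counts)) / counts.total - 0.5

        assert milc(a) + correction(a) == pytest.approx(milc(b) + correction(b))

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_matches_bruteforce_oracle(self, seed):
        codons = random_codons(seed, 300)
        assert milc(counts_of(codons)) == pytest.approx(oracle_milc(codons), abs=1e-9)


class TestMcb:
    def test_uniform_usage_is_zero(self, uniform_counts):
        assert mcb(uniform_counts) == pytest.approx(0.0, abs=1e-12)

    def test_small_family_worked_case(self):
        # Lys family only: 3 AAA, 1 AAG; chi-square vs uniform:
        # (0.75-0.5)^2/0.5 + (0.25-0.5)^2/0.5 = 0.25; weight cancels
        assert mcb(counts_of(["AAA"] * 3 + ["AAG"])) == pytest.approx(0.25)

    def test_relabeling_invariance(self):
        codons = random_codons(10, 300)
        assert mcb(counts_of(codons)) == pytest.approx(
            mcb(counts_of(relabel_within_families(codons))))


class TestCodonPreference:
    def make_table(self, counts):
        base = {c: 100.0 for c in CODONS}
        base.update(counts)
        return CodonUsageTable("t", "database", base)

    def test_uniform_reference_gives_one(self):
        table = self.make_table({})
        counts = counts_of(random_codons(2, 100))
        # equal counts within every family -> fractions equal the null
        assert codon_preference_p(counts, table) == pytest.approx(1.0)

    def test_single_codon_gene(self):
        table = self.make_table({"AAA": 300.0, "AAG": 100.0})
        counts = counts_of(["AAA"] * 5)
        # fraction 0.75 over null 0.5
        assert codon_preference_p(counts, table) == pytest.approx(1.5)

    def test_three_codon_toy_matches_hand_product(self):
        table = self.make_table({"AAA": 300.0, "AAG": 100.0,
                                 "GAT": 100.0, "GAC": 100.0})
        counts = counts_of(["AAA", "AAG", "GAT"])
        expected = ((0.75 / 0.5) * (0.25 / 0.5) * (0.5 / 0.5)) ** (1 / 3)
        assert codon_preference_p(counts, table) == pytest.approx(expected)


class TestRangeProperties:
    def test_bounded_indices_respect_ranges_on_random_genes(self):
        rng = np.random.default_rng(99)
        sense = CODE.sense_codons
        for _ in range(300):
            n = int(rng.integers(20, 400))
            counts = counts_of([sense[i] for i in rng.integers(0, len(sense), n)])
            assert 20.0 <= enc(counts) <= 61.0
            assert 0.0 <= scuo(counts) <= 1.0
            assert 0.0 <= ew(counts) <= 1.0
            assert 0.0 <= icdi(counts) <= 1.0 + 1e-12
            assert 0.0 <= cdc(counts) <= 1.0
            assert mcb(counts) >= 0.0
            r, d = rcbs_dcbs(counts)
            assert r >= -1.0 and d >= 1.0
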