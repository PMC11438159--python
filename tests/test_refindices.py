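"""Reference-based (category-2) indices."""

import math

import numpy as np
import pytest

from rarecodon.codes import CODONS, STANDARD_CODE
from rarecodon.core import CodonCounts
from rarecodon.refindices import (b_index, cai, cousin, cufs, dmean, fop_cbi,
                                  rca, rscu_cosine_dissimilarity)
from rarecodon.reference import CodonUsageTable, relative_adaptiveness

CODE = STANDARD_CODE


def counts_of(codons):
    return CodonCounts.from_codons(list(codons))


def random_codons(seed, n):
    rng = np.random.default_rng(seed)
    sense = CODE.sense_codons
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


def table_from_counts(counts, source="cds"):
    base = {c: 0.0 for c in CODONS}
    base.update(counts)
    return CodonUsageTable("t", source, base)


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(42)
    return table_from_counts({c: float(rng.integers(50, 500)) for c in CODONS})


class TestCai:
    def test_all_optimal_gene_scores_one(self, random_table):
        w = relative_adaptiveness(random_table)
        best = [max(fam, key=lambda c: w[c])
                for aa, fam in CODE.multi_codon_families.items()]
        assert cai(counts_of(best * 5), w) == pytest.approx(1.0)

    def test_single_codon_gene_equals_its_weight(self):
        table = table_from_counts({c: 100.0 for c in CODONS} | {"AAA": 300.0})
        w = relative_adaptiveness(table)
        assert w["AAG"] == pytest.approx(1 / 3)
        assert cai(counts_of(["AAG"] * 7), w) == pytest.approx(1 / 3)

    def test_matches_log_domain_oracle(self, random_table):
        w = relative_adaptiveness(random_table)
        codons = random_codons(1, 1000)
        eligible = [c for c in codons if len(CODE.family_of(c)) >= 2]
        oracle = math.exp(np.mean([math.log(w[c]) for c in eligible]))
        assert cai(counts_of(codons), w) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_duplication(self, random_table):
        w = relative_adaptiveness(random_table)
        codons = random_codons(2, 200)
        assert cai(counts_of(codons), w) == pytest.approx(
            cai(counts_of(codons * 3), w))

    def test_met_trp_stop_only_gene_is_an_error(self, random_table):
        w = relative_adaptiveness(random_table)
        with pytest.raises(ValueError):
            cai(counts_of(["ATG", "TGG"] * 5), w)


class TestFopCbi:
    def test_all_optimal_gene(self, random_table):
        optimal = random_table.optimal_codons()
        codons = [opt[0] for opt in optimal.values()] * 3
        fop, cbi = fop_cbi(counts_of(codons), random_table)
        assert fop == pytest.approx(1.0)
        assert cbi == pytest.approx(1.0)

    def test_uniform_within_family_usage_gives_cbi_zero(self, random_table):
        codons = [c for fam in CODE.multi_codon_families.values() for c in fam]
        fop, cbi = fop_cbi(counts_of(codons * 4), random_table)
        assert cbi == pytest.approx(0.0, abs=1e-12)

    def test_reference_tie_counts_both_codons_as_optimal(self):
        counts = {c: 100.0 for c in CODONS}
        counts["AAA"] = counts["AAG"] = 400.0  # tied Lys codons
        table = table_from_counts(counts)
        gene = counts_of(["AAA", "AAG"] * 10)
        fop, cbi = fop_cbi(gene, table)
        # oracle under the all-ties-optimal rule: every Lys codon optimal
        assert fop == pytest.approx(1.0)
        # N_rand = N_tot for this gene (both of 2 codons optimal), CBI None
        assert cbi is None


class TestCousin:
    def test_query_equal_to_reference_scores_one(self, random_table):
        # query with the reference's own codon distribution (scaled counts)
        probs = random_table.sense_codon_probs()
        query = CodonCounts.from_codons([])
        query.counts = {c: probs[c] * 1e6 for c in CODE.sense_codons}
        query.total = sum(query.counts.values())
        assert cousin(query, random_table, 59) == pytest.approx(1.0)
        assert cousin(query, random_table, 18) == pytest.approx(1.0)

    def test_uniform_synonymous_query_scores_zero(self, random_table):
        codons = [c for fam in CODE.multi_codon_families.values() for c in fam]
        query = counts_of(codons * 5)
        assert cousin(query, random_table, 59) == pytest.approx(0.0, abs=1e-12)
        assert cousin(query, random_table, 18) == pytest.approx(0.0, abs=1e-12)

    def test_opposite_bias_goes_negative(self):
        counts = {c: 100.0 for c in CODONS}
        counts["AAA"], counts["AAG"] = 900.0, 100.0
        table = table_from_counts(counts)
        query = counts_of(["AAG"] * 9 + ["AAA"])  # reversed preference
        assert cousin(query, table, 59) < 0
        assert cousin(query, table, 18) < 0


class TestRca:
    def test_factorizable_reference_scores_one(self):
        # counts proportional to a product of positional base weights
        w1 = {"A": 1, "C": 2, "G": 3, "T": 4}
        counts = {c: float(w1[c[0]] * w1[c[1]] * w1[c[2]]) for c in CODONS}
        table = table_from_counts(counts)
        gene = counts_of(random_codons(3, 200))
        assert rca(gene, table) == pytest.approx(1.0, abs=1e-9)

    @staticmethod
    def oracle_raw(table):
        """Independent evaluation of f(xyz)/(f1 f2 f3) from raw counts."""
        total = sum(table.counts.values())
        pos = [{b: sum(v for c, v in table.counts.items() if c[k] == b) / total
                for b in "ACGT"} for k in range(3)]
        return {c: (table.counts[c] / total) /
                (pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]])
                for c in CODE.sense_codons}

    def test_single_codon_gene_equals_normalized_weight(self, random_table):
        raw = self.oracle_raw(random_table)
        fam = CODE.families["K"]
        expected = raw["AAG"] / max(raw[c] for c in fam)
        assert rca(counts_of(["AAG"] * 6), random_table) == pytest.approx(expected)

    def test_matches_log_domain_oracle(self, random_table):
        raw = self.oracle_raw(random_table)
        weights = {}
        for fam in CODE.families.values():
            best = max(raw[c] for c in fam)
            for c in fam:
                weights[c] = raw[c] / best
        codons = random_codons(4, 300)
        oracle = math.exp(np.mean([math.log(weights[c]) for c in codons]))
        assert rca(counts_of(codons), random_table) == pytest.approx(oracle, abs=1e-9)

    def test_invariant_under_duplication(self, random_table):
        codons = random_codons(5, 150)
        assert rca(counts_of(codons), random_table) == pytest.approx(
            rca(counts_of(codons * 2), random_table))


class TestBIndex:
    def test_gene_equal_to_reference_is_zero(self, random_table):
        probs = random_table.sense_codon_probs()
        query = CodonCounts.from_codons([])
        query.counts = {c: probs[c] * 1e6 for c in CODE.sense_codons}
        query.total = sum(query.counts.values())
        query.aa_counts = {}
        assert b_index(query, random_table) == pytest.approx(0.0, abs=1e-9)

    def test_two_fold_family_worked_case(self):
        counts = {c: 0.0 for c in CODONS}
        counts["AAA"] = counts["AAG"] = 500.0  # reference Lys 50:50
        table = table_from_counts({c: v if v else 1.0 for c, v in counts.items()})
        gene = counts_of(["AAA"] * 10)  # gene 100:0
        # |1-0.5| + |0-0.5| = 1, and Lys is the whole gene
        assert b_index(gene, table) == pytest.approx(1.0, abs=1e-6)

    def test_bounded_by_two(self, random_table):
        for seed in (6, 7, 8):
            gene = counts_of(random_codons(seed, 100))
            assert 0.0 <= b_index(gene, random_table) <= 2.0


class TestCufs:
    def test_identical_distributions_give_zero(self, random_table):
        probs = random_table.sense_codon_probs()
        query = CodonCounts.from_codons([])
        query.counts = {c: probs[c] * 1e6 for c in CODE.sense_codons}
        query.total = sum(query.counts.values())
        assert cufs(query, random_table) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        ca = counts_of(random_codons(9, 200))
        cb = counts_of(random_codons(10, 200))
        ta = table_from_counts({c: ca.counts.get(c, 0) + 0.0 for c in CODONS})
        tb = table_from_counts({c: cb.counts.get(c, 0) + 0.0 for c in CODONS})
        # d(p, q) = d(q, p): swap gene and reference roles
        assert cufs(ca, tb) == pytest.approx(cufs(cb, ta), abs=1e-12)
        assert cufs(ca, tb) == pytest.approx(_metric(ca, tb), abs=1e-12)

    def test_disjoint_support_hits_analytic_maximum(self):
        # JS divergence of disjoint distributions is ln 2 (natural log)
        gene = counts_of(["AAA"] * 10)
        counts = {c: 0.0 for c in CODONS}
        counts["GGG"] = 100.0
        table = table_from_counts(counts)
        assert cufs(gene, table) == pytest.approx(math.sqrt(2 * math.log(2)))


def _metric(counts, table):
    """Independent JSD-metric evaluation used by the symmetry check."""
    p = np.array([counts.counts.get(c, 0) / counts.total for c in CODE.sense_codons])
    ref = table.sense_codon_probs()
    q = np.array([ref[c] for c in CODE.sense_codons])
    m = (p + q) / 2

    def h(v):
        nz = v[v > 0]
        return -(nz * np.log(nz)).sum()

    return math.sqrt(max(0.0, 2 * (h(m) - (h(p) + h(q)) / 2)))


class TestDmean:
    def test_identical_reference_genes_give_zero(self):
        codons = random_codons(11, 200)
        query = counts_of(codons)
        refs = [counts_of(codons) for _ in range(3)]
        assert dmean(query, refs) == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_pairwise_dissimilarities(self):
        query = counts_of(random_codons(12, 150))
        refs = [counts_of(random_codons(s, 150)) for s in (13, 14, 15)]
        expected = np.mean([rscu_cosine_dissimilarity(query, r) for r in refs])
        assert dmean(query, refs) == pytest.approx(expected)

    def test_three_toy_reference_genes_match_hand_mean(self):
        # single Lys family: RSCU vectors reduce to the (AAA, AAG) axis
        query = counts_of(["AAA"] * 4)           # RSCU (2, 0)
        refs = [counts_of(["AAA"] * 4),          # identical: d = 0
                counts_of(["AAG"] * 4),          # orthogonal: d = 0.5
                counts_of(["AAA"] * 2 + ["AAG"] * 2)]  # 45 deg: d = (1-1/sqrt2)/2
        expected = (0 + 0.5 + (1 - 1 / math.sqrt(2)) / 2) / 3
        assert dmean(query, refs) == pytest.approx(expected)

    def test_empty_reference_set_is_unavailable(self):
        assert dmean(counts_of(["AAA"] * 4), []) is None
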