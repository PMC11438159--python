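import numpy as np
import pytest

from rarecodon import fixtures
from rarecodon.codes import STANDARD_CODE
from rarecodon.core import CodonCounts, CodonSequence
from rarecodon.reference import build_pair_table, build_table_from_cds


def counts_from_codons(codons):
    return CodonCounts.from_codons(list(codons))


def seq_from_codons(codons, name="g"):
    return CodonSequence(name, "".join(codons))


def random_gene_codons(rng, n_codons, sense=STANDARD_CODE.sense_codons):
    """Random sense codons (no stops), iid uniform."""
    return [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240927)


@pytest.fixture(scope="session")
def uniform_counts():
    """Every sense codon used equally often: uniform synonymous usage."""
    return CodonCounts.from_codons(
        [c for c in STANDARD_CODE.sense_codons for _ in range(10)]
    )


@pytest.fixture(scope="session")
def single_codon_counts():
    """One codon per family, used repeatedly: maximal bias."""
    chosen = [fam[0] for fam in STANDARD_CODE.families.values()]
    return CodonCounts.from_codons([c for c in chosen for _ in range(10)])


@pytest.fixture(scope="session")
def synthetic_corpus():
    """50 synthetic genes plus the reference resources built from them."""
    records, truth = fixtures.generate_cds(
        50, length_range=(100, 300), freq_spec="uniform", seed=11)
    table, per_gene, _ = build_table_from_cds(records, organism="synthetic")
    pair_table = build_pair_table(records)
    return {
        "records": records,
        "truth": truth,
        "table": table,
        "per_gene": per_gene,
        "pair_table": pair_table,
        "trna": fixtures.generate_trna_profile(seed=12),
    }
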