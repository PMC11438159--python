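"""Genetic code model: codon tables, synonymous families, degeneracy classes.

Every index in this package is defined relative to a genetic code.  Only the
standard code (NCBI translation table 1) ships by default, but the
:class:`GeneticCode` object is a parameter everywhere so alternate tables can
be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Mapping, Tuple

from Bio.Data import CodonTable

BASES = ("T", "C", "A", "G")
CODONS: Tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True, eq=False)  # identity hash: instances are cached
class GeneticCode:
    """A codon translation table plus its synonymous-family structure.

    Attributes
    ----------
    code_id:
        NCBI translation table identifier.
    codon_to_aa:
        All 64 codons mapped to a one-letter amino acid, ``*`` for stops.
    families:
        Amino acid -> tuple of synonymous codons (sense codons only).
    stop_codons:
        The stop codons of this table.
    """

    code_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, Tuple[str, ...]]
    stop_codons: FrozenSet[str]
    sense_codons: Tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 codons")
        sense = tuple(c for c in CODONS if c not in self.stop_codons)
        object.__setattr__(self, "sense_codons", sense)
        n_family = sum(len(v) for v in self.families.values())
        if n_family != len(sense):
            raise ValueError("families must partition the sense codons")

    @property
    def amino_acids(self) -> Tuple[str, ...]:
        return tuple(self.families)

    def family_of(self, codon: str) -> Tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def degeneracy(self, codon: str) -> int:
        return len(self.family_of(codon))

    def translate(self, codons) -> str:
        return "".join(self.codon_to_aa[c] for c in codons)

    @property
    def multi_codon_families(self) -> Dict[str, Tuple[str, ...]]:
        """Families with 2+ codons (the ones that can carry usage bias)."""
        return {aa: fam for aa, fam in self.families.items() if len(fam) >= 2}


@lru_cache(maxsize=None)
def get_genetic_code(code_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    codon_to_aa = {}
    families: Dict[str, list] = {}
    stops = frozenset(table.stop_codons)
    for codon in CODONS:
        if codon in stops:
            codon_to_aa[codon] = "*"
            continue
        aa = table.forward_table[codon]
        codon_to_aa[codon] = aa
        families.setdefault(aa, []).append(codon)
    return GeneticCode(
        code_id=code_id,
        codon_to_aa=codon_to_aa,
        families={aa: tuple(v) for aa, v in families.items()},
        stop_codons=stops,
    )


STANDARD_CODE = get_genetic_code(1)
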