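"""Sequence cleaning, validation and codon counting.

Input coding sequences are arbitrary pasted text (FASTA records or
name/sequence table rows).  Cleaning strips every non-alphabetic character,
upper-cases, maps RNA U to DNA T, and removes stop codons at the end of the
sequence.  Validation then enforces the analysis contract: length within
[60, 12000] bp and a multiple of 3, bases restricted to A/C/G/T, and no
internal stop codon.  Sequences failing any rule are excluded from analysis
with an explicit reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import SeqIO

from .codes import BASES, GeneticCode, STANDARD_CODE

MIN_LENGTH_BP = 60
MAX_LENGTH_BP = 12000

#: rejection reasons a validator can emit
REJECTION_REASONS = (
    "too_short",
    "too_long",
    "internal_stop",
    "invalid_characters",
    "not_multiple_of_3",
    "duplicate_name",
)

_NON_ALPHA = re.compile(r"[^A-Za-z]+")


def clean_sequence(raw: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Strip symbols, upper-case, map U->T and drop terminal stop codons.

    Cleaning never fails; validation happens separately.  Terminal stop
    codons are removed repeatedly, but only while the sequence length is a
    multiple of 3 (otherwise the reading frame of the tail is undefined),
    which makes cleaning idempotent.
    """
    seq = _NON_ALPHA.sub("", raw).upper().replace("U", "T")
    while len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in code.stop_codons:
        seq = seq[:-3]
    return seq


@dataclass
class ValidationReport:
    """Outcome of validating one cleaned sequence."""

    gene_name: str
    accepted: bool
    rejection_reason: Optional[str] = None
    transformations: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.accepted == (self.rejection_reason is not None):
            raise ValueError("accepted iff rejection_reason is empty")


def validate_sequence(
    cleaned: str,
    name: str,
    *,
    seen_names: Optional[Set[str]] = None,
    code: GeneticCode = STANDARD_CODE,
    min_length: int = MIN_LENGTH_BP,
    max_length: int = MAX_LENGTH_BP,
) -> ValidationReport:
    """Validate an already-cleaned sequence, returning the first failing rule.

    ``seen_names`` (mutated in place when given) enforces unique gene names
    within a batch.
    """
    def reject(reason: str) -> ValidationReport:
        return ValidationReport(name, accepted=False, rejection_reason=reason)

    if seen_names is not None:
        if name in seen_names:
            return reject("duplicate_name")
        seen_names.add(name)
    if any(b not in "ACGT" for b in cleaned):
        return reject("invalid_characters")
    if len(cleaned) % 3 != 0:
        return reject("not_multiple_of_3")
    if len(cleaned) < min_length:
        return reject("too_short")
    if len(cleaned) > max_length:
        return reject("too_long")
    codons = [cleaned[i : i + 3] for i in range(0, len(cleaned), 3)]
    if any(c in code.stop_codons for c in codons):
        return reject("internal_stop")
    return ValidationReport(name, accepted=True)


@dataclass(frozen=True)
class CodonSequence:
    """A validated coding sequence in frame 0."""

    gene_name: str
    nucleotides: str
    code: GeneticCode = STANDARD_CODE

    @property
    def codons(self) -> List[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]

    def __len__(self) -> int:
        return len(self.nucleotides) // 3


@dataclass
class CodonCounts:
    """Per-codon counts of one gene plus the marginals the indices need.

    ``positional_base_counts[k][b]`` is the number of codons whose base at
    codon position k (0-based) is b; each position sums to the codon total L.
    """

    counts: Dict[str, int]
    total: int
    aa_counts: Dict[str, int]
    positional_base_counts: List[Dict[str, int]]
    code: GeneticCode = STANDARD_CODE

    @classmethod
    def from_sequence(cls, seq: CodonSequence) -> "CodonCounts":
        return cls.from_codons(seq.codons, code=seq.code)

    @classmethod
    def from_codons(cls, codons: Sequence[str], code: GeneticCode = STANDARD_CODE) -> "CodonCounts":
        counts: Dict[str, int] = {}
        aa_counts: Dict[str, int] = {}
        pos: List[Dict[str, int]] = [dict.fromkeys("ACGT", 0) for _ in range(3)]
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        for c, n in counts.items():
            aa = code.codon_to_aa[c]
            aa_counts[aa] = aa_counts.get(aa, 0) + n
            for k in range(3):
                pos[k][c[k]] += n
        return cls(counts=counts, total=len(codons), aa_counts=aa_counts,
                   positional_base_counts=pos, code=code)

    def family_counts(self, aa: str) -> Dict[str, int]:
        """Counts of every codon of one family (zeros included)."""
        return {c: self.counts.get(c, 0) for c in self.code.families[aa]}

    def positional_base_freqs(self) -> np.ndarray:
        """3x4 array of base frequencies per codon position (T,C,A,G order)."""
        out = np.zeros((3, 4))
        for k in range(3):
            for j, b in enumerate(BASES):
                out[k, j] = self.positional_base_counts[k][b] / self.total
        return out


def count_codons(seq: CodonSequence) -> CodonCounts:
    """Exact frame-0 triplet counts of a validated sequence."""
    return CodonCounts.from_sequence(seq)


# ---------------------------------------------------------------------------
# readers

def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a multi-record FASTA into (name, raw sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_name_sequence_tsv(path) -> List[Tuple[str, str]]:
    """Read a two-column name<TAB>sequence table (spreadsheet-paste layout).

    Blank lines are skipped; a row without a tab is an error.
    """
    pairs: List[Tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ValueError(f"line {lineno}: expected name<TAB>sequence")
        name, seq = line.split("\t", 1)
        pairs.append((name.strip(), seq))
    return pairs


def prepare_batch(
    records: Iterable[Tuple[str, str]],
    code: GeneticCode = STANDARD_CODE,
) -> Iterator[Tuple[ValidationReport, Optional[CodonSequence]]]:
    """Clean + validate a batch, enforcing unique gene names.

    Yields a (report, sequence-or-None) pair per input record, in order.
    """
    seen: Set[str] = set()
    for name, raw in records:
        cleaned = clean_sequence(raw, code)
        report = validate_sequence(cleaned, name, seen_names=seen, code=code)
        if report.accepted:
            yield report, CodonSequence(name, cleaned, code)
        else:
            yield report, None
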