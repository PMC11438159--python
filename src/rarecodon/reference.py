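"""Reference resources: codon usage tables, codon-pair tables, tRNA profiles.

Reference-based indices compare a query gene to a host organism.  Two table
sources are supported, mirroring common practice: a usage table in the
Kazusa Codon Usage Database text dialect (codon, frequency per thousand,
count in parentheses), or a table built from a curated FASTA of coding
sequences.  tRNA gene copy numbers come from a small TSV keyed by anticodon.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .codes import CODONS, GeneticCode, STANDARD_CODE
from .core import CodonCounts, CodonSequence, prepare_batch

#: pseudo-count replacing a zero reference codon count before computing
#: relative adaptiveness (standard CAI practice; avoids w=0 -> CAI=0 collapse)
ZERO_COUNT_PSEUDO = 0.5


@dataclass
class CodonUsageTable:
    """Reference per-codon usage of a host organism.

    ``per_thousand`` sums to ~1000 over the 64 codons; ``fraction`` is the
    within-synonymous-family fraction g_c (sums to 1 inside each family).
    """

    organism: str
    source: str  # "database" (Kazusa-cited) or "cds" (built from a CDS set)
    counts: Dict[str, float]
    code: GeneticCode = STANDARD_CODE
    per_thousand: Dict[str, float] = field(default_factory=dict)
    fraction: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(CODONS) - set(self.counts)
        if missing:
            raise ValueError(f"usage table missing {len(missing)} codons")
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("usage table has zero total count")
        if not self.per_thousand:
            self.per_thousand = {c: 1000.0 * self.counts[c] / total for c in CODONS}
        if not self.fraction:
            self.fraction = {}
            for fam in self.code.families.values():
                fam_total = sum(self.counts[c] for c in fam)
                for c in fam:
                    self.fraction[c] = (
                        self.counts[c] / fam_total if fam_total > 0 else 1.0 / len(fam)
                    )

    def sense_codon_probs(self) -> Dict[str, float]:
        """Codon probabilities restricted and renormalized to sense codons."""
        sense = self.code.sense_codons
        total = sum(self.counts[c] for c in sense)
        return {c: self.counts[c] / total for c in sense}

    def positional_base_freqs(self) -> Dict[int, Dict[str, float]]:
        """Base frequency at each codon position implied by sense-codon usage."""
        probs = self.sense_codon_probs()
        out: Dict[int, Dict[str, float]] = {k: dict.fromkeys("ACGT", 0.0) for k in range(3)}
        for c, p in probs.items():
            for k in range(3):
                out[k][c[k]] += p
        return out

    def optimal_codons(self) -> Dict[str, Tuple[str, ...]]:
        """Most frequent codon(s) of each multi-codon family; ties all count."""
        out = {}
        for aa, fam in self.code.multi_codon_families.items():
            best = max(self.counts[c] for c in fam)
            out[aa] = tuple(c for c in fam if self.counts[c] == best)
        return out


_KAZUSA_ENTRY = re.compile(
    r"([ACGTUacgtu]{3})\s+(\d+(?:\.\d+)?)\s*\(\s*(\d+(?:\.\d+)?)\s*\)"
)


def parse_usage_table(text: str, organism: str = "unknown",
                      source: str = "database",
                      code: GeneticCode = STANDARD_CODE) -> CodonUsageTable:
    """Parse a Kazusa-dialect usage table (codon, per-thousand, (count)).

    DNA and RNA alphabets are both accepted (U is normalized to T).
    """
    counts: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        for codon, _freq, count in _KAZUSA_ENTRY.findall(line):
            codon = codon.upper().replace("U", "T")
            if codon in counts:
                raise ValueError(f"line {lineno}: duplicate codon {codon}")
            counts[codon] = float(count)
    missing = set(CODONS) - set(counts)
    if missing:
        raise ValueError(
            f"incomplete usage table: {len(counts)} codons parsed, "
            f"missing e.g. {sorted(missing)[:3]}"
        )
    return CodonUsageTable(organism=organism, source=source, counts=counts, code=code)


def write_usage_table(table: CodonUsageTable) -> str:
    """Render a table in the Kazusa text dialect (4 codons per line)."""
    cells = [
        f"{c} {table.per_thousand[c]:5.1f} ({table.counts[c]:.0f})" for c in CODONS
    ]
    lines = ["  ".join(cells[i : i + 4]) for i in range(0, 64, 4)]
    return "\n".join(lines) + "\n"


def parse_usage_table_tsv(text: str, organism: str = "unknown",
                          source: str = "database",
                          code: GeneticCode = STANDARD_CODE) -> CodonUsageTable:
    """Parse the documented TSV alternative: codon<TAB>count per line."""
    counts: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected codon<TAB>count")
        codon = parts[0].strip().upper().replace("U", "T")
        counts[codon] = float(parts[1])
    missing = set(CODONS) - set(counts)
    if missing:
        raise ValueError(f"incomplete usage table, missing {sorted(missing)[:3]}")
    return CodonUsageTable(organism=organism, source=source, counts=counts, code=code)


def write_usage_table_tsv(table: CodonUsageTable) -> str:
    lines = ["#codon\tcount\tper_thousand"]
    for c in CODONS:
        lines.append(f"{c}\t{table.counts[c]:g}\t{table.per_thousand[c]:.6f}")
    return "\n".join(lines) + "\n"


def build_table_from_cds(
    records: Iterable[Tuple[str, str]],
    organism: str = "unknown",
    code: GeneticCode = STANDARD_CODE,
) -> Tuple[CodonUsageTable, List[CodonCounts], int]:
    """Pool codon counts over a CDS set into a usage table.

    Records failing validation are skipped.  Returns the table, the per-gene
    counts of accepted records (needed by per-gene reference indices such as
    Dmean), and the number of skipped records.
    """
    pooled = dict.fromkeys(CODONS, 0.0)
    per_gene: List[CodonCounts] = []
    skipped = 0
    for report, seq in prepare_batch(records, code):
        if seq is None:
            skipped += 1
            continue
        counts = CodonCounts.from_sequence(seq)
        per_gene.append(counts)
        for c, n in counts.counts.items():
            pooled[c] += n
    if not per_gene:
        raise ValueError("no valid coding sequences in reference set")
    table = CodonUsageTable(organism=organism, source="cds", counts=pooled, code=code)
    return table, per_gene, skipped


@dataclass(frozen=True)
class RelativeAdaptiveness:
    """Per-codon weights w_c in (0, 1], max within each family = 1."""

    weights: Dict[str, float]
    mode: str  # "cai"

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


def relative_adaptiveness(table: CodonUsageTable, mode: str = "cai") -> RelativeAdaptiveness:
    """CAI-style weights: w_c = count_c / max count within the family.

    Zero reference counts are replaced by ``ZERO_COUNT_PSEUDO`` so that no
    weight (and hence no CAI) collapses to zero.
    """
    if mode != "cai":
        raise ValueError(f"unknown adaptiveness mode {mode!r}")
    weights: Dict[str, float] = {}
    for aa, fam in table.code.families.items():
        fam_counts = {c: max(table.counts[c], ZERO_COUNT_PSEUDO) for c in fam}
        best = max(fam_counts.values())
        if best <= 0:
            raise ValueError(f"empty reference family for {aa}")
        for c in fam:
            weights[c] = fam_counts[c] / best
    return RelativeAdaptiveness(weights=weights, mode=mode)


@dataclass
class CodonPairTable:
    """Adjacent codon-pair counts of a reference CDS set, with marginals.

    Pairs are counted within records only; a pair never spans two genes.
    ``pair_counts[(A, B)]`` uses codons in gene order.  Marginals: ``F(A)``
    codon counts, ``F(x)`` amino-acid counts, ``F(xy)`` amino-acid pair
    counts, all over the same corpus.
    """

    pair_counts: Dict[Tuple[str, str], float]
    codon_counts: Dict[str, float]
    aa_counts: Dict[str, float]
    aa_pair_counts: Dict[Tuple[str, str], float]
    n_records: int
    code: GeneticCode = STANDARD_CODE

    @property
    def total_pairs(self) -> float:
        return sum(self.pair_counts.values())


def build_pair_table(
    records: Iterable[Tuple[str, str]],
    code: GeneticCode = STANDARD_CODE,
) -> CodonPairTable:
    """Count adjacent codon pairs over a validated reference CDS set."""
    pair_counts: Dict[Tuple[str, str], float] = {}
    codon_counts: Dict[str, float] = {}
    aa_counts: Dict[str, float] = {}
    aa_pair_counts: Dict[Tuple[str, str], float] = {}
    n = 0
    for report, seq in prepare_batch(records, code):
        if seq is None:
            continue
        n += 1
        codons = seq.codons
        for c in codons:
            codon_counts[c] = codon_counts.get(c, 0) + 1
            aa = code.codon_to_aa[c]
            aa_counts[aa] = aa_counts.get(aa, 0) + 1
        for a, b in zip(codons, codons[1:]):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
            xy = (code.codon_to_aa[a], code.codon_to_aa[b])
            aa_pair_counts[xy] = aa_pair_counts.get(xy, 0) + 1
    if n == 0:
        raise ValueError("no valid coding sequences in reference set")
    return CodonPairTable(pair_counts, codon_counts, aa_counts, aa_pair_counts,
                          n_records=n, code=code)


# ---------------------------------------------------------------------------
# tRNA profiles

#: default wobble-pairing penalties, dos Reis-style (anticodon base 34 vs
#: codon base 3). Watson-Crick pairings have s = 0; the selective constraints
#: below discount non-canonical decoding.
DEFAULT_S_VALUES: Dict[str, float] = {
    "G:U": 0.41,     # G34 anticodon reading a U-ending codon
    "I:C": 0.28,     # inosine (from A34) reading a C-ending codon
    "I:A": 0.9999,   # inosine reading an A-ending codon
    "U:G": 0.68,     # U34 reading a G-ending codon
}

#: order in which the four wobble penalties appear in an s-vector
S_VECTOR_KEYS: Tuple[str, ...] = ("G:U", "I:C", "I:A", "U:G")


@dataclass
class TRNAProfile:
    """Anticodon-level tRNA gene copy numbers plus wobble penalties."""

    gcn: Dict[str, float]               # anticodon (DNA alphabet) -> copies
    s_values: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_S_VALUES))
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self):
        for anticodon in self.gcn:
            if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
                raise ValueError(f"unknown anticodon {anticodon!r}")
        if not any(v > 0 for v in self.gcn.values()):
            raise ValueError("tRNA profile has no positive gene copy number")

    def copies(self, anticodon: str) -> float:
        return self.gcn.get(anticodon, 0.0)

    def with_s_values(self, s_vector) -> "TRNAProfile":
        s = dict(zip(S_VECTOR_KEYS, s_vector))
        return TRNAProfile(gcn=self.gcn, s_values=s, code=self.code)

    def s_vector(self) -> np.ndarray:
        return np.array([self.s_values[k] for k in S_VECTOR_KEYS])


def load_trna_profile(text: str, code: GeneticCode = STANDARD_CODE) -> TRNAProfile:
    """Load a tRNA profile TSV: anticodon<TAB>gene copy number.

    Optional override lines ``#s <class> <value>`` set wobble penalties,
    e.g. ``#s G:U 0.5``.
    """
    gcn: Dict[str, float] = {}
    s_values = dict(DEFAULT_S_VALUES)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#s"):
            _tag, key, value = line.split()
            if key not in s_values:
                raise ValueError(f"line {lineno}: unknown wobble class {key!r}")
            s_values[key] = float(value)
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected anticodon<TAB>copies")
        anticodon = parts[0].strip().upper().replace("U", "T")
        if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
            raise ValueError(f"line {lineno}: unknown anticodon {parts[0]!r}")
        gcn[anticodon] = float(parts[1])
    return TRNAProfile(gcn=gcn, s_values=s_values, code=code)


def write_trna_profile(profile: TRNAProfile) -> str:
    lines = [f"#s {k} {v:g}" for k, v in profile.s_values.items()]
    lines += [f"{a}\t{n:g}" for a, n in sorted(profile.gcn.items())]
    return "\n".join(lines) + "\n"
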