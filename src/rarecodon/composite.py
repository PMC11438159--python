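"""Category-4 indices: complex codon-usage patterns.

GC content (overall and per codon position), the effective number of codon
pairs (ENcp, a Wright-style estimator generalized to adjacent pairs), the
codon pair score / codon pair bias (CPS/CPB) against a reference pair
table, and codon volatility.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .codes import GeneticCode, STANDARD_CODE
from .core import CodonCounts, CodonSequence
from .reference import CodonPairTable


def gc_content(counts: CodonCounts) -> Tuple[float, float, float, float]:
    """(GC, GC1, GC2, GC3) as percentages; GC is the mean of GC1-3."""
    L = counts.total
    per_pos = []
    for k in range(3):
        pos = counts.positional_base_counts[k]
        per_pos.append(100.0 * (pos["G"] + pos["C"]) / L)
    return (sum(per_pos) / 3.0, per_pos[0], per_pos[1], per_pos[2])


# ---------------------------------------------------------------------------
# ENcp

def pair_counts_of_gene(seq: CodonSequence) -> Dict[Tuple[str, str], int]:
    """Adjacent codon-pair counts of one gene (within-gene pairs only)."""
    codons = seq.codons
    out: Dict[Tuple[str, str], int] = {}
    for a, b in zip(codons, codons[1:]):
        out[(a, b)] = out.get((a, b), 0) + 1
    return out


def encp(seq: CodonSequence) -> float:
    """Effective number of codon pairs: Wright's estimator on pair families.

    Pairs are grouped into amino-acid-pair families (family size = product
    of the two codons' degeneracies).  Per observed family with >= 2 pair
    observations, homozygosity F-hat is estimated from pair proportions;
    F-hat is averaged within each family-size class; ENcp is the sum over
    classes of (observed families of that size) / class-average F-hat.  A
    size class that is observed but inestimable borrows the average of the
    nearest estimable size classes.  The value is capped below the number
    of observed pair types never to claim more diversity than was seen, and
    by the total number of available sense pair types.
    """
    code = seq.code
    pairs = pair_counts_of_gene(seq)
    if not pairs:
        raise ValueError("gene shorter than 2 codons")
    # group pair counts by amino-acid pair family
    fam_counts: Dict[Tuple[str, str], Dict[Tuple[str, str], int]] = {}
    for (a, b), n in pairs.items():
        xy = (code.codon_to_aa[a], code.codon_to_aa[b])
        fam_counts.setdefault(xy, {})[(a, b)] = n
    size_sum: Dict[int, float] = {}
    size_n: Dict[int, int] = {}
    size_total: Dict[int, int] = {}
    for xy, members in fam_counts.items():
        size = len(code.families[xy[0]]) * len(code.families[xy[1]])
        size_total[size] = size_total.get(size, 0) + 1
        n = sum(members.values())
        if size == 1:
            size_sum[size] = size_sum.get(size, 0.0) + 1.0
            size_n[size] = size_n.get(size, 0) + 1
            continue
        if n < 2:
            continue
        s = sum((x / n) ** 2 for x in members.values())
        f = (n * s - 1) / (n - 1)
        if f <= 0:
            continue
        size_sum[size] = size_sum.get(size, 0.0) + f
        size_n[size] = size_n.get(size, 0) + 1
    fbar = {k: size_sum[k] / size_n[k] for k in size_sum if size_n.get(k)}
    estimable = sorted(fbar)
    total = 0.0
    for size, n_fam in size_total.items():
        if size in fbar:
            f = fbar[size]
        elif estimable:
            below = [s for s in estimable if s < size]
            above = [s for s in estimable if s > size]
            neighbors = ([fbar[max(below)]] if below else []) + (
                [fbar[min(above)]] if above else [])
            f = sum(neighbors) / len(neighbors)
        else:
            f = 1.0
        total += n_fam / f
    n_sense = len(code.sense_codons)
    cap = min(float(len(pairs)), float(n_sense * n_sense))
    return min(total, cap)


# ---------------------------------------------------------------------------
# CPS / CPB

def cps_table(ref: CodonPairTable, smoothing: float = 0.0) -> Dict[Tuple[str, str], float]:
    """Per-pair codon pair scores from a reference pair table.

    CPS(AB) = ln[ F(AB) F(x) F(y) / (F(A) F(B) F(xy)) ] with F counts from
    the reference; x, y are the amino acids encoded by A and B.  With
    ``smoothing`` > 0 (e.g. 0.5), unobserved pairs get smoothed counts
    instead of being omitted.
    """
    code = ref.code
    out: Dict[Tuple[str, str], float] = {}
    keys = (ref.pair_counts.keys() if smoothing == 0 else
            [(a, b) for a in code.sense_codons for b in code.sense_codons])
    for a, b in keys:
        f_ab = ref.pair_counts.get((a, b), 0) + smoothing
        if f_ab <= 0:
            continue
        x, y = code.codon_to_aa[a], code.codon_to_aa[b]
        f_a = ref.codon_counts.get(a, 0)
        f_b = ref.codon_counts.get(b, 0)
        f_x = ref.aa_counts.get(x, 0)
        f_y = ref.aa_counts.get(y, 0)
        f_xy = ref.aa_pair_counts.get((x, y), 0) + smoothing
        if min(f_a, f_b, f_x, f_y, f_xy) <= 0:
            continue
        out[(a, b)] = math.log(f_ab * f_x * f_y / (f_a * f_b * f_xy))
    return out


def cps_cpb(
    seq: CodonSequence,
    ref: CodonPairTable,
    smoothing: float = 0.0,
) -> Tuple[Dict[Tuple[str, str], Optional[float]], Optional[float]]:
    """Per-pair CPS over the gene's adjacent pairs, and their mean (CPB).

    Pairs absent from the reference are reported as None and excluded from
    the CPB mean (default); pass ``smoothing=0.5`` for add-half smoothing
    instead.
    """
    table = cps_table(ref, smoothing=smoothing)
    gene_pairs = pair_counts_of_gene(seq)
    per_pair: Dict[Tuple[str, str], Optional[float]] = {}
    total = 0.0
    n = 0
    for pair, count in gene_pairs.items():
        score = table.get(pair)
        per_pair[pair] = score
        if score is not None:
            total += count * score
            n += count
    cpb = total / n if n else None
    return per_pair, cpb


# ---------------------------------------------------------------------------
# codon volatility

@lru_cache(maxsize=None)
def volatility_table(code: GeneticCode = STANDARD_CODE) -> Dict[str, float]:
    """Per-codon volatility: fraction of single-nucleotide sense neighbors
    encoding a different amino acid.  Stop-codon neighbors are excluded
    from numerator and denominator."""
    out: Dict[str, float] = {}
    for c in code.sense_codons:
        aa = code.codon_to_aa[c]
        sense = 0
        different = 0
        for k in range(3):
            for b in "ACGT":
                if b == c[k]:
                    continue
                neighbor = c[:k] + b + c[k + 1:]
                if neighbor in code.stop_codons:
                    continue
                sense += 1
                if code.codon_to_aa[neighbor] != aa:
                    different += 1
        out[c] = different / sense if sense else 0.0
    return out


def volatility(counts: CodonCounts) -> float:
    """Gene-level codon volatility: mean per-codon volatility over the gene."""
    table = volatility_table(counts.code)
    total = sum(x * table[c] for c, x in counts.counts.items())
    return total / counts.total
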