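"""Category-2 indices: comparison against a reference codon usage table.

CAI, FOP, CBI, COUSIN18/59, RCA, B, CUFS, Dmean.  All are pure functions of
a gene's :class:`~rarecodon.core.CodonCounts` plus reference resources.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .codes import GeneticCode
from .core import CodonCounts
from .intrinsic import rscu
from .reference import CodonUsageTable, RelativeAdaptiveness, ZERO_COUNT_PSEUDO


def _eligible_codons(code: GeneticCode, include_single: bool = False):
    """Codons entering CAI-style geometric means.

    Single-codon families (Met, Trp in the standard code) carry no choice and
    are excluded by the Sharp & Li convention unless ``include_single``.
    """
    for aa, fam in code.families.items():
        if len(fam) >= 2 or include_single:
            yield from fam


def cai(counts: CodonCounts, w: RelativeAdaptiveness,
        include_single_codon_families: bool = False) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Computed in the log domain for numerical stability.
    """
    if w.mode != "cai":
        raise ValueError("CAI requires CAI-mode relative adaptiveness weights")
    eligible = set(_eligible_codons(counts.code, include_single_codon_families))
    log_sum = 0.0
    n = 0
    for c, x in counts.counts.items():
        if c not in eligible:
            continue
        log_sum += x * math.log(w[c])
        n += x
    if n == 0:
        raise ValueError("no codons eligible for CAI")
    return math.exp(log_sum / n)


def fop_cbi(counts: CodonCounts, table: CodonUsageTable) -> Tuple[Optional[float], Optional[float]]:
    """Frequency of optimal codons and codon bias index.

    Optimal codons are the most frequent codon(s) of each multi-codon family
    in the reference; reference ties make every tied codon optimal.
    FOP = N_opt / N_tot; CBI = (N_opt - N_rand) / (N_tot - N_rand) with
    N_rand the expectation under uniform synonymous usage.
    """
    optimal = table.optimal_codons()
    n_opt = 0.0
    n_tot = 0.0
    n_rand = 0.0
    for aa, fam in counts.code.multi_codon_families.items():
        n_aa = sum(counts.counts.get(c, 0) for c in fam)
        if n_aa == 0:
            continue
        n_tot += n_aa
        opt = optimal[aa]
        n_opt += sum(counts.counts.get(c, 0) for c in opt)
        n_rand += n_aa * len(opt) / len(fam)
    if n_tot == 0:
        return None, None
    fop = n_opt / n_tot
    cbi = (n_opt - n_rand) / (n_tot - n_rand) if n_tot != n_rand else None
    return fop, cbi


def cousin(counts: CodonCounts, table: CodonUsageTable, variant: int = 59) -> Optional[float]:
    """COUSIN: normalized projection of query usage onto the reference bias.

    Scaled so a query with the reference's own bias scores 1 and a
    bias-free (uniform synonymous) query scores 0; opposite bias goes
    negative.  Variant 59 aggregates over all codons of multi-codon
    families; variant 18 averages per-family scores over the families
    observed in the query.
    """
    code = counts.code
    if variant == 59:
        multi = [c for fam in code.multi_codon_families.values() for c in fam]
        q_total = sum(counts.counts.get(c, 0) for c in multi)
        ref_probs = table.sense_codon_probs()
        ref_total = sum(ref_probs[c] for c in multi)
        if q_total == 0 or ref_total == 0:
            return None
        num = 0.0
        den = 0.0
        for aa, fam in code.multi_codon_families.items():
            u = 1.0 / len(fam)
            for c in fam:
                g = table.fraction[c]
                num += counts.counts.get(c, 0) / q_total * (g - u)
                den += ref_probs[c] / ref_total * (g - u)
        if den == 0:
            return None
        return num / den
    if variant == 18:
        scores = []
        for aa, fam in code.multi_codon_families.items():
            n_aa = sum(counts.counts.get(c, 0) for c in fam)
            if n_aa == 0:
                continue
            u = 1.0 / len(fam)
            num = sum(counts.counts.get(c, 0) / n_aa * (table.fraction[c] - u) for c in fam)
            den = sum(table.fraction[c] * (table.fraction[c] - u) for c in fam)
            if den > 0:
                scores.append(num / den)
        if not scores:
            return None
        return float(np.mean(scores))
    raise ValueError("COUSIN variant must be 18 or 59")


def rca_raw_weights(table: CodonUsageTable) -> Dict[str, float]:
    """f_ref(xyz) / (f1(x) f2(y) f3(z)) over all 64 reference codons."""
    total = sum(table.counts.values())
    probs = {c: table.counts[c] / total for c in table.counts}
    pos = [dict.fromkeys("ACGT", 0.0) for _ in range(3)]
    for c, p in probs.items():
        for k in range(3):
            pos[k][c[k]] += p
    out: Dict[str, float] = {}
    for c in probs:
        p = probs[c] if probs[c] > 0 else ZERO_COUNT_PSEUDO / total
        e = pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]]
        out[c] = p / e if e > 0 else 0.0
    return out


def rca(counts: CodonCounts, table: CodonUsageTable) -> float:
    """Relative codon adaptation: geometric mean of reference codon
    frequencies over the product of reference positional base frequencies,
    normalized to 1 at each family's maximum."""
    code = counts.code
    raw = rca_raw_weights(table)
    weights: Dict[str, float] = {}
    for aa, fam in code.families.items():
        best = max(raw[c] for c in fam)
        for c in fam:
            weights[c] = raw[c] / best if best > 0 else 1.0
    log_sum = 0.0
    for c, x in counts.counts.items():
        log_sum += x * math.log(weights[c])
    return math.exp(log_sum / counts.total)


def b_index(counts: CodonCounts, table: CodonUsageTable) -> float:
    """Karlin-Mrazek codon usage bias B(g|C): amino-acid-weighted L1
    distance between the gene's and the reference's within-family codon
    proportions.  0 = identical usage; bounded by 2."""
    code = counts.code
    L = counts.total
    score = 0.0
    for aa, fam in code.families.items():
        n_aa = sum(counts.counts.get(c, 0) for c in fam)
        if n_aa == 0:
            continue
        term = sum(
            abs(counts.counts.get(c, 0) / n_aa - table.fraction[c]) for c in fam
        )
        score += (n_aa / L) * term
    return score


def cufs(counts: CodonCounts, table: CodonUsageTable) -> float:
    """Codon usage frequency similarity: the Endres-Schindelin metric
    sqrt(2 * JSD) (natural log) between the gene's and the reference's
    sense-codon frequency distributions."""
    code = counts.code
    p = np.array([counts.counts.get(c, 0) / counts.total for c in code.sense_codons])
    ref = table.sense_codon_probs()
    q = np.array([ref[c] for c in code.sense_codons])
    m = (p + q) / 2
    def _h(v):
        nz = v[v > 0]
        return float(-(nz * np.log(nz)).sum())
    jsd = _h(m) - (_h(p) + _h(q)) / 2
    return math.sqrt(max(0.0, 2.0 * jsd))


def _rscu_vector(counts: CodonCounts) -> np.ndarray:
    """RSCU over the multi-family codons, 0 for unobserved amino acids."""
    values = rscu(counts)
    code = counts.code
    out = []
    for aa, fam in code.multi_codon_families.items():
        for c in fam:
            out.append(values.get(c, 0.0))
    return np.array(out)


def rscu_cosine_dissimilarity(a: CodonCounts, b: CodonCounts) -> float:
    """(1 - cosine similarity) / 2 between two genes' RSCU vectors."""
    va, vb = _rscu_vector(a), _rscu_vector(b)
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    if denom == 0:
        return 0.5
    return (1.0 - float(np.dot(va, vb)) / denom) / 2.0


def dmean(counts: CodonCounts, reference_genes: Iterable[CodonCounts]) -> Optional[float]:
    """Mean dissimilarity-based index: average RSCU cosine dissimilarity
    between the query and each individual reference gene.

    Needs per-gene reference vectors; a pooled (Kazusa) table cannot supply
    them, in which case the caller reports the index unavailable.
    """
    dists = [rscu_cosine_dissimilarity(counts, ref) for ref in reference_genes]
    if not dists:
        return None
    return float(np.mean(dists))
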