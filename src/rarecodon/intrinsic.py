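"""Category-1 indices: deviation of codon usage from uniform synonymous usage.

These indices need nothing beyond the gene itself (RSCU, ENC, RCBS, DCBS,
CDC, MILC, ICDI, SCUO, Ew, MCB).  The codon-preference statistic P is listed
in this category by convention although it reads reference frequencies.

All logarithms are natural unless a ratio of logarithms makes the base
cancel (SCUO, Ew).
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

from .codes import GeneticCode
from .core import CodonCounts
from .reference import CodonUsageTable

#: ENC degeneracy classes of the standard code: class size -> family count
ENC_CLASS_SIZES = (2, 3, 4, 6)


def rscu(counts: CodonCounts) -> Dict[str, float]:
    """Relative synonymous codon usage: count over family-mean count.

    Codons of amino acids absent from the gene are omitted (absent, not 0).
    """
    out: Dict[str, float] = {}
    code = counts.code
    for aa, fam in code.families.items():
        n_aa = sum(counts.counts.get(c, 0) for c in fam)
        if n_aa == 0:
            continue
        mean = n_aa / len(fam)
        for c in fam:
            out[c] = counts.counts.get(c, 0) / mean
    return out


def _family_homozygosity(counts: CodonCounts, fam: Tuple[str, ...]) -> Optional[float]:
    """Wright's F-hat = (n * sum p^2 - 1) / (n - 1); None if inestimable."""
    n = sum(counts.counts.get(c, 0) for c in fam)
    if n < 2:
        return None
    s = sum((counts.counts.get(c, 0) / n) ** 2 for c in fam)
    f = (n * s - 1) / (n - 1)
    if f <= 0:
        return None
    return f


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, capped to [20, 61].

    Per-family homozygosity estimates are averaged within each degeneracy
    class; a missing 3-fold class is imputed as the mean of the 2- and
    4-fold class averages (Wright's convention), any other missing class as
    the mean of the available class averages.
    """
    code = counts.code
    class_sum: Dict[int, float] = {k: 0.0 for k in ENC_CLASS_SIZES}
    class_n: Dict[int, int] = {k: 0 for k in ENC_CLASS_SIZES}
    class_total: Dict[int, int] = {k: 0 for k in ENC_CLASS_SIZES}
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        class_total[k] += 1
        f = _family_homozygosity(counts, fam)
        if f is not None:
            class_sum[k] += f
            class_n[k] += 1
    fbar: Dict[int, Optional[float]] = {
        k: (class_sum[k] / class_n[k] if class_n[k] else None) for k in ENC_CLASS_SIZES
    }
    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    available = [v for v in fbar.values() if v is not None]
    if not available:
        return 61.0
    fallback = sum(available) / len(available)
    nc = 2.0
    for k in ENC_CLASS_SIZES:
        f = fbar[k] if fbar[k] is not None else fallback
        nc += class_total[k] / f
    return min(61.0, max(20.0, nc))


def _entropy_terms(counts: CodonCounts):
    """Per multi-codon family: (aa count, entropy H, log family size)."""
    code = counts.code
    for aa, fam in code.multi_codon_families.items():
        n = sum(counts.counts.get(c, 0) for c in fam)
        if n == 0:
            continue
        h = 0.0
        for c in fam:
            x = counts.counts.get(c, 0)
            if x > 0:
                p = x / n
                h -= p * math.log(p)
        yield n, h, math.log(len(fam))


def scuo(counts: CodonCounts) -> Optional[float]:
    """Synonymous codon usage order: entropy deficit, weighted by aa usage.

    1 = one codon per family (maximal order), 0 = uniform synonymous usage.
    """
    terms = list(_entropy_terms(counts))
    total = sum(n for n, _, _ in terms)
    if total == 0:
        return None
    return sum((n / total) * (hmax - h) / hmax for n, h, hmax in terms)


def ew(counts: CodonCounts) -> Optional[float]:
    """Weighted sum of relative entropy; complements SCUO (Ew = 1 - SCUO)."""
    terms = list(_entropy_terms(counts))
    total = sum(n for n, _, _ in terms)
    if total == 0:
        return None
    return sum((n / total) * h / hmax for n, h, hmax in terms)


def icdi(counts: CodonCounts) -> Optional[float]:
    """Intrinsic codon deviation index: mean of S = sum (RSCU-1)^2 / (n(n-1)).

    0 for uniform usage, 1 when each family uses a single codon.
    """
    code = counts.code
    values = []
    for aa, fam in code.multi_codon_families.items():
        n_aa = sum(counts.counts.get(c, 0) for c in fam)
        if n_aa == 0:
            continue
        k = len(fam)
        mean = n_aa / k
        s = sum((counts.counts.get(c, 0) / mean - 1) ** 2 for c in fam)
        values.append(s / (k * (k - 1)))
    if not values:
        return None
    return float(np.mean(values))


def _codon_expected_freqs(counts: CodonCounts) -> Dict[str, float]:
    """Product of the gene's positional base frequencies, per observed codon."""
    pos = counts.positional_base_counts
    L = counts.total
    out = {}
    for c in counts.counts:
        out[c] = (
            pos[0][c[0]] / L * pos[1][c[1]] / L * pos[2][c[2]] / L
        )
    return out


def rcbs_dcbs(counts: CodonCounts) -> Tuple[float, float]:
    """Relative codon bias strength and directional codon bias score.

    Both compare each codon's frequency f(xyz) with the product of the
    gene's positional base frequencies f1(x)f2(y)f3(z).  RCBS is the
    geometric mean of f/(f1f2f3) over the gene minus 1; DCBS is the mean of
    max(f/(f1f2f3), f1f2f3/f) over the gene.
    """
    L = counts.total
    expected = _codon_expected_freqs(counts)
    log_sum = 0.0
    dcbs_sum = 0.0
    for c, x in counts.counts.items():
        f = x / L
        e = expected[c]
        ratio = f / e  # e > 0 whenever the codon itself occurs
        log_sum += x * math.log(ratio)
        dcbs_sum += x * max(ratio, 1.0 / ratio)
    rcbs_score = math.exp(log_sum / L) - 1.0
    dcbs_score = dcbs_sum / L
    return rcbs_score, dcbs_score


def cdc(counts: CodonCounts) -> float:
    """Codon deviation coefficient: 1 - cosine(observed, composition-expected).

    The expected usage of codon xyz is the product over positions of base
    probabilities derived from the gene's positional GC and purine contents
    under an independence model:
    p(G)=GC*R, p(A)=(1-GC)*R, p(C)=GC*(1-R), p(T)=(1-GC)*(1-R).
    """
    code = counts.code
    L = counts.total
    base_p: list[Dict[str, float]] = []
    for k in range(3):
        pos = counts.positional_base_counts[k]
        gc = (pos["G"] + pos["C"]) / L
        pur = (pos["A"] + pos["G"]) / L
        base_p.append({
            "G": gc * pur,
            "A": (1 - gc) * pur,
            "C": gc * (1 - pur),
            "T": (1 - gc) * (1 - pur),
        })
    obs = np.array([counts.counts.get(c, 0) / L for c in code.sense_codons])
    exp = np.array([
        base_p[0][c[0]] * base_p[1][c[1]] * base_p[2][c[2]] for c in code.sense_codons
    ])
    denom = float(np.linalg.norm(obs) * np.linalg.norm(exp))
    if denom == 0:
        return 1.0
    cosine = float(np.dot(obs, exp)) / denom
    return min(1.0, max(0.0, 1.0 - cosine))


def milc(counts: CodonCounts, expected: Optional[CodonUsageTable] = None) -> Optional[float]:
    """Measure independent of length and composition.

    M_a = 2 sum_c x_c ln(p_c / g_c) per amino acid; MILC = sum M_a / L - C
    with correction C = sum_a (n_i - 1)/L - 0.5 over amino acids observed.
    The expected distribution g defaults to uniform within families.
    """
    code = counts.code
    L = counts.total
    if L == 0:
        return None
    m_sum = 0.0
    correction_terms = 0.0
    for aa, fam in code.families.items():
        n_aa = sum(counts.counts.get(c, 0) for c in fam)
        if n_aa == 0:
            continue
        correction_terms += len(fam) - 1
        for c in fam:
            x = counts.counts.get(c, 0)
            if x == 0:
                continue
            p = x / n_aa
            g = expected.fraction[c] if expected is not None else 1.0 / len(fam)
            if g <= 0:
                g = 1e-12
            m_sum += 2.0 * x * math.log(p / g)
    c_corr = correction_terms / L - 0.5
    return m_sum / L - c_corr


def mcb(counts: CodonCounts, null: str = "uniform") -> Optional[float]:
    """Maximum-likelihood codon bias: log-degeneracy-weighted chi-square
    deviation of within-family proportions from the null usage.

    ``null='uniform'`` (default) uses equal synonymous usage;
    ``null='composition'`` corrects the null for the gene's positional base
    composition.
    """
    code = counts.code
    num = 0.0
    den = 0.0
    comp = None
    if null == "composition":
        pos = counts.positional_base_counts
        L = counts.total
        comp = [{b: pos[k][b] / L for b in "ACGT"} for k in range(3)]
    elif null != "uniform":
        raise ValueError(f"unknown MCB null {null!r}")
    for aa, fam in code.multi_codon_families.items():
        n_aa = sum(counts.counts.get(c, 0) for c in fam)
        if n_aa < 2:
            continue
        if comp is None:
            g = {c: 1.0 / len(fam) for c in fam}
        else:
            raw = {c: comp[0][c[0]] * comp[1][c[1]] * comp[2][c[2]] for c in fam}
            tot = sum(raw.values())
            if tot <= 0:
                continue
            g = {c: raw[c] / tot for c in fam}
        b_a = 0.0
        for c in fam:
            if g[c] <= 0:
                continue
            p = counts.counts.get(c, 0) / n_aa
            b_a += (p - g[c]) ** 2 / g[c]
        w = math.log(n_aa)
        num += w * b_a
        den += w
    if den == 0:
        return None
    return num / den


def codon_preference_p(counts: CodonCounts, reference: CodonUsageTable) -> Optional[float]:
    """Gene-level codon preference: geometric mean of the reference's
    within-family codon fraction over a uniform-synonymous null.

    1 means the gene uses codons exactly as often preferred as chance under
    the reference; values > 1 indicate preferred-codon usage.
    """
    code = counts.code
    log_sum = 0.0
    n = 0
    for c, x in counts.counts.items():
        fam = code.family_of(c)
        g = reference.fraction[c]
        if g <= 0:
            g = 1e-12
        null = 1.0 / len(fam)
        log_sum += x * math.log(g / null)
        n += x
    if n == 0:
        return None
    return math.exp(log_sum / n)
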