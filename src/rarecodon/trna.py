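"""Category-3 indices: adaptation to tRNA availability (tAI, gtAI, P2).

tAI weights each codon by the gene-copy-weighted availability of the tRNAs
that can decode it, discounting wobble pairings by selective-constraint
penalties s.  gtAI refines the s penalties for a corpus with a seeded
genetic algorithm.  P2 is a wobble-related ratio of pyrimidine-ending codon
classes computable from the gene alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .codes import GeneticCode, STANDARD_CODE, reverse_complement
from .core import CodonCounts
from .intrinsic import enc
from .reference import S_VECTOR_KEYS, TRNAProfile

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: codon third base -> (wobble anticodon base 34, penalty class)
_WOBBLE_BY_THIRD_BASE = {
    "T": ("G", "G:U"),  # G34 : U3
    "C": ("A", "I:C"),  # inosine (A34) : C3
    "A": ("A", "I:A"),  # inosine (A34) : A3
    "G": ("T", "U:G"),  # U34 : G3
}


def decoders(codon: str) -> List[Tuple[str, str]]:
    """Anticodons able to decode ``codon``: (anticodon, penalty class).

    The Watson-Crick anticodon has penalty class ``WC`` (s = 0); one wobble
    anticodon per codon is added following the dos Reis pairing scheme.
    """
    wc = reverse_complement(codon)
    wobble_base, s_class = _WOBBLE_BY_THIRD_BASE[codon[2]]
    wobble = wobble_base + wc[1:]
    return [(wc, "WC"), (wobble, s_class)]


@dataclass
class TAIWeights:
    """Per-codon tRNA availability and normalized tAI weights."""

    absolute: Dict[str, float]   # W_c = sum (1 - s) * tGCN over decoders
    weights: Dict[str, float]    # w_c = W_c / max W; zeros replaced
    zero_substitute: float       # geometric mean of nonzero weights

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


def tai_weights(profile: TRNAProfile, code: GeneticCode = STANDARD_CODE) -> TAIWeights:
    """Compute tAI weights from a tRNA profile.

    Codons with zero availability receive the geometric mean of the nonzero
    weights (dos Reis convention), keeping the gene-level geometric mean
    defined.
    """
    absolute: Dict[str, float] = {}
    for c in code.sense_codons:
        w = 0.0
        for anticodon, s_class in decoders(c):
            s = 0.0 if s_class == "WC" else profile.s_values[s_class]
            w += (1.0 - s) * profile.copies(anticodon)
        absolute[c] = w
    w_max = max(absolute.values())
    if w_max <= 0:
        raise ValueError("no codon has positive tRNA availability")
    weights = {c: v / w_max for c, v in absolute.items()}
    nonzero = [v for v in weights.values() if v > 0]
    sub = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    for c, v in weights.items():
        if v == 0:
            weights[c] = sub
    return TAIWeights(absolute=absolute, weights=weights, zero_substitute=sub)


def tai(counts: CodonCounts, profile: TRNAProfile,
        weights: Optional[TAIWeights] = None) -> float:
    """tRNA adaptation index: geometric mean of tAI weights over the gene."""
    if weights is None:
        weights = tai_weights(profile, counts.code)
    log_sum = 0.0
    n = 0
    for c, x in counts.counts.items():
        log_sum += x * math.log(weights[c])
        n += x
    if n == 0:
        raise ValueError("empty gene")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# gtAI: genetic-algorithm refinement of the wobble penalties

@dataclass
class GAConfig:
    """Genetic-algorithm settings for gtAI (all overridable)."""

    population_size: int = 50
    generations: int = 100
    tournament_size: int = 3
    mutation_rate: float = 0.1   # per-locus probability of a uniform redraw
    elitism: int = 1

    def validate(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class GtaiResult:
    s_values: Dict[str, float]
    fitness: float
    fitness_trace: List[float]
    per_gene_tai: np.ndarray
    proxy: np.ndarray


def _counts_matrix(genes: Sequence[CodonCounts], code: GeneticCode) -> np.ndarray:
    mat = np.zeros((len(genes), len(code.sense_codons)))
    index = {c: i for i, c in enumerate(code.sense_codons)}
    for g, counts in enumerate(genes):
        for c, x in counts.counts.items():
            mat[g, index[c]] += x
    return mat


def _decoder_arrays(profile: TRNAProfile, code: GeneticCode):
    """Per-sense-codon (WC copies, wobble copies, wobble penalty index)."""
    wc = np.empty(len(code.sense_codons))
    wob = np.empty(len(code.sense_codons))
    s_idx = np.empty(len(code.sense_codons), dtype=int)
    for i, c in enumerate(code.sense_codons):
        (wc_anti, _), (wob_anti, s_class) = decoders(c)
        wc[i] = profile.copies(wc_anti)
        wob[i] = profile.copies(wob_anti)
        s_idx[i] = S_VECTOR_KEYS.index(s_class)
    return wc, wob, s_idx


def _log_weights_from_arrays(wc, wob, s_idx, s_vector: np.ndarray) -> np.ndarray:
    absolute = wc + (1.0 - np.asarray(s_vector)[s_idx]) * wob
    w_max = absolute.max()
    if w_max <= 0:
        raise ValueError("no codon has positive tRNA availability")
    weights = absolute / w_max
    nz = weights[weights > 0]
    sub = math.exp(np.log(nz).mean())
    weights[weights == 0] = sub
    return np.log(weights)


def _weight_log_vector(profile: TRNAProfile, s_vector: np.ndarray,
                       code: GeneticCode) -> np.ndarray:
    """log tAI weights over sense codons for an s-vector (vectorized path)."""
    wc, wob, s_idx = _decoder_arrays(profile, code)
    return _log_weights_from_arrays(wc, wob, s_idx, s_vector)


def gtai(
    genes: Sequence[CodonCounts],
    profile: TRNAProfile,
    config: Optional[GAConfig] = None,
    seed: int = 0,
    expression: Optional[np.ndarray] = None,
) -> GtaiResult:
    """Optimize the wobble penalties s for a gene corpus.

    Fitness is the absolute Spearman rank correlation between the per-gene
    tAI under a candidate s-vector and an expression proxy; the proxy is a
    supplied expression vector, or by default the negated ENC of each gene
    (stronger bias standing in for higher expression).  The profile's own
    s-values seed the initial population, so the result is never worse than
    the starting penalties.  Identical seed + config give identical output.
    """
    config = config or GAConfig()
    config.validate()
    if len(genes) < 2:
        raise ValueError("gtAI needs at least 2 genes")
    code = genes[0].code
    rng = np.random.default_rng(seed)
    mat = _counts_matrix(genes, code)
    lengths = mat.sum(axis=1)
    proxy = (np.asarray(expression, dtype=float) if expression is not None
             else -np.array([enc(g) for g in genes]))
    if proxy.shape[0] != len(genes):
        raise ValueError("expression vector length must match the gene count")

    wc, wob, s_idx = _decoder_arrays(profile, code)
    proxy_ranks = rankdata(proxy)
    proxy_centered = proxy_ranks - proxy_ranks.mean()
    proxy_norm = np.linalg.norm(proxy_centered)

    def fitness(s_vec: np.ndarray) -> float:
        # Spearman = Pearson on ranks; proxy ranks are fixed, so only the
        # candidate's tAI ranks are recomputed per evaluation
        logw = _log_weights_from_arrays(wc, wob, s_idx, s_vec)
        gene_tai = np.exp(mat @ logw / lengths)
        r = rankdata(gene_tai)
        rc = r - r.mean()
        denom = np.linalg.norm(rc) * proxy_norm
        if denom == 0:
            return 0.0
        rho = float(rc @ proxy_centered) / denom
        return abs(rho) if np.isfinite(rho) else 0.0

    n_loci = len(S_VECTOR_KEYS)
    pop = rng.random((config.population_size, n_loci))
    pop[0] = np.clip(profile.s_vector(), 0.0, 1.0 - 1e-4)
    fits = np.array([fitness(ind) for ind in pop])
    trace = [float(fits.max())]

    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            parents = []
            for _p in range(2):
                contenders = rng.integers(0, config.population_size,
                                          size=config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            mask = rng.random(n_loci) < 0.5
            child = np.where(mask, parents[0], parents[1])
            mutate = rng.random(n_loci) < config.mutation_rate
            child = np.where(mutate, rng.random(n_loci), child)
            new_pop.append(child)
        pop = np.array(new_pop)
        fits = np.array([fitness(ind) for ind in pop])
        trace.append(max(trace[-1], float(fits.max())))

    best = int(np.argmax(fits))
    # the elite is carried over, so the final population contains the
    # best-seen candidate
    best_s = pop[best]
    logw = _weight_log_vector(profile, best_s, code)
    per_gene = np.exp(mat @ logw / lengths)
    return GtaiResult(
        s_values=dict(zip(S_VECTOR_KEYS, best_s.tolist())),
        fitness=float(fits[best]),
        fitness_trace=trace,
        per_gene_tai=per_gene,
        proxy=proxy,
    )


# ---------------------------------------------------------------------------
# P2

def p2(counts: CodonCounts) -> Optional[float]:
    """Gouy-Gautier P2 = (WWC + SST) / (WWY + SSY).

    W = A/T, S = G/C at codon positions 1-2; the third base is read
    literally (C or T, i.e. a pyrimidine Y).  Measures the preference for
    intermediate-strength codon-anticodon interactions.  Undefined (None)
    when the gene has no WWY or SSY codons.
    """
    weak, strong, pyr = set("AT"), set("GC"), set("CT")
    num = 0
    den = 0
    for c, x in counts.counts.items():
        ww = c[0] in weak and c[1] in weak
        ss = c[0] in strong and c[1] in strong
        if c[2] in pyr:
            if ww or ss:
                den += x
            if (ww and c[2] == "C") or (ss and c[2] == "T"):
                num += x
    if den == 0:
        return None
    return num / den
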