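"""Seeded synthetic-data generators.

Everything the analysis consumes — CDS sets, reference tables, tRNA
profiles, expression tables, motif-planted carriers — can be generated
here as a pure function of (specification, seed), together with a sidecar
ground-truth record for oracle tests.  No download is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .codes import GeneticCode, STANDARD_CODE, reverse_complement
from .core import CodonSequence
from .reference import CodonUsageTable, TRNAProfile


def _codon_probs(
    spec: Union[str, Mapping[str, float], CodonUsageTable],
    code: GeneticCode,
    rng: np.random.Generator,
) -> Dict[str, float]:
    """Resolve a codon-frequency specification to sense-codon probabilities.

    ``"uniform"`` draws uniformly over sense codons (uniform synonymous
    usage); ``"max_bias"`` picks one codon per family (chosen with the
    rng) and uses only those; a table or mapping is used as-is.
    """
    if isinstance(spec, CodonUsageTable):
        return spec.sense_codon_probs()
    if isinstance(spec, Mapping):
        total = sum(spec.values())
        return {c: v / total for c, v in spec.items()}
    if spec == "uniform":
        n = len(code.sense_codons)
        return {c: 1.0 / n for c in code.sense_codons}
    if spec == "max_bias":
        chosen = [fam[rng.integers(len(fam))] for fam in code.families.values()]
        return {c: 1.0 / len(chosen) for c in chosen}
    raise ValueError(f"unknown codon frequency spec {spec!r}")


def generate_cds(
    n_genes: int,
    length_range: Tuple[int, int] = (100, 400),   # in codons
    freq_spec: Union[str, Mapping[str, float], CodonUsageTable] = "uniform",
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
    name_prefix: str = "gene",
) -> Tuple[List[Tuple[str, str]], Dict]:
    """Draw genes codon-by-codon from a per-codon distribution.

    Only sense codons are sampled, so sequences never contain stops;
    lengths are multiples of 3 within the validation bounds.  Returns
    (records, ground_truth) where ground_truth holds the planted codon
    probabilities and per-gene lengths.
    """
    lo, hi = length_range
    if lo * 3 < 60 or hi * 3 > 12000:
        raise ValueError("length range outside the [60, 12000] bp contract")
    rng = np.random.default_rng(seed)
    probs = _codon_probs(freq_spec, code, rng)
    codons = list(probs)
    p = np.array([probs[c] for c in codons])
    records: List[Tuple[str, str]] = []
    lengths = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        lengths.append(length)
        draw = rng.choice(len(codons), size=length, p=p)
        seq = "".join(codons[j] for j in draw)
        records.append((f"{name_prefix}{i:04d}", seq))
    truth = {
        "codon_probs": probs,
        "lengths": lengths,
        "seed": seed,
        "spec": freq_spec if isinstance(freq_spec, str) else "custom",
    }
    return records, truth


def load_example_genes() -> List[Tuple[str, str]]:
    """The two bundled example sequences (synthetic stand-ins)."""
    from importlib import resources

    text = (resources.files("rarecodon") / "data" / "example_genes.fasta").read_text()
    records: List[Tuple[str, str]] = []
    for chunk in text.split(">"):
        if not chunk.strip():
            continue
        header, *lines = chunk.splitlines()
        records.append((header.split()[0], "".join(lines)))
    return records


def write_fasta(records: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def generate_trna_profile(
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
    max_copies: int = 12,
) -> TRNAProfile:
    """A random but full-coverage tRNA profile: every sense codon's
    Watson-Crick anticodon gets a positive gene copy number."""
    rng = np.random.default_rng(seed)
    gcn = {}
    for c in code.sense_codons:
        gcn[reverse_complement(c)] = int(rng.integers(1, max_copies + 1))
    return TRNAProfile(gcn=gcn, code=code)


def generate_expression(
    index_values: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Expression as a monotone transform of an index column + rank noise.

    The expression of each gene is the rank of its index value plus
    Gaussian noise of standard deviation ``noise_sd`` (in rank units).  At
    ``noise_sd=0`` the Spearman correlation with the generating index is
    exactly 1 (given no ties).
    """
    names = list(index_values)
    values = np.array([index_values[n] for n in names], dtype=float)
    ranks = rankdata(values)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(ranks)) if noise_sd > 0 else 0.0
    return pd.Series(ranks + noise, index=names, name="expression")


def _pad_to_codons(motif: str, code: GeneticCode, offset: int) -> str:
    """Pad a motif so that (offset + motif) fills whole, stop-free codons."""
    padded = "X" * offset + motif
    while len(padded) % 3 != 0:
        padded += "C"
    # replace leading placeholder and fix any stop codon by toggling its
    # third base (stops are TAA/TAG/TGA; a C third base never forms a stop)
    padded = padded.replace("X", "G")
    fixed = []
    for i in range(0, len(padded), 3):
        codon = padded[i : i + 3]
        if codon in code.stop_codons:
            codon = codon[:2] + "C"
        fixed.append(codon)
    out = "".join(fixed)
    assert motif in out
    return out


def plant_motifs(
    sequence: str,
    motif_patterns: Sequence[str],
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> Tuple[str, List[int]]:
    """Insert literal motifs at random codon boundaries.

    Each motif is padded into whole stop-free codons and inserted between
    codons, so a valid carrier stays valid.  Returns the new sequence and
    the 1-based start position of each planted motif, in input order.
    """
    rng = np.random.default_rng(seed)
    seq = sequence
    positions: List[int] = []
    for motif in motif_patterns:
        if any(b not in "ACGT" for b in motif.upper()):
            raise ValueError("plant_motifs needs literal ACGT motifs")
        block = _pad_to_codons(motif.upper(), code, offset=0)
        n_codons = len(seq) // 3
        at = int(rng.integers(0, n_codons + 1)) * 3
        seq = seq[:at] + block + seq[at:]
        # earlier plants downstream of this insertion shift right
        positions = [p + len(block) if p > at else p for p in positions]
        positions.append(at + block.index(motif.upper()) + 1)
    return seq, positions
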