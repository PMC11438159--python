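"""Batch analysis, report assembly, and index-vs-expression analysis.

``analyze_batch`` runs every supported index on a batch of coding
sequences against one host organism's reference resources and assembles a
per-gene :class:`IndexReport` with the 31 index families grouped into four
categories.  ``correlate_with_expression`` computes per-index Spearman
correlations against an expression table, and ``pca_species`` projects
several species' correlation profiles into principal-component space.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from . import composite, intrinsic, motifs as motifs_mod, refindices, trna
from .codes import GeneticCode, STANDARD_CODE
from .core import CodonCounts, CodonSequence, ValidationReport, prepare_batch
from .reference import (CodonPairTable, CodonUsageTable, RelativeAdaptiveness,
                        TRNAProfile, relative_adaptiveness)
from .trna import GAConfig

logger = logging.getLogger("rarecodon")

#: the 31 reported index families, grouped into the four categories
INDEX_CATEGORIES: Dict[str, Tuple[str, ...]] = {
    "intrinsic": ("RSCU", "ENC", "RCBS", "DCBS", "CDC", "MILC", "ICDI",
                  "SCUO", "Ew", "P", "MCB"),
    "reference": ("CAI", "FOP", "COUSIN18", "COUSIN59", "CBI", "Dmean",
                  "RCA", "CUFS", "B"),
    "tRNA": ("tAI", "gtAI", "P2"),
    "composite": ("GC", "GC1", "GC2", "GC3", "ENcp", "CPS", "CPB",
                  "volatility"),
}

INDEX_NAMES: Tuple[str, ...] = tuple(
    name for names in INDEX_CATEGORIES.values() for name in names
)

#: indices whose reported value is a scalar (RSCU and CPS are vectors)
SCALAR_INDICES: Tuple[str, ...] = tuple(
    n for n in INDEX_NAMES if n not in ("RSCU", "CPS")
)

#: static display metadata: documented range of each index
REFERENCE_RANGES: Dict[str, str] = {
    "RSCU": "per codon; 1 = unbiased, >1 over-used, <1 under-used",
    "ENC": "20 (maximal bias) to 61 (no bias)",
    "RCBS": ">= -1; 0 = codon usage factorizes into base composition",
    "DCBS": ">= 1; 1 = no directional bias",
    "CDC": "0 (no deviation) to 1",
    "MILC": "~0 (matches expected usage) and up",
    "ICDI": "0 (uniform) to 1 (one codon per family)",
    "SCUO": "0 (uniform) to 1 (maximal order)",
    "Ew": "0 (maximal bias) to 1 (uniform); Ew = 1 - SCUO",
    "P": "1 = reference prefers codons no more than chance",
    "MCB": "0 (null usage) and up",
    "CAI": "0 to 1; 1 = fully adapted to the reference",
    "FOP": "0 to 1; fraction of optimal codons",
    "COUSIN18": "1 = reference-like bias, 0 = unbiased, <0 opposite",
    "COUSIN59": "1 = reference-like bias, 0 = unbiased, <0 opposite",
    "CBI": "<=1; 1 = only optimal codons, 0 = random usage",
    "Dmean": "0 (identical to reference genes) to 1",
    "RCA": ">0; 1 = fully adapted (geometric-mean weight 1)",
    "CUFS": "0 (identical distribution) to sqrt(2 ln 2)",
    "B": "0 (reference-like) to 2",
    "tAI": "0 to 1; 1 = best tRNA-adapted codons only",
    "gtAI": "0 to 1; tAI under corpus-optimized wobble penalties",
    "P2": "0 to 1; fraction of intermediate-strength third-base pairings",
    "GC": "percent G+C over all bases",
    "GC1": "percent G+C at codon position 1",
    "GC2": "percent G+C at codon position 2",
    "GC3": "percent G+C at codon position 3",
    "ENcp": "up to the number of observed codon-pair types",
    "CPS": "per pair; 0 = pair used as expected from marginals",
    "CPB": "mean CPS over the gene; 0 = no pair bias",
    "volatility": "0 to 1; fraction of amino-acid-changing neighbors",
}


@dataclass
class ReferenceResources:
    """Everything reference-based indices may need for one host organism."""

    organism: str
    usage_table: CodonUsageTable
    trna_profile: Optional[TRNAProfile] = None
    pair_table: Optional[CodonPairTable] = None
    reference_genes: Optional[List[CodonCounts]] = None  # for Dmean
    motif_library: Optional[motifs_mod.MotifLibrary] = None


@dataclass
class AnalysisConfig:
    seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)
    run_gtai: bool = True
    cps_smoothing: float = 0.0
    code: GeneticCode = STANDARD_CODE


@dataclass
class IndexReport:
    """Full per-gene result: 31 index families in four categories."""

    gene_name: str
    validation: ValidationReport
    organism: str = ""
    table_source: str = ""
    values: Dict[str, object] = field(default_factory=dict)
    unavailable: Dict[str, str] = field(default_factory=dict)
    n_negative_cis: Optional[int] = None
    n_negative_repeats: Optional[int] = None
    cis_hits: List[motifs_mod.MotifHit] = field(default_factory=list)
    repeat_hits: List[motifs_mod.RepeatHit] = field(default_factory=list)

    @property
    def categories(self) -> Dict[str, Tuple[str, ...]]:
        return INDEX_CATEGORIES

    def value(self, name: str):
        return self.values.get(name)

    def to_dict(self) -> Dict:
        values = {}
        for name in INDEX_NAMES:
            v = self.values.get(name)
            if isinstance(v, dict):
                v = {("|".join(k) if isinstance(k, tuple) else k): val
                     for k, val in v.items()}
            values[name] = v
        return {
            "gene_name": self.gene_name,
            "accepted": self.validation.accepted,
            "rejection_reason": self.validation.rejection_reason,
            "organism": self.organism,
            "table_source": self.table_source,
            "values": values,
            "unavailable": dict(self.unavailable),
            "n_negative_cis": self.n_negative_cis,
            "n_negative_repeats": self.n_negative_repeats,
            "cis_hits": [h.__dict__ for h in self.cis_hits],
            "repeat_hits": [{"repeat": h.repeat, "starts": list(h.starts)}
                            for h in self.repeat_hits],
            "reference_ranges": REFERENCE_RANGES,
        }


def _failed_report(report: ValidationReport, resources: ReferenceResources) -> IndexReport:
    return IndexReport(
        gene_name=report.gene_name,
        validation=report,
        organism=resources.organism,
        table_source=resources.usage_table.source,
    )


def analyze_gene(
    seq: CodonSequence,
    resources: ReferenceResources,
    config: AnalysisConfig,
    w: RelativeAdaptiveness,
    tai_w: Optional[trna.TAIWeights],
) -> IndexReport:
    """All per-gene indices (gtAI, a corpus quantity, is filled in later)."""
    counts = CodonCounts.from_sequence(seq)
    report = IndexReport(
        gene_name=seq.gene_name,
        validation=ValidationReport(seq.gene_name, accepted=True),
        organism=resources.organism,
        table_source=resources.usage_table.source,
    )
    v = report.values
    miss = report.unavailable
    table = resources.usage_table

    # category 1 — intrinsic
    v["RSCU"] = intrinsic.rscu(counts)
    v["ENC"] = intrinsic.enc(counts)
    v["RCBS"], v["DCBS"] = intrinsic.rcbs_dcbs(counts)
    v["CDC"] = intrinsic.cdc(counts)
    v["MILC"] = intrinsic.milc(counts)
    v["ICDI"] = intrinsic.icdi(counts)
    v["SCUO"] = intrinsic.scuo(counts)
    v["Ew"] = intrinsic.ew(counts)
    v["P"] = intrinsic.codon_preference_p(counts, table)
    v["MCB"] = intrinsic.mcb(counts)

    # category 2 — reference table
    v["CAI"] = refindices.cai(counts, w)
    v["FOP"], v["CBI"] = refindices.fop_cbi(counts, table)
    v["COUSIN18"] = refindices.cousin(counts, table, 18)
    v["COUSIN59"] = refindices.cousin(counts, table, 59)
    if resources.reference_genes:
        v["Dmean"] = refindices.dmean(counts, resources.reference_genes)
    else:
        v["Dmean"] = None
        miss["Dmean"] = "no per-gene reference set (pooled table only)"
    v["RCA"] = refindices.rca(counts, table)
    v["CUFS"] = refindices.cufs(counts, table)
    v["B"] = refindices.b_index(counts, table)

    # category 3 — tRNA
    if resources.trna_profile is not None and tai_w is not None:
        v["tAI"] = trna.tai(counts, resources.trna_profile, weights=tai_w)
    else:
        v["tAI"] = None
        miss["tAI"] = "no tRNA profile"
    v["gtAI"] = None  # corpus-level; filled by analyze_batch
    v["P2"] = trna.p2(counts)
    if v["P2"] is None:
        miss["P2"] = "undefined: gene has no WWY or SSY codons"

    # category 4 — composite
    v["GC"], v["GC1"], v["GC2"], v["GC3"] = composite.gc_content(counts)
    v["ENcp"] = composite.encp(seq)
    if resources.pair_table is not None:
        cps, cpb = composite.cps_cpb(seq, resources.pair_table,
                                     smoothing=config.cps_smoothing)
        v["CPS"] = cps
        v["CPB"] = cpb
        if cpb is None:
            miss["CPB"] = "no gene pair observed in the reference"
    else:
        v["CPS"] = None
        v["CPB"] = None
        miss["CPS"] = miss["CPB"] = "no codon pair reference table"
    v["volatility"] = composite.volatility(counts)

    # motif metrics
    library = resources.motif_library or motifs_mod.load_motif_library()
    report.n_negative_cis, report.cis_hits = motifs_mod.count_negative_cis(seq, library)
    report.n_negative_repeats, report.repeat_hits = motifs_mod.count_negative_repeats(
        seq, library.min_repeat_length, library.min_repeat_copies)

    for name in INDEX_NAMES:
        if name not in v:
            v[name] = None
    return report


def analyze_batch(
    records: Iterable[Tuple[str, str]],
    resources: ReferenceResources,
    config: Optional[AnalysisConfig] = None,
) -> List[IndexReport]:
    """Analyze a batch of raw (name, sequence) records.

    Invalid sequences yield a failed report with no indices.  Per-gene
    values are independent of input order; gtAI (a corpus-level
    optimization over the valid genes) is deterministic given the seed and
    sorted by gene name internally so permuting the input cannot change
    any value.
    """
    config = config or AnalysisConfig()
    prepared = list(prepare_batch(records, config.code))
    valid = [(rep, seq) for rep, seq in prepared if seq is not None]
    for rep, _seq in prepared:
        if not rep.accepted:
            logger.warning("rejected %s: %s", rep.gene_name, rep.rejection_reason)
    logger.info("batch: %d accepted, %d rejected",
                len(valid), len(prepared) - len(valid))

    w = relative_adaptiveness(resources.usage_table)
    tai_w = (trna.tai_weights(resources.trna_profile, config.code)
             if resources.trna_profile is not None else None)

    reports: Dict[str, IndexReport] = {}
    for rep, seq in prepared:
        if seq is None:
            reports[rep.gene_name] = _failed_report(rep, resources)
        else:
            reports[rep.gene_name] = analyze_gene(seq, resources, config, w, tai_w)

    # corpus-level gtAI, order-independent via name-sorted corpus
    valid_sorted = sorted((seq for _r, seq in valid), key=lambda s: s.gene_name)
    if (config.run_gtai and resources.trna_profile is not None
            and len(valid_sorted) >= 2):
        counts_sorted = [CodonCounts.from_sequence(s) for s in valid_sorted]
        result = trna.gtai(counts_sorted, resources.trna_profile,
                           config=config.ga, seed=config.seed)
        for s, value in zip(valid_sorted, result.per_gene_tai):
            reports[s.gene_name].values["gtAI"] = float(value)
    else:
        reason = ("no tRNA profile" if resources.trna_profile is None
                  else "needs >= 2 valid genes" if len(valid_sorted) < 2
                  else "disabled")
        for _rep, seq in valid:
            reports[seq.gene_name].unavailable["gtAI"] = reason

    return [reports[rep.gene_name] for rep, _ in prepared]


# ---------------------------------------------------------------------------
# report serialization

def write_report_json(reports: Sequence[IndexReport], path) -> None:
    payload = {"reports": [r.to_dict() for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_report_json(path) -> List[Dict]:
    return json.loads(Path(path).read_text())["reports"]


_METADATA_COLUMNS = ("gene_name", "accepted", "rejection_reason",
                     "n_negative_cis", "n_negative_repeats")


def reports_to_frame(reports: Sequence[IndexReport]) -> pd.DataFrame:
    """One row per gene, one column per index plus metadata columns.

    Vector-valued indices (RSCU, CPS) are serialized as JSON strings;
    unavailable values stay empty (never 0).
    """
    rows = []
    for r in reports:
        row: Dict[str, object] = {
            "gene_name": r.gene_name,
            "accepted": r.validation.accepted,
            "rejection_reason": r.validation.rejection_reason,
            "n_negative_cis": r.n_negative_cis,
            "n_negative_repeats": r.n_negative_repeats,
        }
        for name in INDEX_NAMES:
            val = r.values.get(name)
            if isinstance(val, dict):
                val = json.dumps(
                    {("|".join(k) if isinstance(k, tuple) else k): x
                     for k, x in val.items()},
                    sort_keys=True)
            row[name] = val
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_METADATA_COLUMNS) + list(INDEX_NAMES))


def write_report_tsv(reports: Sequence[IndexReport], path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False,
                                     float_format="%.12g")


def read_report_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# correlation with expression / PCA across species

@dataclass
class CorrelationResult:
    """Per-index Spearman correlation with expression for one species."""

    species: str
    coefficients: Dict[str, float]
    n_genes: int
    pca_coordinates: Optional[np.ndarray] = None


def scalar_index_frame(reports: Sequence[IndexReport]) -> pd.DataFrame:
    """Accepted genes x scalar indices, NaN where unavailable."""
    rows = {}
    for r in reports:
        if not r.validation.accepted:
            continue
        rows[r.gene_name] = {
            name: (np.nan if r.values.get(name) is None else float(r.values[name]))
            for name in SCALAR_INDICES
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def correlate_with_expression(
    reports: Sequence[IndexReport],
    expression: Mapping[str, float],
    species: str = "",
    method: str = "spearman",
) -> CorrelationResult:
    """Spearman rank correlation of every scalar index with expression.

    Genes missing either value are excluded pairwise; ties get average
    ranks (scipy's convention).  At least 3 shared genes are required.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    frame = scalar_index_frame(reports)
    expr = pd.Series(dict(expression), dtype=float)
    shared = frame.index.intersection(expr.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared with the expression table")
    frame = frame.loc[shared]
    expr = expr.loc[shared]
    coefficients: Dict[str, float] = {}
    for name in SCALAR_INDICES:
        col = frame[name]
        mask = col.notna() & expr.notna()
        if mask.sum() < 3 or col[mask].nunique() < 2:
            coefficients[name] = float("nan")
            continue
        rho = spearmanr(col[mask], expr[mask]).statistic
        coefficients[name] = float(rho)
    return CorrelationResult(species=species, coefficients=coefficients,
                             n_genes=int(len(shared)))


@dataclass
class PCAResult:
    species: List[str]
    indices: List[str]
    coordinates: np.ndarray          # species x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray             # components x indices


def pca_species(
    results: Sequence[CorrelationResult],
    n_components: int = 2,
) -> PCAResult:
    """PCA of the species-by-index Spearman coefficient matrix.

    Columns are centered by the PCA itself; indices with a missing
    coefficient in any species are dropped.  The sign of each component is
    fixed so its largest-magnitude loading is positive, making coordinates
    independent of species input order.
    """
    if len(results) < 2:
        raise ValueError("PCA needs at least 2 species")
    order = np.argsort([r.species for r in results])
    sorted_results = [results[i] for i in order]
    mat = pd.DataFrame([r.coefficients for r in sorted_results],
                       index=[r.species for r in sorted_results])
    mat = mat.dropna(axis=1)
    n_components = min(n_components, len(sorted_results) - 1, mat.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(mat.values)
    loadings = pca.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            coords[:, k] *= -1
    # undo the sort so coordinates align with the caller's input order
    inverse = np.argsort(order)
    for i, r in enumerate(results):
        r.pca_coordinates = coords[inverse[i]]
    return PCAResult(
        species=[r.species for r in results],
        indices=list(mat.columns),
        coordinates=coords[inverse],
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
    )
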