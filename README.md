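# rarecodon

Codon usage bias (CUB) analysis for coding sequences: a library and CLI
that validates DNA/RNA coding sequences, computes **31 CUB index families
in four categories**, counts two motif-based expression metrics (negative
cis elements and negative direct repeats), and runs the downstream
index-vs-expression Spearman correlation and cross-species PCA analysis.

It is aimed at researchers evaluating whether a gene needs codon
optimization for a given expression host: no single index predicts
expression across species, so the whole panel is computed at once.

## The indices

Synonymous codons are used non-randomly; each index quantifies that bias
from a different angle.

1. **Intrinsic** (deviation from uniform synonymous usage, no reference
   needed): RSCU, ENC, RCBS, DCBS, CDC, MILC, ICDI, SCUO, Ew, P, MCB.
   E.g. RSCU_c = x_c / x̄_family, and Wright's effective number of codons
   Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with per-family homozygosity
   F̂ = (n Σp² − 1)/(n − 1), capped to [20, 61].
2. **Reference-based** (comparison to a host codon usage table): CAI,
   FOP, COUSIN18, COUSIN59, CBI, Dmean, RCA, CUFS, B.  E.g.
   CAI = (Π w_cᵏ)^(1/L) with w_c = g_c / max_family g_c.
3. **tRNA-based** (adaptation to tRNA supply): tAI, gtAI, P2.  tAI weighs
   each codon by Σ (1 − s_ij) · tGCN_j over its decoders; gtAI re-optimizes
   the wobble penalties s for a corpus with a seeded genetic algorithm.
4. **Composite** (longer-range patterns): GC, GC1, GC2, GC3, ENcp,
   CPS, CPB, codon volatility.  E.g.
   CPS(AB) = ln[F(AB)·F(x)·F(y) / (F(A)·F(B)·F(xy))].

Preprocessing follows strict rules: non-alphabetic symbols are stripped,
U→T, terminal stop codons removed; sequences are then rejected when
shorter than 60 bp or longer than 12,000 bp, not a multiple of 3,
containing non-ACGT characters or an internal stop codon, or duplicating
a gene name within the batch.

## Worked example

Everything can run on synthetic inputs — no downloads:

```python
from rarecodon import *
from rarecodon import fixtures

records, _ = fixtures.generate_cds(50, length_range=(100, 300), seed=11)
table, per_gene, _ = build_table_from_cds(records, organism="synthetic")
resources = ReferenceResources(
    organism="synthetic", usage_table=table,
    trna_profile=fixtures.generate_trna_profile(seed=12),
    pair_table=build_pair_table(records),
    reference_genes=per_gene)

reports = analyze_batch(fixtures.load_example_genes(), resources,
                        AnalysisConfig(seed=1))
r = reports[0]
for name in ("ENC", "SCUO", "CAI", "FOP", "COUSIN59", "tAI", "GC3",
             "CPB", "volatility"):
    print(f"  {name:10s} {r.values[name]:.4f}")
print("  negative cis elements:", r.n_negative_cis)
print("  negative repeat elements:", r.n_negative_repeats)
```

prints

```
  ENC        56.9771
  SCUO       0.2103
  CAI        0.9191
  FOP        0.2677
  COUSIN59   -3.3980
  tAI        0.4112
  GC3        54.6154
  CPB        -0.0060
  volatility 0.7374
  negative cis elements: 1
  negative repeat elements: 0
```

The example gene was drawn with uniform synonymous usage, so ENC is near
61 and SCUO near 0 (little bias); CAI is high because the reference table
was itself built from unbiased genes, while COUSIN59 is strongly negative
because the gene does not share what little bias the reference has.  CPB
near 0 says adjacent codon pairs occur as expected from the reference's
marginals.

The same run from the shell:

```sh
rarecodon fixtures --make all --seed 11 --n-genes 50 --out fx
rarecodon analyze --fasta fx/cds.fasta --organism-table fx/usage_table.txt \
    --trna fx/trna_profile.tsv --pair-table fx/cds.fasta --out out
rarecodon correlate --reports out/report.tsv --expression expr.tsv --out corr
```

`analyze` writes `report.json` / `report.tsv` (one row per gene, one
column per index; unavailable values are null with a reason, never 0) and
exits 0 when all genes were valid, 3 on partial failures, 4 when none were.

## Input formats

- Query sequences: multi-record FASTA or a two-column `name<TAB>sequence`
  table.
- Codon usage table: the Kazusa text dialect — `codon per-thousand
  (count)` — or a `codon<TAB>count` TSV, or built from a CDS FASTA with
  `build-table`.
- tRNA profile: TSV of `anticodon<TAB>gene copy number`; lines like
  `#s G:U 0.41` override the wobble penalties.
- Motif library: TSV of `name<TAB>IUPAC pattern<TAB>category<TAB>citation`
  (an editable default ships with the package).

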