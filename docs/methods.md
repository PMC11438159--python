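# Methods

This note records the definitions actually implemented, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer would want
spelled out.

## Sequence model and validation

Inputs are declared coding sequences read in frame 0; there is no ORF
search, intron handling or frame correction.  Cleaning removes every
non-alphabetic character, upper-cases, maps U→T and strips stop codons
from the end of the sequence.  Terminal-stop stripping repeats while the
remaining length is a multiple of 3; when the length is not a multiple of
3 the terminal frame is undefined and nothing is stripped, which makes
cleaning idempotent.  Validation then rejects, in this order: non-ACGT
characters (ambiguity codes such as N are treated as errors rather than
deletable symbols, because every index is undefined on ambiguous codons),
length not a multiple of 3, length outside [60, 12000] bp, internal stop
codons, and duplicate gene names within a batch.  Only NCBI translation
table 1 ships, but every function takes a `GeneticCode` parameter so other
tables can be added.

## Index definitions and numerical choices

Natural logarithms are used throughout except where a ratio of logarithms
cancels the base (SCUO, Ew).  Geometric means (CAI, RCA, tAI, RCBS) are
computed in the log domain.

- **ENC** (Wright's estimator): per-family homozygosity
  F̂ = (nΣp²−1)/(n−1) over families with ≥ 2 observations and F̂ > 0,
  averaged within degeneracy classes {2, 3, 4, 6};
  Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.  A missing 3-fold class is
  imputed as (F̄₂+F̄₄)/2 (Wright's convention); any other missing class
  borrows the mean of the available class averages.  The result is capped
  to [20, 61]: short unbiased genes otherwise overshoot 61 because F̂ is
  an unbiased estimator of Σp², not of its reciprocal.
- **SCUO / Ew**: entropy deficit / relative entropy per multi-codon
  family, weighted by amino-acid usage; with identical weighting
  Ew = 1 − SCUO, which the tests assert as an algebraic identity.
- **ICDI**: mean over observed multi-codon families of
  Σ(RSCU−1)²/(n(n−1)); equals 1 for one-codon-per-family usage for every
  family size.
- **RCBS / DCBS**: both compare codon frequency to the product of the
  gene's own positional base frequencies; RCBS is the geometric mean of
  the ratio minus 1, DCBS the arithmetic mean of max(ratio, 1/ratio).
- **CDC**: expected codon usage from positional GC and purine contents
  under an independence model (p(G)=GC·R, p(A)=(1−GC)·R, ...);
  CDC = 1 − cosine(observed, expected) over sense codons.  The original's
  bootstrap significance machinery is out of scope.
- **MILC**: Σ_a 2Σ_c x_c ln(p_c/g_c) / L − C with C = Σ_a(n_i−1)/L − 0.5
  over amino acids observed; expected usage defaults to uniform within
  families, optionally a reference table.
- **MCB**: per-family chi-square deviation of within-family proportions
  from the null, weighted by ln(amino-acid count) and normalized by the
  weight sum.  The null is uniform by default (the index sits in the
  no-reference category); a composition-corrected null is available via
  `null="composition"`.
- **P (codon preference)**: geometric mean over the gene's codons of the
  reference's within-family fraction divided by the uniform null.  It is
  listed with the intrinsic indices by convention although it consumes the
  active reference table; this tension is inherent to the index and
  documented rather than resolved.
- **CAI**: Sharp & Li weights w_c = g_c/max_family g_c with zero reference
  counts replaced by 0.5 before weighting (standard practice; prevents
  CAI collapsing to 0 on a single unseen codon).  Met, Trp and stops are
  excluded; a flag includes them for cross-tool comparison.
- **FOP / CBI**: optimal codons are each family's most frequent codon(s)
  in the reference; ties make all tied codons optimal (deterministic and
  symmetric).  CBI = (N_opt−N_rand)/(N_tot−N_rand) with N_rand the uniform
  expectation; when N_tot = N_rand the value is undefined and reported as
  missing.
- **COUSIN**: the query's within-family usage is projected onto the
  reference's bias direction (g − u, u uniform) and normalized by the
  reference's own projection, so reference-like bias scores 1, no bias 0,
  opposite bias < 0.  COUSIN59 aggregates over all multi-codon-family
  codons with overall codon-frequency weighting restricted to that
  support; COUSIN18 averages per-family scores over families observed in
  the query (families whose reference usage is exactly uniform have a
  zero denominator and are skipped).
- **RCA**: reference weight f(xyz)/(f1(x)f2(y)f3(z)) computed over all 64
  codons of the reference table (stops included in the marginals, so an
  exactly factorizable reference gives weight 1 for every codon),
  normalized to each family's maximum; gene score is the geometric mean.
- **B**: Karlin–Mrázek amino-acid-weighted L1 distance between
  within-family proportion vectors; bounded by 2.
- **CUFS**: Endres–Schindelin metric √(2·JSD), natural log, between
  sense-codon frequency distributions; maximum √(2 ln 2) for disjoint
  support.
- **Dmean**: mean cosine dissimilarity (1−cos)/2 between RSCU vectors of
  the query and each individual reference gene.  It needs per-gene
  vectors, so with a pooled (Kazusa) reference it is reported unavailable
  with a reason; when the table is built from a CDS FASTA the builder's
  per-gene counts serve as the reference set.  Cost is O(genes ×
  reference genes), the only non-linear step in a batch.
- **tAI**: decoders per codon follow the dos Reis pairing scheme — the
  Watson–Crick anticodon plus one wobble anticodon determined by the
  third base (G34:U, I34:C, I34:A, U34:G) — with default penalties
  s = (0.41, 0.28, 0.9999, 0.68) shipped as overridable configuration.
  Codons with zero availability receive the geometric mean of the nonzero
  weights so the gene-level geometric mean stays defined.
- **gtAI**: a seeded genetic algorithm over the four wobble penalties
  (bounded [0,1)) maximizing |Spearman| between per-gene tAI and an
  expression proxy.  The proxy is a supplied expression vector or, by
  default, the negated ENC of each gene (stronger bias as a stand-in for
  higher expression).  Defaults: population 50, generations 100,
  tournament size 3, uniform crossover, per-locus mutation 0.1, elitism 1.
  The profile's current s-values seed the population, so the optimized
  fitness is never below the default penalties'; zero generations returns
  the best member of the initial population; identical seed and
  configuration give identical output.  The corpus is name-sorted before
  optimization so batch input order cannot change any value.
- **ENcp**: Wright's estimator generalized to adjacent codon pairs
  grouped into amino-acid-pair families (family size = product of
  degeneracies).  Observed families with < 2 pair observations are
  counted but contribute no F̂; a size class that is observed but
  inestimable borrows the mean of the nearest estimable classes,
  mirroring the ENC imputation.  The value is capped at the number of
  observed pair types and can never exceed 61².
- **CPS / CPB**: CPS(AB) = ln[F(AB)F(x)F(y)/(F(A)F(B)F(xy))] with counts
  from a reference CDS corpus whose pairs never span record junctions or
  a stripped terminal stop.  Pairs unobserved in the reference default to
  "missing" and are excluded from the CPB mean; add-0.5 smoothing is
  available behind a flag.  This avoids silent −∞ scores.
- **P2**: (WWC+SST)/(WWY+SSY) over codons, W=A/T and S=G/C at the first
  two positions and the third base read literally; reported as missing
  (never 0) when the gene has no WWY/SSY codons.
- **Codon volatility**: fraction of single-nucleotide sense neighbors
  encoding a different amino acid, unweighted (transitions and
  transversions equal — the simplest published variant; a weighted
  variant would slot into the same precomputed table).

## Motif metrics

The two sequence-level counts are matches to a library of negative cis
elements and the number of maximal direct repeats.  No authoritative
motif list exists for this kind of panel, so the default library is a
small literature-derived TSV (poly(A) signals AATAAA/ATTAAA, the ARE
instability pentamer ATTTA, splice donor/acceptor consensi, the chi site)
that users are expected to edit; per-motif hits are reported so counts
can be matched to any external library.  Matching is on the coding strand
by default (reverse complement behind a flag), overlapping matches
counted.  Repeats are maximal repeated substrings of length ≥ 10
occurring ≥ 2 times — maximal meaning the occurrence set cannot be
extended by a common character on either side — found by seed-and-extend
over 10-mers; each distinct repeated substring counts once.  The scan is
worst-case quadratic on pathological (near-homopolymer) inputs, which
validated coding sequences do not approach.

## Synthetic data

Generators are pure functions of (specification, seed).  Genes are drawn
codon-by-codon from sense-codon distributions ("uniform" = uniform over
sense codons, "max_bias" = one codon per family, a table, or an explicit
distribution), so they contain no stops by construction and always pass
validation.  Expression tables are monotone transforms of a chosen index
column plus Gaussian rank noise; tRNA profiles assign every Watson–Crick
anticodon a random positive copy number; motif planting inserts padded,
stop-free codon blocks at codon boundaries and returns ground-truth
positions.

These fixtures emulate iid codon sampling only: no codon autocorrelation,
no amino-acid composition constraints from real proteomes, no GC
isochores, no genuine tRNA abundances, no real motif backgrounds.
Passing tests therefore demonstrate that the computational chain is
correct (definitions, estimators, recovery of planted parameters), not
that any index predicts expression in real organisms.

## Problem sizes used in tests and the acceptance script

Property tests use 200–500 gene corpora of 80–300 codons; the
table-recovery experiment uses three replicate corpora of 500 genes and
requires the per-codon 3-standard-error bound on the majority of
replicates (a single corpus has a ~15% chance of one benign >3 SE
exceedance among 61 codons even for an exact chain); the gtAI recovery
experiment uses 30 genes, population 50 and 200 generations against an
expression vector generated from a planted s-vector, requiring ≥ 95% of
the planted optimum's fitness.

## Known limitations

- Only the standard genetic code is bundled.
- The MCB and Dmean literature contains several variants; the ones here
  are the simplest internally consistent forms (chi-square vs uniform
  null; RSCU cosine dissimilarity) and are documented above rather than
  claimed to reproduce any specific web tool's numbers.
- The motif library is explicitly not a reproduction of any proprietary
  set; absolute counts are only comparable between runs of this package.
- Dmean is unavailable with a database-cited (pooled) reference table.
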