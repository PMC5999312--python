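# Methods

## Scope and data model

`panhe` implements the depth-track core of an allopolyploid pangenome
analysis: gene presence/absence (PAV) calling, homoeologous-exchange (HE)
detection, core/variable classification, and pangenome growth modelling.
Read mapping is upstream and out of scope: the pipeline starts from
per-base depth vectors (one per chromosome per accession) that are assumed
to derive from properly paired read alignments. All internal coordinates
are 0-based half-open; GFF3 and 3-column depth TSVs convert at the I/O
boundary, as does BLAST tabular (whose subject coordinates may be reversed
on minus-strand hits and are normalized on read).

## PAV rule

For gene *g* and accession *a*, the covered fraction is

  f(g, a) = |{ exon-union bases of g with depth ≥ minCov }| / |exon-union of g|

and *g* is absent in *a* iff f < lostCutoff. Defaults minCov = 2,
lostCutoff = 0.05 suit ~12× short-read panels; the high-depth preset
minCov = 300, lostCutoff = 0.70 is interpreted with identical semantics
(absent iff fewer than 70% of bases reach depth 300). The boundary is
strict: f exactly equal to lostCutoff is present. This convention is a
deliberate choice — the rule's published descriptions do not fix the
boundary — and is what makes the monotonicity properties clean (raising
minCov can only lower f; raising lostCutoff can only convert present to
absent). Coverage is computed over the exon union by default; a gene-span
mode exists for annotations without exon features. Accessions whose
genome-wide mean depth falls below `min_mean_depth` (default 5×,
configurable; low-coverage samples yield spurious absences) are excluded
before the matrix is assembled and reported with their depths.

## HE detection

Candidate events are maximal runs of rank-consecutive absent genes with at
least `min_run_genes` (default 3) members; shorter runs are reported as
non-HE PAV directly, which separates single-gene deletions from exchange
tracts. Each candidate run on chromosome R with homoeologous partner D is
accepted as an HE iff all three tests pass:

1. **Homology.** For each run gene, its best hit (ties broken by bitscore,
   then identity, then leftmost subject position) must lie on D with
   identity > `pid_min` (90), alignment length within `aln_len_tol`
   (10 bp) of the query's exon-union length, and the annotated D gene with
   the largest overlap of the hit must itself be called present. At least
   `support_frac` (0.8) of run genes must pass. Requiring only 80% rather
   than all genes tolerates occasional annotation or hit dropout inside a
   true tract while still rejecting chance runs.
2. **Order.** Collinearity ("hits roughly arranged consecutively") is
   operationalised as |Spearman ρ| ≥ `order_rho_min` (0.8) between the
   supported genes' ranks and their hit midpoints; one or two supported
   genes are trivially collinear.
3. **Coverage.** With 1000-bp bins tiled from the interval start (the last
   partial bin averaged over its true width; the interval mean is the
   length-weighted bin mean, i.e. the per-base mean), the recipient
   interval mean must be < `zero_factor` (0.1) × baseline and the donor
   interval mean (the span of supported hits, clipped to the chromosome)
   must be > `dup_factor` (1.5) × baseline.

**Baseline.** The default baseline is the mean depth of the tested
chromosome *excluding the interval under test*. Including the interval is
self-defeating: a terminal exchange covering a fraction s of the donor
chromosome raises that chromosome's mean to λ(1 + s), so at 2λ segment
depth the 1.5× criterion fails once s ≥ 1/3 even with no noise at all. A
genome-mean baseline is offered as an alternative; because an HE only
moves coverage between homoeologues, the genome-wide mean is invariant
under exchanges and equally usable. Direction is reported as
donor-subgenome → recipient-subgenome.

Every absent gene ends up in exactly one of: some HE call's recipient list,
or the non-HE list — runs on chromosomes without a homoeologous partner go
to the non-HE list with a warning.

## Core/variable classification and clustering

A gene is core iff present in every retained accession. A family is core
if ≥ 1 member is present in all accessions, variable if some accession
lacks every member. With a fixed accession set these clauses are mutually
exclusive but not exhaustive; the uncovered middle case (no always-present
member, never wholly missing) defaults to core, so "variable" always
certifies a demonstrable whole-family loss. Both raw clause outcomes are
returned alongside the final label. Unassigned genes become singleton
families.

The accession dendrogram uses Hamming distances between binary PAV columns
and average linkage. The published analyses used a correlation-based
clustering package without printing its settings; Hamming + average linkage
was chosen for determinism on binary data, with metric and linkage
configurable. Node support is the fraction of `n_boot` (default 1000)
gene-resampled (rows, with replacement, seeded) trees containing the same
accession subset; approximately-unbiased multiscale p-values are not
computed. Columns are sorted by accession id before clustering so that
zero-distance ties resolve deterministically.

## Growth modelling

For each subset size k of the n-accession panel, all C(n, k) combinations
are enumerated when C(n, k) ≤ cap (default 100 000); otherwise cap distinct
combinations are drawn uniformly without replacement (exact index sampling
when C(n, k) ≤ 10 × cap, rejection sampling of sorted k-subsets beyond
that), seeded per k. Each combination contributes one growth point:
pan = genes (or families, any member) present in ≥ 1 member; core = genes
present in all members (families: ≥ 1 member present in all subset
members). Fits use every sampled point, not per-k means:

* pangenome: y = A·x^B + C, started at C₀ = 1.01·max(pan),
  A₀ = mean(pan at n = 1) − C₀, B₀ = −1;
* core: y = A·e^{Bx} + C, started at C₀ = 0.99·min(core),
  A₀ = mean(core at n = 1) − C₀, B₀ = −0.5;

with up to 5 jittered restarts on failure (the underlying least-squares
machinery is the Levenberg–Marquardt family; the published analyses name
the algorithm but not the starting values). Standard errors come from the
coefficient covariance; with B < 0 the curve is bounded and C ± se(C) is
reported as the predicted asymptotic size. Reading the published "±" as
the standard error of C is an interpretation — confidence half-widths are
the stated alternative — and is noted in the CLI output metadata.

## Contaminant filter

An assembled contig is contamination iff its best nucleotide hit is
against a non-green-plant, mitochondrial or chloroplast sequence with
identity > 90 and alignment length ≥ 50% of the contig length. The
published threshold is printed as "≥ 50"; it is read here as the fraction
0.5 of the query length and exposed as `len_frac_min` rather than fixed.

## Synthetic allotetraploid generator

The generator emulates a resequenced allopolyploid panel at desk scale:
3 homoeologous chromosome pairs (A0i/C0i) × 60 genes of 1500 bp separated
by 1000-bp gaps; every A-gene has exactly one rank-aligned homoeologue on
the paired C chromosome with identity drawn uniformly from 91–99% and
alignment length within ±10 bp of the gene length (mirroring the >90%
identity of real homoeologues and the ancestral collinearity that makes
hit order informative). Genes carry two abutting exons whose union equals
the gene span, so exon-union arithmetic is exercised without decoupling
exon length from the homology table's alignment lengths.

A 20-accession panel (half "synthetic", i.e. resynthesised from the
progenitors, half natural) carries per chromosome pair at most one HE with
probability 0.5 (synthetic) or 0.1 (natural) — resynthesised lines show
more frequent and larger exchanges — with gene span uniform 5–20, terminal
anchoring with probability 0.9 (exchanges concentrate at chromosome ends)
and direction C→A with probability 0.8 (nonreciprocal exchange runs mostly
from the C to the A subgenome). Independent single-gene deletions occur at
rate 0.01 per gene, never inside an HE segment on either side: recipient
genes are already lost, and deleting one copy of a doubled donor gene
would create a 1× state the binary truth cannot express. Published
analyses do not quantify HE rates or size distributions; these defaults
are order-of-magnitude choices fixed in `SimConfig`, not estimates.

Depth is Poisson per base: λ = 12 (the panel-typical mean coverage) in
neutral regions, 0 in HE-recipient segments and deleted gene spans, 24 in
donor segments, with boundaries aligned to gene/intergenic edges and
terminal segments extended to the chromosome end. A noise-free mode emits
the λ profile as exact depths for boundary-condition tests. Tracks are
generated directly rather than via read simulation: the detectors consume
depth vectors and homology tables, so the 0×/1×/2× statistical structure
is preserved without aligner dependencies. An optional
`duplicate_donor=False` mode produces loss without doubling, giving the
counterexample where the coverage test must reject.

What passing on this generator does *not* show: robustness to mapping
artefacts (repeats, paralogue cross-mapping), GC-dependent coverage bias,
annotation errors, partial-gene losses, overlapping or reciprocal
exchanges, and gene conversion. Real-data use inherits those caveats from
the upstream alignment.

## Problem sizes and numerics

Tests and the acceptance script run the default 3 × 60 × 20 configuration
(360 genes; ~0.9 Mbp of depth per accession), an 80-accession panel where
≥ 50 true exchanges are expected, exhaustive growth enumeration at 9
accessions, and fit recovery at 30 points per n over n = 1..20 — sizes at
which exact enumeration oracles are feasible and the full suite runs in
well under a minute of compute per stage. Degenerate inputs are handled
explicitly: empty depth files are all-zero tracks; zero-length exon unions
are errors; constant growth curves fit with A ≈ 0 and C at the constant;
identical PAV columns cluster at distance zero with deterministic
tie-breaks; non-convergent fits return `converged=False` rather than
raising.
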