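# panhe

Gene presence/absence variation (PAV), homoeologous-exchange (HE) detection
and pangenome growth modelling for allopolyploid genomes, driven by per-base
read-depth tracks.

Recent allopolyploids such as oilseed rape (*Brassica napus*, subgenomes
A and C) lose and duplicate genes through homoeologous exchanges: meiotic
pairing between near-identical homoeologous chromosomes replaces a segment
of one subgenome with the corresponding segment of the other, deleting the
recipient's genes while doubling the donor's copy number. Across a panel of
resequenced accessions this produces extensive gene PAV, and the union of
all genes — the pangenome — exceeds any single genome. `panhe` is aimed at
researchers analysing such panels: it takes a gene annotation (GFF3),
per-accession depth files (`samtools depth`/`bedtools genomecov -d` TSV or
bedGraph) and a gene-to-gene homology table (BLAST `-outfmt 6`), and
produces PAV matrices, HE calls with direction, core/variable partitions
and fitted pangenome growth curves.

## Methods in brief

* **PAV calling** uses the exon-coverage threshold rule: a gene is absent
  when the fraction of its exon-union bases covered at depth ≥ `minCov`
  (default 2) is below `lostCutoff` (default 0.05). A high-depth preset
  (`minCov = 300`, `lostCutoff = 0.70`) suits deeply sequenced panels.
* **HE detection** tests maximal runs of consecutively absent genes for
  three joint signatures: (i) each run gene's best hit lies on the
  homoeologous partner chromosome with identity > 90% and alignment length
  within ±10 bp of the query's exon length, over a gene that is itself
  present; (ii) the hits are collinear with the run (|Spearman ρ| ≥ 0.8);
  (iii) binned coverage (1000-bp bins) is near zero over the recipient
  interval and > 1.5× baseline over the donor interval. Runs passing all
  three become directed HE calls (donor → recipient).
* **Core/variable partitioning**: a gene is core when present in every
  accession; a gene family is core if at least one member is present in
  all accessions and variable if the whole family is missing from at least
  one. Accessions are clustered on Hamming distances between PAV columns
  (average linkage) with gene-bootstrap node support.
* **Growth modelling**: for each combination size *n* (up to 100 000
  sampled combinations per *n*), pangenome size (genes in ≥ 1 member) and
  core size (genes in all members) are fitted by nonlinear least squares to
  *y* = *Ax*<sup>*B*</sup> + *C* (pangenome) and *y* = *Ae*<sup>*Bx*</sup> + *C*
  (core); with *B* < 0, *C* estimates the asymptotic pangenome or core
  size, reported ± its standard error.

A synthetic allotetraploid generator (`panhe.simulate`) produces references,
accessions with known HE/deletion truth and Poisson depth tracks, so every
stage is testable without sequencing data. See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
from panhe import SimConfig, simulate_dataset
from panhe.pav import call_pav, build_pav_matrix
from panhe.he import detect_hes
from panhe.classify import classify_genes
from panhe.model import growth_curves, fit_growth_models

truth, tracks = simulate_dataset(SimConfig(seed=42))
calls = {a: call_pav(truth.annotation, tracks[a]) for a in truth.accessions}
matrix, _ = build_pav_matrix(calls, tracks)

labels = classify_genes(matrix)
print((labels == "core").sum(), (labels == "variable").sum())
# 212 148            -> 212 core and 148 variable genes of 360, 20 accessions

hes, non_he = detect_hes(calls["syn01"], truth.annotation, tracks["syn01"],
                         truth.homology)
c = hes[0]
print(c.recipient_chrom, c.recipient_interval, "<-", c.donor_chrom,
      c.direction, round(c.donor_cov_ratio, 2))
# A02 (106000, 150000) <- C02 C->A 2.01
#   -> a terminal segment of A02 was replaced by its C02 homoeologue:
#      its genes are absent, the C02 copies doubled (2.01x baseline)

pan, core = fit_growth_models(growth_curves(matrix, cap=1000, seed=0))
print(round(pan.predicted_size, 1), round(core.predicted_size, 1))
# 360.0 145.3        -> asymptotic pangenome and core sizes (genes)
```

The same pipeline is available from the shell:

```
panhe simulate --seed 42 --out sim/
panhe pav --gff sim/annotation.gff3 --depth sim/syn01.depth.tsv ... --out pav.tsv
panhe he  --gff sim/annotation.gff3 --depth sim/syn01.depth.tsv \
          --pav pav.tsv --homology sim/homology.blast.tsv --out he.tsv
panhe classify --matrix pav.tsv --out summary/
panhe model --matrix pav.tsv --cap 100000 --seed 1 --out model.json
```

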