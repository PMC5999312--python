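"""Synthetic allotetraploid data generator.

Builds a small A/C allotetraploid reference in which every gene on an A
chromosome has exactly one homoeologue at the same positional rank on the
paired C chromosome, then simulates accessions carrying:

* homoeologous exchanges (HEs): contiguous runs of genes on one subgenome
  are lost while the rank-aligned homoeologous segment doubles in copy
  number.  HEs anchor preferentially at chromosome termini, are more
  frequent in resynthesised ("synthetic") accessions than in natural ones,
  and run mostly C -> A;
* independent single-gene deletions, never inside an HE segment.

Per-base depth is Poisson with mean ``mean_depth`` in neutral regions,
0 in lost segments and deleted genes, and twice the mean in duplicated
donor segments — the coverage signature the HE detector tests for.
Depth is generated directly rather than via simulated reads: the
downstream rules consume depth vectors and homology tables, so read-level
simulation would add aligner dependencies without changing what is tested.

All randomness derives from ``SimConfig.seed``; identical configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io_formats import (
    Chromosome,
    DepthTrack,
    Gene,
    GenomeAnnotation,
    HomologyHit,
    write_annotation,
    write_depth_tsv,
    write_homology_table,
)

__all__ = ["SimConfig", "TrueHE", "SimTruth", "simulate_reference",
           "simulate_accessions", "simulate_depth", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Rates are per-accession-per-chromosome-pair (``he_rate_*``) or per-gene
    (``single_gene_deletion_rate``); spans are in genes; depths in reads.
    """

    n_chrom_pairs: int = 3
    genes_per_chromosome: int = 60
    gene_length: int = 1500            # bp
    intergenic_gap: int = 1000         # bp
    n_accessions: int = 20
    synthetic_fraction: float = 0.5    # fraction of accessions that are resynthesised
    mean_depth: float = 12.0           # reads, genome-wide sequencing depth
    he_rate_synthetic: float = 0.5
    he_rate_nonsynthetic: float = 0.1
    he_span_genes: tuple[int, int] = (5, 20)   # inclusive uniform range
    he_end_bias: float = 0.9           # P(HE anchors at a chromosome terminus)
    he_direction_c_to_a_prob: float = 0.8
    single_gene_deletion_rate: float = 0.01
    homoeolog_pid: tuple[float, float] = (91.0, 99.0)
    duplicate_donor: bool = True       # False: HE loses genes without doubling the donor
    depth_noise: Literal["poisson", "none"] = "poisson"
    seed: int = 0

    def __post_init__(self):
        for name in ("synthetic_fraction", "he_rate_synthetic", "he_rate_nonsynthetic",
                     "he_end_bias", "he_direction_c_to_a_prob",
                     "single_gene_deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.he_span_genes[0] < 1 or self.he_span_genes[0] > self.he_span_genes[1]:
            raise ValueError(f"invalid he_span_genes {self.he_span_genes}")
        if self.n_chrom_pairs < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome pair and one gene")


@dataclass(frozen=True)
class TrueHE:
    """One simulated homoeologous exchange.

    Rank intervals are half-open over gene ranks; recipient and donor
    intervals are identical because homoeologues are rank-aligned.
    ``direction`` is donor-subgenome -> recipient-subgenome.
    """

    recipient_chrom: str
    donor_chrom: str
    rank_start: int
    rank_stop: int
    direction: str  # "C->A" or "A->C"

    @property
    def n_genes(self) -> int:
        return self.rank_stop - self.rank_start


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    config: SimConfig
    annotation: GenomeAnnotation
    homology: list[HomologyHit]
    accessions: list[str]
    accession_class: dict[str, str]              # "synthetic" | "nonsynthetic"
    he_events: dict[str, list[TrueHE]]
    deletions: dict[str, set[str]]
    pav: pd.DataFrame                            # genes x accessions, bool (True = present)

    def absent_genes(self, accession: str) -> set[str]:
        col = self.pav[accession]
        return set(col.index[~col])


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def simulate_reference(config: SimConfig) -> tuple[GenomeAnnotation, list[HomologyHit]]:
    """Build the allotetraploid reference and its homoeologue homology table.

    Chromosome pair ``i`` is named ``A0i``/``C0i`` (``A10``... beyond 9) and
    paired in ``homoeolog_pairs``.  Gene ``j`` on ``A0i`` has one homoeologue
    at rank ``j`` on ``C0i``; the homology table carries the pair in both
    directions with identity drawn uniformly from ``homoeolog_pid`` and
    alignment length within +/-10 bp of the gene length.
    """
    rng = _rng(config, 0)
    step = config.gene_length + config.intergenic_gap
    chrom_len = config.intergenic_gap + config.genes_per_chromosome * step

    chromosomes: list[Chromosome] = []
    genes: list[Gene] = []
    pairs: dict[str, str] = {}
    for i in range(1, config.n_chrom_pairs + 1):
        a_name, c_name = f"A{i:02d}", f"C{i:02d}"
        pairs[a_name] = c_name
        pairs[c_name] = a_name
        for name, sub in ((a_name, "A"), (c_name, "C")):
            chromosomes.append(Chromosome(name, chrom_len, sub))
            for j in range(config.genes_per_chromosome):
                start = config.intergenic_gap + j * step
                end = start + config.gene_length
                # two abutting exons whose union is the full span
                cut = start + int(rng.integers(200, config.gene_length - 200))
                genes.append(
                    Gene(
                        id=f"{name}g{j:04d}",
                        chrom=name,
                        start=start,
                        end=end,
                        strand="+" if rng.random() < 0.5 else "-",
                        exons=((start, cut), (cut, end)),
                    )
                )
    annotation = GenomeAnnotation(chromosomes, genes, pairs)

    hits: list[HomologyHit] = []
    lo_pid, hi_pid = config.homoeolog_pid
    for i in range(1, config.n_chrom_pairs + 1):
        a_name, c_name = f"A{i:02d}", f"C{i:02d}"
        for j in range(config.genes_per_chromosome):
            a_gene = annotation.gene(f"{a_name}g{j:04d}")
            c_gene = annotation.gene(f"{c_name}g{j:04d}")
            pid = float(rng.uniform(lo_pid, hi_pid))
            delta = int(rng.integers(0, 11)) * (1 if rng.random() < 0.5 else -1)
            aln_len = config.gene_length + delta
            bitscore = round(1.8 * aln_len * pid / 100.0, 1)
            for q, s in ((a_gene, c_gene), (c_gene, a_gene)):
                hits.append(
                    HomologyHit(
                        query_gene=q.id,
                        subject_chrom=s.chrom,
                        subject_start=s.start,
                        subject_end=s.end,
                        pident=round(pid, 2),
                        length=aln_len,
                        bitscore=bitscore,
                        subject_gene=s.id,
                    )
                )
    return annotation, hits


def _draw_he(rng: np.random.Generator, config: SimConfig, pair_index: int) -> TrueHE:
    a_name, c_name = f"A{pair_index:02d}", f"C{pair_index:02d}"
    if rng.random() < config.he_direction_c_to_a_prob:
        donor, recipient, direction = c_name, a_name, "C->A"
    else:
        donor, recipient, direction = a_name, c_name, "A->C"
    k = config.genes_per_chromosome
    span = int(rng.integers(config.he_span_genes[0], config.he_span_genes[1] + 1))
    span = min(span, k)
    if rng.random() < config.he_end_bias or span >= k:
        if rng.random() < 0.5:
            lo, hi = 0, span
        else:
            lo, hi = k - span, k
    else:
        lo = int(rng.integers(1, k - span))  # strictly interior
        hi = lo + span
    return TrueHE(recipient, donor, lo, hi, direction)


def simulate_accessions(
    reference: tuple[GenomeAnnotation, list[HomologyHit]], config: SimConfig
) -> SimTruth:
    """Draw HE events and single-gene deletions for every accession and
    assemble the ground-truth presence/absence matrix."""
    annotation, homology = reference
    rng = _rng(config, 1)
    n_syn = int(round(config.n_accessions * config.synthetic_fraction))
    accessions, acc_class = [], {}
    for i in range(config.n_accessions):
        name = f"syn{i + 1:02d}" if i < n_syn else f"nat{i + 1:02d}"
        accessions.append(name)
        acc_class[name] = "synthetic" if i < n_syn else "nonsynthetic"

    gene_ids = annotation.gene_ids()
    pav = pd.DataFrame(True, index=gene_ids, columns=accessions)
    he_events: dict[str, list[TrueHE]] = {}
    deletions: dict[str, set[str]] = {}

    for acc in accessions:
        rate = (config.he_rate_synthetic if acc_class[acc] == "synthetic"
                else config.he_rate_nonsynthetic)
        events: list[TrueHE] = []
        for i in range(1, config.n_chrom_pairs + 1):
            if rng.random() < rate:
                events.append(_draw_he(rng, config, i))
        he_events[acc] = events

        # genes inside any HE segment (either side) are off-limits for
        # independent deletions: recipient genes are already lost, and
        # deleting one copy of a doubled donor gene has no binary PAV state
        blocked: set[str] = set()
        for ev in events:
            for chrom in (ev.recipient_chrom, ev.donor_chrom):
                for g in annotation.genes_on(chrom)[ev.rank_start:ev.rank_stop]:
                    blocked.add(g.id)
        dels: set[str] = set()
        if config.single_gene_deletion_rate > 0:
            draw = rng.random(len(gene_ids)) < config.single_gene_deletion_rate
            dels = {gid for gid, d in zip(gene_ids, draw) if d and gid not in blocked}
        deletions[acc] = dels

        for ev in events:
            lost = [g.id for g in
                    annotation.genes_on(ev.recipient_chrom)[ev.rank_start:ev.rank_stop]]
            pav.loc[lost, acc] = False
        if dels:
            pav.loc[sorted(dels), acc] = False

    return SimTruth(
        config=config,
        annotation=annotation,
        homology=homology,
        accessions=accessions,
        accession_class=acc_class,
        he_events=he_events,
        deletions=deletions,
        pav=pav,
    )


def _he_segment_bp(
    annotation: GenomeAnnotation, chrom: str, rank_start: int, rank_stop: int
) -> tuple[int, int]:
    """bp interval of an HE segment: gene-span bounded, extended to the
    chromosome terminus when the segment is anchored there."""
    genes = annotation.genes_on(chrom)
    start = genes[rank_start].start
    stop = genes[rank_stop - 1].end
    if rank_start == 0:
        start = 0
    if rank_stop == len(genes):
        stop = annotation.chromosome(chrom).length
    return start, stop


def simulate_depth(truth: SimTruth, accession: str, config: SimConfig | None = None) -> DepthTrack:
    """Per-base depth for one accession.

    The expected-depth profile is ``mean_depth`` everywhere, 0 over HE
    recipient segments and deleted gene spans, and ``2 * mean_depth`` over
    HE donor segments (unless donor doubling is disabled); Poisson noise is
    applied unless ``depth_noise == "none"``, in which case the profile is
    returned as exact integer depths.
    """
    config = config or truth.config
    if accession not in truth.accessions:
        raise KeyError(f"unknown accession {accession!r}")
    annotation = truth.annotation
    lam: dict[str, np.ndarray] = {
        c.name: np.full(c.length, float(config.mean_depth)) for c in annotation.chromosomes
    }
    for ev in truth.he_events[accession]:
        r0, r1 = _he_segment_bp(annotation, ev.recipient_chrom, ev.rank_start, ev.rank_stop)
        lam[ev.recipient_chrom][r0:r1] = 0.0
        if config.duplicate_donor:
            d0, d1 = _he_segment_bp(annotation, ev.donor_chrom, ev.rank_start, ev.rank_stop)
            lam[ev.donor_chrom][d0:d1] = 2.0 * config.mean_depth
    for gid in truth.deletions[accession]:
        g = annotation.gene(gid)
        lam[g.chrom][g.start:g.end] = 0.0

    idx = truth.accessions.index(accession)
    rng = _rng(config, 2, idx)
    depth = {}
    for chrom, lv in lam.items():
        if config.depth_noise == "poisson":
            depth[chrom] = rng.poisson(lv).astype(np.int64)
        else:
            depth[chrom] = np.rint(lv).astype(np.int64)
    return DepthTrack(accession, depth)


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, dict[str, DepthTrack]]:
    """Reference + accessions + depth tracks in one call."""
    truth = simulate_accessions(simulate_reference(config), config)
    tracks = {acc: simulate_depth(truth, acc) for acc in truth.accessions}
    return truth, tracks


def emit_dataset(truth: SimTruth, tracks: dict[str, DepthTrack], outdir: str | Path) -> None:
    """Write the dataset in the pipeline's file formats: GFF3 annotation,
    per-accession depth TSVs, BLAST-tabular homology, and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation(truth.annotation, outdir / "annotation.gff3")
    write_homology_table(truth.homology, outdir / "homology.blast.tsv")
    for acc, track in tracks.items():
        write_depth_tsv(track, outdir / f"{acc}.depth.tsv")
    truth.pav.astype(int).to_csv(outdir / "truth_pav.tsv", sep="\t", index_label="gene")
    rows = [
        (acc, ev.recipient_chrom, ev.donor_chrom, ev.rank_start, ev.rank_stop, ev.direction)
        for acc in truth.accessions
        for ev in truth.he_events[acc]
    ]
    pd.DataFrame(
        rows, columns=["accession", "recipient", "donor", "rank_start", "rank_stop", "direction"]
    ).to_csv(outdir / "truth_he.tsv", sep="\t", index=False)
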