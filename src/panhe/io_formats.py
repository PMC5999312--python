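"""Readers and writers for the standard formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  File formats convert at
the boundary: GFF3 and 3-column depth TSVs are 1-based inclusive, bedGraph
is 0-based half-open, BLAST tabular subject coordinates are 1-based
inclusive and may be reversed (sstart > send on minus-strand hits).

Also home to the contig contaminant-filter rule, which partitions assembled
contigs on the identity and alignment-length of their best nucleotide hit.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Chromosome",
    "Gene",
    "GenomeAnnotation",
    "DepthTrack",
    "HomologyHit",
    "ContigHitRecord",
    "merge_intervals",
    "read_annotation",
    "write_annotation",
    "read_depth",
    "write_depth_tsv",
    "write_bedgraph",
    "read_homology_table",
    "write_homology_table",
    "filter_contaminant_contigs",
    "load_config",
    "dump_config",
]

#: chromosome naming convention for the two subgenomes of an A/C
#: allotetraploid (A01..A10 vs C01..C09 style names)
DEFAULT_SUBGENOME_PATTERNS: dict[str, str] = {"A": r"^A(\d+)$", "C": r"^C(\d+)$"}


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union a set of half-open intervals into sorted, disjoint intervals.

    Abutting intervals (end == next start) are merged, so two exons that
    tile a gene without overlap collapse into one spanning interval.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"invalid interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    subgenome: str = "unplaced"  # one of {"A", "C", "unplaced"}


@dataclass(frozen=True)
class Gene:
    """One annotated gene; ``exons`` are half-open intervals within the span."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exon intervals; the gene span if no exons are annotated."""
        if not self.exons:
            return [(self.start, self.end)]
        return merge_intervals(self.exons)

    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union())

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """Chromosomes (with subgenome labels and homoeologous pairing) plus an
    ordered gene list with per-chromosome positional ranks.

    Genes are kept sorted by (chromosome, start); ``gene_rank`` maps each
    gene id to its 0-based rank along its chromosome, so rank-consecutive
    genes are physical neighbours.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        genes: Sequence[Gene],
        homoeolog_pairs: Mapping[str, str] | None = None,
    ):
        self.chromosomes: list[Chromosome] = list(chromosomes)
        self._chrom_by_name = {c.name: c for c in self.chromosomes}
        if len(self._chrom_by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for g in genes:
            if g.chrom not in self._chrom_by_name:
                raise ValueError(f"gene {g.id!r} on unknown chromosome {g.chrom!r}")
            for s, e in g.exons:
                if s < g.start or e > g.end:
                    raise ValueError(f"gene {g.id!r}: exon ({s},{e}) outside span")
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.start, g.id))
        self._by_id = {g.id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self.gene_rank: dict[str, int] = {}
        for glist in self._by_chrom.values():
            for rank, g in enumerate(glist):
                self.gene_rank[g.id] = rank
        pairs = dict(homoeolog_pairs or {})
        for a, b in list(pairs.items()):
            if pairs.get(b, a) != a:
                raise ValueError(f"homoeolog pairing not symmetric at {a!r}/{b!r}")
            pairs[b] = a
        unknown = set(pairs) - set(self._chrom_by_name)
        if unknown:
            raise ValueError(f"homoeolog pairing names unknown chromosomes: {sorted(unknown)}")
        self.homoeolog_pairs: dict[str, str] = pairs

    # -- lookups -----------------------------------------------------------
    def chromosome(self, name: str) -> Chromosome:
        return self._chrom_by_name[name]

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def partner(self, chrom: str) -> str | None:
        return self.homoeolog_pairs.get(chrom)

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        return [g for g in self.genes_on(chrom) if g.start < end and g.end > start]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _infer_subgenomes(
    names: Iterable[str], patterns: Mapping[str, str]
) -> dict[str, str]:
    labels = {}
    for name in names:
        labels[name] = "unplaced"
        for sub, pat in patterns.items():
            if re.match(pat, name):
                labels[name] = sub
                break
    return labels


def _default_pairing(labels: Mapping[str, str], patterns: Mapping[str, str]) -> dict[str, str]:
    """Pair A and C chromosomes sharing the same number (A01<->C01 etc.)."""
    by_number: dict[str, dict[str, str]] = {}
    for name, sub in labels.items():
        if sub == "unplaced":
            continue
        m = re.match(patterns[sub], name)
        if m and m.groups():
            by_number.setdefault(m.group(1).lstrip("0") or "0", {})[sub] = name
    pairs: dict[str, str] = {}
    for group in by_number.values():
        if "A" in group and "C" in group:
            pairs[group["A"]] = group["C"]
            pairs[group["C"]] = group["A"]
    return pairs


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line ({len(fields)} fields, expected 9)"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid coordinate range {start}-{end}")


def read_annotation(
    path: str | Path,
    subgenome_patterns: Mapping[str, str] | None = None,
    homoeolog_map: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Read gene/exon features from a GFF3 file into a :class:`GenomeAnnotation`.

    Chromosome lengths come from ``##sequence-region`` directives when
    present, otherwise from the furthest feature end.  Chromosomes matching
    the A/C naming convention are labelled by subgenome and paired by number
    unless ``homoeolog_map`` overrides the pairing; all other chromosomes
    are labelled ``unplaced``.  A gene without exon children uses its span
    as a single exon (with a warning).
    """
    path = Path(path)
    patterns = dict(subgenome_patterns or DEFAULT_SUBGENOME_PATTERNS)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])

    genes: list[Gene] = []
    seen_chroms: dict[str, int] = {}
    for feat in db.features_of_type("gene"):
        exons = tuple(
            (child.start - 1, child.end)
            for child in db.children(feat, featuretype="exon")
        )
        if not exons:
            warnings.warn(
                f"gene {feat.id!r} has no exons; using gene span as a single exon"
            )
            exons = ((feat.start - 1, feat.end),)
        genes.append(
            Gene(
                id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or "+",
                exons=exons,
            )
        )
        seen_chroms[feat.seqid] = max(seen_chroms.get(feat.seqid, 0), feat.end)

    names = list(dict.fromkeys(list(lengths) + list(seen_chroms)))
    labels = _infer_subgenomes(names, patterns)
    chromosomes = [
        Chromosome(name, lengths.get(name, seen_chroms.get(name, 0)), labels[name])
        for name in names
    ]
    pairing = dict(homoeolog_map) if homoeolog_map else _default_pairing(labels, patterns)
    return GenomeAnnotation(chromosomes, genes, pairing)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in annotation.chromosomes:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tpanhe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tpanhe\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.exon{i};Parent={g.id}\n"
                )


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Per-base read depth for one accession, one dense vector per chromosome."""

    accession: str
    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def chromosome_mean(self, chrom: str) -> float:
        return float(self.depth[chrom].mean())

    def genome_mean(self) -> float:
        total = sum(int(v.sum()) for v in self.depth.values())
        length = sum(v.size for v in self.depth.values())
        return total / length if length else 0.0


def read_depth(path: str | Path, annotation: GenomeAnnotation, accession: str) -> DepthTrack:
    """Read a per-base depth file into a :class:`DepthTrack`.

    Accepts either a ``samtools depth`` / ``bedtools genomecov -d`` style
    3-column TSV (chromosome, 1-based position, depth) or a 4-column
    bedGraph (chromosome, 0-based start, end, depth).  Positions absent
    from the file have depth 0; vectors match annotated chromosome lengths.
    """
    path = Path(path)
    vectors = {
        c.name: np.zeros(c.length, dtype=np.int64) for c in annotation.chromosomes
    }
    ncols = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            ncols = len(line.split("\t"))
            break
    if ncols is None:
        return DepthTrack(accession, vectors)  # empty file -> all-zero track
    if ncols == 3:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "pos", "depth"],
                         dtype={"chrom": str, "pos": np.int64, "depth": np.int64})
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in vectors:
                raise ValueError(f"{path}: unknown chromosome {chrom!r}")
            pos = sub["pos"].to_numpy()
            if pos.min() < 1 or pos.max() > vectors[chrom].size:
                raise ValueError(
                    f"{path}: position out of range on chromosome {chrom!r} "
                    f"(length {vectors[chrom].size})"
                )
            vectors[chrom][pos - 1] = sub["depth"].to_numpy()
    elif ncols == 4:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "depth"],
                         dtype={"chrom": str, "start": np.int64,
                                "end": np.int64, "depth": np.int64})
        for row in df.itertuples(index=False):
            if row.chrom not in vectors:
                raise ValueError(f"{path}: unknown chromosome {row.chrom!r}")
            if row.start < 0 or row.end > vectors[row.chrom].size or row.end < row.start:
                raise ValueError(
                    f"{path}: interval out of range on chromosome {row.chrom!r} "
                    f"(length {vectors[row.chrom].size})"
                )
            vectors[row.chrom][row.start:row.end] = row.depth
    else:
        raise ValueError(f"{path}: expected 3 (depth TSV) or 4 (bedGraph) columns, got {ncols}")
    return DepthTrack(accession, vectors)


def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    """Write a dense 3-column depth TSV (1-based positions, every base)."""
    with open(path, "w") as fh:
        for chrom in track.depth:
            v = track.depth[chrom]
            block = pd.DataFrame(
                {"chrom": chrom, "pos": np.arange(1, v.size + 1), "depth": v}
            )
            block.to_csv(fh, sep="\t", header=False, index=False)


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Write a run-length-encoded bedGraph (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for chrom, v in track.depth.items():
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]}\n")


# ---------------------------------------------------------------------------
# BLAST tabular homology tables
# ---------------------------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST hit of a query gene against the genome.

    Subject coordinates are chromosomal, 0-based half-open, normalized so
    start <= end regardless of hit orientation.
    """

    query_gene: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    pident: float
    length: int
    bitscore: float
    subject_gene: str | None = None

    def __post_init__(self):
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start > subject_end after normalization")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")


def read_homology_table(
    path: str | Path, annotation: GenomeAnnotation
) -> list[HomologyHit]:
    """Parse a 12-column BLAST tabular file (``-outfmt 6``) into hits.

    ``sseqid`` may be a chromosome name (coordinates taken as chromosomal)
    or a gene id known to the annotation (coordinates taken as offsets into
    that gene's span).  Unresolvable subjects are skipped with a warning.
    Reversed subject coordinates (minus-strand hits) are normalized.
    No identity/length filtering happens here.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#")
    hits: list[HomologyHit] = []
    skipped = 0
    chrom_names = set(annotation.chromosome_names)
    for row in df.itertuples(index=False):
        sseqid = str(row.sseqid)
        lo, hi = sorted((int(row.sstart), int(row.send)))
        if sseqid in chrom_names:
            chrom, start, end = sseqid, lo - 1, hi
        elif sseqid in annotation:
            g = annotation.gene(sseqid)
            chrom, start, end = g.chrom, g.start + lo - 1, g.start + hi
        else:
            skipped += 1
            continue
        hits.append(
            HomologyHit(
                query_gene=str(row.qseqid),
                subject_chrom=chrom,
                subject_start=start,
                subject_end=end,
                pident=float(row.pident),
                length=int(row.length),
                bitscore=float(row.bitscore),
            )
        )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} hit(s) with unresolvable subject ids")
    return hits


def write_homology_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular with chromosomal subject coords."""
    rows = []
    for h in hits:
        mismatch = int(round(h.length * (100.0 - h.pident) / 100.0))
        rows.append(
            (h.query_gene, h.subject_chrom, f"{h.pident:.2f}", h.length, mismatch, 0,
             1, h.length, h.subject_start + 1, h.subject_end, "1e-100",
             f"{h.bitscore:.1f}")
        )
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def best_hits(
    hits: Iterable[HomologyHit],
) -> dict[str, HomologyHit]:
    """Best hit per query gene: highest bitscore, then pident, then
    lowest subject start (deterministic tie-break)."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_gene)
        if cur is None or (
            (h.bitscore, h.pident, -h.subject_start)
            > (cur.bitscore, cur.pident, -cur.subject_start)
        ):
            best[h.query_gene] = h
    return best


# ---------------------------------------------------------------------------
# Contaminant filter
# ---------------------------------------------------------------------------

CONTAMINANT_TAXA = frozenset({"nongreen", "mitochondrial", "chloroplast"})
TAXON_CATEGORIES = frozenset({"green-plant", "nongreen", "mitochondrial", "chloroplast", "none"})


@dataclass(frozen=True)
class ContigHitRecord:
    """Best nucleotide-database hit for one assembled contig."""

    contig_id: str
    contig_length: int
    taxon_category: str = "none"
    pident: float | None = None
    aln_length: int | None = None

    def __post_init__(self):
        if self.contig_length <= 0:
            raise ValueError(f"contig {self.contig_id!r}: non-positive length")
        if self.taxon_category not in TAXON_CATEGORIES:
            raise ValueError(f"unknown taxon category {self.taxon_category!r}")
        if self.aln_length is not None and self.aln_length < 0:
            raise ValueError(f"contig {self.contig_id!r}: negative alignment length")


def filter_contaminant_contigs(
    records: Sequence[ContigHitRecord],
    pid_min: float = 90.0,
    len_frac_min: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Partition contigs into (retained, contaminant) ids.

    A contig is contamination iff its best hit is against a non-green-plant,
    mitochondrial or chloroplast sequence with identity strictly above
    ``pid_min`` and alignment covering at least ``len_frac_min`` of the
    contig.  Everything else (including contigs with no hit) is retained.
    """
    retained, contaminant = [], []
    for r in records:
        is_contaminant = (
            r.taxon_category in CONTAMINANT_TAXA
            and r.pident is not None
            and r.aln_length is not None
            and r.pident > pid_min
            and r.aln_length / r.contig_length >= len_frac_min
        )
        (contaminant if is_contaminant else retained).append(r.contig_id)
    return retained, contaminant


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a nested key-value parameter file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
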