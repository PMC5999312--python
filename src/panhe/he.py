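"""Homoeologous-exchange (HE) detection.

An HE replaces a chromosome segment with its homoeologous counterpart:
the recipient's genes disappear while the donor segment doubles in copy
number.  In depth + homology space that leaves three joint signatures,
each tested here on runs of consecutively absent genes:

1. *homology*: each absent gene's best hit lies on the homoeologous
   partner chromosome with high identity (> ``pid_min``) and an alignment
   length matching the query's exon-union length to within
   ``aln_len_tol`` bp, and the annotated gene under the hit is itself
   called present;
2. *order*: the supported hits are arranged collinearly with the absent
   run (|Spearman rho| >= ``order_rho_min``);
3. *coverage*: mean binned depth over the recipient interval is near zero
   (< ``zero_factor`` x baseline) while the donor interval is amplified
   (> ``dup_factor`` x baseline).

Runs passing all three become :class:`HECall`\\ s with a donor->recipient
direction; every other absent gene is reported as non-HE PAV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DepthTrack, GenomeAnnotation, HomologyHit, best_hits

logger = logging.getLogger(__name__)

__all__ = ["HEParams", "HECall", "absent_runs", "binned_coverage", "detect_hes",
           "write_he_calls", "write_interval_bed"]


@dataclass(frozen=True)
class HEParams:
    """Thresholds of the three HE evidence tests."""

    pid_min: float = 90.0        # percent identity a homoeologue hit must exceed
    aln_len_tol: int = 10        # bp tolerance between hit and query exon lengths
    min_run_genes: int = 3       # shortest absent run considered an HE candidate
    bin_size: int = 1000         # bp, coverage averaging bins
    dup_factor: float = 1.5      # donor interval must exceed this x baseline
    zero_factor: float = 0.1     # recipient interval must fall below this x baseline
    order_rho_min: float = 0.8   # |Spearman rho| for hit collinearity
    support_frac: float = 0.8    # fraction of run genes that must pass homology
    baseline: Literal["chromosome-mean", "genome-mean"] = "chromosome-mean"

    def __post_init__(self):
        if not 0.0 < self.pid_min <= 100.0:
            raise ValueError("pid_min must be in (0, 100]")
        if self.dup_factor <= 1.0:
            raise ValueError("dup_factor must exceed 1")
        if self.zero_factor >= 1.0:
            raise ValueError("zero_factor must be below 1")
        if self.min_run_genes < 1:
            raise ValueError("min_run_genes must be >= 1")


@dataclass
class HECall:
    """One detected homoeologous exchange with its supporting evidence.

    Intervals are bp, 0-based half-open.  ``direction`` reads
    donor-subgenome -> recipient-subgenome (e.g. ``"C->A"``).
    """

    accession: str
    recipient_chrom: str
    recipient_interval: tuple[int, int]
    recipient_genes: list[str]
    donor_chrom: str
    donor_interval: tuple[int, int]
    direction: str
    n_supported: int = 0
    support_fraction: float = 0.0
    order_rho: float = 0.0
    recipient_cov_ratio: float = 0.0
    donor_cov_ratio: float = 0.0

    @property
    def rank_interval(self) -> tuple[int, int]:
        # filled in post-detection by detect_hes
        return self._rank_interval

    _rank_interval: tuple[int, int] = field(default=(0, 0), repr=False)


def absent_runs(
    calls: pd.DataFrame, annotation: GenomeAnnotation, min_run_genes: int = 3
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Maximal runs of rank-consecutive absent genes per chromosome.

    ``calls`` is the per-gene table from :func:`panhe.pav.call_pav` and must
    cover every annotated gene.  Returns ``(runs, short_runs)`` as
    ``(chromosome, rank_start, rank_stop)`` half-open rank intervals, where
    runs shorter than ``min_run_genes`` land in ``short_runs``.
    """
    missing = [g.id for g in annotation.genes if g.id not in calls.index]
    if missing:
        raise ValueError(f"calls missing {len(missing)} annotated genes (e.g. {missing[:3]})")
    runs: list[tuple[str, int, int]] = []
    short: list[tuple[str, int, int]] = []
    for chrom in annotation.chromosome_names:
        genes = annotation.genes_on(chrom)
        if not genes:
            continue
        absent = ~calls.loc[[g.id for g in genes], "present"].to_numpy(dtype=bool)
        rank = 0
        while rank < len(genes):
            if absent[rank]:
                start = rank
                while rank < len(genes) and absent[rank]:
                    rank += 1
                (runs if rank - start >= min_run_genes else short).append(
                    (chrom, start, rank)
                )
            else:
                rank += 1
    return runs, short


def binned_coverage(
    track: DepthTrack, chrom: str, interval: tuple[int, int], bin_size: int = 1000
) -> tuple[list[float], float]:
    """Mean depth per ``bin_size`` bp bin tiled from the interval start,
    plus the length-weighted interval mean (== the per-base mean)."""
    start, stop = interval
    depth = track.depth[chrom]
    if not 0 <= start < stop <= depth.size:
        raise ValueError(f"empty or out-of-range interval ({start}, {stop}) on {chrom}")
    bins: list[float] = []
    for s in range(start, stop, bin_size):
        e = min(s + bin_size, stop)
        bins.append(float(depth[s:e].mean()))
    return bins, float(depth[start:stop].mean())


def _baseline(track: DepthTrack, chrom: str, exclude: tuple[int, int], params: HEParams) -> float:
    """Background depth the coverage tests compare against.

    Chromosome mode masks out the interval under test: a large zeroed or
    doubled segment would otherwise drag its own baseline toward itself.
    Genome mode uses the genome-wide mean (conserved under HEs, which only
    move coverage between homoeologues).
    """
    if params.baseline == "genome-mean":
        return track.genome_mean()
    v = track.depth[chrom]
    s, e = max(exclude[0], 0), min(exclude[1], v.size)
    total = float(v.sum()) - float(v[s:e].sum())
    n = v.size - (e - s)
    return total / n if n > 0 else float(v.mean())


def _order_rho(query_ranks: Sequence[int], subject_mids: Sequence[float]) -> float:
    if len(query_ranks) <= 2:
        return 1.0  # 1-2 points are trivially collinear
    rho = stats.spearmanr(query_ranks, subject_mids).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def detect_hes(
    calls: pd.DataFrame,
    annotation: GenomeAnnotation,
    track: DepthTrack,
    homology: Sequence[HomologyHit],
    params: HEParams = HEParams(),
) -> tuple[list[HECall], list[str]]:
    """Classify absent-gene runs of one accession as HEs or non-HE PAV.

    Returns detected :class:`HECall` s and the ids of all absent genes not
    explained by any call; together these partition the accession's absent
    genes.
    """
    runs, short = absent_runs(calls, annotation, params.min_run_genes)
    best = best_hits(homology)
    present = calls["present"]
    he_calls: list[HECall] = []
    non_he: set[str] = set()
    for chrom, r0, r1 in short:
        non_he.update(g.id for g in annotation.genes_on(chrom)[r0:r1])

    for chrom, r0, r1 in runs:
        run_genes = annotation.genes_on(chrom)[r0:r1]
        partner = annotation.partner(chrom)
        if partner is None:
            warnings.warn(f"chromosome {chrom!r} has no homoeologous partner; run skipped")
            non_he.update(g.id for g in run_genes)
            continue

        supported, ranks, mids = [], [], []
        for rank, gene in zip(range(r0, r1), run_genes):
            hit = best.get(gene.id)
            if hit is None or hit.subject_chrom != partner:
                continue
            if hit.pident <= params.pid_min:
                continue
            if abs(hit.length - gene.exon_union_length()) > params.aln_len_tol:
                continue
            targets = annotation.genes_overlapping(
                partner, hit.subject_start, hit.subject_end
            )
            if not targets:
                continue
            target = max(
                targets,
                key=lambda g: min(g.end, hit.subject_end) - max(g.start, hit.subject_start),
            )
            if not bool(present.get(target.id, False)):
                continue
            supported.append((gene, hit))
            ranks.append(rank)
            mids.append((hit.subject_start + hit.subject_end) / 2.0)

        support_fraction = len(supported) / len(run_genes)
        rho = _order_rho(ranks, mids) if supported else 0.0
        rec_interval = (run_genes[0].start, run_genes[-1].end)
        rec_base = _baseline(track, chrom, rec_interval, params)
        _, rec_mean = binned_coverage(track, chrom, rec_interval, params.bin_size)
        rec_ratio = rec_mean / rec_base if rec_base > 0 else np.inf

        ok = support_fraction >= params.support_frac and abs(rho) >= params.order_rho_min
        donor_interval = (0, 0)
        donor_ratio = 0.0
        if ok:
            chrom_len = annotation.chromosome(partner).length
            donor_interval = (
                max(0, min(h.subject_start for _, h in supported)),
                min(chrom_len, max(h.subject_end for _, h in supported)),
            )
            donor_base = _baseline(track, partner, donor_interval, params)
            _, donor_mean = binned_coverage(track, partner, donor_interval, params.bin_size)
            donor_ratio = donor_mean / donor_base if donor_base > 0 else np.inf
            ok = rec_ratio < params.zero_factor and donor_ratio > params.dup_factor

        if ok:
            call = HECall(
                accession=track.accession,
                recipient_chrom=chrom,
                recipient_interval=rec_interval,
                recipient_genes=[g.id for g in run_genes],
                donor_chrom=partner,
                donor_interval=donor_interval,
                direction=(
                    f"{annotation.chromosome(partner).subgenome}->"
                    f"{annotation.chromosome(chrom).subgenome}"
                ),
                n_supported=len(supported),
                support_fraction=support_fraction,
                order_rho=rho,
                recipient_cov_ratio=rec_ratio,
                donor_cov_ratio=donor_ratio,
            )
            call._rank_interval = (r0, r1)
            he_calls.append(call)
        else:
            non_he.update(g.id for g in run_genes)

    return he_calls, sorted(non_he)


def write_he_calls(calls: Sequence[HECall], path: str | Path) -> None:
    rows = [
        dict(
            accession=c.accession,
            recipient_chrom=c.recipient_chrom,
            recipient_start=c.recipient_interval[0],
            recipient_end=c.recipient_interval[1],
            donor_chrom=c.donor_chrom,
            donor_start=c.donor_interval[0],
            donor_end=c.donor_interval[1],
            direction=c.direction,
            n_genes=len(c.recipient_genes),
            n_supported=c.n_supported,
            support_fraction=round(c.support_fraction, 4),
            order_rho=round(c.order_rho, 4),
            recipient_cov_ratio=round(c.recipient_cov_ratio, 4),
            donor_cov_ratio=round(c.donor_cov_ratio, 4),
            genes=",".join(c.recipient_genes),
        )
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_interval_bed(calls: Sequence[HECall], path: str | Path, side: str = "recipient") -> None:
    """BED (0-based half-open) of recipient or donor intervals."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            chrom, (s, e) = (
                (c.recipient_chrom, c.recipient_interval)
                if side == "recipient"
                else (c.donor_chrom, c.donor_interval)
            )
            fh.write(f"{chrom}\t{s}\t{e}\t{c.accession}.HE{i + 1}.{side}\t0\t.\n")
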