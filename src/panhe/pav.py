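"""Depth-threshold gene presence/absence (PAV) calling.

Implements the SGSGeneLoss rule: a gene is called absent when the fraction
of its exon-union bases covered at depth >= ``min_cov`` falls below
``lost_cutoff`` (strictly below — a gene exactly at the cutoff is present).
The default thresholds (min_cov=2, lost_cutoff=0.05) suit ~12x short-read
data; a high-depth preset (min_cov=300, lost_cutoff=0.70) is appropriate
for deeply sequenced diversity panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io_formats import DepthTrack, Gene, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = ["PAVParams", "PAVMatrix", "gene_covered_fraction", "call_pav",
           "build_pav_matrix"]

#: thresholds used for high-coverage diversity panels
DIVERSITY_PRESET = dict(min_cov=300, lost_cutoff=0.70)


@dataclass(frozen=True)
class PAVParams:
    """Thresholds for the presence/absence rule."""

    min_cov: int = 2            # depth at which a base counts as covered
    lost_cutoff: float = 0.05   # gene absent iff covered fraction < this
    region: Literal["exon-union", "gene-span"] = "exon-union"

    def __post_init__(self):
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0.0 < self.lost_cutoff <= 1.0:
            raise ValueError("lost_cutoff must be in (0, 1]")


def _regions(gene: Gene, region: str) -> list[tuple[int, int]]:
    return gene.exon_union() if region == "exon-union" else [(gene.start, gene.end)]


def gene_covered_fraction(
    gene: Gene, track: DepthTrack, min_cov: int = 2,
    region: str = "exon-union",
) -> float:
    """Fraction of the gene's exon-union bases with depth >= ``min_cov``."""
    depth = track.depth[gene.chrom]
    covered = 0
    total = 0
    for s, e in _regions(gene, region):
        total += e - s
        covered += int(np.count_nonzero(depth[s:e] >= min_cov))
    if total == 0:
        raise ValueError(f"gene {gene.id!r}: zero-length exon union")
    return covered / total


def call_pav(
    annotation: GenomeAnnotation,
    track: DepthTrack,
    params: PAVParams = PAVParams(),
) -> pd.DataFrame:
    """Presence/absence calls for every annotated gene against one depth track.

    Returns a DataFrame indexed by gene id with columns ``present`` (bool)
    and ``covered_fraction``; absent iff covered_fraction < lost_cutoff.
    """
    gene_ids, fractions = [], []
    for gene in annotation.genes:
        gene_ids.append(gene.id)
        fractions.append(
            gene_covered_fraction(gene, track, params.min_cov, params.region)
        )
    frac = np.asarray(fractions)
    return pd.DataFrame(
        {"present": frac >= params.lost_cutoff, "covered_fraction": frac},
        index=pd.Index(gene_ids, name="gene"),
    )


class PAVMatrix:
    """Binary genes x accessions presence/absence matrix.

    ``data`` holds 1 (present) / 0 (absent) as int8; ``fractions`` keeps the
    underlying covered fractions for diagnostics when available.
    """

    def __init__(self, data: pd.DataFrame, fractions: pd.DataFrame | None = None):
        if data.isna().any().any():
            raise ValueError("PAV matrix must be complete")
        if not data.index.is_unique or not data.columns.is_unique:
            raise ValueError("gene and accession ids must be unique")
        self.data = data.astype(np.int8)
        self.data.index.name = "gene"
        self.fractions = fractions

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=bool)

    def __eq__(self, other) -> bool:
        return isinstance(other, PAVMatrix) and self.data.equals(other.data)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: header of accession ids, first column gene id,
        cells '1' (present) / '0' (absent)."""
        self.data.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PAVMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        bad = set(np.unique(df.to_numpy())) - {0, 1}
        if bad:
            raise ValueError(f"{path}: non-binary cells {sorted(bad)}")
        return cls(df)

    @classmethod
    def from_truth(cls, truth_pav: pd.DataFrame) -> "PAVMatrix":
        return cls(truth_pav.astype(np.int8))


def build_pav_matrix(
    calls: Mapping[str, pd.DataFrame],
    tracks: Mapping[str, DepthTrack] | None = None,
    min_mean_depth: float = 5.0,
) -> tuple[PAVMatrix, dict[str, float]]:
    """Assemble per-accession call tables into a :class:`PAVMatrix`.

    Accessions whose genome-wide mean depth (from ``tracks``) is below
    ``min_mean_depth`` are excluded before assembly — low-coverage samples
    produce spurious absence calls.  Returns the matrix over retained
    accessions and a map of excluded accession -> mean depth.
    """
    if not calls:
        raise ValueError("no call tables supplied")
    universes = {acc: frozenset(df.index) for acc, df in calls.items()}
    reference = next(iter(universes.values()))
    for acc, uni in universes.items():
        if uni != reference:
            diff = sorted(uni ^ reference)
            raise ValueError(
                f"accession {acc!r} has a different gene universe; "
                f"symmetric difference (first 10): {diff[:10]}"
            )
    excluded: dict[str, float] = {}
    retained = []
    for acc in calls:
        if tracks is not None and acc in tracks:
            mean = tracks[acc].genome_mean()
            if mean < min_mean_depth:
                excluded[acc] = mean
                logger.info("excluding %s: mean depth %.2f < %.2f", acc, mean, min_mean_depth)
                continue
        retained.append(acc)
    if not retained:
        raise ValueError("all accessions excluded by the depth filter")
    presence = pd.DataFrame(
        {acc: calls[acc]["present"].astype(np.int8) for acc in retained}
    )
    fractions = pd.DataFrame({acc: calls[acc]["covered_fraction"] for acc in retained})
    return PAVMatrix(presence, fractions), excluded
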