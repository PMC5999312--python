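"""Core/variable partitioning and PAV-based accession clustering.

A gene is *core* when present in every retained accession and *variable*
otherwise.  At the family level the rule works on whole clusters: a family
is core if at least one member is present in all accessions, and variable
if some accession has lost every member.  The two clauses are neither
exhaustive nor exclusive; here the core clause wins when both hold, and
families in the uncovered middle (no always-present member, never wholly
missing) default to core, so "variable" always certifies a demonstrable
whole-family loss.  Raw clause outcomes are reported alongside the labels.

Accession relatedness is summarised by average-linkage hierarchical
clustering of Hamming distances between PAV columns, with node support
from gene-bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .pav import PAVMatrix

__all__ = ["FamilyAssignment", "classify_genes", "classify_families",
           "unique_presence_absence", "pav_dendrogram", "BootstrapTree"]


class FamilyAssignment:
    """Gene -> family map (e.g. from orthology clustering).

    Genes without an assignment form singleton families named
    ``singleton:<gene-id>``.
    """

    def __init__(self, gene_to_family: Mapping[str, str]):
        self.gene_to_family = dict(gene_to_family)
        self.families: dict[str, list[str]] = {}
        for gene, fam in self.gene_to_family.items():
            self.families.setdefault(fam, []).append(gene)

    @classmethod
    def from_tsv(cls, path) -> "FamilyAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "family"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["gene"], df["family"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.gene_to_family.items()), columns=["gene", "family"]
        ).to_csv(path, sep="\t", header=False, index=False)

    def completed(self, genes: Sequence[str]) -> "FamilyAssignment":
        """Assignment covering ``genes``, adding singletons for the unassigned."""
        mapping = dict(self.gene_to_family)
        for g in genes:
            mapping.setdefault(g, f"singleton:{g}")
        return FamilyAssignment(mapping)


def classify_genes(matrix: PAVMatrix) -> pd.Series:
    """Label every gene ``core`` (present in all accessions) or ``variable``."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty PAV matrix")
    core = matrix.values().all(axis=1)
    return pd.Series(
        np.where(core, "core", "variable"), index=matrix.data.index, name="label"
    )


def classify_families(matrix: PAVMatrix, families: FamilyAssignment) -> pd.DataFrame:
    """Core/variable labels per family.

    Returns a DataFrame indexed by family id with boolean columns
    ``has_core_member`` (clause 1) and ``wholly_missing_somewhere``
    (clause 2) plus the final ``label``; core wins when both clauses hold.
    """
    missing = [g for g in matrix.genes if g not in families.gene_to_family]
    if missing:
        raise ValueError(
            f"{len(missing)} matrix genes without a family (e.g. {missing[:3]}); "
            "use FamilyAssignment.completed() to add singletons"
        )
    unknown = [g for g in families.gene_to_family if g not in matrix.data.index]
    if unknown:
        raise ValueError(f"{len(unknown)} family genes absent from the matrix "
                         f"(e.g. {unknown[:3]})")
    vals = matrix.values()
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    rows = []
    for fam, members in sorted(families.families.items()):
        block = vals[[gene_index[g] for g in members], :]
        has_core = bool(block.all(axis=1).any())
        wholly_missing = bool((~block).all(axis=0).any())
        label = "core" if has_core or not wholly_missing else "variable"
        rows.append((fam, has_core, wholly_missing, label))
    return pd.DataFrame(
        rows, columns=["family", "has_core_member", "wholly_missing_somewhere", "label"]
    ).set_index("family")


def unique_presence_absence(matrix: PAVMatrix) -> pd.DataFrame:
    """Per accession: genes present only there, and genes absent only there."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 accessions")
    vals = matrix.values()
    presence_count = vals.sum(axis=1)
    uniquely_present = vals & (presence_count == 1)[:, None]
    uniquely_absent = (~vals) & (presence_count == vals.shape[1] - 1)[:, None]
    return pd.DataFrame(
        {
            "uniquely_present": uniquely_present.sum(axis=0),
            "uniquely_absent": uniquely_absent.sum(axis=0),
        },
        index=pd.Index(matrix.accessions, name="accession"),
    )


# ---------------------------------------------------------------------------
# Bootstrap dendrogram
# ---------------------------------------------------------------------------

@dataclass
class BootstrapTree:
    """Average-linkage tree over accessions with bootstrap node supports."""

    labels: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset, float]   # leaf-set of each internal node -> support
    n_boot: int

    def newick(self) -> str:
        """Newick string with bootstrap supports as internal node labels."""
        n = len(self.labels)
        Z = self.linkage_matrix

        def render(node: int) -> tuple[str, frozenset]:
            if node < n:
                return self.labels[node], frozenset([self.labels[node]])
            i = node - n
            left, lset = render(int(Z[i, 0]))
            right, rset = render(int(Z[i, 1]))
            clade = lset | rset
            support = self.supports.get(clade, 1.0)
            dist = Z[i, 2] / 2.0
            return f"({left},{right}){support:.3f}:{dist:.6g}", clade

        body, _ = render(2 * n - 2)
        return body + ";"


def _clades(Z: np.ndarray, labels: Sequence[str]) -> list[frozenset]:
    """Leaf-set of every internal node of a linkage matrix."""
    n = len(labels)
    sets: list[frozenset] = [frozenset([lab]) for lab in labels]
    out = []
    for i in range(Z.shape[0]):
        clade = sets[int(Z[i, 0])] | sets[int(Z[i, 1])]
        sets.append(clade)
        out.append(clade)
    return out


def pav_dendrogram(
    matrix: PAVMatrix, n_boot: int = 1000, seed: int = 0, method: str = "average",
    metric: str = "hamming",
) -> BootstrapTree:
    """Cluster accessions by PAV profile with gene-bootstrap node support.

    Distances are pairwise Hamming distances between the binary accession
    columns; node support is the fraction of ``n_boot`` gene-resampled
    (rows, with replacement) trees containing the same accession
    bipartition.  Columns are ordered by accession id first so that
    zero-distance ties resolve deterministically.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 accessions for a dendrogram")
    order = np.argsort(matrix.accessions)
    labels = [matrix.accessions[i] for i in order]
    vals = matrix.values()[:, order]

    def tree_of(v: np.ndarray) -> np.ndarray:
        dist = pdist(v.T, metric=metric)
        return linkage(dist, method=method)

    Z = tree_of(vals)
    observed = _clades(Z, labels)
    counts = {clade: 0 for clade in observed}
    rng = np.random.default_rng(seed)
    n_genes = vals.shape[0]
    for _ in range(n_boot):
        rows = rng.integers(0, n_genes, size=n_genes)
        boot_clades = set(_clades(tree_of(vals[rows, :]), labels))
        for clade in counts:
            if clade in boot_clades:
                counts[clade] += 1
    supports = {clade: c / n_boot for clade, c in counts.items()}
    return BootstrapTree(labels, Z, supports, n_boot)
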