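import numpy as np
import pandas as pd
import pytest

from panhe.classify import (
    FamilyAssignment,
    classify_families,
    classify_genes,
    pav_dendrogram,
    unique_presence_absence,
)
from panhe.pav import PAVMatrix
from panhe.simulate import SimConfig, simulate_dataset


def _matrix(arr, genes=None, accessions=None):
    arr = np.asarray(arr, dtype=np.int8)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    accessions = accessions or [f"a{j}" for j in range(arr.shape[1])]
    return PAVMatrix(pd.DataFrame(arr, index=genes, columns=accessions))


class TestGeneLabels:
    def test_present_everywhere_is_core_one_absence_is_variable(self):
        m = _matrix([[1, 1, 1], [1, 0, 1]])
        labels = classify_genes(m)
        assert labels["g0"] == "core" and labels["g1"] == "variable"

    def test_counts_match_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(0)
        arr = (rng.random((100, 10)) > 0.2).astype(int)
        labels = classify_genes(_matrix(arr))
        expected = sum(1 for row in arr if all(row))
        assert (labels == "core").sum() == expected
        assert (labels == "variable").sum() == 100 - expected

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(1)
        arr = (rng.random((50, 6)) > 0.3).astype(int)
        m = _matrix(arr)
        labels = classify_genes(m)
        perm_rows = rng.permutation(50)
        perm_cols = rng.permutation(6)
        m2 = PAVMatrix(m.data.iloc[perm_rows, perm_cols])
        labels2 = classify_genes(m2)
        assert labels2.sort_index().equals(labels.sort_index())


class TestFamilyLabels:
    def test_family_with_core_member_is_core(self):
        m = _matrix([[1, 1, 1], [1, 0, 1]])
        fams = FamilyAssignment({"g0": "F1", "g1": "F1"})
        out = classify_families(m, fams)
        assert out.loc["F1", "label"] == "core"
        assert out.loc["F1", "has_core_member"]

    def test_family_wholly_missing_somewhere_is_variable(self):
        m = _matrix([[1, 0, 1], [1, 0, 1]])
        fams = FamilyAssignment({"g0": "F1", "g1": "F1"})
        out = classify_families(m, fams)
        assert out.loc["F1", "label"] == "variable"
        assert out.loc["F1", "wholly_missing_somewhere"]

    def test_middle_case_defaults_to_core(self):
        # no member present everywhere, but never wholly lost either
        m = _matrix([[1, 0, 1], [0, 1, 1]])
        fams = FamilyAssignment({"g0": "F1", "g1": "F1"})
        out = classify_families(m, fams)
        assert not out.loc["F1", "has_core_member"]
        assert not out.loc["F1", "wholly_missing_somewhere"]
        assert out.loc["F1", "label"] == "core"

    def test_core_member_family_never_variable(self):
        # g1 always absent, but g0 is core so the family can never be wholly lost
        m = _matrix([[1, 1, 1], [0, 0, 0]])
        fams = FamilyAssignment({"g0": "F1", "g1": "F1"})
        assert classify_families(m, fams).loc["F1", "label"] == "core"

    def test_unassigned_matrix_gene_errors(self):
        m = _matrix([[1, 1]])
        with pytest.raises(ValueError, match="without a family"):
            classify_families(m, FamilyAssignment({}))

    def test_singleton_completion_and_tsv_roundtrip(self, tmp_path):
        m = _matrix([[1, 1], [1, 0]])
        fams = FamilyAssignment({"g0": "F1"}).completed(m.genes)
        assert fams.gene_to_family["g1"] == "singleton:g1"
        path = tmp_path / "fam.tsv"
        fams.to_tsv(path)
        assert FamilyAssignment.from_tsv(path).gene_to_family == fams.gene_to_family

    def test_he_families_on_simulated_truth(self):
        # homoeologue pairs form 2-gene families: a family is core unless
        # both copies are lost simultaneously in some accession
        config = SimConfig(seed=31, n_accessions=10)
        truth, _ = simulate_dataset(config)
        m = PAVMatrix.from_truth(truth.pav)
        pairs = {}
        for g in truth.annotation.genes:
            rank = truth.annotation.gene_rank[g.id]
            num = g.chrom[1:]
            pairs[g.id] = f"F{num}_{rank:04d}"
        out = classify_families(m, FamilyAssignment(pairs))
        vals = m.values()
        gene_index = {g: i for i, g in enumerate(m.genes)}
        for fam, members in FamilyAssignment(pairs).families.items():
            both_lost = (~vals[[gene_index[g] for g in members]]).all(axis=0).any()
            has_core = vals[[gene_index[g] for g in members]].all(axis=1).any()
            expected = "core" if has_core or not both_lost else "variable"
            assert out.loc[fam, "label"] == expected


class TestUniqueCounts:
    def test_all_present_gives_zero_counts(self):
        m = _matrix(np.ones((5, 4)))
        out = unique_presence_absence(m)
        assert (out == 0).all().all()

    def test_single_private_gene(self):
        m = _matrix([[1, 0, 0], [1, 1, 1]])
        out = unique_presence_absence(m)
        assert out.loc["a0", "uniquely_present"] == 1
        assert out["uniquely_present"].sum() == 1

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(2)
        arr = (rng.random((200, 8)) > 0.3).astype(int)
        out = unique_presence_absence(_matrix(arr))
        for j in range(8):
            up = sum(
                1 for i in range(200)
                if arr[i, j] == 1 and all(arr[i, k] == 0 for k in range(8) if k != j)
            )
            ua = sum(
                1 for i in range(200)
                if arr[i, j] == 0 and all(arr[i, k] == 1 for k in range(8) if k != j)
            )
            assert out.iloc[j]["uniquely_present"] == up
            assert out.iloc[j]["uniquely_absent"] == ua

    def test_requires_two_accessions(self):
        with pytest.raises(ValueError):
            unique_presence_absence(_matrix([[1]]))


class TestDendrogram:
    def test_identical_pair_merges_first(self):
        arr = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1], [1, 1, 0]])
        tree = pav_dendrogram(_matrix(arr), n_boot=10, seed=0)
        first_merge = {tree.labels[int(tree.linkage_matrix[0, i])] for i in (0, 1)}
        assert first_merge == {"a0", "a1"}
        assert tree.linkage_matrix[0, 2] == 0.0

    def test_supports_are_proportions(self, noisy_data):
        *_, matrix = noisy_data
        tree = pav_dendrogram(matrix, n_boot=50, seed=1)
        assert tree.supports
        assert all(0.0 <= s <= 1.0 for s in tree.supports.values())

    def test_class_split_support_with_strong_signal(self):
        config = SimConfig(seed=30, n_accessions=12, he_rate_synthetic=1.0,
                           he_rate_nonsynthetic=0.0, single_gene_deletion_rate=0.0,
                           he_end_bias=1.0, depth_noise="none")
        truth, _ = simulate_dataset(config)
        tree = pav_dendrogram(PAVMatrix.from_truth(truth.pav), n_boot=200, seed=0)
        nat = frozenset(a for a in truth.accessions
                        if truth.accession_class[a] == "nonsynthetic")
        assert tree.supports.get(nat, 0.0) >= 0.9

    def test_column_permutation_gives_same_tree(self, noisy_data):
        *_, matrix = noisy_data
        rng = np.random.default_rng(3)
        perm = rng.permutation(matrix.shape[1])
        shuffled = PAVMatrix(matrix.data.iloc[:, perm])
        t1 = pav_dendrogram(matrix, n_boot=20, seed=0)
        t2 = pav_dendrogram(shuffled, n_boot=20, seed=0)
        assert t1.newick() == t2.newick()

    def test_newick_parses_with_supports(self):
        arr = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 0, 0], [0, 0, 1, 1]])
        tree = pav_dendrogram(_matrix(arr), n_boot=20, seed=0)
        nwk = tree.newick()
        assert nwk.endswith(";") and nwk.count("(") == 3

    def test_needs_three_accessions(self):
        with pytest.raises(ValueError):
            pav_dendrogram(_matrix([[1, 0], [0, 1]]), n_boot=5)
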