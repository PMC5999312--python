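import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panhe.he import HEParams, absent_runs, binned_coverage, detect_hes
from panhe.io_formats import Chromosome, DepthTrack, Gene, GenomeAnnotation
from panhe.evaluate import score_he_detection
from panhe.simulate import SimConfig, simulate_accessions, simulate_depth, simulate_reference
from panhe.pav import call_pav


def _calls_frame(annotation, absent_ids):
    return pd.DataFrame(
        {"present": [g.id not in absent_ids for g in annotation.genes]},
        index=pd.Index([g.id for g in annotation.genes], name="gene"),
    )


@pytest.fixture(scope="module")
def chrom60():
    genes = [Gene(f"g{i:02d}", "A01", i * 100, i * 100 + 80, "+", ((i * 100, i * 100 + 80),))
             for i in range(60)]
    return GenomeAnnotation([Chromosome("A01", 6000, "A")], genes)


class TestAbsentRuns:
    def test_no_absent_genes(self, chrom60):
        runs, short = absent_runs(_calls_frame(chrom60, set()), chrom60)
        assert runs == [] and short == []

    def test_run_and_singleton_split(self, chrom60):
        absent = {"g03", "g04", "g05", "g09"}
        runs, short = absent_runs(_calls_frame(chrom60, absent), chrom60, min_run_genes=3)
        assert runs == [("A01", 3, 6)]
        assert short == [("A01", 9, 10)]

    def test_whole_chromosome_is_one_run(self, chrom60):
        absent = {g.id for g in chrom60.genes}
        runs, short = absent_runs(_calls_frame(chrom60, absent), chrom60)
        assert runs == [("A01", 0, 60)] and short == []

    def test_missing_calls_rejected(self, chrom60):
        calls = _calls_frame(chrom60, set()).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            absent_runs(calls, chrom60)

    @given(st.sets(st.integers(0, 59), max_size=30), st.integers(1, 5))
    @settings(deadline=None, max_examples=60)
    def test_matches_bruteforce_run_scan(self, chrom60, absent_ranks, min_run):
        absent = {f"g{i:02d}" for i in absent_ranks}
        runs, short = absent_runs(_calls_frame(chrom60, absent), chrom60, min_run)
        # brute force: scan every maximal run of consecutive absent ranks
        expected = []
        i = 0
        while i < 60:
            if i in absent_ranks:
                j = i
                while j < 60 and j in absent_ranks:
                    j += 1
                expected.append(("A01", i, j))
                i = j
            else:
                i += 1
        assert sorted(runs + short) == sorted(expected)
        assert all(r1 - r0 >= min_run for _, r0, r1 in runs)
        assert all(r1 - r0 < min_run for _, r0, r1 in short)


class TestBinnedCoverage:
    def test_constant_depth_tiling(self):
        track = DepthTrack("a", {"A01": np.full(5000, 12, dtype=np.int64)})
        bins, mean = binned_coverage(track, "A01", (0, 3500), 1000)
        assert bins == [12.0, 12.0, 12.0, 12.0]  # last bin is a 500-bp partial
        assert mean == 12.0

    def test_zero_interval(self):
        track = DepthTrack("a", {"A01": np.zeros(2000, dtype=np.int64)})
        bins, mean = binned_coverage(track, "A01", (100, 900))
        assert bins == [0.0] and mean == 0.0

    def test_interval_mean_equals_per_base_mean(self):
        rng = np.random.default_rng(5)
        v = rng.integers(0, 40, size=10_000)
        track = DepthTrack("a", {"A01": v})
        _, mean = binned_coverage(track, "A01", (123, 8765), 1000)
        assert mean == pytest.approx(v[123:8765].mean(), abs=1e-9)

    def test_empty_interval_errors(self):
        track = DepthTrack("a", {"A01": np.zeros(100, dtype=np.int64)})
        with pytest.raises(ValueError):
            binned_coverage(track, "A01", (50, 50))


def _detect_all(truth, tracks, calls, params=HEParams()):
    return {
        acc: detect_hes(calls[acc], truth.annotation, tracks[acc],
                        truth.homology, params)
        for acc in truth.accessions
    }


class TestDetection:
    def test_noise_free_event_recovery_is_exact(self, noisefree_data):
        truth, tracks, calls, _ = noisefree_data
        results = _detect_all(truth, tracks, calls)
        score = score_he_detection({a: r[0] for a, r in results.items()}, truth)
        assert score.n_true > 0
        assert score.precision == 1.0 and score.recall == 1.0
        assert score.direction_accuracy == 1.0

    def test_noisy_event_recovery_above_090(self, noisy_many_he_data):
        truth, tracks, calls, _ = noisy_many_he_data
        results = _detect_all(truth, tracks, calls)
        score = score_he_detection({a: r[0] for a, r in results.items()}, truth)
        assert score.n_true >= 50
        assert score.precision >= 0.9 and score.recall >= 0.9
        assert score.direction_accuracy == 1.0

    def test_absent_genes_partition_into_calls_and_non_he(self, noisy_data):
        truth, tracks, calls, _ = noisy_data
        for acc, (he_calls, non_he) in _detect_all(truth, tracks, calls).items():
            absent = set(calls[acc].index[~calls[acc]["present"]])
            in_calls = [g for c in he_calls for g in c.recipient_genes]
            assert len(in_calls) == len(set(in_calls))
            assert set(in_calls) | set(non_he) == absent
            assert not set(in_calls) & set(non_he)

    def test_double_deletion_fails_presence_clause(self, noisefree_data):
        truth, tracks, calls, _ = noisefree_data
        acc = next(a for a in truth.accessions if truth.he_events[a])
        ev = truth.he_events[acc][0]
        # also delete the donor homoeologues: run genes now have no present hit
        donor_ids = [g.id for g in truth.annotation.genes_on(ev.donor_chrom)[
            ev.rank_start:ev.rank_stop]]
        broken = calls[acc].copy()
        broken.loc[donor_ids, "present"] = False
        he_calls, non_he = detect_hes(broken, truth.annotation, tracks[acc],
                                      truth.homology)
        rec_ids = {g.id for g in truth.annotation.genes_on(ev.recipient_chrom)[
            ev.rank_start:ev.rank_stop]}
        assert all(not rec_ids & set(c.recipient_genes) for c in he_calls)
        assert rec_ids <= set(non_he)

    def test_without_donor_doubling_coverage_test_fails(self):
        config = SimConfig(seed=21, depth_noise="none", duplicate_donor=False,
                           he_rate_synthetic=1.0, single_gene_deletion_rate=0.0)
        truth = simulate_accessions(simulate_reference(config), config)
        acc = truth.accessions[0]
        assert truth.he_events[acc]
        track = simulate_depth(truth, acc)
        calls = call_pav(truth.annotation, track)
        he_calls, non_he = detect_hes(calls, truth.annotation, track, truth.homology)
        assert he_calls == []
        assert set(non_he) == truth.absent_genes(acc)

    def test_unpaired_chromosome_run_goes_to_non_he(self):
        genes = [Gene(f"u{i}", "scaffold_1", i * 100, i * 100 + 80, "+",
                      ((i * 100, i * 100 + 80),)) for i in range(5)]
        ann = GenomeAnnotation([Chromosome("scaffold_1", 1000, "unplaced")], genes)
        calls = _calls_frame(ann, {"u1", "u2", "u3"})
        track = DepthTrack("a", {"scaffold_1": np.full(1000, 12, dtype=np.int64)})
        with pytest.warns(UserWarning, match="no homoeologous partner"):
            he_calls, non_he = detect_hes(calls, ann, track, [])
        assert he_calls == [] and set(non_he) == {"u1", "u2", "u3"}

    @pytest.mark.parametrize("param,values", [
        ("dup_factor", [1.2, 1.5, 2.5, 5.0, 50.0]),
        ("pid_min", [90.0, 95.0, 98.0, 99.9]),
    ])
    def test_call_count_monotone_nonincreasing(self, noisy_data, param, values):
        truth, tracks, calls, _ = noisy_data
        counts = []
        for v in values:
            params = HEParams(**{param: v})
            results = _detect_all(truth, tracks, calls, params)
            counts.append(sum(len(r[0]) for r in results.values()))
        assert counts[0] > 0
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_genome_mean_baseline_also_recovers_noise_free(self, noisefree_data):
        truth, tracks, calls, _ = noisefree_data
        results = _detect_all(truth, tracks, calls, HEParams(baseline="genome-mean"))
        score = score_he_detection({a: r[0] for a, r in results.items()}, truth)
        assert score.precision == 1.0 and score.recall == 1.0


def test_params_validation():
    with pytest.raises(ValueError):
        HEParams(dup_factor=1.0)
    with pytest.raises(ValueError):
        HEParams(zero_factor=1.0)
    with pytest.raises(ValueError):
        HEParams(pid_min=0.0)
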