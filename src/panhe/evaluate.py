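"""Scoring detected events and calls against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .he import HECall
from .pav import PAVMatrix
from .simulate import SimTruth, TrueHE

__all__ = ["pav_accuracy", "match_events", "score_he_detection", "HEScore"]


def pav_accuracy(matrix: PAVMatrix, truth: SimTruth) -> float:
    """Fraction of (gene, accession) cells where the called state equals
    the simulated truth, over the accessions retained in the matrix."""
    called = matrix.data.astype(bool)
    ref = truth.pav.loc[called.index, called.columns]
    return float((called == ref).to_numpy().mean())


def _matches(call: HECall, event: TrueHE, edge_tol: int) -> bool:
    r0, r1 = call.rank_interval
    return (
        call.recipient_chrom == event.recipient_chrom
        and abs(r0 - event.rank_start) <= edge_tol
        and abs(r1 - event.rank_stop) <= edge_tol
    )


def match_events(
    detected: Sequence[HECall], true_events: Sequence[TrueHE], edge_tol: int = 1
) -> tuple[list[tuple[HECall, TrueHE]], list[HECall], list[TrueHE]]:
    """Greedy one-to-one matching of detected calls to true events on the
    same recipient chromosome with rank-interval edges within ``edge_tol``
    genes.  Returns (matched pairs, unmatched calls, unmatched events)."""
    remaining = list(true_events)
    pairs: list[tuple[HECall, TrueHE]] = []
    unmatched_calls: list[HECall] = []
    for call in detected:
        hit = next((ev for ev in remaining if _matches(call, ev, edge_tol)), None)
        if hit is None:
            unmatched_calls.append(call)
        else:
            remaining.remove(hit)
            pairs.append((call, hit))
    return pairs, unmatched_calls, remaining


@dataclass
class HEScore:
    n_true: int
    n_detected: int
    n_matched: int
    n_direction_correct: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 1.0

    @property
    def direction_accuracy(self) -> float:
        return self.n_direction_correct / self.n_matched if self.n_matched else 1.0


def score_he_detection(
    detected: Mapping[str, Sequence[HECall]], truth: SimTruth, edge_tol: int = 1
) -> HEScore:
    """Event-level precision/recall over all accessions, plus the fraction
    of matched events whose reported direction equals the truth."""
    n_true = n_det = n_match = n_dir = 0
    for acc in truth.accessions:
        calls = list(detected.get(acc, []))
        events = truth.he_events[acc]
        n_true += len(events)
        n_det += len(calls)
        pairs, _, _ = match_events(calls, events, edge_tol)
        n_match += len(pairs)
        n_dir += sum(1 for call, ev in pairs if call.direction == ev.direction)
    return HEScore(n_true, n_det, n_match, n_dir)


def summarize_pav(matrix: PAVMatrix) -> pd.Series:
    """Core/variable gene counts and percentages for a PAV matrix."""
    present_all = matrix.values().all(axis=1)
    n = present_all.size
    core = int(present_all.sum())
    return pd.Series(
        {
            "n_genes": n,
            "core": core,
            "variable": n - core,
            "core_pct": 100.0 * core / n,
            "variable_pct": 100.0 * (n - core) / n,
        }
    )
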