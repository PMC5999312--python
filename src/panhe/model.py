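"""Pangenome and core-genome growth modelling.

For every subset size ``k`` of the accession panel, sampled genome
combinations yield growth points: the pangenome size (genes or families
present in at least one member) and the core size (present in all
members; families by the core-family rule restricted to the subset).
When the number of combinations C(n, k) exceeds a cap (100 000 by
default) a seeded uniform sample of distinct combinations is used
instead of full enumeration.

The point clouds are then fitted by nonlinear least squares
(Levenberg-Marquardt family):

* pangenome:  y = A * x**B + C   (power law)
* core:       y = A * exp(B * x) + C   (exponential decay)

With B < 0 both curves are bounded and C estimates the asymptotic
pangenome / core-genome size; its standard error comes from the
coefficient covariance of the fit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .classify import FamilyAssignment
from .pav import PAVMatrix

__all__ = ["GrowthPoint", "FitResult", "GrowthModel", "sample_combinations",
           "growth_curves", "fit_growth_models"]


@dataclass(frozen=True)
class GrowthPoint:
    """Pan/core sizes for one sampled combination of ``n`` genomes."""

    n: int
    pan_size: int
    core_size: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.core_size > self.pan_size:
            raise ValueError("core_size cannot exceed pan_size")


@dataclass
class FitResult:
    """Fitted coefficients of one growth curve."""

    model: Literal["power-law", "exponential"]
    A: float
    B: float
    C: float
    se_A: float
    se_B: float
    se_C: float
    converged: bool
    n_points: int

    @property
    def predicted_size(self) -> float | None:
        """Asymptote of the curve; defined only for a closed (B < 0) fit."""
        return self.C if self.B < 0 else None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "power-law":
            return self.A * np.power(x, self.B) + self.C
        return self.A * np.exp(self.B * x) + self.C


def sample_combinations(
    n_total: int, k: int, cap: int | None = 100_000, seed: int = 0
) -> list[tuple[int, ...]]:
    """Index combinations of size ``k`` from ``range(n_total)``.

    All C(n_total, k) combinations when that count is within ``cap``
    (or ``cap`` is None); otherwise ``cap`` distinct combinations drawn
    uniformly without replacement, seeded.
    """
    if not 1 <= k <= n_total:
        raise ValueError(f"k={k} outside [1, {n_total}]")
    total = math.comb(n_total, k)
    if cap is None or total <= cap:
        return list(itertools.combinations(range(n_total), k))
    if total <= 10 * cap:
        # enumerable: choose cap combinations without replacement exactly
        rng = np.random.default_rng(seed)
        all_combos = list(itertools.combinations(range(n_total), k))
        idx = rng.choice(total, size=cap, replace=False)
        return [all_combos[i] for i in np.sort(idx)]
    # sparse regime: rejection sampling of sorted k-subsets
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < cap:
        combo = tuple(sorted(rng.choice(n_total, size=k, replace=False).tolist()))
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
    return out


def _family_presence(matrix: PAVMatrix, families: FamilyAssignment) -> np.ndarray:
    """families x accessions boolean: any member present."""
    fam_ids = sorted(families.families)
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    vals = matrix.values()
    out = np.zeros((len(fam_ids), vals.shape[1]), dtype=bool)
    for fi, fam in enumerate(fam_ids):
        rows = [gene_index[g] for g in families.families[fam]]
        out[fi] = vals[rows].any(axis=0)
    return out


def growth_curves(
    matrix: PAVMatrix,
    unit: Literal["genes", "families"] = "genes",
    families: FamilyAssignment | None = None,
    cap: int | None = 100_000,
    seed: int = 0,
) -> list[GrowthPoint]:
    """Growth points for every subset size ``k`` in 1..n_accessions.

    For genes: pan = genes present in >= 1 subset member, core = genes
    present in all members.  For families: pan = families with any member
    present in >= 1 subset accession; core = families with >= 1 member
    gene present in every subset accession.
    """
    vals = matrix.values()
    n_acc = vals.shape[1]
    if n_acc == 0 or vals.shape[0] == 0:
        raise ValueError("empty PAV matrix")
    if unit == "families":
        if families is None:
            raise ValueError("unit='families' requires a FamilyAssignment")
        families = families.completed(matrix.genes)
        fam_pres = _family_presence(matrix, families)
        fam_ids = sorted(families.families)
        gene_index = {g: i for i, g in enumerate(matrix.genes)}
        fam_rows = [
            np.array([gene_index[g] for g in families.families[fam]])
            for fam in fam_ids
        ]
    points: list[GrowthPoint] = []
    for k in range(1, n_acc + 1):
        for combo in sample_combinations(n_acc, k, cap=cap, seed=seed + k):
            sub = vals[:, combo]
            if unit == "genes":
                pan = int(sub.any(axis=1).sum())
                core = int(sub.all(axis=1).sum())
            else:
                pan = int(fam_pres[:, combo].any(axis=1).sum())
                gene_core = sub.all(axis=1)
                core = int(sum(bool(gene_core[rows].any()) for rows in fam_rows))
            points.append(GrowthPoint(n=k, pan_size=pan, core_size=core))
    return points


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

def _power_law(x, A, B, C):
    return A * np.power(x, B) + C


def _exponential(x, A, B, C):
    return A * np.exp(B * x) + C


class GrowthModel:
    """Nonlinear least-squares fit of one growth curve.

    Parameters
    ----------
    kind : "power-law" (``y = A x^B + C``) or "exponential"
        (``y = A e^{Bx} + C``).
    n_restarts : jittered re-initialisations tried on failure.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : (A, B, C) estimates.
    se_ : their standard errors from the coefficient covariance.
    predicted_size_ : the asymptote C when B < 0, else None.
    converged_ : whether any start converged.
    """

    def __init__(self, kind: Literal["power-law", "exponential"], n_restarts: int = 5,
                 seed: int = 0):
        self.kind = kind
        self.n_restarts = n_restarts
        self.seed = seed

    def _initial_guess(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        y1 = float(y[x == x.min()].mean())
        if self.kind == "power-law":
            C0 = float(y.max()) * 1.01
            return np.array([y1 - C0, -1.0, C0])
        C0 = float(y.min()) * 0.99
        return np.array([y1 - C0, -0.5, C0])

    def fit(self, x: Sequence[float], y: Sequence[float]) -> "GrowthModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size == 0:
            raise ValueError("x and y must be equal-length and non-empty")
        if np.unique(x).size < 4:
            raise ValueError("need points at >= 4 distinct n values")
        fn = _power_law if self.kind == "power-law" else _exponential
        p0 = self._initial_guess(x, y)
        rng = np.random.default_rng(self.seed)
        best = None
        for attempt in range(self.n_restarts + 1):
            start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=3)
            try:
                popt, pcov = curve_fit(fn, x, y, p0=start, maxfev=20_000)
            except (RuntimeError, ValueError):
                continue
            resid = float(np.sum((fn(x, *popt) - y) ** 2))
            if best is None or resid < best[2]:
                best = (popt, pcov, resid)
            if best is not None and attempt == 0:
                break  # first start converged; keep it
        if best is None:
            self.coef_ = p0
            self.se_ = np.full(3, np.nan)
            self.converged_ = False
        else:
            popt, pcov, _ = best
            self.coef_ = popt
            with np.errstate(invalid="ignore"):
                self.se_ = np.sqrt(np.diag(pcov))
            self.converged_ = True
        self.n_points_ = int(x.size)
        return self

    @property
    def predicted_size_(self) -> float | None:
        A, B, C = self.coef_
        return float(C) if B < 0 else None

    def predict(self, x: Sequence[float]) -> np.ndarray:
        fn = _power_law if self.kind == "power-law" else _exponential
        return fn(np.asarray(x, dtype=float), *self.coef_)

    def result_(self) -> FitResult:
        A, B, C = (float(v) for v in self.coef_)
        se = [float(v) for v in self.se_]
        return FitResult(self.kind, A, B, C, *se,
                         converged=self.converged_, n_points=self.n_points_)

    def get_params(self) -> dict:
        return {"kind": self.kind, "n_restarts": self.n_restarts, "seed": self.seed}

    def set_params(self, **params) -> "GrowthModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def fit_growth_models(points: Sequence[GrowthPoint], seed: int = 0) -> tuple[FitResult, FitResult]:
    """Fit the pangenome (power-law) and core (exponential) curves over all
    sampled points (not per-n means); returns (pan, core) results."""
    x = np.array([p.n for p in points], dtype=float)
    pan = np.array([p.pan_size for p in points], dtype=float)
    core = np.array([p.core_size for p in points], dtype=float)
    pan_fit = GrowthModel("power-law", seed=seed).fit(x, pan).result_()
    core_fit = GrowthModel("exponential", seed=seed).fit(x, core).result_()
    return pan_fit, core_fit


def points_table(points: Sequence[GrowthPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.n, p.pan_size, p.core_size) for p in points],
        columns=["n", "pan_size", "core_size"],
    )
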