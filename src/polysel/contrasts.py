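"""Per-gene contrast statistics with threshold-style filtering.

One contrast compares two design cells (cold vs control within a genotype, or
mutant vs wild type within a condition) inside a single RNA fraction. For
every gene it reports replicate-mean signals, the plain ratio alt/ref, the
signed fold change (a decrease from a to b is written -(a/b), so magnitudes
are always >= 1), a two-sided p-value from a Welch t-test on log2 signals,
the Benjamini-Hochberg q-value across all genes of the contrast, and whether
the gene passes the expression filter (sum of the two signal values strictly
greater than a floor, 10 by default).

The decision rules are deliberately threshold-based — no dispersion-modelling
differential-expression framework is involved; with two replicates per cell
there is little information to fit one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DesignCell, SignalMatrix

__all__ = [
    "Thresholds",
    "ContrastResult",
    "ratio_fold",
    "signed_fold",
    "expression_pass",
    "replicate_test",
    "bh_adjust",
    "summarize_contrast",
    "contrast_frame",
    "write_contrast_tsv",
]


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds: fold floor, expression-sum floor, significance level.

    ``sig_metric`` chooses whether q-values (BH-adjusted, the default) or raw
    p-values are compared against ``alpha``.
    """

    fold_min: float = 1.5
    expr_sum_min: float = 10.0
    alpha: float = 0.05
    sig_metric: str = "q"

    def __post_init__(self) -> None:
        if self.fold_min < 1:
            raise ValueError("fold_min must be >= 1")
        if self.expr_sum_min < 0:
            raise ValueError("expr_sum_min must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sig_metric not in ("q", "p"):
            raise ValueError("sig_metric must be 'q' or 'p'")


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene summary of one contrast. NaN folds mark undefined (zero-mean) cases."""

    gene_id: str
    mean_ref: float
    mean_alt: float
    ratio: float
    signed_fold: float
    p: float
    q: float
    expressed: bool

    @property
    def complete(self) -> bool:
        return math.isfinite(self.ratio)


class UndefinedFoldError(ValueError):
    """Raised by the scalar fold helpers on non-positive means."""


def ratio_fold(mean_ref: float, mean_alt: float) -> float:
    """Plain ratio mean_alt / mean_ref; both means must be strictly positive."""
    if mean_ref <= 0 or mean_alt <= 0:
        raise UndefinedFoldError(
            f"fold undefined for means ({mean_ref}, {mean_alt}); both must be > 0"
        )
    return mean_alt / mean_ref


def signed_fold(mean_ref: float, mean_alt: float) -> float:
    """Signed fold: alt/ref for increases, -(ref/alt) for decreases; |fold| >= 1."""
    r = ratio_fold(mean_ref, mean_alt)
    return r if r >= 1.0 else -1.0 / r


def expression_pass(mean_ref: float, mean_alt: float, expr_sum_min: float = 10.0) -> bool:
    """Strict expression filter: the sum of the two signal values must exceed the floor."""
    return (mean_ref + mean_alt) > expr_sum_min


def replicate_test(
    ref_reps: Sequence[float],
    alt_reps: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """Two-sided Welch t-test on log2(signal + pseudocount) replicate values.

    Degenerate cases with zero variance in both groups return p = 1.0 when the
    group means are equal and p = 0.0 otherwise (the difference is then exact).
    """
    ref = np.asarray(ref_reps, dtype=float)
    alt = np.asarray(alt_reps, dtype=float)
    if ref.size < 2 or alt.size < 2:
        raise ValueError(
            "replicate_test needs >= 2 replicates per group; "
            "use fold-only selection when replicates are unavailable"
        )
    lref = np.log2(ref + pseudocount)
    lalt = np.log2(alt + pseudocount)
    if np.ptp(lref) == 0 and np.ptp(lalt) == 0:
        return 1.0 if lref[0] == lalt[0] else 0.0
    p = stats.ttest_ind(lref, lalt, equal_var=False).pvalue
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cell_means(
    matrix: SignalMatrix, cell: DesignCell
) -> tuple[np.ndarray, np.ndarray]:
    try:
        reps = matrix.cell_values(cell)
    except KeyError:
        raise ValueError(
            f"design cell {cell} has no samples in the sample sheet"
        ) from None
    return reps.mean(axis=1), reps


def _welch_pvalues(lref: np.ndarray, lalt: np.ndarray) -> np.ndarray:
    """Per-gene two-sided Welch t on log2 replicate values (rows = genes)."""
    p = stats.ttest_ind(lref, lalt, axis=1, equal_var=False).pvalue
    degenerate = (np.ptp(lref, axis=1) == 0) & (np.ptp(lalt, axis=1) == 0)
    p = np.where(degenerate, np.where(lref[:, 0] == lalt[:, 0], 1.0, 0.0), p)
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def _pooled_z_pvalues(lref: np.ndarray, lalt: np.ndarray) -> np.ndarray:
    """Two-sided z-test with replicate variance pooled across all genes.

    With very few replicates a per-gene variance estimate is hopelessly noisy;
    assuming a shared multiplicative noise level across genes, the within-cell
    log-scale variance is pooled over every gene of the contrast and then
    treated as known. Degenerate (noise-free) input falls back to exact
    comparison of the group means.
    """
    n1, n2 = lref.shape[1], lalt.shape[1]
    var_pooled = 0.5 * (np.var(lref, axis=1, ddof=1) + np.var(lalt, axis=1, ddof=1))
    sigma2 = float(np.mean(var_pooled))
    diff = lalt.mean(axis=1) - lref.mean(axis=1)
    if sigma2 == 0:
        return np.where(diff == 0, 1.0, 0.0)
    z = diff / np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n2))
    return 2.0 * stats.norm.sf(np.abs(z))


def summarize_contrast(
    matrix: SignalMatrix,
    ref_cell: DesignCell,
    alt_cell: DesignCell,
    thresholds: Thresholds = Thresholds(),
    *,
    pseudocount: float = 1.0,
    expr_basis: str = "mean_sum",
    test: str = "pooled",
) -> list[ContrastResult]:
    """One ContrastResult per gene for alt_cell vs ref_cell.

    Means are replicate averages of the raw signals; the significance test runs
    on log2(signal + pseudocount); q-values are BH-adjusted over all genes in
    this contrast. ``expr_basis`` selects whether the expression filter sums
    the two replicate-mean signals ("mean_sum", the default convention) or the
    raw replicate values of both sides ("replicate_sum").

    ``test`` chooses the p-value source: "pooled" (default) shares the
    replicate log-scale variance across all genes of the contrast and applies
    a z-test — the sensible regime for two replicates, where a per-gene
    variance estimate carries almost no information; "welch" runs the per-gene
    Welch t of :func:`replicate_test` instead.

    A gene with a zero mean on exactly one side gets NaN folds (never an
    infinite fold, never silently dropped); a gene at zero on both sides is an
    exact no-change and reports ratio = signed fold = 1.
    """
    if expr_basis not in ("mean_sum", "replicate_sum"):
        raise ValueError("expr_basis must be 'mean_sum' or 'replicate_sum'")
    if test not in ("pooled", "welch"):
        raise ValueError("test must be 'pooled' or 'welch'")
    ref_means, ref_reps = _cell_means(matrix, ref_cell)
    alt_means, alt_reps = _cell_means(matrix, alt_cell)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = alt_means / ref_means
    both_zero = (ref_means == 0) & (alt_means == 0)
    one_zero = ((ref_means == 0) | (alt_means == 0)) & ~both_zero
    ratio = np.where(both_zero, 1.0, ratio)
    ratio = np.where(one_zero, np.nan, ratio)
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    if ref_reps.shape[1] < 2 or alt_reps.shape[1] < 2:
        raise ValueError(
            "summarize_contrast needs >= 2 replicates per design cell"
        )
    lref = np.log2(ref_reps + pseudocount)
    lalt = np.log2(alt_reps + pseudocount)
    if test == "welch":
        p = _welch_pvalues(lref, lalt)
    else:
        p = _pooled_z_pvalues(lref, lalt)
    q = bh_adjust(p)

    if expr_basis == "mean_sum":
        expressed = (ref_means + alt_means) > thresholds.expr_sum_min
    else:
        expressed = (ref_reps.sum(axis=1) + alt_reps.sum(axis=1)) > thresholds.expr_sum_min

    return [
        ContrastResult(
            gene_id=g,
            mean_ref=float(ref_means[i]),
            mean_alt=float(alt_means[i]),
            ratio=float(ratio[i]),
            signed_fold=float(signed[i]),
            p=float(p[i]),
            q=float(q[i]),
            expressed=bool(expressed[i]),
        )
        for i, g in enumerate(matrix.genes)
    ]


_COLUMNS = ["gene_id", "mean_ref", "mean_alt", "ratio", "signed_fold", "p", "q", "expressed"]


def contrast_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "mean_ref": [r.mean_ref for r in results],
            "mean_alt": [r.mean_alt for r in results],
            "ratio": [r.ratio for r in results],
            "signed_fold": [r.signed_fold for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "expressed": [r.expressed for r in results],
        },
        columns=_COLUMNS,
    )


def write_contrast_tsv(results: Sequence[ContrastResult], path: str | Path) -> None:
    contrast_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
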