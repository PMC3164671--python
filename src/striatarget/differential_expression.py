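"""Two-group expression testing with fold-change / p / FDR thresholds.

Per gene: Welch's two-sample t on log2 values, fold change as the linear
treated/control ratio (down-regulation < 1), Benjamini-Hochberg q across all
tested genes.  Also houses the two-tailed Fisher exact test used for
overrepresentation questions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "de_test",
    "bh_fdr",
    "apply_thresholds",
    "fisher_exact_two_tailed",
    "read_expression_tsv",
    "write_expression_tsv",
    "results_to_frame",
]

GROUPS = ("control", "treated")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 expression with a group label per sample."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    data: np.ndarray  # genes x samples, log2 scale

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"data shape {d.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label required per sample")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        for g in GROUPS:
            if sum(1 for x in self.groups if x == g) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")
        if np.isnan(d).any():
            raise ValueError("expression matrix contains missing values")

    def group_data(self, group: str) -> np.ndarray:
        cols = [i for i, g in enumerate(self.groups) if g == group]
        return self.data[:, cols]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    fold_change: float  # linear treated/control ratio
    p_value: float
    q_value: float
    direction: str = "unchanged"  # up | down | unchanged

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.gene_id}: fold_change must be > 0")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.gene_id}: p outside [0, 1]")


def de_test(expr: ExpressionMatrix) -> list[DEResult]:
    """Welch's t per gene on log2 values; BH q over all genes.

    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means are equal and p = 0 otherwise, never NaN.
    """
    treated = expr.group_data("treated")
    control = expr.group_data("control")
    diff = treated.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # scipy warns on zero-variance genes; those p-values are repaired below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(treated, control, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad] = np.where(np.isclose(diff[bad], 0.0), 1.0, 0.0)
    q = bh_fdr(p)
    fold = np.power(2.0, diff)
    return [
        DEResult(gid, float(fc), float(pv), float(qv))
        for gid, fc, pv, qv in zip(expr.gene_ids, fold, p, q)
    ]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def apply_thresholds(
    results: Sequence[DEResult], fc_cut: float = 1.25, p_cut: float = 0.05
) -> list[DEResult]:
    """Keep genes with |fold change| beyond ``fc_cut`` (either direction) and
    p < ``p_cut``; set direction on the survivors.

    ``fc_cut = 1.0`` disables the fold-change filter.
    """
    if fc_cut < 1.0:
        raise ValueError(f"fc_cut must be >= 1, got {fc_cut}")
    kept: list[DEResult] = []
    for r in results:
        passes_fc = r.fold_change >= fc_cut or r.fold_change <= 1.0 / fc_cut
        if passes_fc and r.p_value < p_cut:
            direction = "up" if r.fold_change > 1.0 else "down"
            kept.append(replace(r, direction=direction))
    return kept


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's (within relative
    tolerance 1e-7).  Any zero margin gives p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV whose header encodes groups as
    ``sample_id:group``."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    sample_ids, groups = [], []
    for col in df.columns:
        if ":" not in col:
            raise ValueError(f"column {col!r} is not of the form sample:group")
        sid, grp = col.rsplit(":", 1)
        sample_ids.append(sid)
        groups.append(grp)
    return ExpressionMatrix(
        tuple(str(g) for g in df.index),
        tuple(sample_ids),
        tuple(groups),
        df.to_numpy(dtype=float),
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    cols = [f"{s}:{g}" for s, g in zip(expr.sample_ids, expr.groups)]
    df = pd.DataFrame(expr.data, index=list(expr.gene_ids), columns=cols)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    cols = ["gene_id", "fold_change", "p_value", "q_value", "direction"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)
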