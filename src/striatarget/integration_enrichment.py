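"""Intersect expression-responsive genes with peak-assigned genes into a
direct-target list, and gene-set enrichment with Fisher and EASE scores.

The EASE score is the one-tailed hypergeometric enrichment p recomputed with
one success removed from the overlap; it is never smaller than the plain
Fisher p.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import pandas as pd
from scipy import stats

from .differential_expression import DEResult, bh_fdr, fisher_exact_two_tailed
from .peak_annotation import PeakAssignment

__all__ = [
    "TargetGene",
    "EnrichmentResult",
    "integrate",
    "summarize_targets",
    "gene_set_enrichment",
    "overrepresentation_test",
]


@dataclass(frozen=True)
class TargetGene:
    """A gene that is both expression-responsive and peak-assigned."""

    gene_id: str
    symbol: str
    peak_ids: tuple[str, ...]
    de: DEResult
    direction: str  # up | down

    def __post_init__(self) -> None:
        expected = "up" if self.de.fold_change > 1.0 else "down"
        if self.direction != expected:
            raise ValueError(
                f"{self.gene_id}: direction {self.direction!r} inconsistent with "
                f"fold change {self.de.fold_change}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    n_targets: int
    universe_size: int
    fisher_p: float
    ease_p: float
    q_value: float


def integrate(
    de_genes: Sequence[DEResult], assignments: Sequence[PeakAssignment]
) -> list[TargetGene]:
    """One TargetGene per gene present in both the filtered DE list and the
    peak assignments, with peak ids aggregated and direction from the fold
    change.  Order-independent and idempotent; output sorted by gene id.
    """
    peaks_by_gene: dict[str, set[str]] = defaultdict(set)
    symbol_by_gene: dict[str, str] = {}
    for a in assignments:
        peaks_by_gene[a.gene_id].add(a.peak_id)
        symbol_by_gene[a.gene_id] = a.symbol
    best_de: dict[str, DEResult] = {}
    for r in de_genes:
        prev = best_de.get(r.gene_id)
        if prev is None or r.p_value < prev.p_value:
            best_de[r.gene_id] = r
    targets = []
    for gene_id in sorted(set(best_de) & set(peaks_by_gene)):
        de = best_de[gene_id]
        direction = "up" if de.fold_change > 1.0 else "down"
        targets.append(
            TargetGene(
                gene_id,
                symbol_by_gene[gene_id],
                tuple(sorted(peaks_by_gene[gene_id])),
                de,
                direction,
            )
        )
    return targets


def summarize_targets(targets: Sequence[TargetGene]) -> dict[str, int]:
    up = sum(1 for t in targets if t.direction == "up")
    down = sum(1 for t in targets if t.direction == "down")
    return {"targets_total": len(targets), "targets_up": up, "targets_down": down}


def _hypergeom_sf(overlap: int, universe: int, set_size: int, n_draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, n_draws)."""
    return float(min(1.0, stats.hypergeom.sf(overlap - 1, universe, set_size, n_draws)))


def gene_set_enrichment(
    targets: Set[str],
    collections: Mapping[str, Set[str]],
    universe: Set[str],
) -> list[EnrichmentResult]:
    """One-tailed hypergeometric enrichment per gene set, plus the EASE
    variant (overlap reduced by one), with BH q across sets.

    Sets are intersected with the universe before testing; targets must be a
    subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = set(targets) - set(universe)
    if stray:
        raise ValueError(f"targets outside universe: {sorted(stray)[:5]}")
    n_targets = len(targets)
    n_universe = len(universe)
    rows = []
    for set_id in sorted(collections):
        members = set(collections[set_id]) & set(universe)
        a = len(members & set(targets))
        fisher_p = _hypergeom_sf(a, n_universe, len(members), n_targets)
        ease_p = _hypergeom_sf(max(a - 1, 0), n_universe, len(members), n_targets)
        rows.append((set_id, a, len(members), fisher_p, ease_p))
    qs = bh_fdr([r[3] for r in rows]) if rows else []
    return [
        EnrichmentResult(set_id, a, size, n_targets, n_universe, fp, ep, float(q))
        for (set_id, a, size, fp, ep), q in zip(rows, qs)
    ]


def overrepresentation_test(
    special_genes: Set[str], altered_genes: Set[str], universe: Set[str]
) -> float:
    """Two-tailed Fisher exact p for the 2x2 of
    (special vs not) x (altered vs not) over the universe."""
    special = set(special_genes) & set(universe)
    altered = set(altered_genes) & set(universe)
    a = len(special & altered)
    b = len(special - altered)
    c = len(altered - special)
    d = len(universe) - a - b - c
    return fisher_exact_two_tailed(a, b, c, d)


def targets_to_frame(targets: Sequence[TargetGene]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": t.gene_id,
            "symbol": t.symbol,
            "peak_ids": ",".join(t.peak_ids),
            "fold_change": t.de.fold_change,
            "p_value": t.de.p_value,
            "q_value": t.de.q_value,
            "direction": t.direction,
        }
        for t in targets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "peak_ids",
            "fold_change",
            "p_value",
            "q_value",
            "direction",
        ],
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=[
            "set_id",
            "overlap",
            "set_size",
            "n_targets",
            "universe_size",
            "fisher_p",
            "ease_p",
            "q_value",
        ],
    )


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a two-column TSV (set_id, gene_id) into named gene sets."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["set_id", "gene_id"]:
        raise ValueError(f"{path}: expected columns set_id, gene_id")
    out: dict[str, set[str]] = defaultdict(set)
    for set_id, gene_id in zip(df["set_id"], df["gene_id"]):
        out[str(set_id)].add(str(gene_id))
    return dict(out)
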