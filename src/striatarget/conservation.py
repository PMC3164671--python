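"""Branch-length conservation scoring of motif instances across aligned
species, and the retention rule (score above threshold in enough distinct
peak sequences).

The conservation score of an instance is the total branch length of the
minimal connected subtree (Steiner subtree) of the phylogeny spanning the
species in which the instance is preserved.  Species matching is a hard
call: the instance's k-mer (or a PWM hit at the same significance level used
on the reference) must occur, on either strand, in the species' ungapped row
within a slack window around the instance's alignment columns.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AlignmentBlock, PhyloTree
from .motif_analysis import (
    BackgroundModel,
    LogOddsPWM,
    revcomp,
    scan_sequence,
    zscore_p,
)

__all__ = [
    "MotifInstance",
    "ConservationResult",
    "MotifRetention",
    "species_matches",
    "branch_length_score",
    "score_instances",
    "retain_motifs",
]

BLS_THRESHOLD_DEFAULT = 1.0
MIN_HITS_DEFAULT = 4
WINDOW_SLACK_DEFAULT = 10


@dataclass(frozen=True)
class MotifInstance:
    """One motif occurrence in a peak sequence: k-mer or PWM based."""

    motif_id: str
    seq_id: str
    offset: int  # 0-based within the peak sequence
    strand: str
    kmer: str | None = None

    def __post_init__(self) -> None:
        if self.kmer is not None and not self.kmer:
            raise ValueError("empty k-mer")


@dataclass(frozen=True)
class ConservationResult:
    instance: MotifInstance
    matched_species: frozenset[str]
    bls: float


@dataclass(frozen=True)
class MotifRetention:
    motif_id: str
    qualifying_hits: int
    retained: bool


def species_matches(
    instance: MotifInstance,
    block: AlignmentBlock,
    length: int | None = None,
    window_slack: int = WINDOW_SLACK_DEFAULT,
    pwm: LogOddsPWM | None = None,
    bg: BackgroundModel | None = None,
    p_threshold: float = 0.001,
) -> frozenset[str]:
    """Species in which the instance is preserved; the reference always is.

    For k-mer instances a species matches when the k-mer (either strand)
    occurs in its ungapped sequence within +/- ``window_slack`` alignment
    columns of the instance.  For PWM instances a species matches when a PWM
    window in that slack region reaches Z-score p below ``p_threshold``
    against the reference background.
    """
    if instance.kmer is not None:
        k = len(instance.kmer)
        targets = {instance.kmer.upper(), revcomp(instance.kmer.upper())}
    else:
        if pwm is None or bg is None:
            raise ValueError("PWM instances require pwm and bg")
        k = pwm.length
        targets = None
    ref_cols = block.ref_columns()
    if instance.offset < 0 or instance.offset + k > len(ref_cols):
        raise ValueError(
            f"instance at offset {instance.offset} (length {k}) outside "
            f"block reference span of {len(ref_cols)} bp"
        )
    c_start = int(ref_cols[instance.offset])
    c_end = int(ref_cols[instance.offset + k - 1]) + 1
    lo = max(0, c_start - window_slack)
    hi = min(block.width, c_end + window_slack)
    matched = {block.ref_species}
    for species, row in block.rows.items():
        if species == block.ref_species:
            continue
        window = row[lo:hi].replace("-", "").upper()
        if len(window) < k:
            continue
        if targets is not None:
            if any(t in window for t in targets):
                matched.add(species)
        else:
            for _off, _strand, score in scan_sequence(window, pwm):
                _z, p = zscore_p(score, bg)
                if p < p_threshold:
                    matched.add(species)
                    break
    return frozenset(matched)


def branch_length_score(
    tree: PhyloTree, matched: Iterable[str], reference: str
) -> float:
    """Total branch length of the minimal connected subtree spanning the
    matched species (Steiner subtree on the unrooted topology).

    An edge contributes iff matched leaves lie on both of its sides, so the
    score is invariant under re-rooting.  ``matched = {reference}`` gives 0;
    all leaves give the total tree length.
    """
    matched_set = frozenset(matched)
    if reference not in matched_set:
        raise ValueError(f"reference {reference!r} not in matched set")
    leaves = tree.leaves
    unknown = matched_set - leaves
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    below = tree.leafsets_below()
    total = 0.0
    for i in range(1, tree.n_nodes):
        inside = below[i] & matched_set
        if inside and inside != matched_set:
            total += tree.blen[i]
    return total


def score_instances(
    instances: Sequence[MotifInstance],
    blocks_by_seq: Mapping[str, AlignmentBlock],
    tree: PhyloTree,
    reference: str,
    window_slack: int = WINDOW_SLACK_DEFAULT,
    pwms: Mapping[str, LogOddsPWM] | None = None,
    backgrounds: Mapping[str, BackgroundModel] | None = None,
    p_threshold: float = 0.001,
) -> list[ConservationResult]:
    """Score every instance against its peak's alignment block."""
    missing = {b.ref_species for b in blocks_by_seq.values()} - {reference}
    if missing:
        raise ValueError(
            f"alignment reference species {sorted(missing)} differ from {reference!r}"
        )
    alien = set().union(
        *(set(b.rows) for b in blocks_by_seq.values())
    ) - tree.leaves if blocks_by_seq else set()
    if alien:
        raise ValueError(f"alignment names species absent from tree: {sorted(alien)}")
    out: list[ConservationResult] = []
    for inst in instances:
        if inst.seq_id not in blocks_by_seq:
            raise ValueError(f"no alignment block for sequence {inst.seq_id!r}")
        block = blocks_by_seq[inst.seq_id]
        pwm = bg = None
        if inst.kmer is None:
            pwm = (pwms or {}).get(inst.motif_id)
            bg = (backgrounds or {}).get(inst.motif_id)
        matched = species_matches(
            inst,
            block,
            window_slack=window_slack,
            pwm=pwm,
            bg=bg,
            p_threshold=p_threshold,
        )
        out.append(
            ConservationResult(inst, matched, branch_length_score(tree, matched, reference))
        )
    return out


def retain_motifs(
    results: Iterable[ConservationResult],
    bls_threshold: float = BLS_THRESHOLD_DEFAULT,
    min_hits: int = MIN_HITS_DEFAULT,
) -> list[MotifRetention]:
    """Apply the retention rule per motif: at least ``min_hits`` distinct
    peak sequences must each carry an instance scoring above
    ``bls_threshold``.  Instances piling up in one peak count once.
    """
    qualifying: dict[str, set[str]] = defaultdict(set)
    seen: set[str] = set()
    for r in results:
        seen.add(r.instance.motif_id)
        if r.bls > bls_threshold:
            qualifying[r.instance.motif_id].add(r.instance.seq_id)
    return [
        MotifRetention(mid, len(qualifying[mid]), len(qualifying[mid]) >= min_hits)
        for mid in sorted(seen)
    ]


def conservation_to_frame(results: Sequence[ConservationResult]) -> pd.DataFrame:
    rows = [
        {
            "motif_id": r.instance.motif_id,
            "seq_id": r.instance.seq_id,
            "offset": r.instance.offset,
            "strand": r.instance.strand,
            "kmer": r.instance.kmer if r.instance.kmer is not None else "",
            "n_matched_species": len(r.matched_species),
            "matched_species": ",".join(sorted(r.matched_species)),
            "bls": r.bls,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "seq_id",
            "offset",
            "strand",
            "kmer",
            "n_matched_species",
            "matched_species",
            "bls",
        ],
    )


def retention_to_frame(retentions: Sequence[MotifRetention]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in retentions],
        columns=["motif_id", "qualifying_hits", "retained"],
    )
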