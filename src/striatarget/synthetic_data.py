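"""Synthetic data with full ground truth for end-to-end testing.

Generates a repeat-masked genome, gene models, peaks carrying planted motif
instances, multi-species alignments evolved along a fixed tree
(Jukes-Cantor, substitution-only) with elevated conservation at motif
positions, and a two-group expression matrix with planted fold changes on
peak-proximal genes.  Every generator is a pure function of the config and
its seed, and the truth record verifies against the emitted sequences by
direct lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .differential_expression import ExpressionMatrix
from .io_formats import AlignmentBlock, GeneModel, GenomicInterval, Peak, PhyloTree
from .motif_analysis import revcomp
from .peak_annotation import anchor_of, tss_of

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_genes_and_peaks",
    "evolve_alignments",
    "generate_expression",
    "peak_sequences",
    "fixture_config",
    "demo_config",
    "SHALLOW_TREE",
    "DEEP_TREE",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# 8 species, total branch length 3.6 substitutions/site
SHALLOW_TREE = (
    "((((ref:0.10,sp1:0.10):0.20,sp2:0.30):0.20,(sp3:0.20,sp4:0.30):0.30):0.20,"
    "(sp5:0.50,(sp6:0.30,sp7:0.40):0.20):0.30);"
)
# same topology, every branch deep enough to randomize unconstrained sites
DEEP_TREE = (
    "((((ref:1.0,sp1:1.0):2.0,sp2:3.0):2.0,(sp3:2.0,sp4:3.0):3.0):2.0,"
    "(sp5:5.0,(sp6:3.0,sp7:4.0):2.0):3.0);"
)

# sub-seed tags so each stage draws from an independent stream
_STAGE_GENOME, _STAGE_FEATURES, _STAGE_ALIGN, _STAGE_EXPR = 11, 13, 17, 19


@dataclass(frozen=True)
class SimConfig:
    """Declarative description of one synthetic dataset."""

    genome_length: int
    n_genes: int
    n_peaks: int
    seed: int
    chrom: str = "chrS"
    gc_fraction: float = 0.42
    repeat_fraction: float = 0.15
    repeat_run_length: int = 300
    gene_length_range: tuple[int, int] = (1_000, 2_500)
    gene_territory_fraction: float = 0.7
    peak_length_range: tuple[int, int] = (61, 428)
    motif: str = "ACCACA"
    planting_rate: float = 0.6
    frac_peaks_within_10kb: float = 0.8
    frac_peaks_within_1kb: float = 0.2
    annotation_window: int = 10_000
    annotation_inner: int = 1_000
    n_samples_per_group: int = 4
    de_effect: float = math.log2(1.6)  # log2 fold change of planted targets
    noise_sd: float = 0.15
    n_target_genes: int = 25
    target_proximal_fraction: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    tree_newick: str = SHALLOW_TREE
    ref_species: str = "ref"
    background_conservation_rate: float = 0.0
    motif_conservation_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "repeat_fraction",
            "planting_rate",
            "frac_peaks_within_10kb",
            "frac_peaks_within_1kb",
            "target_proximal_fraction",
            "background_conservation_rate",
            "motif_conservation_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.repeat_fraction >= 1.0:
            raise ValueError("repeat_fraction must be < 1")
        if self.frac_peaks_within_1kb > self.frac_peaks_within_10kb:
            raise ValueError("frac_peaks_within_1kb cannot exceed frac_peaks_within_10kb")
        lo, hi = self.peak_length_range
        if not (0 < lo <= hi <= self.genome_length):
            raise ValueError(f"bad peak_length_range {self.peak_length_range}")
        if self.genome_length < 10 * hi:
            raise ValueError("genome_length must be >= 10 x max peak length")
        if any(b not in "ACGT" for b in self.motif.upper()) or len(self.motif) < 4:
            raise ValueError(f"motif must be an ACGT string of length >= 4")
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset, for parameter-recovery tests."""

    planted_motif: str
    motif_positions: list[tuple[str, int, str]] = field(default_factory=list)
    planted_target_genes: list[tuple[str, float]] = field(default_factory=list)
    conserved_species_sets: dict[tuple[str, int, str], frozenset[str]] = field(
        default_factory=dict
    )
    seed: int = 0


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[GenomicInterval]]:
    """I.i.d. genome at the configured GC, with contiguous lowercase repeat
    runs covering ``repeat_fraction`` of positions.  Returns the sequence map
    and the mask intervals."""
    rng = _rng(cfg, _STAGE_GENOME)
    L = cfg.genome_length
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=L, p=probs)
    seq = _BASES[codes]
    target = int(round(cfg.repeat_fraction * L))
    masked = np.zeros(L, dtype=bool)
    run = min(cfg.repeat_run_length, L)
    covered = 0
    attempts = 0
    while covered < target and attempts < 100 * max(1, target // run):
        start = int(rng.integers(0, L - run + 1))
        span = masked[start : start + run]
        covered += int(run - span.sum())
        span[:] = True
        attempts += 1
    seq = np.where(masked, seq + 32, seq)  # +32 = ASCII lowercase
    mask_intervals: list[GenomicInterval] = []
    padded = np.concatenate([[False], masked, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        mask_intervals.append(GenomicInterval(cfg.chrom, int(s), int(e)))
    return {cfg.chrom: seq.tobytes().decode()}, mask_intervals


# ---------------------------------------------------------------------------
# genes and peaks
# ---------------------------------------------------------------------------


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    lo: int,
    hi: int,
    taken: list[tuple[int, int]],
    accept=None,
    cap_per_item: int = 200,
) -> list[tuple[int, int]]:
    """Rejection-sample ``n`` non-overlapping [start, end) spans in [lo, hi)."""
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _attempt in range(cap_per_item):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if hi - lo < length:
                continue
            start = int(rng.integers(lo, hi - length + 1))
            span = (start, start + length)
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            if accept is not None and not accept(span):
                continue
            placed.append(span)
            taken.append(span)
            break
        else:
            raise ValueError(
                "placement cap exceeded; use a larger genome or fewer features"
            )
    return placed


def _make_exons(
    rng: np.random.Generator, chrom: str, start: int, end: int, strand: str
) -> tuple[GenomicInterval, ...]:
    n_ex = int(rng.integers(2, 5))
    cuts = np.sort(rng.choice(np.arange(start, end + 1), size=2 * n_ex, replace=False))
    return tuple(
        GenomicInterval(chrom, int(cuts[2 * i]), int(cuts[2 * i + 1]), strand)
        for i in range(n_ex)
        if cuts[2 * i] < cuts[2 * i + 1]
    )


def generate_genes_and_peaks(
    cfg: SimConfig, genome: dict[str, str]
) -> tuple[list[GeneModel], list[Peak], SyntheticTruth, dict[str, str]]:
    """Place gene models and peaks, plant the motif into a deterministic
    count of peaks, and return the (updated) genome with the truth record.

    Exactly ``floor(planting_rate * n_peaks)`` peaks receive the motif, at a
    recorded offset on a seeded-random strand.  Peak regions are kept
    non-overlapping and repeat-free so planted instances are never masked
    away or overwritten.
    """
    rng = _rng(cfg, _STAGE_FEATURES)
    seq = genome[cfg.chrom]
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    is_upper_acgt = np.isin(arr, _BASES)

    territory_hi = int(cfg.gene_territory_fraction * L)
    taken_genes: list[tuple[int, int]] = []
    gene_spans = _place_nonoverlapping(
        rng, cfg.n_genes, cfg.gene_length_range, 0, territory_hi, taken_genes
    )
    genes: list[GeneModel] = []
    for i, (s, e) in enumerate(gene_spans):
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(cfg.chrom, s, e, strand)
        genes.append(
            GeneModel(f"g{i:04d}", f"Sy{i:04d}", body, _make_exons(rng, cfg.chrom, s, e, strand))
        )
    tss_positions = np.array([tss_of(g) for g in genes]) if genes else np.empty(0, int)

    n_1kb = int(round(cfg.frac_peaks_within_1kb * cfg.n_peaks))
    n_10kb = int(round(cfg.frac_peaks_within_10kb * cfg.n_peaks))
    n_10kb_only = n_10kb - n_1kb
    n_far = cfg.n_peaks - n_10kb
    if n_10kb > 0 and not genes:
        raise ValueError("proximal peaks requested but no genes configured")

    def region_clean(span: tuple[int, int]) -> bool:
        return bool(is_upper_acgt[span[0] : span[1]].all())

    taken_peaks: list[tuple[int, int]] = []
    peak_specs: list[tuple[int, int]] = []  # (start, end)

    # proximal peaks: distinct genes where possible, anchors at a sampled
    # TSS distance inside the requested window
    gene_order = list(rng.permutation(len(genes))) if genes else []
    gi = 0
    for kind, count in (("inner", n_1kb), ("outer", n_10kb_only)):
        for _ in range(count):
            placed = False
            for _attempt in range(500):
                gene = genes[gene_order[gi % len(gene_order)]]
                tss = tss_of(gene)
                if kind == "inner":
                    d = int(rng.integers(-cfg.annotation_inner, cfg.annotation_inner + 1))
                else:
                    mag = int(
                        rng.integers(cfg.annotation_inner + 1, cfg.annotation_window - 500)
                    )
                    d = mag if rng.random() < 0.5 else -mag
                length = int(rng.integers(*cfg.peak_length_range))
                start = tss + d - length // 2
                span = (start, start + length)
                if span[0] < 0 or span[1] > L:
                    continue
                if any(span[0] < e and s < span[1] for s, e in taken_peaks):
                    continue
                if not region_clean(span):
                    continue
                taken_peaks.append(span)
                peak_specs.append(span)
                gi += 1
                placed = True
                break
            if not placed:
                raise ValueError(
                    "placement cap exceeded for proximal peaks; use a larger genome"
                )

    # intergenic peaks: anchor farther than the window from every TSS
    def far_enough(span: tuple[int, int]) -> bool:
        anchor = (span[0] + span[1]) // 2
        if len(tss_positions) and np.abs(anchor - tss_positions).min() <= cfg.annotation_window + 500:
            return False
        return region_clean(span)

    far_spans = _place_nonoverlapping(
        rng, n_far, cfg.peak_length_range, 0, L, taken_peaks, accept=far_enough,
        cap_per_item=2000,
    )
    peak_specs.extend(far_spans)

    peaks = [
        Peak(
            f"peak_{i:04d}",
            GenomicInterval(cfg.chrom, s, e),
            tag_count=int(rng.integers(10, 200)),
        )
        for i, (s, e) in enumerate(peak_specs)
    ]

    truth = SyntheticTruth(planted_motif=cfg.motif.upper(), seed=cfg.seed)
    k = len(cfg.motif)
    n_plant = int(math.floor(cfg.planting_rate * cfg.n_peaks))
    plant_idx = rng.permutation(cfg.n_peaks)[:n_plant]
    for i in sorted(int(x) for x in plant_idx):
        p = peaks[i]
        offset = int(rng.integers(0, p.region.length - k + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = truth.planted_motif if strand == "+" else revcomp(truth.planted_motif)
        pos = p.region.start + offset
        arr[pos : pos + k] = np.frombuffer(oriented.encode(), dtype=np.uint8)
        truth.motif_positions.append((p.peak_id, offset, strand))

    new_genome = dict(genome)
    new_genome[cfg.chrom] = arr.tobytes().decode()
    return genes, peaks, truth, new_genome


def peak_sequences(genome: dict[str, str], peaks: Sequence[Peak]) -> dict[str, str]:
    """Uppercased peak sequences keyed by peak id."""
    return {
        p.peak_id: genome[p.region.chrom][p.region.start : p.region.end].upper()
        for p in peaks
    }


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def evolve_alignments(
    cfg: SimConfig,
    genome: dict[str, str],
    peaks: Sequence[Peak],
    truth: SyntheticTruth,
):
    """One gap-free alignment block per peak, evolved outward from the
    reference leaf along the tree (Jukes-Cantor substitutions).

    Per edge of length t, an unconstrained site substitutes with probability
    (1 - background_conservation_rate) * (1 - exp(-t)); planted motif sites
    substitute at the same rate scaled by (1 - motif_conservation_rate).
    Fills ``truth.conserved_species_sets`` with the species in which each
    planted instance survives intact.
    """
    tree = PhyloTree.from_newick(cfg.tree_newick)
    if len(tree.leaves) < 3:
        raise ValueError("tree must have >= 3 leaves")
    if cfg.ref_species not in tree.leaves:
        raise ValueError(
            f"reference species {cfg.ref_species!r} is not a leaf of the tree"
        )
    rng = _rng(cfg, _STAGE_ALIGN)

    # undirected adjacency, then BFS order away from the reference leaf
    neighbors: dict[int, list[tuple[int, float]]] = {i: [] for i in range(tree.n_nodes)}
    for i in range(1, tree.n_nodes):
        neighbors[tree.parent[i]].append((i, tree.blen[i]))
        neighbors[i].append((tree.parent[i], tree.blen[i]))
    ref_node = tree.leaf_node(cfg.ref_species)
    order: list[tuple[int, int, float]] = []  # (node, source, edge length)
    seen = {ref_node}
    frontier = [ref_node]
    while frontier:
        nxt = []
        for u in frontier:
            for v, t in neighbors[u]:
                if v not in seen:
                    seen.add(v)
                    order.append((v, u, t))
                    nxt.append(v)
        frontier = nxt
    leaf_nodes = {tree.leaf_node(name): name for name in tree.leaves}

    planted_by_peak: dict[str, list[tuple[int, str]]] = {}
    for peak_id, offset, strand in truth.motif_positions:
        planted_by_peak.setdefault(peak_id, []).append((offset, strand))

    k = len(truth.planted_motif)
    blocks = []
    code = np.full(256, 0, dtype=np.int8)
    for idx, b in enumerate(_BASES):
        code[b] = idx
    for peak in peaks:
        refseq = genome[peak.region.chrom][peak.region.start : peak.region.end].upper()
        ref_codes = code[np.frombuffer(refseq.encode(), dtype=np.uint8)]
        n = len(ref_codes)
        motif_mask = np.zeros(n, dtype=bool)
        for offset, _strand in planted_by_peak.get(peak.peak_id, []):
            motif_mask[offset : offset + k] = True
        node_seq: dict[int, np.ndarray] = {ref_node: ref_codes}
        for node, source, t in order:
            parent_codes = node_seq[source]
            p_site = 1.0 - math.exp(-t)
            p = np.where(
                motif_mask,
                (1.0 - cfg.motif_conservation_rate) * p_site,
                (1.0 - cfg.background_conservation_rate) * p_site,
            )
            hit = rng.random(n) < p
            child = parent_codes.copy()
            if hit.any():
                child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            node_seq[node] = child
        rows = {
            name: _BASES[node_seq[node]].tobytes().decode()
            for node, name in leaf_nodes.items()
        }
        blocks.append(AlignmentBlock(peak.region, cfg.ref_species, rows))
        for offset, strand in planted_by_peak.get(peak.peak_id, []):
            target = ref_codes[offset : offset + k]
            survivors = {
                name
                for node, name in leaf_nodes.items()
                if np.array_equal(node_seq[node][offset : offset + k], target)
            }
            truth.conserved_species_sets[(peak.peak_id, offset, strand)] = frozenset(
                survivors | {cfg.ref_species}
            )
    return blocks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    cfg: SimConfig,
    genes: Sequence[GeneModel] | Sequence[str],
    truth: SyntheticTruth,
    peaks: Sequence[Peak] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log2 expression = baseline + group effect + N(0, noise_sd) noise.

    Planted targets get a +/-``de_effect`` shift in the treated group; when
    peaks are supplied, targets are drawn preferentially (per
    ``target_proximal_fraction``) from genes with a peak anchor inside the
    annotation window of their TSS, so the integration stage has true
    positives.  ``de_effect = 0`` plants nothing (a null configuration).
    """
    gene_ids = [g if isinstance(g, str) else g.gene_id for g in genes]
    rng = _rng(cfg, _STAGE_EXPR)
    n_genes = len(gene_ids)

    planted: dict[str, float] = {}
    if cfg.n_target_genes > 0 and cfg.de_effect != 0.0:
        proximal: list[str] = []
        distal: list[str] = list(gene_ids)
        if peaks is not None and genes and not isinstance(genes[0], str):
            anchors = np.array([anchor_of(p) for p in peaks])
            proximal, distal = [], []
            for g in genes:  # type: ignore[assignment]
                tss = tss_of(g)
                near = len(anchors) and np.abs(anchors - tss).min() <= cfg.annotation_window
                (proximal if near else distal).append(g.gene_id)
        n_want = min(cfg.n_target_genes, n_genes)
        n_prox = min(int(round(cfg.target_proximal_fraction * n_want)), len(proximal))
        chosen = list(rng.choice(proximal, size=n_prox, replace=False)) if n_prox else []
        rest = [g for g in gene_ids if g not in set(chosen)]
        n_rest = min(n_want - n_prox, len(rest))
        if n_rest > 0:
            chosen += list(rng.choice(rest, size=n_rest, replace=False))
        for gid in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            planted[gid] = sign * cfg.de_effect

    m = cfg.n_samples_per_group
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_genes)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_genes, 2 * m))
    effect = np.array([planted.get(g, 0.0) for g in gene_ids])
    data = baseline[:, None] + noise
    data[:, m:] += effect[:, None]

    sample_ids = tuple(f"c{i + 1}" for i in range(m)) + tuple(
        f"t{i + 1}" for i in range(m)
    )
    groups = ("control",) * m + ("treated",) * m
    expr = ExpressionMatrix(tuple(gene_ids), sample_ids, groups, data)
    new_truth = replace_truth_targets(
        truth, [(gid, float(2.0**eff)) for gid, eff in sorted(planted.items())]
    )
    return expr, new_truth


def replace_truth_targets(
    truth: SyntheticTruth, targets: list[tuple[str, float]]
) -> SyntheticTruth:
    truth.planted_target_genes = targets
    return truth


# ---------------------------------------------------------------------------
# canned configurations
# ---------------------------------------------------------------------------


def fixture_config(seed: int = 7, conserved: bool = True) -> SimConfig:
    """The standard small fixture: 50 peaks, motif planted in 30 of them,
    25 planted peak-proximal targets, 8-species tree.

    ``conserved=False`` swaps in a deep tree and lets motif sites drift
    freely, so conservation filtering should drop the planted motif.
    """
    return SimConfig(
        genome_length=400_000,
        n_genes=40,
        n_peaks=50,
        seed=seed,
        n_target_genes=25,
        tree_newick=SHALLOW_TREE if conserved else DEEP_TREE,
        motif_conservation_rate=1.0 if conserved else 0.0,
    )


def demo_config(seed: int = 7) -> SimConfig:
    """A larger dataset for the shipped demo: ~2 Mb genome, 300 genes,
    150 peaks."""
    return SimConfig(
        genome_length=2_000_000,
        n_genes=300,
        n_peaks=150,
        seed=seed,
        gene_length_range=(1_500, 4_000),
        n_target_genes=60,
    )
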