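"""End-to-end orchestration: annotate -> DE -> integrate -> scan/discover ->
conserve -> enrich, from a declarative config, with a machine-readable run
report.

Every output TSV carries a header comment naming the producing stage, the
config hash and the seed; nothing timestamped, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import (
    conservation,
    differential_expression as de,
    integration_enrichment as ie,
    io_formats as iof,
    motif_analysis as ma,
    peak_annotation as pa,
    synthetic_data as sd,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo"]

log = logging.getLogger("striatarget")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All paths and thresholds for one run.  Paths are resolved relative to
    the config file's directory when loaded from YAML."""

    genome_fasta: str
    peaks_bed: str
    genes_tsv: str
    expr_tsv: str
    alignments_maf: str | None = None
    tree_newick: str | None = None
    pwms_file: str | None = None
    gene_sets_tsv: str | None = None
    window: int = 10_000
    inner: int = 1_000
    fc_cut: float = 1.25
    p_cut: float = 0.05
    z_p: float = 0.001
    bls_threshold: float = 1.0
    min_hits: int = 4
    min_support: int = 25
    k_values: tuple[int, ...] = (6, 7)
    max_kmers_conserved: int = 10
    window_slack: int = 10
    n_background: int = 10_000_000
    ref_species: str = "ref"
    seed: int = 0

    def validate(self) -> None:
        for name in ("window", "inner", "fc_cut", "p_cut", "z_p", "bls_threshold",
                     "min_hits", "min_support", "n_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        for name in ("genome_fasta", "peaks_bed", "genes_tsv", "expr_tsv",
                     "alignments_maf", "tree_newick", "pwms_file", "gene_sets_tsv"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValueError(f"{name}: file not found: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        path_keys = {
            "genome_fasta", "peaks_bed", "genes_tsv", "expr_tsv",
            "alignments_maf", "tree_newick", "pwms_file", "gene_sets_tsv",
        }
        for key in path_keys & set(raw):
            if raw[key] is not None:
                raw[key] = str((path.parent / raw[key]).resolve())
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _write(df, path: Path, stage: str, cfg: PipelineConfig) -> None:
    iof.write_tsv(df, path, header_comment=f"stage={stage} config={cfg.hash()} seed={cfg.seed}")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages, write per-stage TSVs plus ``report.json``, and
    return the run directory.  Any stage error aborts with the stage name."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.hash(), "seed": cfg.seed, "counts": {}}
    counts = report["counts"]

    genome = _stage("load-genome")(iof.read_fasta)(cfg.genome_fasta)
    peaks = _stage("load-peaks")(iof.read_bed)(cfg.peaks_bed)
    genes = _stage("load-genes")(iof.read_gene_table)(cfg.genes_tsv)
    expr = _stage("load-expression")(de.read_expression_tsv)(cfg.expr_tsv)
    counts["peaks"] = len(peaks)
    counts["genes"] = len(genes)
    counts["expression_genes"] = len(expr.gene_ids)
    log.info("loaded %d peaks, %d genes, %d expression rows",
             len(peaks), len(genes), len(expr.gene_ids))

    # --- annotate ---------------------------------------------------------
    assignments = _stage("annotate")(pa.assign_peaks)(peaks, genes, cfg.window, cfg.inner)
    counts.update(pa.summarize_assignments(assignments))
    _write(pa.assignments_to_frame(assignments), outdir / "assignments.tsv", "annotate", cfg)
    log.info("annotate: %d assignments (%d peaks within %d bp)",
             len(assignments), counts["peaks_within_10kb"], cfg.window)

    # --- differential expression -----------------------------------------
    results = _stage("de")(de.de_test)(expr)
    filtered = _stage("de")(de.apply_thresholds)(results, cfg.fc_cut, cfg.p_cut)
    counts["de_tested"] = len(results)
    counts["de_passing"] = len(filtered)
    _write(de.results_to_frame(results), outdir / "de_all.tsv", "de", cfg)
    _write(de.results_to_frame(filtered), outdir / "de_filtered.tsv", "de", cfg)
    log.info("de: %d/%d genes pass fc >= %.3g, p < %.3g",
             len(filtered), len(results), cfg.fc_cut, cfg.p_cut)

    # --- integrate --------------------------------------------------------
    targets = _stage("integrate")(ie.integrate)(filtered, assignments)
    counts.update(ie.summarize_targets(targets))
    _write(ie.targets_to_frame(targets), outdir / "targets.tsv", "integrate", cfg)
    log.info("integrate: %d targets (%d up / %d down)",
             counts["targets_total"], counts["targets_up"], counts["targets_down"])

    # --- motif discovery and PWM scanning --------------------------------
    peak_seqs = sd.peak_sequences(genome, peaks)
    seq_ids = sorted(peak_seqs)
    seq_list = [peak_seqs[s] for s in seq_ids]
    discovered: list[ma.KmerMotif] = []
    for k in cfg.k_values:
        discovered.extend(
            _stage("discover")(ma.discover_kmers)(seq_list, k, cfg.min_support)
        )
    counts["kmers_discovered"] = len(discovered)
    _write(
        [m.__dict__ for m in discovered] or [{"kmer": "", "k": 0, "support": 0, "rank": 0}],
        outdir / "kmers.tsv", "discover", cfg,
    )
    log.info("discover: %d k-mers with support >= %d", len(discovered), cfg.min_support)

    pwm_hits: list[tuple[str, ma.MotifHit]] = []  # (motif_id, hit)
    pwms: dict[str, ma.LogOddsPWM] = {}
    backgrounds: dict[str, ma.BackgroundModel] = {}
    if cfg.pwms_file:
        records = _stage("scan")(iof.read_pwm_file)(cfg.pwms_file)
        base_freqs = _genome_base_freqs(genome)
        for rec in records:
            pwm = _stage("scan")(ma.build_log_odds)(rec, base_freqs)
            bg = _stage("scan")(ma.sample_background)(
                pwm, genome, n=cfg.n_background, seed=cfg.seed
            )
            pwms[rec.motif_id] = pwm
            backgrounds[rec.motif_id] = bg
            for sid in seq_ids:
                for hit in ma.scan_with_background(sid, peak_seqs[sid], pwm, bg, cfg.z_p):
                    pwm_hits.append((rec.motif_id, hit))
        rows = [
            {"motif_id": mid, "seq_id": h.seq_id, "offset": h.offset,
             "strand": h.strand, "score": h.score, "z": h.z, "p": h.p}
            for mid, h in pwm_hits
        ]
        _write(
            rows or [{"motif_id": "", "seq_id": "", "offset": 0, "strand": "",
                      "score": 0.0, "z": 0.0, "p": 1.0}],
            outdir / "pwm_hits.tsv", "scan", cfg,
        )
        log.info("scan: %d PWM hits at p < %.3g over %d motifs",
                 len(pwm_hits), cfg.z_p, len(pwms))
    counts["pwm_hits"] = len(pwm_hits)

    # --- conservation -----------------------------------------------------
    retained_kmers = 0
    retained_pwms = 0
    if cfg.alignments_maf and cfg.tree_newick:
        blocks = _stage("conserve")(iof.read_alignment_blocks)(cfg.alignments_maf)
        tree = _stage("conserve")(iof.read_newick)(cfg.tree_newick)
        blocks_by_seq = _match_blocks_to_peaks(blocks, peaks)
        top = sorted(discovered, key=lambda m: m.rank)[: cfg.max_kmers_conserved]
        instances = _kmer_instances(top, peak_seqs)
        cons = _stage("conserve")(conservation.score_instances)(
            instances, blocks_by_seq, tree, cfg.ref_species,
            window_slack=cfg.window_slack,
        )
        retention = conservation.retain_motifs(cons, cfg.bls_threshold, cfg.min_hits)
        retained_kmers = sum(1 for r in retention if r.retained)
        _write(conservation.conservation_to_frame(cons),
               outdir / "kmer_conservation.tsv", "conserve", cfg)
        _write(conservation.retention_to_frame(retention),
               outdir / "kmer_retention.tsv", "conserve", cfg)
        log.info("conserve: %d/%d k-mer motifs retained", retained_kmers, len(retention))
        if pwm_hits:
            pwm_instances = [
                conservation.MotifInstance(mid, h.seq_id, h.offset, h.strand)
                for mid, h in pwm_hits
            ]
            pcons = _stage("conserve")(conservation.score_instances)(
                pwm_instances, blocks_by_seq, tree, cfg.ref_species,
                window_slack=cfg.window_slack, pwms=pwms, backgrounds=backgrounds,
                p_threshold=cfg.z_p,
            )
            pret = conservation.retain_motifs(pcons, cfg.bls_threshold, cfg.min_hits)
            retained_pwms = sum(1 for r in pret if r.retained)
            _write(conservation.retention_to_frame(pret),
                   outdir / "pwm_retention.tsv", "conserve", cfg)
    counts["kmer_motifs_retained"] = retained_kmers
    counts["pwm_motifs_retained"] = retained_pwms

    # --- enrichment -------------------------------------------------------
    if cfg.gene_sets_tsv:
        sets = _stage("enrich")(ie.read_gene_sets)(cfg.gene_sets_tsv)
        universe = set(expr.gene_ids)
        target_set = {t.gene_id for t in targets} & universe
        enr = _stage("enrich")(ie.gene_set_enrichment)(target_set, sets, universe)
        counts["enriched_sets_q05"] = sum(1 for r in enr if r.q_value < 0.05)
        _write(ie.enrichment_to_frame(enr), outdir / "enrichment.tsv", "enrich", cfg)
        log.info("enrich: %d/%d sets at q < 0.05", counts["enriched_sets_q05"], len(enr))

    (outdir / "effective_config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return outdir


def _genome_base_freqs(genome: dict[str, str]) -> np.ndarray:
    """A/C/G/T frequencies over the non-repeat (uppercase) genome."""
    counts = np.zeros(4)
    for seq in genome.values():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            counts[i] += int((arr == b).sum())
    if counts.sum() == 0:
        raise ValueError("no unmasked ACGT bases in genome")
    return counts / counts.sum()


def _match_blocks_to_peaks(blocks, peaks) -> dict[str, iof.AlignmentBlock]:
    by_coord = {(b.ref_interval.chrom, b.ref_interval.start, b.ref_interval.end): b
                for b in blocks}
    out = {}
    for p in peaks:
        key = (p.region.chrom, p.region.start, p.region.end)
        if key in by_coord:
            out[p.peak_id] = by_coord[key]
    return out


def _kmer_instances(motifs, peak_seqs) -> list:
    """All occurrences of each discovered k-mer (either strand) in the peaks."""
    out = []
    for m in motifs:
        rc = ma.revcomp(m.kmer)
        for sid in sorted(peak_seqs):
            seq = peak_seqs[sid].upper()
            for off in range(len(seq) - m.k + 1):
                window = seq[off : off + m.k]
                if window == m.kmer:
                    out.append(conservation.MotifInstance(m.kmer, sid, off, "+", m.kmer))
                elif window == rc and rc != m.kmer:
                    out.append(conservation.MotifInstance(m.kmer, sid, off, "-", m.kmer))
    return out


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------


def make_demo(
    seed: int = 7,
    outdir: str | Path = "demo_data",
    cfg: sd.SimConfig | None = None,
    n_background: int = 200_000,
) -> Path:
    """Write a complete synthetic dataset plus config and truth manifest.

    The directory is directly runnable with ``run_pipeline``; two different
    seeds give different genomes with the same schema.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or sd.demo_config(seed)

    genome, mask = sd.generate_genome(cfg)
    genes, peaks, truth, genome = sd.generate_genes_and_peaks(cfg, genome)
    blocks = sd.evolve_alignments(cfg, genome, peaks, truth)
    expr, truth = sd.generate_expression(cfg, genes, truth, peaks=peaks)

    iof.write_fasta(genome, outdir / "genome.fa")
    iof.write_mask_bed(mask, outdir / "mask.bed")
    iof.write_bed(peaks, outdir / "peaks.bed")
    iof.write_gene_table(genes, outdir / "genes.tsv")
    de.write_expression_tsv(expr, outdir / "expr.tsv")
    iof.write_alignment_blocks(blocks, outdir / "alignments.maf")
    (outdir / "tree.nwk").write_text(cfg.tree_newick + "\n")
    pwm_text = resources.files("striatarget.data").joinpath("toy_pwms.txt").read_text()
    (outdir / "pwms.txt").write_text(pwm_text)

    # toy gene-set collection: one set seeded with planted targets, two decoys
    rng = np.random.default_rng([seed, 23])
    planted_ids = [g for g, _ in truth.planted_target_genes]
    all_ids = [g.gene_id for g in genes]
    lines = ["set_id\tgene_id"]
    pathway = planted_ids[:8] + list(
        rng.choice([g for g in all_ids if g not in planted_ids], size=4, replace=False)
    )
    for g in pathway:
        lines.append(f"signaling_toy\t{g}")
    for g in rng.choice(all_ids, size=12, replace=False):
        lines.append(f"decoy_a\t{g}")
    for g in rng.choice(all_ids, size=15, replace=False):
        lines.append(f"decoy_b\t{g}")
    (outdir / "gene_sets.tsv").write_text("\n".join(lines) + "\n")

    pipeline_cfg = {
        "genome_fasta": "genome.fa",
        "peaks_bed": "peaks.bed",
        "genes_tsv": "genes.tsv",
        "expr_tsv": "expr.tsv",
        "alignments_maf": "alignments.maf",
        "tree_newick": "tree.nwk",
        "pwms_file": "pwms.txt",
        "gene_sets_tsv": "gene_sets.tsv",
        "n_background": n_background,
        "min_support": 25,
        "seed": seed,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(pipeline_cfg))

    manifest = {
        "seed": seed,
        "planted_motif": truth.planted_motif,
        "n_planted_peaks": len(truth.motif_positions),
        "motif_positions": [list(t) for t in truth.motif_positions],
        "planted_target_genes": [[g, f] for g, f in truth.planted_target_genes],
        "conserved_species_sets": {
            f"{pid}:{off}:{strand}": sorted(sp)
            for (pid, off, strand), sp in truth.conserved_species_sets.items()
        },
        "sim_config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
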