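"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally.  BED is adopted verbatim;
gene tables declare their convention in a ``#coordinates:`` header line and
are converted at the boundary.  Browser-style 1-based inclusive spans
``[a, b]`` map to ``[a-1, b)``.

Formats handled here: FASTA (lowercase = repeat-masked), BED3/BED5,
a documented tab-delimited gene table, TRANSFAC-style matrix text,
MAF-like multiple-alignment text, Newick trees, and generic TSV tables.
All parsers tolerate ``\\r\\n`` line endings and trailing blank lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "PWMRecord",
    "AlignmentBlock",
    "PhyloTree",
    "from_one_based",
    "to_one_based",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_pwm_file",
    "write_pwm_file",
    "read_alignment_blocks",
    "write_alignment_blocks",
    "read_newick",
    "read_tsv",
    "write_tsv",
]

PWM_ALPHABET = "ACGT"


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A transcript-level gene model: stranded body plus ordered exons."""

    gene_id: str
    symbol: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for exon in self.exons:
            if not self.body.contains_interval(exon):
                raise ValueError(f"gene {self.gene_id}: exon {exon} outside body")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = exon.end


@dataclass(frozen=True)
class Peak:
    """A binding-site call: interval plus optional summit and tag count."""

    peak_id: str
    region: GenomicInterval
    summit_offset: int | None = None
    tag_count: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.region.length
        ):
            raise ValueError(
                f"peak {self.peak_id}: summit_offset {self.summit_offset} "
                f"outside [0, {self.region.length})"
            )
        if self.tag_count is not None and self.tag_count < 0:
            raise ValueError(f"peak {self.peak_id}: negative tag_count")


@dataclass(frozen=True)
class PWMRecord:
    """A count- or weight-form position matrix over A, C, G, T."""

    motif_id: str
    name: str
    matrix: np.ndarray  # L x 4, row order A C G T
    consensus: str
    is_counts: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError(f"motif {self.motif_id}: length {m.shape[0]} < 4")
        if self.is_counts and (m < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if len(self.consensus) != m.shape[0]:
            raise ValueError(f"motif {self.motif_id}: consensus length mismatch")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])


@dataclass(frozen=True)
class AlignmentBlock:
    """One multiple-alignment block anchored on a reference interval.

    ``rows`` maps species name to a gapped sequence over ``ACGTN-``; all rows
    have equal length, and the ungapped reference row spans exactly
    ``ref_interval``.
    """

    ref_interval: GenomicInterval
    ref_species: str
    rows: Mapping[str, str]

    def __post_init__(self) -> None:
        rows = dict(self.rows)
        object.__setattr__(self, "rows", rows)
        if self.ref_species not in rows:
            raise ValueError(f"reference species {self.ref_species!r} missing from rows")
        widths = {len(s) for s in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment rows: widths {sorted(widths)}")
        ref_ungapped = rows[self.ref_species].replace("-", "")
        if len(ref_ungapped) != self.ref_interval.length:
            raise ValueError(
                f"ungapped reference length {len(ref_ungapped)} != "
                f"interval length {self.ref_interval.length}"
            )

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def ref_columns(self) -> np.ndarray:
        """Alignment-column index of each ungapped reference position."""
        row = self.rows[self.ref_species]
        return np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-"))


class PhyloTree:
    """A rooted phylogeny with branch lengths, indexed for fast traversal.

    Nodes are numbered in preorder with the root at 0.  ``parent[i]`` is the
    parent index (-1 for the root) and ``blen[i]`` the length of the edge to
    the parent (0 for the root).  Branch lengths are substitutions/site.
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = list(parent)
        self.blen = [float(b) for b in blen]
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.blen) == len(self.labels) == n):
            raise ValueError("parent/blen/labels length mismatch")
        if any(b < 0 for b in self.blen):
            raise ValueError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self._leaf_index: dict[str, int] = {}
        for i in range(n):
            if not self.children[i]:
                name = self.labels[i]
                if name is None:
                    raise ValueError(f"unlabeled leaf node {i}")
                if name in self._leaf_index:
                    raise ValueError(f"duplicate leaf name {name!r}")
                self._leaf_index[name] = i

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self._leaf_index)

    def leaf_node(self, name: str) -> int:
        try:
            return self._leaf_index[name]
        except KeyError:
            raise ValueError(f"species {name!r} is not a leaf of the tree") from None

    @property
    def total_length(self) -> float:
        return float(sum(self.blen[1:]))

    def leafsets_below(self) -> list[frozenset[str]]:
        """For each node, the set of leaf names in its subtree."""
        out: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes - 1, -1, -1):
            if not self.children[i]:
                out[i].add(self.labels[i])  # type: ignore[arg-type]
            for c in self.children[i]:
                out[i] |= out[c]
        return [frozenset(s) for s in out]

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several exception types
            raise ParseError(f"invalid Newick: {exc}") from exc
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent, blen, labels = [], [], []
        for n in nodes:
            if n.parent_node is None:
                parent.append(-1)
                blen.append(0.0)
            else:
                parent.append(index[id(n.parent_node)])
                length = n.edge.length if n.edge.length is not None else 0.0
                if length < 0:
                    raise ParseError(f"negative branch length {length}")
                blen.append(float(length))
            if n.taxon is not None:
                labels.append(n.taxon.label)
            else:
                labels.append(n.label)
        try:
            return cls(parent, blen, labels)
        except ValueError as exc:
            raise ParseError(str(exc)) from exc

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                return f"{self.labels[i]}:{self.blen[i]:g}"
            inner = ",".join(render(c) for c in self.children[i])
            if i == 0:
                return f"({inner})"
            return f"({inner}):{self.blen[i]:g}"

        return render(0) + ";"


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------


def from_one_based(a: int, b: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span [a, b] to 0-based half-open [a-1, b)."""
    return a - 1, b


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open span [start, end) to 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence map, preserving case.

    Lowercase letters mark repeat-masked positions.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED5 into Peaks.  BED is already 0-based half-open.

    Column 4, if present, is the peak id (auto-generated ``peak_<n>``
    otherwise); column 5 is the tag count.  Duplicate names get an
    auto-suffix so no record is silently dropped.
    """
    peaks: list[Peak] = []
    seen: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
        if name is None:
            name = f"peak_{len(peaks) + 1}"
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        tag_count = None
        if len(fields) >= 5 and fields[4] not in ("", "."):
            try:
                tag_count = int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer score column") from None
        peaks.append(Peak(name, GenomicInterval(chrom, start, end), tag_count=tag_count))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = p.tag_count if p.tag_count is not None else 0
            fh.write(
                f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\t{p.peak_id}\t{score}\n"
            )


def write_mask_bed(mask: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in mask:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

_GENE_COLUMNS = [
    "gene_id",
    "symbol",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "exon_starts",
    "exon_ends",
]

_COORD_DECLARATIONS = ("0based-halfopen", "1based-inclusive")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the documented tab-delimited gene table.

    The first line must declare the coordinate convention, e.g.
    ``#coordinates: 0based-halfopen``; 1-based inclusive coordinates are
    converted at this boundary so everything downstream is half-open.
    """
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines or not lines[0].startswith("#coordinates:"):
        raise ParseError(f"{path}: missing '#coordinates:' declaration line")
    declared = lines[0].split(":", 1)[1].strip()
    if declared not in _COORD_DECLARATIONS:
        raise ParseError(
            f"{path}: unknown coordinate declaration {declared!r}; "
            f"expected one of {_COORD_DECLARATIONS}"
        )
    one_based = declared == "1based-inclusive"
    header = lines[1].split("\t")
    if header != _GENE_COLUMNS:
        raise ParseError(f"{path}: bad header {header}; expected {_GENE_COLUMNS}")
    genes: list[GeneModel] = []
    for lineno, line in enumerate(lines[2:], start=3):
        fields = line.split("\t")
        if len(fields) != len(_GENE_COLUMNS):
            raise ParseError(f"{path}:{lineno}: expected {len(_GENE_COLUMNS)} columns")
        gene_id, symbol, chrom, strand = fields[:4]
        try:
            tx_start, tx_end = int(fields[4]), int(fields[5])
            starts = [int(x) for x in fields[6].split(",") if x != ""]
            ends = [int(x) for x in fields[7].split(",") if x != ""]
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
        if len(starts) != len(ends):
            raise ParseError(f"{path}:{lineno}: exon_starts/exon_ends length mismatch")
        if one_based:
            tx_start, tx_end = from_one_based(tx_start, tx_end)
            pairs = [from_one_based(a, b) for a, b in zip(starts, ends)]
        else:
            pairs = list(zip(starts, ends))
        try:
            body = GenomicInterval(chrom, tx_start, tx_end, strand)
            exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in pairs)
            genes.append(GeneModel(gene_id, symbol, body, exons))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models in the internal (0-based half-open) convention."""
    with open(path, "w") as fh:
        fh.write("#coordinates: 0based-halfopen\n")
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.body.chrom}\t{g.body.strand}\t"
                f"{g.body.start}\t{g.body.end}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# TRANSFAC-style matrices
# ---------------------------------------------------------------------------


def read_pwm_file(path: str | Path) -> list[PWMRecord]:
    """Read TRANSFAC-like matrix blocks.

    Each block is an ``ID`` line, an optional ``NA`` line, numbered rows of
    four numbers plus a consensus letter, and a ``//`` terminator.  ``P0``
    and ``XX`` lines are ignored.
    """
    records: list[PWMRecord] = []
    motif_id: str | None = None
    name = ""
    rows: list[list[float]] = []
    consensus: list[str] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").strip()
            if not line:
                continue
            if line.startswith("ID"):
                motif_id = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
                name, rows, consensus = "", [], []
            elif line.startswith("NA"):
                parts = line.split(None, 1)
                name = parts[1] if len(parts) > 1 else ""
            elif line.startswith(("P0", "PO", "XX", "BF")):
                continue
            elif line == "//":
                if motif_id is None:
                    raise ParseError(f"{path}:{lineno}: '//' before any ID line")
                try:
                    records.append(
                        PWMRecord(
                            motif_id,
                            name,
                            np.array(rows, dtype=float),
                            "".join(consensus),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                motif_id = None
            else:
                if motif_id is None:
                    raise ParseError(f"{path}:{lineno}: matrix row outside a block")
                fields = line.split()
                body = fields[1:]  # drop the position number
                letter = ""
                if body and not _is_number(body[-1]):
                    letter = body[-1]
                    body = body[:-1]
                if len(body) != 4 or not all(_is_number(x) for x in body):
                    raise ParseError(
                        f"{path}:{lineno}: expected 4 numeric fields, got {line!r}"
                    )
                rows.append([float(x) for x in body])
                consensus.append(letter if letter else "N")
    if motif_id is not None:
        raise ParseError(f"{path}: unterminated matrix block {motif_id!r}")
    return records


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_pwm_file(records: Iterable[PWMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"ID {rec.motif_id}\n")
            if rec.name:
                fh.write(f"NA {rec.name}\n")
            fh.write("P0      A      C      G      T\n")
            for i in range(rec.length):
                vals = "  ".join(f"{v:g}" for v in rec.matrix[i])
                fh.write(f"{i + 1:02d}  {vals}  {rec.consensus[i]}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# MAF-like alignment blocks
# ---------------------------------------------------------------------------


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read MAF-like paragraphs: an ``a`` line, then ``s`` rows.

    The first ``s`` row of each block is the reference; its ``src`` field is
    ``species.chrom`` and carries the reference coordinates (0-based start,
    ungapped size).  Non-reference rows may use a bare species name.
    """
    blocks: list[AlignmentBlock] = []
    cur: list[tuple[str, int, int, str]] | None = None

    def flush(cur_rows, lineno):
        if not cur_rows:
            return
        src, start, size, text = cur_rows[0]
        if "." in src:
            species, chrom = src.split(".", 1)
        else:
            species, chrom = src, src
        rows = {species: text}
        for other_src, _, _, other_text in cur_rows[1:]:
            sp = other_src.split(".", 1)[0]
            rows[sp] = other_text
        try:
            blocks.append(
                AlignmentBlock(
                    GenomicInterval(chrom, start, start + size), species, rows
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc

    lineno = 0
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("a"):
                flush(cur, lineno)
                cur = []
            elif line.startswith("s"):
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: 's' line before any 'a' line")
                fields = line.split()
                if len(fields) != 7:
                    raise ParseError(f"{path}:{lineno}: expected 7 fields on 's' line")
                _, src, start, size, strand, _srcsize, text = fields
                try:
                    cur.append((src, int(start), int(size), text.upper()))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            else:
                raise ParseError(f"{path}:{lineno}: unexpected line {line!r}")
    flush(cur, lineno)
    return blocks


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write("a\n")
            iv = b.ref_interval
            ref_text = b.rows[b.ref_species]
            fh.write(
                f"s {b.ref_species}.{iv.chrom} {iv.start} {iv.length} + "
                f"{iv.end} {ref_text}\n"
            )
            for sp, text in b.rows.items():
                if sp == b.ref_species:
                    continue
                size = len(text.replace("-", ""))
                fh.write(f"s {sp} 0 {size} + {size} {text}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Newick / TSV
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV table, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(
    records: pd.DataFrame | Sequence[Mapping],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write records as TSV; ``header_comment`` becomes a leading ``#`` line."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    buf = io.StringIO()
    if header_comment is not None:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
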