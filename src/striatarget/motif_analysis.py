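"""PWM log-odds scanning with an empirically sampled genomic background,
degenerate-consensus search, and exhaustive k-mer discovery.

Scores are log2-odds against a background base composition.  Significance is
a Z-score against the mean/SD of scores at positions sampled uniformly from
the non-repeat (uppercase) part of a genome; the default tail probability is
one-sided upper (a flag gives two-sided).  Windows containing any non-ACGT
base score ``-inf`` and never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import PWMRecord

__all__ = [
    "revcomp",
    "canonical_kmer",
    "LogOddsPWM",
    "BackgroundModel",
    "MotifHit",
    "KmerMotif",
    "build_log_odds",
    "scan_sequence",
    "sample_background",
    "zscore_p",
    "expand_pattern",
    "fraction_containing",
    "discover_kmers",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# base codes: A=0 C=1 G=2 T=3, anything else (incl. N) = 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; case preserved, N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Map a sequence (uppercased) to integer codes A,C,G,T -> 0..3, other -> 4."""
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class LogOddsPWM:
    """An L x 4 log2-odds scoring matrix plus the background it was built on."""

    motif_id: str
    weights: np.ndarray  # L x 4
    background: np.ndarray  # length-4 frequencies, sums to 1
    pseudocount: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)
        if not np.isfinite(w).all():
            raise ValueError(f"motif {self.motif_id}: non-finite weights")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


@dataclass(frozen=True)
class BackgroundModel:
    """Empirical null for one motif's match score: mean, SD, sample size, seed."""

    motif_id: str
    mean: float
    sd: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"motif {self.motif_id}: background sd must be > 0")
        if self.n_samples < 1000:
            raise ValueError(
                f"motif {self.motif_id}: background needs >= 1000 samples, "
                f"got {self.n_samples}"
            )


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM occurrence within one peak sequence."""

    seq_id: str
    offset: int
    strand: str
    score: float
    z: float
    p: float


@dataclass(frozen=True)
class KmerMotif:
    """A discovered k-mer in canonical (strand-collapsed) form."""

    kmer: str
    k: int
    support: int
    rank: int


def build_log_odds(
    record: PWMRecord,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.25,
) -> LogOddsPWM:
    """Turn a count-form matrix into log2-odds weights.

    weight[i][b] = log2( (count[i][b] + pc*bg[b]) / (rowsum[i] + pc) / bg[b] )
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    counts = np.asarray(record.matrix, dtype=float)
    rowsums = counts.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError(f"motif {record.motif_id}: zero count row")
    probs = (counts + pseudocount * bg[None, :]) / (rowsums + pseudocount)[:, None]
    weights = np.log2(probs / bg[None, :])
    return LogOddsPWM(record.motif_id, weights, bg, pseudocount)


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores for every window; windows containing non-ACGT score -inf."""
    L = weights.shape[0]
    w5 = np.column_stack([weights, np.full(L, -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    with np.errstate(invalid="ignore"):
        return w5[np.arange(L), windows].sum(axis=1)


def scan_sequence(
    seq: str, pwm: LogOddsPWM, both_strands: bool = True
) -> list[tuple[int, str, float]]:
    """Score every full window of ``seq``; minus-strand hits are reported in
    plus-strand coordinates (offset of the window's leftmost base).

    Windows containing N (or any non-ACGT base) are dropped.
    """
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < motif length {L}")
    out: list[tuple[int, str, float]] = []
    plus = _window_scores(encode(seq), pwm.weights)
    for off in np.flatnonzero(np.isfinite(plus)):
        out.append((int(off), "+", float(plus[off])))
    if both_strands:
        minus = _window_scores(encode(revcomp(seq)), pwm.weights)
        n_off = len(seq) - L
        for off in np.flatnonzero(np.isfinite(minus)):
            out.append((int(n_off - off), "-", float(minus[off])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def valid_window_starts(genome_seq: str, window: int) -> np.ndarray:
    """Start positions whose full window is uppercase ACGT (non-repeat, no N)."""
    arr = np.frombuffer(genome_seq.encode(), dtype=np.uint8)
    ok = np.zeros(arr.shape, dtype=bool)
    for b in b"ACGT":
        ok |= arr == b
    if len(arr) < window:
        return np.empty(0, dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(ok)])
    counts = csum[window:] - csum[:-window]
    return np.flatnonzero(counts == window).astype(np.int64)


def sample_background(
    pwm: LogOddsPWM,
    genome: Mapping[str, str] | str,
    n: int = 10_000_000,
    seed: int = 0,
    chunk: int = 1_000_000,
) -> BackgroundModel:
    """Empirical score null from ``n`` locations sampled uniformly with
    replacement from the non-repeat (uppercase, N-free) part of the genome.

    ``n`` defaults to ten million but is configurable down for desk-scale
    runs; positions are scored on the plus strand.
    """
    seqs = {"": genome} if isinstance(genome, str) else dict(genome)
    L = pwm.length
    codes_list, starts_list, offsets = [], [], []
    base = 0
    for name in sorted(seqs):
        s = seqs[name]
        starts = valid_window_starts(s, L)
        if len(starts):
            codes_list.append(encode(s))
            starts_list.append(starts + base)
            offsets.append((base, len(s)))
            base += len(s)
    if not starts_list:
        raise ValueError("no valid background positions")
    all_codes = np.concatenate(codes_list) if len(codes_list) > 1 else codes_list[0]
    all_starts = np.concatenate(starts_list)
    if len(all_starts) < 1000:
        raise ValueError(
            f"only {len(all_starts)} valid background positions (< 1000)"
        )
    rng = np.random.default_rng(seed)
    total = 0
    s1 = 0.0
    s2 = 0.0
    remaining = n
    col = np.arange(L)
    while remaining > 0:
        m = min(chunk, remaining)
        pos = rng.choice(all_starts, size=m, replace=True)
        window_codes = all_codes[pos[:, None] + col[None, :]]
        scores = pwm.weights[col, window_codes].sum(axis=1)
        total += m
        s1 += float(scores.sum())
        s2 += float((scores**2).sum())
        remaining -= m
    mean = s1 / total
    var = max(s2 / total - mean**2, 0.0)
    sd = float(np.sqrt(var))
    if sd == 0.0:
        raise ValueError(f"motif {pwm.motif_id}: degenerate background (sd = 0)")
    return BackgroundModel(pwm.motif_id, mean, sd, total, seed)


def zscore_p(
    score: float, bg: BackgroundModel, two_sided: bool = False
) -> tuple[float, float]:
    """Z-score of a match score against the empirical background and its
    normal tail probability (one-sided upper by default)."""
    z = (score - bg.mean) / bg.sd
    p = 2.0 * norm.sf(abs(z)) if two_sided else norm.sf(z)
    return float(z), float(min(p, 1.0))


def scan_with_background(
    seq_id: str,
    seq: str,
    pwm: LogOddsPWM,
    bg: BackgroundModel,
    p_threshold: float = 0.001,
    both_strands: bool = True,
    two_sided: bool = False,
) -> list[MotifHit]:
    """Scan one sequence and keep windows with Z-score p below threshold."""
    hits = []
    for off, strand, score in scan_sequence(seq, pwm, both_strands=both_strands):
        z, p = zscore_p(score, bg, two_sided=two_sided)
        if p < p_threshold:
            hits.append(MotifHit(seq_id, off, strand, score, z, p))
    return hits


# ---------------------------------------------------------------------------
# degenerate patterns and k-mers
# ---------------------------------------------------------------------------


def expand_pattern(pattern: str) -> set[str]:
    """Expand a degenerate consensus into its explicit k-mers.

    ``[XY]`` is a bracket class at one position; ``X/Y`` marks two
    alternative bases at one position ("AGG/TTCA" -> {AGGTCA, AGTTCA}).
    """
    tokens: list[tuple[str, ...]] = []
    i = 0
    n = len(pattern)
    while i < n:
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise ValueError(f"unclosed bracket in pattern {pattern!r}")
            inner = pattern[i + 1 : j]
            if not inner or any(b not in "ACGT" for b in inner):
                raise ValueError(f"bad bracket class {inner!r} in {pattern!r}")
            tokens.append(tuple(inner))
            i = j + 1
        elif c == "/":
            if not tokens or i + 1 >= n or pattern[i + 1] not in "ACGT":
                raise ValueError(f"misplaced '/' in pattern {pattern!r}")
            prev = tokens.pop()
            tokens.append(tuple(sorted(set(prev) | {pattern[i + 1]})))
            i += 2
        elif c in "ACGT":
            tokens.append((c,))
            i += 1
        else:
            raise ValueError(f"invalid character {c!r} in pattern {pattern!r}")
    return {"".join(combo) for combo in product(*tokens)}


def fraction_containing(
    seqs: Sequence[str], kmers: Iterable[str], both_strands: bool = True
) -> float:
    """Fraction of sequences containing at least one of the k-mers on either
    strand (substring match, case-insensitive)."""
    kmers = set(kmers)
    if not kmers:
        raise ValueError("kmers must be non-empty")
    if not seqs:
        raise ValueError("seqs must be non-empty")
    search = set(kmers)
    if both_strands:
        search |= {revcomp(k) for k in kmers}
    n_hit = sum(1 for s in seqs if any(k in s.upper() for k in search))
    return n_hit / len(seqs)


def discover_kmers(
    seqs: Sequence[str],
    k: int,
    min_support: int,
    tiebreak_z: Mapping[str, float] | None = None,
) -> list[KmerMotif]:
    """Exhaustively enumerate canonical k-mers supported by at least
    ``min_support`` distinct sequences (either strand).

    Ranked by support descending, ties broken by background z descending
    when ``tiebreak_z`` is supplied, then lexicographically.  Windows
    containing non-ACGT bases are skipped.
    """
    if not (4 <= k <= 12):
        raise ValueError(f"k must be in [4, 12], got {k}")
    if min_support < 2:
        raise ValueError(f"min_support must be >= 2, got {min_support}")
    if all(len(s) < k for s in seqs):
        raise ValueError(f"all sequences shorter than k = {k}")
    support: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        present = set()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if any(b not in "ACGT" for b in kmer):
                continue
            present.add(canonical_kmer(kmer))
        for kmer in present:
            support[kmer] = support.get(kmer, 0) + 1
    kept = [(kmer, n) for kmer, n in support.items() if n >= min_support]
    z = tiebreak_z or {}
    kept.sort(key=lambda t: (-t[1], -z.get(t[0], 0.0), t[0]))
    return [KmerMotif(kmer, k, n, rank) for rank, (kmer, n) in enumerate(kept, 1)]
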