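"""Independent brute-force oracles.

Everything here is deliberately naive (double loops, exact fractions,
exhaustive enumeration) and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy import stats

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------


def naive_scan(seq: str, weights: np.ndarray, both_strands: bool = True):
    """Double-loop scorer; windows with non-ACGT bases are skipped."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = weights.shape[0]
    seq = seq.upper()
    hits = []

    def score_at(s: str, off: int):
        total = 0.0
        for i in range(L):
            b = s[off + i]
            if b not in base_idx:
                return None
            total += weights[i, base_idx[b]]
        return total

    for off in range(len(seq) - L + 1):
        sc = score_at(seq, off)
        if sc is not None:
            hits.append((off, "+", sc))
    if both_strands:
        rc = naive_revcomp(seq)
        for off in range(len(rc) - L + 1):
            sc = score_at(rc, off)
            if sc is not None:
                hits.append((len(seq) - L - off, "-", sc))
    hits.sort(key=lambda t: (t[0], t[1]))
    return hits


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------


def welch_t(x, y):
    """Hand-computed Welch two-sample t (two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    se2 = vx + vy
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0 if x.mean() == y.mean() else 0.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# BH step-up
# ---------------------------------------------------------------------------


def brute_bh(p_values):
    """q_i = min over j >= rank(i) of p_(j) * n / j, straight from the
    step-up definition."""
    p = list(p_values)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for pos, i in enumerate(order):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(pos, n)
        ]
        q[i] = min(1.0, min(candidates))
    return q


# ---------------------------------------------------------------------------
# exact 2x2 / hypergeometric enumeration
# ---------------------------------------------------------------------------


def _table_prob(a, b, c, d) -> Fraction:
    n = a + b + c + d
    return Fraction(
        math.comb(a + b, a) * math.comb(c + d, c), math.comb(n, a + c)
    )


def fisher_two_tailed_enum(a, b, c, d) -> float:
    """Sum over all same-margin tables at most as probable as observed."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    p_obs = _table_prob(a, b, c, d)
    total = Fraction(0)
    for aa in range(max(0, col1 - row2), min(row1, col1) + 1):
        bb = row1 - aa
        cc = col1 - aa
        dd = row2 - cc
        p = _table_prob(aa, bb, cc, dd)
        # exact fractions: no tolerance needed for the <= comparison
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def hypergeom_upper_enum(a, universe, set_size, n_draws) -> float:
    """P(X >= a) by exact enumeration with fractions."""
    total = Fraction(0)
    for j in range(a, min(set_size, n_draws) + 1):
        if n_draws - j > universe - set_size:
            continue
        total += Fraction(
            math.comb(set_size, j) * math.comb(universe - set_size, n_draws - j),
            math.comb(universe, n_draws),
        )
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Steiner subtree by exhaustive edge-subset enumeration
# ---------------------------------------------------------------------------


def steiner_brute(tree, matched) -> float:
    """Minimum total length over all connected edge subsets whose node set
    contains every matched leaf.  Feasible for trees with <= 8 leaves."""
    matched_nodes = {tree.leaf_node(name) for name in matched}
    if len(matched_nodes) <= 1:
        return 0.0
    edges = [(i, tree.parent[i], tree.blen[i]) for i in range(1, tree.n_nodes)]
    best = math.inf
    for r in range(1, len(edges) + 1):
        if r >= best and best < math.inf:
            pass  # still check: lengths vary, cannot prune on count
        for subset in combinations(edges, r):
            nodes = set()
            for u, v, _ in subset:
                nodes.add(u)
                nodes.add(v)
            if not matched_nodes <= nodes:
                continue
            # connectivity of the chosen edge subgraph
            adj = {n: [] for n in nodes}
            for u, v, _ in subset:
                adj[u].append(v)
                adj[v].append(u)
            start = next(iter(nodes))
            seen = {start}
            stack = [start]
            while stack:
                for w in adj[stack.pop()]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if seen != nodes:
                continue
            total = sum(t for _, _, t in subset)
            best = min(best, total)
    return best


# ---------------------------------------------------------------------------
# peak assignment / location classification
# ---------------------------------------------------------------------------


def naive_assign(peaks, genes, window=10_000, inner=1_000):
    """All-pairs distance scan; returns {(peak_id, gene_id): (signed_d, wclass)}."""
    out = {}
    for p in peaks:
        if p.summit_offset is not None:
            anchor = p.region.start + p.summit_offset
        else:
            anchor = (p.region.start + p.region.end) // 2
        for g in genes:
            if g.body.chrom != p.region.chrom:
                continue
            tss = g.body.start if g.body.strand == "+" else g.body.end - 1
            d = anchor - tss
            if g.body.strand == "-":
                d = -d
            if abs(d) <= window:
                wclass = "within_1kb" if abs(d) <= inner else "within_10kb"
                out[(p.peak_id, g.gene_id)] = (d, wclass)
    return out


def naive_classify(peak, gene) -> str:
    """Interval-algebra reimplementation of the location precedence."""
    tss = gene.body.start if gene.body.strand == "+" else gene.body.end - 1
    ps, pe = peak.region.start, peak.region.end
    if ps <= tss < pe:
        return "tss_overlap"
    for exon in gene.exons:
        if ps < exon.end and exon.start < pe:
            return "exon"
    if gene.body.start <= ps and pe <= gene.body.end:
        return "intron"
    if peak.summit_offset is not None:
        anchor = ps + peak.summit_offset
    else:
        anchor = (ps + pe) // 2
    plus = gene.body.strand == "+"
    if anchor < gene.body.start:
        return "upstream_5prime" if plus else "downstream_3prime"
    if anchor >= gene.body.end:
        return "downstream_3prime" if plus else "upstream_5prime"
    crosses_5p = ps < gene.body.start if plus else pe > gene.body.end
    return "upstream_5prime" if crosses_5p else "downstream_3prime"


# ---------------------------------------------------------------------------
# species matching
# ---------------------------------------------------------------------------


def naive_species_match(block, offset, k, kmer, slack=10):
    """Per-species substring search around the instance's columns."""
    ref_row = block.rows[block.ref_species]
    cols = [i for i, ch in enumerate(ref_row) if ch != "-"]
    c_start = cols[offset]
    c_end = cols[offset + k - 1] + 1
    lo = max(0, c_start - slack)
    hi = min(len(ref_row), c_end + slack)
    targets = {kmer.upper(), naive_revcomp(kmer)}
    matched = {block.ref_species}
    for sp, row in block.rows.items():
        if sp == block.ref_species:
            continue
        window = row[lo:hi].replace("-", "").upper()
        if any(t in window for t in targets):
            matched.add(sp)
    return matched
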