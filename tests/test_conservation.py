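import numpy as np
import pytest

from conftest import random_tree
from oracles import naive_species_match, steiner_brute

from striatarget import synthetic_data as sd
from striatarget.conservation import (
    MotifInstance,
    branch_length_score,
    retain_motifs,
    score_instances,
    species_matches,
    ConservationResult,
)
from striatarget.io_formats import AlignmentBlock, GenomicInterval, PhyloTree
from striatarget.pipeline import _kmer_instances, _match_blocks_to_peaks


def block_of(rows, start=0, ref="ref"):
    width = len(rows[ref].replace("-", ""))
    return AlignmentBlock(GenomicInterval("chr1", start, start + width), ref, rows)


class TestSpeciesMatches:
    def test_identical_rows_all_match(self):
        b = block_of({"ref": "ACGTACGTAC", "sp1": "ACGTACGTAC", "sp2": "ACGTACGTAC"})
        inst = MotifInstance("m", "p", 2, "+", kmer="GTACGT")
        assert species_matches(inst, b) == {"ref", "sp1", "sp2"}

    def test_all_gap_row_never_matches(self):
        b = block_of({"ref": "ACGTACGTAC", "sp1": "----------"})
        inst = MotifInstance("m", "p", 0, "+", kmer="ACGTAC")
        assert species_matches(inst, b) == {"ref"}

    def test_reverse_complement_counts_as_match(self):
        b = block_of({"ref": "AAACCACAAA", "sp1": "AATGTGGTAA"})
        inst = MotifInstance("m", "p", 3, "+", kmer="CCACA")
        assert "sp1" in species_matches(inst, b, window_slack=2)

    def test_instance_outside_block_errors(self):
        b = block_of({"ref": "ACGTACGT"})
        with pytest.raises(ValueError, match="outside"):
            species_matches(MotifInstance("m", "p", 5, "+", kmer="ACGTA"), b)

    def test_matches_naive_oracle_on_synthetic_alignments(self, conserved_data):
        d = conserved_data
        blocks = _match_blocks_to_peaks(d.blocks, d.peaks)
        seqs = sd.peak_sequences(d.genome, d.peaks)
        rng = np.random.default_rng(99)
        checked = 0
        for pid, off, strand in d.truth.motif_positions:
            inst = MotifInstance("m", pid, off, strand, kmer=d.truth.planted_motif)
            got = species_matches(inst, blocks[pid])
            want = naive_species_match(blocks[pid], off, 6, d.truth.planted_motif)
            assert got == want
            checked += 1
        # plus random non-motif instances
        for _ in range(100):
            pid = d.peaks[int(rng.integers(len(d.peaks)))].peak_id
            seq = seqs[pid]
            off = int(rng.integers(0, len(seq) - 6))
            kmer = seq[off : off + 6]
            inst = MotifInstance("m", pid, off, "+", kmer=kmer)
            assert species_matches(inst, blocks[pid]) == naive_species_match(
                blocks[pid], off, 6, kmer
            )
            checked += 1
        assert checked >= 100


class TestBranchLengthScore:
    def test_reference_only_is_zero(self):
        tree = PhyloTree.from_newick("(A:0.1,(B:0.2,C:0.3):0.4);")
        assert branch_length_score(tree, {"A"}, "A") == 0.0

    def test_all_leaves_give_total_length(self):
        tree = PhyloTree.from_newick("(A:0.1,(B:0.2,C:0.3):0.4);")
        got = branch_length_score(tree, {"A", "B", "C"}, "A")
        assert got == pytest.approx(1.0)

    def test_unknown_species_rejected(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError, match="not in tree|not a leaf"):
            branch_length_score(tree, {"A", "X"}, "A")

    def test_matches_exhaustive_subtree_enumeration(self, rng):
        for _ in range(12):
            n_leaves = int(rng.integers(3, 9))
            tree = random_tree(rng, n_leaves)
            leaves = sorted(tree.leaves)
            for _ in range(6):
                size = int(rng.integers(1, n_leaves + 1))
                matched = set(rng.choice(leaves, size=size, replace=False))
                ref = sorted(matched)[0]
                got = branch_length_score(tree, matched, ref)
                want = steiner_brute(tree, matched)
                assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_under_species_addition(self, rng):
        tree = random_tree(rng, 8)
        leaves = sorted(tree.leaves)
        ref = leaves[0]
        matched = {ref}
        prev = 0.0
        for leaf in leaves[1:]:
            matched.add(leaf)
            cur = branch_length_score(tree, matched, ref)
            assert cur >= prev - 1e-12
            prev = cur
        assert prev == pytest.approx(tree.total_length)

    def test_invariant_under_rerooting(self, rng):
        import dendropy

        for _ in range(5):
            tree = random_tree(rng, 7)
            leaves = sorted(tree.leaves)
            matched = set(rng.choice(leaves, size=4, replace=False))
            ref = sorted(matched)[0]
            base = branch_length_score(tree, matched, ref)
            dtree = dendropy.Tree.get(
                data=tree.to_newick(), schema="newick", preserve_underscores=True
            )
            internal = [
                n for n in dtree.preorder_node_iter()
                if not n.is_leaf() and n.parent_node is not None
            ]
            for node in internal[:3]:
                dtree.reroot_at_node(node, update_bipartitions=False)
                rerooted = PhyloTree._from_dendropy(dtree)
                assert rerooted.total_length == pytest.approx(tree.total_length)
                got = branch_length_score(rerooted, matched, ref)
                assert got == pytest.approx(base, abs=1e-9)


class TestRetention:
    def _res(self, motif, seq, bls):
        return ConservationResult(
            MotifInstance(motif, seq, 0, "+", kmer="ACCACA"), frozenset({"ref"}), bls
        )

    def test_four_distinct_peaks_retained(self):
        results = [self._res("m", f"p{i}", 1.5) for i in range(4)]
        (r,) = retain_motifs(results)
        assert r.qualifying_hits == 4 and r.retained

    def test_instances_in_one_peak_count_once(self):
        results = [self._res("m", "p0", 1.5) for _ in range(10)]
        (r,) = retain_motifs(results)
        assert r.qualifying_hits == 1 and not r.retained

    def test_threshold_is_strict(self):
        results = [self._res("m", f"p{i}", 1.0) for i in range(10)]
        (r,) = retain_motifs(results)
        assert r.qualifying_hits == 0

    def test_retention_monotone_in_thresholds(self):
        results = [self._res("m", f"p{i}", 0.5 + i) for i in range(6)]
        for lo_t, hi_t in [(0.4, 2.0), (1.0, 3.0)]:
            lo = retain_motifs(results, bls_threshold=lo_t)[0]
            hi = retain_motifs(results, bls_threshold=hi_t)[0]
            assert hi.qualifying_hits <= lo.qualifying_hits
        lo = retain_motifs(results, min_hits=2)[0]
        hi = retain_motifs(results, min_hits=6)[0]
        assert (not hi.retained) or lo.retained

    def test_conserved_config_retains_planted_motif(self, conserved_data):
        d = conserved_data
        blocks = _match_blocks_to_peaks(d.blocks, d.peaks)
        seqs = sd.peak_sequences(d.genome, d.peaks)
        instances = [
            MotifInstance(d.truth.planted_motif, pid, off, strand, kmer=d.truth.planted_motif)
            for pid, off, strand in d.truth.motif_positions
        ]
        results = score_instances(instances, blocks, d.tree, "ref")
        (r,) = retain_motifs(results)
        assert r.retained
        # fully conserved: every planted instance spans the whole tree
        for res in results:
            assert res.matched_species == d.tree.leaves
            assert res.bls == pytest.approx(d.tree.total_length)

    def test_unconserved_config_drops_planted_motif(self, unconserved_data):
        d = unconserved_data
        blocks = _match_blocks_to_peaks(d.blocks, d.peaks)
        instances = [
            MotifInstance(d.truth.planted_motif, pid, off, strand, kmer=d.truth.planted_motif)
            for pid, off, strand in d.truth.motif_positions
        ]
        results = score_instances(instances, blocks, d.tree, "ref")
        (r,) = retain_motifs(results)
        assert not r.retained

    def test_alien_species_in_alignment_rejected(self, conserved_data):
        d = conserved_data
        blocks = _match_blocks_to_peaks(d.blocks, d.peaks)
        small_tree = PhyloTree.from_newick("(ref:0.1,sp1:0.2);")
        inst = [
            MotifInstance("m", d.peaks[0].peak_id, 0, "+", kmer="ACGTAC")
        ]
        with pytest.raises(ValueError, match="absent from tree"):
            score_instances(inst, blocks, small_tree, "ref")
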