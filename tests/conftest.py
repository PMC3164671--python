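import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from striatarget import synthetic_data as sd
from striatarget.io_formats import PhyloTree

FIXTURE_SEED = 7


@dataclass
class Dataset:
    cfg: sd.SimConfig
    genome: dict
    mask: list
    genes: list
    peaks: list
    truth: sd.SyntheticTruth
    blocks: list
    expr: object
    tree: PhyloTree


def _build(cfg: sd.SimConfig) -> Dataset:
    genome, mask = sd.generate_genome(cfg)
    genes, peaks, truth, genome = sd.generate_genes_and_peaks(cfg, genome)
    blocks = sd.evolve_alignments(cfg, genome, peaks, truth)
    expr, truth = sd.generate_expression(cfg, genes, truth, peaks=peaks)
    tree = PhyloTree.from_newick(cfg.tree_newick)
    return Dataset(cfg, genome, mask, genes, peaks, truth, blocks, expr, tree)


@pytest.fixture(scope="session")
def conserved_data() -> Dataset:
    """The standard fixture: motif planted in 30/50 peaks, fully conserved."""
    return _build(sd.fixture_config(FIXTURE_SEED, conserved=True))


@pytest.fixture(scope="session")
def unconserved_data() -> Dataset:
    """Identical planting, deep tree, motif sites drift freely."""
    return _build(sd.fixture_config(FIXTURE_SEED, conserved=False))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """A random binary tree with uniform branch lengths, via random joins."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    newicks = {n: n for n in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        merged = f"({newicks[a]}:{la:.4f},{newicks[b]}:{lb:.4f})"
        name = f"I{len(newicks)}"
        newicks[name] = merged
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [name]
    return PhyloTree.from_newick(newicks[nodes[0]] + ";")
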