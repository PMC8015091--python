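"""Shared fixtures: random DNA, planted similarity matrices, random trees."""

import numpy as np
import pytest

from wgks import CorrelationMatrix, GenomeSequence, TreeNode


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_genome():
    return GenomeSequence("toy", ["AAAA"])


def planted_matrix(n_per_block, within, between, noise=0.0, seed=0, prefix="sp"):
    """Block-structured similarity matrix with optional symmetric noise.

    ``n_per_block`` is a list of block sizes; entries are ``within`` inside
    a block and ``between`` across blocks, perturbed by N(0, noise).
    """
    rng = np.random.default_rng(seed)
    n = sum(n_per_block)
    block_of = np.repeat(np.arange(len(n_per_block)), n_per_block)
    M = np.where(block_of[:, None] == block_of[None, :], within, between)
    if noise:
        eps = rng.normal(0.0, noise, size=(n, n))
        M = M + (eps + eps.T) / 2.0
    M = np.clip(M, -0.999, 0.999)
    np.fill_diagonal(M, 1.0)
    labels = [f"{prefix}{i:02d}" for i in range(n)]
    truth = {l: int(b) for l, b in zip(labels, block_of)}
    return CorrelationMatrix(labels=tuple(labels), values=M, kind="pcc"), truth


def random_tree(rng, n_leaves, min_bl=0.01, max_bl=1.0):
    """Random binary tree with positive branch lengths and labeled leaves."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(
            TreeNode(children=[(a, float(rng.uniform(min_bl, max_bl))),
                               (b, float(rng.uniform(min_bl, max_bl)))])
        )
    return nodes[0]
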