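"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from domgain.config import ThresholdConfig
from domgain.io_model import (
    DomainHit,
    ExonModel,
    GeneFamily,
    GeneTree,
    Transcript,
    TreeNode,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def smith_waterman_oracle(query: str, target: str, matrix, gap_open: float,
                          gap_extend: float) -> float:
    """Quadratic-space affine-gap local alignment score (Gotoh recursion).

    Gap of length k costs ``gap_open + (k - 1) * gap_extend`` (the first gap
    position pays the open penalty).  Written independently of any alignment
    library; used to verify the production aligner's scores exactly.
    """
    m, n = len(query), len(target)
    neg = float("-inf")
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), neg)  # gap in target (query consumed)
    F = np.full((m + 1, n + 1), neg)  # gap in query
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            s = matrix[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sankoff_cost_oracle(tree: GeneTree, leaf_states: dict[str, int],
                        gain_cost: float, loss_cost: float) -> float:
    """Minimum total cost over *all* internal labellings, by enumeration."""
    internal = [n for n in tree.root.walk() if not n.is_leaf]
    parents = tree.parent_map()
    best = float("inf")
    for states in itertools.product((0, 1), repeat=len(internal)):
        labels = {id(n): s for n, s in zip(internal, states)}
        for leaf in tree.leaves():
            labels[id(leaf)] = leaf_states[leaf.name]
        cost = 0.0
        for node in tree.root.walk():
            parent = parents[id(node)]
            if parent is None:
                continue
            p, c = labels[id(parent)], labels[id(node)]
            if p == 0 and c == 1:
                cost += gain_cost
            elif p == 1 and c == 0:
                cost += loss_cost
        best = min(best, cost)
    return best


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       prefix: str = "g") -> GeneTree:
    """Random rooted binary tree with species-tagged leaves."""
    counter = itertools.count()

    def build(leaf_ids: list[int]) -> TreeNode:
        if len(leaf_ids) == 1:
            return TreeNode(
                name=f"{prefix}{leaf_ids[0]}",
                branch_length=float(rng.uniform(0.05, 1.0)),
                node_kind="leaf",
                species="human",
            )
        k = int(rng.integers(1, len(leaf_ids)))
        kind = "duplication" if rng.random() < 0.5 else "speciation"
        return TreeNode(
            name=f"i{next(counter)}",
            children=[build(leaf_ids[:k]), build(leaf_ids[k:])],
            branch_length=float(rng.uniform(0.05, 1.0)),
            node_kind=kind,
        )

    root = build(list(range(n_leaves)))
    root.branch_length = 0.0
    return GeneTree(root)


def presence_stub(tree: GeneTree, states: dict[str, int]):
    """PresenceMatrix for one character ("PF1") from a leaf-state dict."""
    from domgain.gain_inference import PresenceMatrix

    return PresenceMatrix(
        genes=tuple(tree.leaf_names()),
        characters=("PF1",),
        data={(g, "PF1"): s for g, s in states.items() if s},
    )


# ---------------------------------------------------------------------------
# family construction helpers
# ---------------------------------------------------------------------------


def make_leaf(name: str, species: str = "human", bl: float = 1.0) -> TreeNode:
    return TreeNode(name=name, branch_length=bl, node_kind="leaf",
                    species=species)


def make_family(
    tree: GeneTree,
    sequences: dict[str, str],
    hits: list[DomainHit],
    species: dict[str, str] | None = None,
    exon_models: dict[str, ExonModel] | None = None,
) -> GeneFamily:
    """One-transcript-per-gene family over the given tree."""
    transcripts = {}
    for leaf in tree.leaves():
        g = leaf.name
        tid = f"{g}_t1"
        transcripts[g] = [
            Transcript(
                transcript_id=tid,
                gene_id=g,
                species=(species or {}).get(g, leaf.species or "human"),
                protein_sequence=sequences[g],
                exon_model=(exon_models or {}).get(g),
            )
        ]
    return GeneFamily(
        family_id="fam1", tree=tree, transcripts=transcripts, hits=hits
    )


@pytest.fixture
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
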