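"""Random tree/pattern generators shared by the tests."""

from __future__ import annotations

import numpy as np

from homoplasy.io import Node, PhyloTree

AMBIGUOUS = "NRYSWKMBDHV-U"


def random_binary_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Uniform random joins of labelled tips into a rooted binary tree."""
    nodes = [Node(label=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(Node(children=[left, right]))
    return PhyloTree(nodes[0])


def random_polytomy_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random joins of 2-4 nodes at a time, producing multifurcations."""
    nodes = [Node(label=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        k = min(len(nodes), int(rng.integers(2, 5)))
        picks = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        children = [nodes.pop(i) for i in picks][::-1]
        nodes.append(Node(children=children))
    return PhyloTree(nodes[0])


def random_pattern(rng: np.random.Generator, labels: list[str],
                   p_ambiguous: float = 0.2) -> dict[str, str]:
    """One random site: mostly A/C/G/T, sometimes an ambiguity code or gap."""
    out = {}
    for lab in labels:
        if rng.random() < p_ambiguous:
            out[lab] = AMBIGUOUS[rng.integers(len(AMBIGUOUS))]
        else:
            out[lab] = "ACGT"[rng.integers(4)]
    return out


def pattern_alignment(patterns: list[dict[str, str]], labels: list[str]):
    """Stack per-site patterns into an Alignment (sites in list order)."""
    from homoplasy.io import Alignment

    return Alignment([(lab, "".join(p[lab] for p in patterns)) for lab in labels])
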