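"""Per-site parsimony tree lengths, consistency index and homoplasy flagging.

The per-site minimum number of state changes ("tree length") is computed
with a Fitch-style set downpass: tips carry the IUPAC expansion of their
character as a subset of {A,C,G,T}; each internal node folds over its
children taking the intersection of state sets when it is non-empty and
otherwise the union, counting one change per union step. The consistency
index of a site is then

    CI = (number of distinct observed nucleotides - 1) / tree length

so CI = 1 means the site fits the tree perfectly and CI < 1 flags the
site as homoplasious. Invariant sites (fewer than two distinct observed
nucleotides) are defined to have CI = 1 and are never flagged.

On binary trees the downpass is exact, which :func:`oracle_min_changes`
verifies by enumeration. At a multifurcation the left-to-right fold
solves the node's ladderized binary resolution instead (Hartigan's
algorithm would be exact for the multifurcation itself), so there it
can report fewer changes than the multifurcating tree strictly needs —
never more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import HomoplasyError, InputError, LabelMismatchError
from .io import Alignment, Node, PhyloTree

__all__ = [
    "IUPAC_SETS",
    "expand_state",
    "fitch_site_lengths",
    "consistency_index",
    "find_homoplasies",
    "oracle_min_changes",
    "SiteConsistency",
    "HomoplasyResult",
]

_BASES = "ACGT"
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

# IUPAC nucleotide codes -> subset of {A,C,G,T}. 'N' and gap '-' carry no
# information and expand to all four; 'U' is treated as 'T'.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("ACGT"),
}

_CHAR_MASK = {
    c: np.uint8(sum(_BASE_BIT[b] for b in s)) for c, s in IUPAC_SETS.items()
}

# byte -> 4-bit state mask; 0 marks an invalid character
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _CHAR_MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m


def expand_state(character: str) -> frozenset[str]:
    """Expand one alignment character into its set of possible nucleotides."""
    try:
        return IUPAC_SETS[character.upper()]
    except KeyError:
        raise InputError(
            f"invalid alignment character {character!r}: not a nucleotide, "
            "IUPAC ambiguity code, 'N' or '-'"
        ) from None


def _encode_rows(alignment: Alignment) -> dict[str, np.ndarray]:
    """Per label, the per-site 4-bit state masks; loud error on bad characters."""
    rows: dict[str, np.ndarray] = {}
    for label in alignment.labels:
        seq = alignment.sequences[label]
        raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
        masks = _MASK_LUT[raw]
        if masks.size and not masks.all():
            i = int(np.argmin(masks != 0))
            raise InputError(
                f"invalid character {seq[i]!r} in sequence '{label}' at site {i + 1}"
            )
        rows[label] = masks
    return rows


def _check_labels(tree: PhyloTree, alignment: Alignment) -> None:
    tree_labels = set(tree.tip_labels())
    aln_labels = set(alignment.labels)
    if tree_labels != aln_labels:
        only_tree = sorted(tree_labels - aln_labels)
        only_aln = sorted(aln_labels - tree_labels)
        raise LabelMismatchError(
            "tree tips and alignment labels differ; "
            f"only in tree: {only_tree or 'none'}; only in alignment: {only_aln or 'none'}"
        )


def _downpass(
    tree: PhyloTree, alignment: Alignment
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Run the set downpass over every site at once.

    Returns the per-site tree lengths and, per internal node (keyed by
    ``id(node)``), the boolean per-site vector of whether folding that
    node's children took at least one union step at the site.
    """
    _check_labels(tree, alignment)
    rows = _encode_rows(alignment)
    n_sites = alignment.length
    lengths = np.zeros(n_sites, dtype=np.int64)
    union_at: dict[int, np.ndarray] = {}
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            masks[id(node)] = rows[node.label]
            continue
        children = node.children
        running = masks.pop(id(children[0]))
        took_any = np.zeros(n_sites, dtype=bool)
        for child in children[1:]:
            m = masks.pop(id(child))
            inter = running & m
            took = inter == 0
            lengths += took
            running = np.where(took, running | m, inter)
            took_any |= took
        masks[id(node)] = running
        union_at[id(node)] = took_any
    return lengths, union_at


def fitch_site_lengths(tree: PhyloTree, alignment: Alignment) -> np.ndarray:
    """Minimum number of state changes on ``tree`` for every alignment site.

    Requires a strict 1:1 match between tree tip labels and alignment
    labels; raises :class:`LabelMismatchError` listing the differences
    otherwise.
    """
    lengths, _ = _downpass(tree, alignment)
    return lengths


def consistency_index(tree_length: int, n_states: int) -> float:
    """Consistency index of one site from its tree length and number of
    distinct observed (unambiguous) nucleotides."""
    if tree_length < 0 or n_states < 0:
        raise InputError("tree_length and n_states must be non-negative")
    if n_states <= 1:
        return 1.0
    if tree_length == 0:
        raise HomoplasyError(
            f"impossible site: {n_states} distinct states but 0 changes on the tree"
        )
    return (n_states - 1) / tree_length


@dataclass(frozen=True)
class SiteConsistency:
    """Per-site consistency record (positions are 1-based)."""

    position: int
    tree_length: int
    n_states: int
    consistency_index: float
    is_inconsistent: bool
    counts: tuple[int, int, int, int]  # occurrences of A, C, G, T among tips


@dataclass
class HomoplasyResult:
    """Everything the detector produces for one tree/alignment pair."""

    sites: list[SiteConsistency]
    annotated_tree: PhyloTree
    filtered_alignment: Alignment

    @property
    def flagged_positions(self) -> list[int]:
        return [s.position for s in self.sites if s.is_inconsistent]


def _site_counts(alignment: Alignment) -> np.ndarray:
    """(4, n_sites) counts of unambiguous A/C/G/T tip characters per site."""
    rows = _encode_rows(alignment)
    stack = np.stack([rows[lab] for lab in alignment.labels])
    counts = np.empty((4, alignment.length), dtype=np.int64)
    for k, base in enumerate(_BASES):
        counts[k] = (stack == _BASE_BIT[base]).sum(axis=0)
    return counts


def find_homoplasies(tree: PhyloTree, alignment: Alignment) -> HomoplasyResult:
    """Score every site, flag the inconsistent ones, and build the three
    artifacts: per-site records, an annotated copy of the tree, and the
    alignment with flagged sites removed.

    An internal node is annotated with a flagged site's 1-based position
    iff the downpass took at least one union step (i.e. required a state
    change) at that node for that site.
    """
    annotated = tree.copy()
    lengths, union_at = _downpass(annotated, alignment)
    counts = _site_counts(alignment)
    n_states = (counts > 0).sum(axis=0)

    sites: list[SiteConsistency] = []
    flagged0: list[int] = []
    for i in range(alignment.length):
        ci = consistency_index(int(lengths[i]), int(n_states[i]))
        inconsistent = ci < 1.0
        if inconsistent:
            flagged0.append(i)
        sites.append(
            SiteConsistency(
                position=i + 1,
                tree_length=int(lengths[i]),
                n_states=int(n_states[i]),
                consistency_index=ci,
                is_inconsistent=inconsistent,
                counts=tuple(int(c) for c in counts[:, i]),
            )
        )

    flagged_arr = np.array(flagged0, dtype=np.int64)
    for node in annotated.internal_nodes():
        took = union_at.get(id(node))
        if took is None:
            node.annotation = None
            continue
        here = flagged_arr[took[flagged_arr]] if flagged_arr.size else flagged_arr
        node.annotation = ",".join(str(p + 1) for p in here) if here.size else None

    filtered = alignment.drop_sites(set(flagged0))
    return HomoplasyResult(sites=sites, annotated_tree=annotated, filtered_alignment=filtered)


_MAX_ORACLE_TIPS = 12


def oracle_min_changes(tree: PhyloTree, site_states: dict[str, object]) -> int:
    """Exact minimum number of changes at one site by brute enumeration.

    ``site_states`` maps each tip label to either a single character
    (expanded through the IUPAC table) or an explicit set of allowed
    nucleotides. Every assignment of one nucleotide per internal node is
    enumerated; an edge to a tip costs 0 iff the parent's state is in
    the tip's allowed set. Only feasible for small trees (<= 12 tips);
    serves as an independent check of the downpass, which it must match
    exactly on binary trees.
    """
    if tree.n_tips > _MAX_ORACLE_TIPS:
        raise InputError(
            f"oracle enumeration refused for > {_MAX_ORACLE_TIPS} tips"
        )
    allowed: dict[str, np.ndarray] = {}
    for label, states in site_states.items():
        chars = expand_state(states) if isinstance(states, str) else states
        vec = np.zeros(4, dtype=bool)
        for c in chars:
            vec[_BASES.index(c)] = True
        if not vec.any():
            raise InputError(f"tip '{label}' has an empty state set")
        allowed[label] = vec

    internals = tree.internal_nodes()
    index = {id(n): i for i, n in enumerate(internals)}
    n_int = len(internals)
    n_assign = 4**n_int
    assign = np.empty((n_assign, n_int), dtype=np.int8)
    base = np.arange(n_assign)
    for k in range(n_int):
        assign[:, k] = (base // 4**k) % 4

    cost = np.zeros(n_assign, dtype=np.int64)
    for node in internals:
        p = assign[:, index[id(node)]]
        for child in node.children:
            if child.is_tip:
                cost += ~allowed[child.label][p]
            else:
                cost += p != assign[:, index[id(child)]]
    return int(cost.min())
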