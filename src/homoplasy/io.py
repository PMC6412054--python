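"""Reading and writing the formats the tool touches.

Three surfaces: rooted Newick trees (with ``[&homoplasy=...]`` node
annotations in the BEAST/FigTree comment dialect), FASTA nucleotide
alignments, and the per-site CSV consistency report.

Newick parsing is delegated to dendropy; serialization is done here so
that node annotations land immediately after the node's closing element
(before the colon), where FigTree, icytree and ape expect them.
"""

from __future__ import annotations

import csv
import io as _stdio
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy
from Bio import SeqIO

from .errors import AlignmentError, InputError, NewickParseError

__all__ = [
    "Node",
    "PhyloTree",
    "Alignment",
    "read_newick",
    "read_newick_string",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "format_report",
    "write_report",
]

# characters that force quoting of a label in Newick output
_NEWICK_SPECIALS = set("(),:;[]' \t\n")


@dataclass
class Node:
    """One node of a rooted phylogeny.

    ``annotation`` is an arbitrary string attached to the node; for
    homoplasy output it holds the comma-separated 1-based positions of
    the flagged sites whose downpass required a change at this node.
    """

    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float | None = None
    annotation: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class PhyloTree:
    """A rooted tree of named tips; supports post-order traversal and
    per-node annotation strings.

    Invariants enforced on construction: unique, non-empty tip labels;
    no unary internal nodes (they are collapsed by :func:`read_newick`).
    """

    def __init__(self, root: Node):
        self.root = root
        labels = [tip.label for tip in self.tips()]
        if any(not lab for lab in labels):
            raise InputError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dups = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise InputError(f"duplicate tip labels: {', '.join(dups)}")

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            return Node(
                label=node.label,
                children=[_copy(c) for c in node.children],
                length=node.length,
                annotation=node.annotation,
            )

        return PhyloTree(_copy(self.root))

    def __str__(self) -> str:
        return _serialize_newick(self.root) + ";"


class Alignment:
    """An ordered multiple nucleotide alignment keyed by label.

    Sequences are stored upper-case; all must have identical length.
    """

    def __init__(self, records: dict[str, str] | list[tuple[str, str]]):
        items = list(records.items()) if isinstance(records, dict) else list(records)
        if not items:
            raise AlignmentError("alignment contains no records")
        labels = [lab for lab, _ in items]
        if len(set(labels)) != len(labels):
            dups = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise InputError(f"duplicate sequence labels: {', '.join(dups)}")
        seqs = [seq.upper() for _, seq in items]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            ref = len(seqs[0])
            bad = [lab for lab, s in zip(labels, seqs) if len(s) != ref]
            raise AlignmentError(
                "sequences are not all the same length; offending labels "
                f"(vs '{labels[0]}' of length {ref}): {', '.join(bad)}"
            )
        self.labels: list[str] = labels
        self.sequences: dict[str, str] = dict(zip(labels, seqs))
        self.length: int = len(seqs[0])

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> str:
        return self.sequences[label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.labels == other.labels and self.sequences == other.sequences

    def drop_sites(self, positions: set[int]) -> "Alignment":
        """Return a copy without the given 0-based site indices."""
        keep = [i for i in range(self.length) if i not in positions]
        if not keep and self.length:
            warnings.warn("all sites removed; writing a 0-site alignment", stacklevel=2)
        records = [
            (lab, "".join(self.sequences[lab][i] for i in keep)) for lab in self.labels
        ]
        out = object.__new__(Alignment)
        out.labels = [lab for lab, _ in records]
        out.sequences = dict(records)
        out.length = len(keep)
        return out


# ---------------------------------------------------------------------------
# Newick


def _from_dendropy(nd: dendropy.Node) -> Node:
    label = nd.taxon.label if nd.taxon is not None else nd.label
    annotation = None
    for comment in nd.comments:
        text = comment.lstrip("&")
        annotation = text[len("homoplasy=") :] if text.startswith("homoplasy=") else text
    return Node(
        label=label,
        children=[_from_dendropy(c) for c in nd.child_nodes()],
        length=nd.edge.length,
        annotation=annotation,
    )


def _collapse_unary(node: Node) -> Node:
    """Splice out internal nodes with exactly one child, summing branch lengths."""
    node.children = [_collapse_unary(c) for c in node.children]
    if len(node.children) == 1:
        child = node.children[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        return child
    return node


def read_newick(path: str | Path) -> PhyloTree:
    """Read a single rooted Newick tree from a file.

    The tree is used as written — no re-rooting is performed. Unary
    internal nodes are collapsed (their branch lengths summed) since
    they carry no parsimony information.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise InputError(f"empty Newick file: {path}")
    return read_newick_string(text, source=str(path))


def read_newick_string(text: str, source: str = "<string>") -> PhyloTree:
    """Parse a Newick string; see :func:`read_newick`."""
    if not text.strip():
        raise InputError(f"empty Newick input: {source}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises many DataError subclasses
        raise NewickParseError(
            f"malformed Newick in {source}: {exc}",
            line=getattr(exc, "line_num", None),
            column=getattr(exc, "col_num", None),
        ) from exc
    root = _collapse_unary(_from_dendropy(dtree.seed_node))
    return PhyloTree(root)


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_SPECIALS for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _serialize_newick(node: Node) -> str:
    parts = ""
    if node.children:
        parts = "(" + ",".join(_serialize_newick(c) for c in node.children) + ")"
    if node.label:
        parts += _quote_label(node.label)
    if node.annotation:
        parts += f"[&homoplasy={node.annotation}]"
    if node.length is not None:
        parts += f":{node.length!r}"
    return parts


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write a tree as Newick; annotated nodes get ``[&homoplasy=...]``
    comment blocks immediately after the node's closing element."""
    Path(path).write_text(str(tree) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Alignment:
    """Read a FASTA alignment; wrapped lines are joined, case is
    normalized to upper, the label is the header text up to the first
    whitespace."""
    with open(path) as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    """Write an alignment as FASTA, wrapping sequence lines at ``width``."""
    if alignment.length == 0:
        warnings.warn(
            "writing a FASTA file whose sequences have zero sites", stacklevel=2
        )
    with open(path, "w") as handle:
        for label in alignment.labels:
            handle.write(f">{label}\n")
            seq = alignment.sequences[label]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            if not seq:
                handle.write("\n")


# ---------------------------------------------------------------------------
# CSV report

REPORT_COLUMNS = [
    "Position",
    "ConsistencyIndex",
    "MinimumNumberChangesOnTree",
    "CountsACGT",
]


def format_report(records, include_consistent: bool = False) -> str:
    """Render SiteConsistency records as CSV text (header always present)."""
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(REPORT_COLUMNS)
    for rec in records:
        if not (include_consistent or rec.is_inconsistent):
            continue
        writer.writerow(
            [
                rec.position,
                f"{rec.consistency_index:g}",
                rec.tree_length,
                ":".join(str(c) for c in rec.counts),
            ]
        )
    return buf.getvalue()


def write_report(records, path: str | Path, include_consistent: bool = False) -> None:
    """Write the per-site consistency report: one row per inconsistent
    site, or per site when ``include_consistent`` is set."""
    Path(path).write_text(format_report(records, include_consistent))
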