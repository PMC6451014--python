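"""Readers/writers for alignments, distance matrices, trees and annotations.

All readers validate strictly: they never silently repair invalid data.
The only whitelisted repairs are case folding of amino-acid codes and the
'.' -> '-' gap synonym, both applied (and logged at DEBUG level) at parse
time.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from seqspace.errors import FormatError, ValidationError

log = logging.getLogger(__name__)

AA20 = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = set(AA20) | {"X", "-"}

#: characters not allowed in taxon identifiers (whitespace + newick-reserved)
_BAD_TAXON_CHARS = re.compile(r"[\s,:;()\[\]']")


# ---------------------------------------------------------------------------
# Msa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Msa:
    """An aligned set of protein sequences.

    Rows are upper-case strings over the 20 canonical amino acids plus
    ``X`` (ambiguous) and ``-`` (gap); all rows share the same length.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValidationError("taxa and rows differ in count")
        if not self.taxa:
            raise ValidationError("empty alignment")
        seen: set[str] = set()
        for name in self.taxa:
            if not name:
                raise ValidationError("empty taxon identifier")
            if _BAD_TAXON_CHARS.search(name):
                raise ValidationError(
                    f"taxon {name!r} contains whitespace or newick-reserved characters"
                )
            if name in seen:
                raise ValidationError(f"duplicate taxon {name!r}")
            seen.add(name)
        n = len(self.rows[0])
        if n < 1:
            raise ValidationError("alignment has zero columns")
        for name, row in zip(self.taxa, self.rows):
            if len(row) != n:
                raise ValidationError(
                    f"alignment-length mismatch: taxon {name!r} has {len(row)} "
                    f"columns, expected {n}"
                )
            for pos, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise ValidationError(
                        f"illegal character {ch!r} in taxon {name!r} at column {pos + 1}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def _normalize_row(raw: str, taxon: str) -> str:
    up = raw.upper()
    if up != raw:
        log.debug("case-folded sequence of %s", taxon)
    if "." in up:
        log.debug("'.' treated as gap in %s", taxon)
        up = up.replace(".", "-")
    return up


def _sniff_alignment_format(path: str) -> str:
    with open(path) as fh:
        head = fh.readline()
    if head.startswith(">"):
        return "fasta"
    if head.upper().startswith("CLUSTAL"):
        return "clustal"
    parts = head.split()
    if len(parts) == 2 and all(p.isdigit() for p in parts):
        return "phylip"
    raise FormatError(f"cannot auto-detect alignment format of {path}")


def read_msa(path: str, format: str = "auto") -> Msa:
    """Read an alignment in FASTA, PHYLIP (strict or relaxed) or Clustal.

    Case is folded to upper and ``.`` is accepted as a gap synonym; any
    other deviation from the alphabet is an error naming the taxon and
    column.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_alignment_format(path)
    if format not in ("fasta", "phylip", "clustal"):
        raise ValueError(f"unknown alignment format {format!r}")

    if format == "phylip":
        aln = _read_phylip(path)
    else:
        try:
            aln = AlignIO.read(path, format)
        except ValueError as exc:
            msg = str(exc)
            if "same length" in msg or "length" in msg:
                raise ValidationError(f"alignment-length error in {path}: {msg}") from exc
            raise FormatError(f"cannot parse {path} as {format}: {msg}") from exc

    taxa = [rec.id for rec in aln]
    rows = [_normalize_row(str(rec.seq), rec.id) for rec in aln]
    return Msa(tuple(taxa), tuple(rows))


def _read_phylip(path: str) -> MultipleSeqAlignment:
    # Relaxed dialect first (names of any length, whitespace-delimited);
    # fall back to strict 10-column names.
    for schema in ("phylip-relaxed", "phylip"):
        try:
            with open(path) as fh:
                return AlignIO.read(fh, schema)
        except ValueError:
            continue
    raise FormatError(f"cannot parse {path} as strict or relaxed PHYLIP")


def write_msa(msa: Msa, path: str, format: str = "fasta") -> None:
    """Write an alignment in FASTA, relaxed PHYLIP or Clustal."""
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(msa.taxa, msa.rows)
    ]
    aln = MultipleSeqAlignment(records)
    schema = {"fasta": "fasta", "phylip": "phylip-relaxed", "clustal": "clustal"}[format]
    AlignIO.write(aln, path, schema)


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of original-space distances (substitutions/site).

    ``saturated`` holds unordered label pairs whose distance hit the cap.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    saturated: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if vals.shape != (n, n):
            raise ValidationError(
                f"matrix order {vals.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite distance entry")
        if np.any(vals < 0):
            raise ValidationError("negative distance entry")
        if np.any(np.abs(np.diag(vals)) > 0):
            raise ValidationError("non-zero diagonal")
        if not np.allclose(vals, vals.T, rtol=0, atol=1e-12):
            raise ValidationError("matrix is not symmetric")
        vals.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.saturated)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed (i<j row-major) order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


def write_distance_matrix(dm: DistanceMatrix, path: str, dialect: str = "phylip_square") -> None:
    """Write a distance matrix.

    ``phylip_square`` is the protdist interchange dialect: first line is the
    taxon count, each row a name padded/truncated to 10 characters followed
    by the distances in fixed 6-decimal notation. Name truncation collisions
    are a hard error. ``tsv`` writes a full matrix with a label header.
    """
    if dialect == "phylip_square":
        short = [name[:10] for name in dm.labels]
        if len(set(short)) != len(short):
            dupes = sorted({s for s in short if short.count(s) > 1})
            raise ValidationError(
                f"taxon names collide after 10-character truncation: {dupes}"
            )
        with open(path, "w") as fh:
            fh.write(f"{dm.n:5d}\n")
            for i, name in enumerate(short):
                row = " ".join(f"{dm.values[i, j]:.6f}" for j in range(dm.n))
                fh.write(f"{name:<10s} {row}\n")
    elif dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(("",) + dm.labels) + "\n")
            for i, name in enumerate(dm.labels):
                row = "\t".join(f"{dm.values[i, j]:.10g}" for j in range(dm.n))
                fh.write(f"{name}\t{row}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str, dialect: str = "phylip_square") -> DistanceMatrix:
    """Read a distance matrix (protdist square, lower-triangle, or TSV).

    Asymmetries up to 1e-6 are symmetrized by averaging; larger ones are an
    error, as are negative entries and header/row count mismatches.
    """
    if dialect == "phylip_square":
        labels, mat = _read_phylip_matrix(path)
    elif dialect == "tsv":
        labels, mat = _read_tsv_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if np.any(mat < 0):
        raise ValidationError(f"negative distance entry in {path}")
    asym = float(np.max(np.abs(mat - mat.T))) if mat.size else 0.0
    if asym > 1e-6:
        raise ValidationError(f"asymmetry {asym:g} exceeds 1e-6 in {path}")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(tuple(labels), mat)


def _read_phylip_matrix(path: str) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path} is empty")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise FormatError(f"{path}: first line must be the taxon count") from exc

    # Token stream; rows may wrap across physical lines.
    tokens: list[str] = []
    for ln in lines[1:]:
        tokens.extend(ln.split())

    labels: list[str] = []
    rows: list[list[float]] = []
    i = 0
    while i < len(tokens):
        label = tokens[i]
        i += 1
        vals: list[float] = []
        while i < len(tokens):
            try:
                vals.append(float(tokens[i]))
            except ValueError:
                break
            i += 1
            # square rows carry n values; lower-triangle row r carries r
            if len(vals) == n:
                break
        labels.append(label)
        rows.append(vals)

    if len(labels) != n:
        raise FormatError(
            f"{path}: header declares {n} taxa but {len(labels)} rows found"
        )
    counts = [len(r) for r in rows]
    mat = np.zeros((n, n))
    if counts == [n] * n:
        mat[:] = np.array(rows)
    elif counts == list(range(n)):
        for r, vals in enumerate(rows):
            for c, v in enumerate(vals):
                mat[r, c] = v
                mat[c, r] = v
    else:
        raise FormatError(
            f"{path}: rows are neither square (n values each) nor lower-triangle"
        )
    return labels, mat


def _read_tsv_matrix(path: str) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    labels = header[1:]
    n = len(labels)
    if len(lines) - 1 != n:
        raise FormatError(
            f"{path}: header declares {n} taxa but {len(lines) - 1} rows found"
        )
    mat = np.zeros((n, n))
    for r, ln in enumerate(lines[1:]):
        parts = ln.split("\t")
        if parts[0] != labels[r]:
            raise FormatError(f"{path}: row label {parts[0]!r} != header {labels[r]!r}")
        if len(parts) - 1 != n:
            raise FormatError(f"{path}: row {parts[0]!r} has {len(parts) - 1} values")
        mat[r] = [float(x) for x in parts[1:]]
    return labels, mat


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted tree view; branch length is the edge to the parent."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or ''} {kind} t={self.length}>"


class PhyloTree:
    """Phylogenetic tree with branch lengths and optional supports.

    Stored as a rooted node structure; ``rooted=False`` marks trees whose
    root is a display artifact (e.g. the trifurcation NJ leaves behind).
    """

    def __init__(self, root: TreeNode, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        names = [leaf.name for leaf in self.leaves()]
        if any(not n for n in names):
            raise ValidationError("tree has an unnamed leaf")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} on node {node.name!r}"
                )

    # traversals ------------------------------------------------------------
    def postorder(self):
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs."""
        return [(n.parent, n) for n in self.postorder() if n.parent is not None]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.name, node.length, node.support)
            for child in node.children:
                c.add(clone(child))
            return c

        return PhyloTree(clone(self.root), self.rooted)


def _support_from_label(label: str | None) -> tuple[float | None, str | None]:
    """Numeric internal labels in [0,1] or [0,100] are supports."""
    if label is None or label == "":
        return None, None
    try:
        val = float(label)
    except ValueError:
        return None, label
    if 0.0 <= val <= 100.0:
        return val, None
    return None, label


def read_newick(source: str) -> PhyloTree:
    """Parse a Newick tree from a path or a literal string.

    Numeric internal node labels in [0,1] or [0,100] are interpreted as
    branch supports; negative branch lengths on input are rejected.
    """
    if os.path.exists(source):
        with open(source) as fh:
            data = fh.read()
    elif "(" in source and ";" in source:
        data = source
    else:
        raise FileNotFoundError(source)

    try:
        dtree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels in newick: {exc}") from exc
        raise FormatError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            name = dnode.taxon.label
            node = TreeNode(name=name, length=dnode.edge.length)
        else:
            support, label = _support_from_label(dnode.label)
            node = TreeNode(name=label, length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def _fmt_len(x: float) -> str:
    return f"{x:.12g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick, preserving lengths and supports."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _fmt_len(node.support)
            elif node.name:
                label = node.name
            s = f"({inner}){label}"
        if node.parent is not None and node.length is not None:
            s += f":{_fmt_len(node.length)}"
        return s

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# GroupAnnotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupAnnotation:
    """taxon -> group label mapping with optional display colors per group."""

    groups: dict[str, str]
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, label in self.groups.items():
            if not taxon:
                raise ValidationError("empty taxon identifier in annotation")
            if not label:
                raise ValidationError(f"empty group label for taxon {taxon!r}")

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.groups.items() if g == group]


def read_groups(path: str) -> GroupAnnotation:
    """Read a two-column TSV (taxon, group); an optional third column is a color."""
    groups: dict[str, str] = {}
    colors: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
            taxon, label = parts[0], parts[1]
            if taxon in groups:
                raise ValidationError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            groups[taxon] = label
            if len(parts) >= 3 and parts[2]:
                colors[label] = parts[2]
    return GroupAnnotation(groups, colors)


def write_groups(ann: GroupAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        for taxon, label in ann.groups.items():
            color = ann.colors.get(label, "")
            fh.write(f"{taxon}\t{label}" + (f"\t{color}" if color else "") + "\n")
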