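"""Tree and taxonomy data model, plus Newick / delimited-table readers and writers.

The pipeline works on three plain objects:

* :class:`PhyloTree` -- a rooted tree (polytomies allowed) whose tips are
  species; nodes may carry absolute ages in Mya (a chronogram) and an origin
  flag distinguishing molecularly placed nodes from taxonomically grafted ones.
* :class:`TaxonomyTable` -- a ranked species list (species, genus, optional
  tribe/subfamily, family, major clade) with a per-species ``sampled`` flag
  marking which species have molecular data.
* :class:`EpochTable` -- an ordered, contiguous list of geological epochs
  used by the temporal stage.

Newick I/O is delegated to dendropy; this module only converts between
dendropy trees and the lightweight :class:`PhyloTree` used by the statistics.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "NewickParseError",
    "TreeValidationError",
    "TaxonomyError",
    "Node",
    "PhyloTree",
    "TaxonomyTable",
    "Epoch",
    "EpochTable",
    "CENOZOIC_EPOCHS",
    "parse_newick",
    "write_newick",
    "read_taxonomy",
    "read_epochs",
]

# Relative tolerance (fraction of tree height) for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-6

GRAFTED_TAG = "&grafted"

AgeSemantics = Literal["none", "branch-lengths", "node-ages"]


class TreeError(ValueError):
    """Base class for tree construction and validation problems."""


class NewickParseError(TreeError):
    """Malformed Newick input (message carries dendropy's line/column)."""


class TreeValidationError(TreeError):
    """Structurally parseable input that violates a PhyloTree invariant."""


class TaxonomyError(ValueError):
    """Taxonomy table violates uniqueness or rank-nesting constraints."""


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class Node:
    """A single tree node. Tips carry a species label; ages are in Mya."""

    __slots__ = ("id", "label", "parent", "children", "age", "length", "origin")

    def __init__(self, id: int, label: str | None = None):
        self.id = id
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.age: float | None = None
        self.length: float | None = None
        self.origin: str = "molecular"

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} {self.label or ''}>"


class PhyloTree:
    """Rooted phylogeny with optional node ages.

    Invariants (checked by :meth:`validate`): a single root; every non-root
    node has exactly one parent; internal nodes have >= 2 children; tip labels
    are unique; if ages are present, every parent is at least as old as each
    of its children.
    """

    def __init__(self, root: Node, nodes: list[Node]):
        self.root = root
        self.nodes = nodes  # nodes[i].id == i

    # -- construction helpers ------------------------------------------------

    def new_node(self, label: str | None = None, parent: Node | None = None) -> Node:
        node = Node(len(self.nodes), label)
        self.nodes.append(node)
        if parent is not None:
            node.parent = parent
            parent.children.append(node)
        return node

    def copy(self) -> "PhyloTree":
        new_nodes = [Node(n.id, n.label) for n in self.nodes]
        for n in self.nodes:
            m = new_nodes[n.id]
            m.age, m.length, m.origin = n.age, n.length, n.origin
            if n.parent is not None:
                m.parent = new_nodes[n.parent.id]
            m.children = [new_nodes[c.id] for c in n.children]
        return PhyloTree(new_nodes[self.root.id], new_nodes)

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def tip_map(self) -> dict[str, Node]:
        return {n.label: n for n in self.tips()}

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def polytomies(self) -> list[Node]:
        return [n for n in self.internal_nodes() if len(n.children) > 2]

    @property
    def has_ages(self) -> bool:
        return self.root.age is not None

    # -- queries -------------------------------------------------------------

    def mrca(self, nodes: Sequence[Node]) -> Node:
        """Most recent common ancestor; a single node is its own MRCA."""
        if not nodes:
            raise TreeError("MRCA of an empty node set is undefined")
        anc: set[int] = set()
        cur: Node | None = nodes[0]
        while cur is not None:
            anc.add(cur.id)
            cur = cur.parent
        best = nodes[0]
        for node in nodes[1:]:
            cur = node
            while cur.id not in anc:
                cur = cur.parent
            # restrict the ancestor set to the path above the new MRCA
            path: set[int] = set()
            walk: Node | None = cur
            while walk is not None:
                path.add(walk.id)
                walk = walk.parent
            anc &= path
            best = cur
        cur = best
        while cur.id not in anc:  # pragma: no cover - defensive
            cur = cur.parent
        return cur

    def clade_tip_labels(self, node: Node) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            if cur.is_tip:
                out.append(cur.label)
            else:
                stack.extend(cur.children)
        return frozenset(out)

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """New tree restricted to the given tips, unifurcations suppressed.

        Ages are preserved; suppressed-node branch lengths are merged.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels())
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)[:5]}")
        if len(keep) < 2:
            raise TreeError("pruning needs at least two tips")

        # number of retained tips below every node
        count: dict[int, int] = {}
        for node in self.postorder():
            if node.is_tip:
                count[node.id] = 1 if node.label in keep else 0
            else:
                count[node.id] = sum(count[c.id] for c in node.children)

        new = PhyloTree.__new__(PhyloTree)
        new.nodes = []

        def build(node: Node, parent: Node | None) -> Node:
            # descend through unifurcations
            while not node.is_tip:
                live = [c for c in node.children if count[c.id] > 0]
                if len(live) != 1:
                    break
                node = live[0]
            out = Node(len(new.nodes), node.label)
            new.nodes.append(out)
            out.age, out.origin = node.age, node.origin
            out.parent = parent
            if parent is not None:
                parent.children.append(out)
                if node.age is not None and parent.age is not None:
                    out.length = parent.age - node.age
            if not node.is_tip:
                for child in node.children:
                    if count[child.id] > 0:
                        build(child, out)
            return out

        import sys

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 4 * len(self.nodes) + 100))
        try:
            new.root = build(self.root, None)
        finally:
            sys.setrecursionlimit(old_limit)
        return new

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        seen: set[int] = set()
        for node in self.preorder():
            if node.id in seen:
                raise TreeValidationError("cycle or repeated node detected")
            seen.add(node.id)
            if node is not self.root and node.parent is None:
                raise TreeValidationError(f"non-root node {node.id} has no parent")
            if not node.is_tip and len(node.children) < 2 and node is not self.root:
                raise TreeValidationError(
                    f"internal node {node.id} has {len(node.children)} child(ren)"
                )
        labels = [n.label for n in self.tips()]
        if any(not l for l in labels):
            raise TreeValidationError("tip with empty label")
        dupes = {l for l in labels if labels.count(l) > 1} if len(labels) < 64 else None
        if dupes is None:
            counts = pd.Series(labels).value_counts()
            dupes = set(counts[counts > 1].index)
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)[:5]}")
        if self.has_ages:
            for node in self.preorder():
                if node.age is None:
                    continue
                if node.age < 0:
                    raise TreeValidationError(f"negative age at node {node.id}")
                for child in node.children:
                    if child.age is not None and child.age > node.age + 1e-12:
                        raise TreeValidationError(
                            f"child {child.id} older ({child.age}) than parent "
                            f"{node.id} ({node.age})"
                        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {len(self.nodes)} nodes>"


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------


def parse_newick(text: str, ages: AgeSemantics = "none") -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    ``ages`` controls how the numbers after ``:`` are interpreted:

    ``"none"``
        numbers are kept as branch lengths but no ages are assigned;
    ``"branch-lengths"``
        the tree is assumed ultrametric; node ages are computed as
        (maximum root-to-tip path length) - (root-to-node path length),
        and deviation from ultrametricity beyond ``ULTRAMETRIC_RTOL`` x
        tree height raises :class:`TreeValidationError` naming the
        worst-offending tip;
    ``"node-ages"``
        numbers are read directly as absolute node ages in Mya.

    Square-bracket comments are ignored except ``[&grafted]``, which sets the
    node origin flag.
    """
    if ages not in ("none", "branch-lengths", "node-ages"):
        raise ValueError(f"unknown age semantics: {ages!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise TreeValidationError(str(e)) from e
    except Exception as e:  # dendropy's parse errors carry line/column info
        raise NewickParseError(str(e)) from e

    nodes: list[Node] = []
    root = None
    stack: list[tuple[dendropy.Node, Node | None]] = [(dtree.seed_node, None)]
    while stack:
        dnode, parent = stack.pop()
        node = Node(len(nodes))
        nodes.append(node)
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            node.label = dnode.label
        node.length = dnode.edge.length
        if any(GRAFTED_TAG in (c or "") for c in dnode.comments):
            node.origin = "grafted"
        node.parent = parent
        if parent is not None:
            parent.children.append(node)
        else:
            root = node
        for child in dnode.child_nodes():
            stack.append((child, node))

    # collapse a unifurcate root ("(a,b);" wrapped once more by some writers)
    while root is not None and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    tree = PhyloTree(root, nodes)

    if ages == "branch-lengths":
        _ages_from_branch_lengths(tree)
    elif ages == "node-ages":
        for node in tree.preorder():
            node.age = node.length if node.length is not None else (0.0 if node.is_tip else None)
        if tree.root.age is None:
            raise TreeValidationError("node-ages semantics requires an age on the root")
        for node in tree.preorder():
            node.length = None

    tree.validate()
    return tree


def _ages_from_branch_lengths(tree: PhyloTree) -> None:
    depth: dict[int, float] = {tree.root.id: 0.0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise TreeValidationError(
                f"branch-lengths semantics requires a length on every edge "
                f"(missing above node {node.id})"
            )
        depth[node.id] = depth[node.parent.id] + node.length
    tips = tree.tips()
    height = max(depth[t.id] for t in tips)
    if height <= 0:
        raise TreeValidationError("tree height is zero; cannot assign ages")
    worst = max(tips, key=lambda t: abs(height - depth[t.id]))
    if abs(height - depth[worst.id]) > ULTRAMETRIC_RTOL * height:
        raise TreeValidationError(
            f"tree is not ultrametric: tip {worst.label!r} has root-to-tip path "
            f"{depth[worst.id]:g} vs height {height:g}"
        )
    for node in tree.preorder():
        node.age = 0.0 if node.is_tip else height - depth[node.id]


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)

    def sanitize(label: str) -> str:
        return label.replace(" ", "_")

    pairs = [(tree.root, dtree.seed_node)]
    while pairs:
        node, dnode = pairs.pop()
        if node.is_tip:
            dnode.taxon = tns.new_taxon(sanitize(node.label))
        if node.origin == "grafted":
            dnode.comments.append(GRAFTED_TAG)
        if node.age is not None and node.parent is not None and node.parent.age is not None:
            dnode.edge.length = node.parent.age - node.age
        elif node.length is not None:
            dnode.edge.length = node.length
        for child in node.children:
            pairs.append((child, dnode.new_child()))
    return dtree


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; grafted nodes carry a ``[&grafted]`` comment.

    If the tree has ages, branch lengths are emitted so that re-parsing with
    ``ages="branch-lengths"`` recovers them (within 1e-9).
    """
    tree.validate()
    dtree = _to_dendropy(tree)
    out = dtree.as_string(
        schema="newick",
        suppress_item_comments=False,
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return out.strip()


# ---------------------------------------------------------------------------
# TaxonomyTable
# ---------------------------------------------------------------------------

_TAX_COLUMNS = ["species", "genus", "tribe", "family", "clade", "sampled"]


class TaxonomyTable:
    """Ranked species list with per-species molecular-sampling flags.

    Backed by a DataFrame with columns ``species, genus, tribe, family,
    clade, sampled`` (``tribe`` may be all-NA; it stands for the optional
    tribe-or-subfamily rank between genus and family). Rank nesting is strict:
    a genus belongs to exactly one family and a family to exactly one major
    clade.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if "tribe" not in df.columns:
            df["tribe"] = pd.NA
        if "sampled" not in df.columns:
            df["sampled"] = True
        missing = [c for c in _TAX_COLUMNS if c not in df.columns]
        if missing:
            raise TaxonomyError(f"taxonomy is missing columns: {missing}")
        df = df[_TAX_COLUMNS].reset_index(drop=True)
        df["sampled"] = df["sampled"].astype(bool)
        if len(df) == 0:
            raise TaxonomyError("taxonomy table is empty")
        if df["species"].duplicated().any():
            dupes = df.loc[df["species"].duplicated(), "species"].tolist()
            raise TaxonomyError(f"duplicate species: {dupes[:5]}")
        for col in ("species", "genus", "family", "clade"):
            if df[col].isna().any() or (df[col].astype(str) == "").any():
                raise TaxonomyError(f"missing values in required column {col!r}")
        self._check_nesting(df, "genus", "family")
        self._check_nesting(df, "family", "clade")
        sub = df.dropna(subset=["tribe"])
        if len(sub):
            self._check_nesting(sub, "tribe", "family")
            self._check_nesting(sub, "genus", "tribe")
        self.frame = df
        self.unknown_tips: list[str] = []

    @staticmethod
    def _check_nesting(df: pd.DataFrame, child: str, parent: str) -> None:
        counts = df.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            pairs = [
                (name, sorted(df.loc[df[child] == name, parent].unique()))
                for name in bad.index[:5]
            ]
            raise TaxonomyError(f"rank nesting violated ({child} -> {parent}): {pairs}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        return self.frame["species"].tolist()

    def sampled_species(self) -> list[str]:
        return self.frame.loc[self.frame["sampled"], "species"].tolist()

    def species_of(self, rank: str, name: str) -> list[str]:
        if rank not in ("genus", "tribe", "family", "clade"):
            raise TaxonomyError(f"unknown rank {rank!r}")
        return self.frame.loc[self.frame[rank] == name, "species"].tolist()

    def row(self, species: str) -> pd.Series:
        sel = self.frame.loc[self.frame["species"] == species]
        if sel.empty:
            raise TaxonomyError(f"species {species!r} not in taxonomy")
        return sel.iloc[0]

    def __repr__(self) -> str:  # pragma: no cover
        n = len(self.frame)
        return f"<TaxonomyTable {n} species, {int(self.frame['sampled'].sum())} sampled>"


def read_taxonomy(
    source,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
    tip_labels: Iterable[str] | None = None,
) -> TaxonomyTable:
    """Read a delimited species list into a :class:`TaxonomyTable`.

    ``columns`` maps the standard names (``species``, ``genus``, ``tribe``,
    ``family``, ``clade``, ``sampled``) to the file's column headers; columns
    already bearing the standard names need no mapping. If ``tip_labels`` is
    given, the ``sampled`` flag is derived by intersection with that set and
    tip labels absent from the species list are collected on the returned
    table's ``unknown_tips`` (with a warning) -- resolving such synonyms is
    the caller's responsibility.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, engine="python")
    if columns:
        rename = {v: k for k, v in columns.items()}
        df = df.rename(columns=rename)
    table_cols = set(df.columns)
    required = {"species", "genus", "family", "clade"}
    if not required <= table_cols:
        raise TaxonomyError(
            f"taxonomy header must provide {sorted(required)}; got {sorted(table_cols)}"
        )
    unknown: list[str] = []
    if tip_labels is not None:
        tip_set = set(tip_labels)
        df["sampled"] = df["species"].isin(tip_set)
        unknown = sorted(tip_set - set(df["species"]))
        if unknown:
            warnings.warn(
                f"{len(unknown)} tip label(s) not found in the species list "
                f"(first few: {unknown[:5]}); synonym resolution is up to the caller",
                stacklevel=2,
            )
    table = TaxonomyTable(df)
    table.unknown_tips = unknown
    return table


# ---------------------------------------------------------------------------
# EpochTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    name: str
    older: float  # older bound, Mya
    younger: float  # younger bound, Mya

    def __post_init__(self):
        if not self.older > self.younger >= 0:
            raise ValueError(f"epoch {self.name}: need older > younger >= 0")


@dataclass
class EpochTable:
    """Ordered geological epochs, oldest first, contiguous down to 0 Mya."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("epoch table is empty")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not math.isclose(a.younger, b.older, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"epochs not contiguous: {a.name} ends {a.younger}, "
                    f"{b.name} starts {b.older}"
                )
        if self.epochs[-1].younger != 0:
            raise ValueError("youngest epoch must end at 0 Mya")

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.epochs]

    @property
    def oldest(self) -> float:
        return self.epochs[0].older


def read_epochs(source, sep: str = "\t") -> EpochTable:
    """Read an epoch table (columns: epoch, start_mya, end_mya; oldest first)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep)
    need = {"epoch", "start_mya", "end_mya"}
    if not need <= set(df.columns):
        raise ValueError(f"epoch table must have columns {sorted(need)}")
    return EpochTable(
        [Epoch(r.epoch, float(r.start_mya), float(r.end_mya)) for r in df.itertuples()]
    )


#: The Cenozoic epochs used for the temporal binning of shift statistics.
CENOZOIC_EPOCHS = EpochTable(
    [
        Epoch("Paleocene", 65.5, 55.8),
        Epoch("Eocene", 55.8, 33.9),
        Epoch("Oligocene", 33.9, 23.03),
        Epoch("Miocene", 23.03, 5.3),
        Epoch("Pliocene", 5.3, 1.8),
        Epoch("Quaternary", 1.8, 0.0),
    ]
)
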