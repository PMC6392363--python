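"""Trees, rooted level-1 networks, and (extended) Newick I/O.

Gene trees are plain :class:`dendropy.Tree` objects throughout the package.
This module adds the shared taxon bookkeeping, a per-locus gene-tree
collection, a rooted level-1 phylogenetic network with inheritance
probabilities, and readers/writers for one-tree-per-line Newick and the
``#H`` extended-Newick convention used by network tools.

Branch lengths are coalescent units everywhere: two lineages entering a
branch of length ``t`` fail to coalesce along it with probability
``exp(-t)``.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import dendropy
import networkx as nx

__all__ = [
    "GAMMA_TOL",
    "TreeIOError",
    "NetworkStructureError",
    "ApproximationWarning",
    "TaxonSet",
    "GeneTreeSet",
    "NetEdge",
    "PhyloNetwork",
    "parse_newick",
    "write_newick",
    "read_gene_trees",
    "parse_extended_newick",
    "root_at_bipartition",
    "displayed_trees",
]

#: tolerance for the inheritance-probability pair summing to one
GAMMA_TOL = 1e-6


class TreeIOError(ValueError):
    """Malformed tree or network input."""


class NetworkStructureError(TreeIOError):
    """Input is not a valid rooted level-1 network."""


class ApproximationWarning(UserWarning):
    """An analytic shortcut is being used outside its exactness conditions."""


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


class TaxonSet(Sequence[str]):
    """An ordered set of unique, non-empty taxon labels."""

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if not labels:
            raise ValueError("TaxonSet requires at least one label")
        if any(not lab for lab in labels):
            raise ValueError("TaxonSet labels must be non-empty")
        dup = _duplicates(labels)
        if dup:
            raise ValueError(f"duplicate taxon labels: {dup}")
        self._labels = labels
        self._pos = {lab: i for i, lab in enumerate(labels)}

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def __getitem__(self, i):
        return self._labels[i]

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, lab) -> bool:
        return lab in self._pos

    def index(self, lab: str) -> int:
        return self._pos[lab]

    def __eq__(self, other) -> bool:
        if isinstance(other, TaxonSet):
            return self._labels == other._labels
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self._labels)!r})"


# ---------------------------------------------------------------------------
# Newick gene trees (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str, taxon_namespace: Optional[dendropy.TaxonNamespace] = None
                 ) -> dendropy.Tree:
    """Parse a single Newick string into a :class:`dendropy.Tree`.

    Polytomies are preserved; branch lengths are optional.  Duplicate leaf
    labels raise :class:`TreeIOError`.
    """
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            taxon_namespace=taxon_namespace,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeIOError(f"could not parse Newick string: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = _duplicates(labels)
    if dup:
        raise TreeIOError(f"duplicate leaf labels in tree: {dup}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, one line, no rooting token."""
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


@dataclass
class GeneTreeSet:
    """Per-locus gene trees over a shared taxon universe.

    Each locus carries either a single tree or a posterior sample of trees;
    within a locus all trees must share a leaf set.  Different loci may
    cover different taxon subsets.
    """

    loci: list[tuple[str, list[dendropy.Tree]]]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("GeneTreeSet requires at least one locus")
        ids = [locus_id for locus_id, _ in self.loci]
        dup = _duplicates(ids)
        if dup:
            raise ValueError(f"duplicate locus ids: {dup}")
        for locus_id, trees in self.loci:
            if not trees:
                raise ValueError(f"locus {locus_id!r} has no trees")
            ref = leaf_labels(trees[0])
            for t in trees[1:]:
                if leaf_labels(t) != ref:
                    raise ValueError(
                        f"trees within locus {locus_id!r} differ in leaf set"
                    )

    @classmethod
    def from_trees(cls, trees: Sequence[dendropy.Tree],
                   locus_ids: Optional[Sequence[str]] = None) -> "GeneTreeSet":
        """One single-tree locus per input tree."""
        if locus_ids is None:
            locus_ids = [f"L{i + 1}" for i in range(len(trees))]
        return cls([(lid, [t]) for lid, t in zip(locus_ids, trees)])

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def labels(self) -> TaxonSet:
        """Sorted union of leaf labels across loci."""
        union: set[str] = set()
        for _, trees in self.loci:
            union |= leaf_labels(trees[0])
        return TaxonSet(sorted(union))

    def is_single_tree(self) -> bool:
        return all(len(trees) == 1 for _, trees in self.loci)


def read_gene_trees(path, locus_ids: Optional[Sequence[str]] = None) -> GeneTreeSet:
    """Read one Newick tree per line into single-tree loci."""
    ns = dendropy.TaxonNamespace()
    trees: list[dendropy.Tree] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            trees.append(parse_newick(line, taxon_namespace=ns))
    if not trees:
        raise TreeIOError(f"no trees found in {path}")
    return GeneTreeSet.from_trees(trees, locus_ids)


def write_gene_trees(gts: GeneTreeSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for _, trees in gts.loci:
            for t in trees:
                fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Rooted level-1 networks
# ---------------------------------------------------------------------------

@dataclass
class NetEdge:
    """Directed edge ``parent -> child`` of a network.

    ``gamma`` is the inheritance probability and is set only on the two
    parent edges of a hybrid node (the pair sums to one).
    """

    id: int
    parent: int
    child: int
    length: Optional[float] = None
    gamma: Optional[float] = None


class PhyloNetwork:
    """A rooted level-1 phylogenetic network.

    Nodes are integer ids mapped to an optional label (leaves must be
    labelled).  Hybrid nodes have exactly two parent edges carrying
    inheritance probabilities ``gamma`` and ``1 - gamma``; the edge with
    the larger ``gamma`` is the major edge.  With no hybrid nodes the
    network is an ordinary rooted species tree.
    """

    def __init__(self, nodes: dict[int, Optional[str]], edges: Iterable[NetEdge],
                 root: int, hybrid_tags: Optional[dict[int, str]] = None,
                 validate: bool = True):
        self.nodes: dict[int, Optional[str]] = dict(nodes)
        self.edges: dict[int, NetEdge] = {}
        for e in edges:
            if e.id in self.edges:
                raise NetworkStructureError(f"duplicate edge id {e.id}")
            self.edges[e.id] = e
        self.root = root
        self._rebuild()
        if hybrid_tags is None:
            hybrid_tags = {}
        self.hybrid_tags: dict[int, str] = dict(hybrid_tags)
        self._assign_missing_tags()
        if validate:
            self.validate()

    # -- structure bookkeeping ------------------------------------------------

    def _rebuild(self) -> None:
        self.children_edges: dict[int, list[NetEdge]] = {n: [] for n in self.nodes}
        self.parent_edges: dict[int, list[NetEdge]] = {n: [] for n in self.nodes}
        for e in self.edges.values():
            if e.parent not in self.nodes or e.child not in self.nodes:
                raise NetworkStructureError(f"edge {e.id} references unknown node")
            self.children_edges[e.parent].append(e)
            self.parent_edges[e.child].append(e)
        for lst in self.children_edges.values():
            lst.sort(key=lambda e: e.id)
        for lst in self.parent_edges.values():
            lst.sort(key=lambda e: e.id)

    def _assign_missing_tags(self) -> None:
        used = set(self.hybrid_tags.values())
        counter = 1
        for h in self.hybrid_nodes:
            if h in self.hybrid_tags:
                continue
            while f"H{counter}" in used:
                counter += 1
            self.hybrid_tags[h] = f"H{counter}"
            used.add(f"H{counter}")

    @property
    def hybrid_nodes(self) -> list[int]:
        return sorted(n for n, pes in self.parent_edges.items() if len(pes) == 2)

    @property
    def k(self) -> int:
        """Number of hybrid nodes (= number of minor hybrid edges)."""
        return len(self.hybrid_nodes)

    @property
    def leaves(self) -> list[int]:
        return sorted(n for n, ces in self.children_edges.items() if not ces)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.nodes[n] for n in self.leaves)

    def node_by_tag(self, tag: str) -> int:
        for nid, t in self.hybrid_tags.items():
            if t == tag:
                return nid
        raise KeyError(f"no hybrid node tagged {tag!r}")

    def major_edge(self, hybrid: int) -> NetEdge:
        pes = sorted(self.parent_edges[hybrid], key=lambda e: (-(e.gamma or 0.0), e.id))
        return pes[0]

    def minor_edge(self, hybrid: int) -> NetEdge:
        pes = sorted(self.parent_edges[hybrid], key=lambda e: (-(e.gamma or 0.0), e.id))
        return pes[1]

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(
            dict(self.nodes),
            [replace(e) for e in self.edges.values()],
            self.root,
            dict(self.hybrid_tags),
            validate=False,
        )

    def topological_order(self) -> list[int]:
        """Node ids, children before parents (leaves first, root last)."""
        indeg = {n: len(self.children_edges[n]) for n in self.nodes}
        queue = [n for n, d in indeg.items() if d == 0]
        order: list[int] = []
        while queue:
            n = queue.pop()
            order.append(n)
            for e in self.parent_edges[n]:
                indeg[e.parent] -= 1
                if indeg[e.parent] == 0:
                    queue.append(e.parent)
        if len(order) != len(self.nodes):
            raise NetworkStructureError("network contains a directed cycle")
        return order

    def descendant_leaf_labels(self, nid: int, skip_edge: Optional[int] = None
                               ) -> frozenset[str]:
        """Labels of leaves reachable from ``nid`` (hardwired descendants)."""
        out: set[str] = set()
        stack = [nid]
        seen: set[int] = set()
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            ces = self.children_edges[n]
            if not ces:
                out.add(self.nodes[n])
            for e in ces:
                if skip_edge is not None and e.id == skip_edge:
                    continue
                stack.append(e.child)
        return frozenset(out)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise NetworkStructureError("root id not among nodes")
        if self.parent_edges[self.root]:
            raise NetworkStructureError("root must have no parent edges")
        for n in self.nodes:
            np_ = len(self.parent_edges[n])
            if n == self.root:
                continue
            if np_ == 0:
                raise NetworkStructureError(f"node {n} unreachable (no parent)")
            if np_ > 2:
                raise NetworkStructureError(f"node {n} has {np_} parents (max 2)")
        labels = [self.nodes[n] for n in self.leaves]
        if any(lab is None or lab == "" for lab in labels):
            raise NetworkStructureError("all leaves must be labelled")
        dup = _duplicates(labels)
        if dup:
            raise NetworkStructureError(f"duplicate leaf labels: {dup}")
        # hybrid edges and their inheritance probabilities
        for h in self.hybrid_nodes:
            e1, e2 = self.parent_edges[h]
            if e1.parent == e2.parent:
                raise NetworkStructureError(
                    f"hybrid node {h} has both parent edges from node {e1.parent}"
                )
            for e in (e1, e2):
                if e.gamma is None:
                    raise NetworkStructureError(
                        f"hybrid parent edge {e.id} lacks an inheritance probability"
                    )
                if not (-GAMMA_TOL <= e.gamma <= 1 + GAMMA_TOL):
                    raise NetworkStructureError(
                        f"gamma {e.gamma} on edge {e.id} outside [0, 1]"
                    )
            if abs(e1.gamma + e2.gamma - 1.0) > GAMMA_TOL:
                raise NetworkStructureError(
                    f"gamma pair on hybrid node {h} sums to {e1.gamma + e2.gamma}, not 1"
                )
        for e in self.edges.values():
            if e.length is not None and e.length < 0:
                raise NetworkStructureError(f"negative branch length on edge {e.id}")
        # acyclicity + connectivity
        self.topological_order()
        reachable = {self.root}
        stack = [self.root]
        while stack:
            n = stack.pop()
            for e in self.children_edges[n]:
                if e.child not in reachable:
                    reachable.add(e.child)
                    stack.append(e.child)
        if reachable != set(self.nodes):
            raise NetworkStructureError("nodes unreachable from root")
        self._check_level1()

    def _check_level1(self) -> None:
        """Level-1: no two hybrid cycles share an edge."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        pair_count: dict[tuple[int, int], int] = {}
        for e in self.edges.values():
            key = (min(e.parent, e.child), max(e.parent, e.child))
            pair_count[key] = pair_count.get(key, 0) + 1
            if pair_count[key] > 1:
                raise NetworkStructureError(
                    f"parallel edges between nodes {key[0]} and {key[1]}"
                )
            g.add_edge(e.parent, e.child)
        hybrids = self.hybrid_nodes
        for comp in nx.biconnected_components(g):
            if len(comp) < 3:
                continue
            sub = g.subgraph(comp)
            n_edges = sub.number_of_edges()
            n_nodes = sub.number_of_nodes()
            inside = [h for h in hybrids
                      if all(e.parent in comp for e in self.parent_edges[h])
                      and h in comp]
            if n_edges > n_nodes or len(inside) > 1:
                raise NetworkStructureError(
                    "network is not level-1: two hybrid cycles share an edge"
                )

    # -- displayed trees ------------------------------------------------------

    def displayed_combinations(self):
        """Yield ``(kept_parent_edges, dropped_edge_ids, weight)`` per combination."""
        hybrids = self.hybrid_nodes
        choices = [self.parent_edges[h] for h in hybrids]
        for combo in itertools.product(*choices):
            weight = 1.0
            dropped: set[int] = set()
            for h, kept in zip(hybrids, combo):
                weight *= kept.gamma if kept.gamma is not None else 1.0
                for e in self.parent_edges[h]:
                    if e.id != kept.id:
                        dropped.add(e.id)
            yield combo, dropped, weight

    def displayed_trees(self) -> list[tuple[dendropy.Tree, float]]:
        """All ``2**k`` displayed trees with their inheritance weights.

        Each tree keeps one parent edge per hybrid node; its weight is the
        product of the chosen ``gamma`` values.  Weights sum to one.
        Suppressed degree-2 nodes have their branch lengths summed.
        """
        out: list[tuple[dendropy.Tree, float]] = []
        ns = dendropy.TaxonNamespace()
        for _, dropped, weight in self.displayed_combinations():
            tree = self._displayed_dendropy(dropped, ns)
            out.append((tree, weight))
        return out

    def _displayed_dendropy(self, dropped: set[int],
                            ns: dendropy.TaxonNamespace) -> dendropy.Tree:
        def build(nid: int):
            ces = self.children_edges[nid]
            if not ces:  # leaf
                node = dendropy.Node()
                node.taxon = ns.require_taxon(label=self.nodes[nid])
                return node
            kids = []
            for e in ces:
                if e.id in dropped:
                    continue
                child = build(e.child)
                if child is None:
                    continue
                child.edge.length = _sum_lengths(child.edge.length, e.length)
                kids.append(child)
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]  # suppress unifurcation; lengths accumulate
            node = dendropy.Node()
            for c in kids:
                # re-ground the accumulated length on a fresh attachment
                length = c.edge.length
                node.add_child(c)
                c.edge.length = length
            return node

        seed = build(self.root)
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = seed
        tree.is_rooted = True
        return tree

    # -- extended Newick ------------------------------------------------------

    def to_enewick(self, include_gamma: bool = True) -> str:
        """Serialize as extended Newick.

        The subtree below a hybrid node is written under its major parent;
        the minor parent carries only the ``#H`` reference.  Both hybrid
        edges are annotated with their gamma (``:length::gamma``).
        """
        hybrids = set(self.hybrid_nodes)

        def annot(e: Optional[NetEdge]) -> str:
            if e is None:
                return ""
            if e.gamma is not None and include_gamma:
                lpart = _fmt_num(e.length) if e.length is not None else ""
                return f":{lpart}::{_fmt_num(e.gamma)}"
            if e.length is not None:
                return f":{_fmt_num(e.length)}"
            return ""

        def sub(nid: int, via: Optional[NetEdge]) -> str:
            if nid in hybrids and via is not None and via.id != self.major_edge(nid).id:
                return f"#{self.hybrid_tags[nid]}{annot(via)}"
            ces = self.children_edges[nid]
            parts = [sub(e.child, e) for e in ces]
            inner = f"({','.join(parts)})" if parts else ""
            name = self.nodes[nid] or ""
            if nid in hybrids:
                name += f"#{self.hybrid_tags[nid]}"
            return f"{inner}{name}{annot(via)}"

        return sub(self.root, None) + ";"

    def __repr__(self) -> str:
        return (f"PhyloNetwork({len(self.leaves)} leaves, k={self.k}, "
                f"{len(self.edges)} edges)")


def _sum_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def displayed_trees(net: PhyloNetwork) -> list[tuple[dendropy.Tree, float]]:
    """Module-level convenience wrapper for :meth:`PhyloNetwork.displayed_trees`."""
    return net.displayed_trees()


# ---------------------------------------------------------------------------
# extended-Newick parsing
# ---------------------------------------------------------------------------

class _PNode:
    __slots__ = ("name", "fields", "children")

    def __init__(self):
        self.name = ""
        self.fields: list[str] = []
        self.children: list["_PNode"] = []


_NAME_STOP = set("(),;:")


class _ENewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str):
        raise TreeIOError(f"{msg} at position {self.pos}")

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> _PNode:
        root = self.subtree()
        if self.peek() != ";":
            self.error("expected ';' terminating the tree")
        self.pos += 1
        self._skip_ws()
        if self.pos < len(self.text):
            self.error("trailing characters after ';'")
        return root

    def subtree(self) -> _PNode:
        node = _PNode()
        if self.peek() == "(":
            self.pos += 1
            node.children.append(self.subtree())
            while self.peek() == ",":
                self.pos += 1
                node.children.append(self.subtree())
            if self.peek() != ")":
                self.error("expected ')' ")
            self.pos += 1
        node.name = self._name()
        node.fields = self._annotations()
        return node

    def _name(self) -> str:
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "'":
            end = self.text.find("'", self.pos + 1)
            if end < 0:
                self.error("unterminated quoted label")
            name = self.text[self.pos + 1:end]
            self.pos = end + 1
            return name
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _NAME_STOP \
                and not self.text[self.pos].isspace():
            self.pos += 1
        return self.text[start:self.pos]

    def _annotations(self) -> list[str]:
        fields: list[str] = []
        while self.peek() == ":" and len(fields) < 3:
            self.pos += 1
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos] not in _NAME_STOP \
                    and not self.text[self.pos].isspace():
                self.pos += 1
            fields.append(self.text[start:self.pos])
        if self.peek() == ":":
            self.error("more than three ':' annotation fields")
        return fields


def _field_float(fields: list[str], idx: int, what: str) -> Optional[float]:
    if idx >= len(fields) or fields[idx] == "":
        return None
    try:
        return float(fields[idx])
    except ValueError:
        raise TreeIOError(f"invalid {what} value {fields[idx]!r}") from None


def parse_extended_newick(text: str) -> PhyloNetwork:
    """Parse an extended-Newick string with ``#H``-tagged hybrid nodes.

    Annotation fields follow the ``:length:support:gamma`` convention; the
    support field is ignored.  Gamma may be given on either or both hybrid
    edges (``minor-edge-carries-gamma`` and ``both-edges-annotated``
    dialects are accepted); a missing pair defaults to 0.5/0.5 with a
    warning.  A string without ``#H`` tags yields a network with ``k = 0``.
    """
    rootp = _ENewickParser(text).parse()

    nodes: dict[int, Optional[str]] = {}
    edges: list[NetEdge] = []
    occurrences: dict[str, list[tuple[int, _PNode, Optional[int]]]] = {}
    counter = itertools.count()
    edge_counter = itertools.count()

    def walk(p: _PNode, parent_id: Optional[int]) -> int:
        nid = next(counter)
        name, tag = p.name, None
        if "#" in name:
            name, tagpart = name.split("#", 1)
            tag = tagpart
            if not tag:
                raise TreeIOError("empty #H tag")
        nodes[nid] = name or None
        if parent_id is not None:
            edges.append(NetEdge(
                id=next(edge_counter), parent=parent_id, child=nid,
                length=_field_float(p.fields, 0, "branch length"),
                gamma=_field_float(p.fields, 2, "gamma"),
            ))
        if tag is not None:
            occurrences.setdefault(tag, []).append((nid, p, parent_id))
        for c in p.children:
            walk(c, nid)
        return nid

    root_id = walk(rootp, None)

    # merge #H occurrences pairwise
    remap: dict[int, int] = {}
    hybrid_tags: dict[int, str] = {}
    for tag, occs in occurrences.items():
        if len(occs) != 2:
            raise NetworkStructureError(
                f"#H tag {tag!r} appears {len(occs)} time(s); expected exactly 2"
            )
        with_children = [o for o in occs if o[1].children]
        if len(with_children) == 2:
            raise NetworkStructureError(
                f"#H tag {tag!r} carries a subtree at both occurrences"
            )
        if with_children:
            primary = with_children[0]
        else:
            named = [o for o in occs if nodes[o[0]]]
            primary = named[0] if named else occs[0]
        secondary = occs[0] if occs[1] is primary else occs[1]
        if primary is secondary:
            secondary = occs[1]
        remap[secondary[0]] = primary[0]
        hybrid_tags[primary[0]] = tag
        if nodes[secondary[0]] and not nodes[primary[0]]:
            nodes[primary[0]] = nodes[secondary[0]]
        del nodes[secondary[0]]

    for e in edges:
        e.child = remap.get(e.child, e.child)
        e.parent = remap.get(e.parent, e.parent)

    # resolve gamma pairs per hybrid node
    by_child: dict[int, list[NetEdge]] = {}
    for e in edges:
        by_child.setdefault(e.child, []).append(e)
    for nid in hybrid_tags:
        pes = by_child.get(nid, [])
        if len(pes) != 2:
            raise NetworkStructureError(
                f"hybrid node #{hybrid_tags[nid]} has {len(pes)} parent edges"
            )
        g1, g2 = pes[0].gamma, pes[1].gamma
        if g1 is None and g2 is None:
            warnings.warn(
                f"no inheritance probability on hybrid #{hybrid_tags[nid]}; "
                "defaulting to 0.5/0.5",
                stacklevel=2,
            )
            pes[0].gamma, pes[1].gamma = 0.5, 0.5
        elif g1 is None:
            pes[0].gamma = 1.0 - g2
        elif g2 is None:
            pes[1].gamma = 1.0 - g1
        elif abs(g1 + g2 - 1.0) > GAMMA_TOL:
            raise NetworkStructureError(
                f"gamma pair {g1}/{g2} on hybrid #{hybrid_tags[nid]} does not sum to 1"
            )
    for e in edges:
        if e.child not in hybrid_tags:
            e.gamma = None  # gamma annotations only meaningful on hybrid edges

    return PhyloNetwork(nodes, edges, root_id, hybrid_tags=hybrid_tags)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_at_bipartition(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root a (possibly unrooted) tree on the edge separating ``outgroup``.

    The outgroup must form one block of a bipartition of the tree; the
    returned tree's root edge separates the outgroup from the remaining
    taxa.  The input tree is not modified.
    """
    og = frozenset(outgroup)
    if not og:
        raise ValueError("outgroup must be non-empty")
    t = tree.clone(depth=1)
    all_leaves = leaf_labels(t)
    missing = og - all_leaves
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if og == all_leaves:
        raise ValueError("outgroup cannot contain every taxon")

    below: dict[int, frozenset[str]] = {}
    target_edge = None
    for node in t.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
        if node is t.seed_node:
            continue
        s = below[id(node)]
        if s == og or s == all_leaves - og:
            target_edge = node.edge
    if target_edge is None:
        # name the clash: smallest clade containing the outgroup
        best = all_leaves
        for s in below.values():
            if og <= s and len(s) < len(best):
                best = s
        clash = sorted(best - og)
        raise ValueError(
            f"outgroup {sorted(og)} is not a bipartition block; "
            f"its smallest containing clade also includes {clash}"
        )
    t.reroot_at_edge(target_edge, update_bipartitions=False)
    t.is_rooted = True
    return t
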