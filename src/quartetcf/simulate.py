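"""Multispecies-coalescent gene-tree simulation on trees and networks.

One lineage is sampled per species.  Within every branch of length ``t``
(coalescent units) each pair of lineages coalesces at rate 1, so two
lineages fail to coalesce across the branch with probability ``exp(-t)``;
population sizes are absorbed into the branch lengths.  At a hybrid node a
lineage follows the major parent with probability gamma and the minor
parent otherwise -- either independently per lineage (``"independent"``)
or with the whole locus committed to a single displayed tree (``"locus"``).
The two rules coincide whenever each hybrid node subtends a single sampled
lineage, as in the hybrid-leaf scenario below.

The bundled scenario mirrors the data structure of an eight-locus,
one-sample-per-species study in which one species (``H``) is a candidate
hybrid between two others: with gamma near 0.5 and long internal branches
the per-locus topology counts split roughly half/half between ``H+A`` and
``H+B`` with the third resolution nearly absent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .ilstest import ILSNullModel
from .treeio import GeneTreeSet, NetEdge, PhyloNetwork

__all__ = [
    "SimulationConfig",
    "simulate_gene_trees",
    "aulophallus_network",
    "aulophallus_scenario",
    "backbone_network",
    "backbone_tree",
    "simulate_counts",
]


@dataclass
class SimulationConfig:
    """Settings for one simulation run; the seed is mandatory."""

    model: PhyloNetwork
    n_loci: int
    seed: int
    lineage_choice: str = "independent"

    def __post_init__(self):
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if self.lineage_choice not in ("independent", "locus"):
            raise ValueError("lineage_choice must be 'independent' or 'locus'")


def _coalesce_along(lineages: list[list], t: Optional[float],
                    rng: np.random.Generator) -> list[list]:
    """Kingman coalescent among ``lineages`` for duration ``t`` (None = inf).

    A lineage is ``[node, pending]`` where ``pending`` accumulates branch
    length since the node was created.
    """
    remaining = t
    while len(lineages) > 1:
        n = len(lineages)
        wait = rng.exponential(2.0 / (n * (n - 1)))
        if remaining is not None and wait > remaining:
            break
        for lin in lineages:
            lin[1] += wait
        if remaining is not None:
            remaining -= wait
        i, j = rng.choice(n, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a[0])
        a[0].edge.length = a[1]
        parent.add_child(b[0])
        b[0].edge.length = b[1]
        merged = [parent, 0.0]
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    if remaining is not None and remaining > 0:
        for lin in lineages:
            lin[1] += remaining
    return lineages


def _simulate_locus(net: PhyloNetwork, rng: np.random.Generator,
                    ns: dendropy.TaxonNamespace,
                    dropped: Optional[set[int]] = None) -> dendropy.Tree:
    """One gene tree under the MSC on ``net`` (minus ``dropped`` hybrid edges)."""
    incoming: dict[int, list[list]] = {nid: [] for nid in net.nodes}
    for nid in net.leaves:
        node = dendropy.Node()
        node.taxon = ns.require_taxon(label=net.nodes[nid])
        incoming[nid].append([node, 0.0])

    for nid in net.topological_order():
        pool = incoming[nid]
        if nid == net.root:
            survivors = _coalesce_along(pool, None, rng)
            root = survivors[0][0]
            tree = dendropy.Tree(taxon_namespace=ns)
            tree.seed_node = root
            tree.is_rooted = True
            return tree
        pes = net.parent_edges[nid]
        if dropped is not None:
            pes = [e for e in pes if e.id not in dropped]
        if len(pes) == 1:
            e = pes[0]
            for lin in _coalesce_along(pool, e.length or 0.0, rng):
                incoming[e.parent].append(lin)
        else:
            # hybrid node: route each lineage independently by gamma
            buckets: dict[int, list[list]] = {e.id: [] for e in pes}
            g0 = pes[0].gamma if pes[0].gamma is not None else 0.5
            for lin in pool:
                chosen = pes[0] if rng.random() < g0 else pes[1]
                buckets[chosen.id].append(lin)
            for e in pes:
                for lin in _coalesce_along(buckets[e.id], e.length or 0.0, rng):
                    incoming[e.parent].append(lin)
    raise AssertionError("root never reached")  # pragma: no cover


def simulate_gene_trees(cfg: SimulationConfig) -> GeneTreeSet:
    """Simulate ``n_loci`` unlinked gene trees; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    ns = dendropy.TaxonNamespace()
    net = cfg.model
    combos = None
    if cfg.lineage_choice == "locus" and net.k > 0:
        combos = list(net.displayed_combinations())
        weights = np.array([w for _, _, w in combos])
        weights = weights / weights.sum()
    trees: list[dendropy.Tree] = []
    for _ in range(cfg.n_loci):
        if combos is not None:
            _, dropped, _ = combos[rng.choice(len(combos), p=weights)]
            trees.append(_simulate_locus(net, rng, ns, dropped=dropped))
        else:
            trees.append(_simulate_locus(net, rng, ns))
    if not trees:
        raise ValueError("n_loci must be >= 1 to build a GeneTreeSet")
    return GeneTreeSet.from_trees(trees)


# ---------------------------------------------------------------------------
# fixture networks (synthetic constructions, not transcriptions of any study)
# ---------------------------------------------------------------------------

def aulophallus_network(gamma: float = 0.5, t1: float = 5.0,
                        t2: float = 5.0) -> PhyloNetwork:
    """Four-taxon hybrid-leaf network: H inherits from A's side w.p. gamma.

    Taxa: ``H`` the putative hybrid, ``A`` and ``B`` its candidate parent
    lineages, ``O`` an outgroup.  ``t1`` (``t2``) is the internal branch
    above the ``A+H`` (``B+H``) attachment in coalescent units.  Defaults
    emulate the strongly reticulate regime: an even gamma and internal
    branches long enough that the third resolution is essentially never
    seen (its per-displayed-tree probability is ``(1/3) e^-5`` = 0.2%).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    nodes = {0: None, 1: None, 2: None, 3: None, 4: None,
             5: "A", 6: "B", 7: "H", 8: "O"}
    #          root=0; 1 = ingroup; 2 = A-side; 3 = B-side; 4 = hybrid node
    edges = [
        NetEdge(0, parent=0, child=8, length=1.0),            # root -> O
        NetEdge(1, parent=0, child=1, length=1.0),            # root -> ingroup
        NetEdge(2, parent=1, child=2, length=t1),             # ingroup -> A-side
        NetEdge(3, parent=1, child=3, length=t2),             # ingroup -> B-side
        NetEdge(4, parent=2, child=5, length=1.0),            # A
        NetEdge(5, parent=3, child=6, length=1.0),            # B
        NetEdge(6, parent=2, child=4, length=0.0, gamma=gamma),
        NetEdge(7, parent=3, child=4, length=0.0, gamma=1.0 - gamma),
        NetEdge(8, parent=4, child=7, length=1.0),            # hybrid -> H
    ]
    return PhyloNetwork(nodes, edges, root=0, hybrid_tags={4: "H1"})


def aulophallus_scenario(gamma: float = 0.5, t1: float = 5.0, t2: float = 5.0,
                         n_loci: int = 8, seed: int = 0,
                         lineage_choice: str = "independent") -> GeneTreeSet:
    """Gene trees from the four-taxon hybrid scenario (defaults: 8 loci)."""
    cfg = SimulationConfig(
        model=aulophallus_network(gamma, t1, t2),
        n_loci=n_loci, seed=seed, lineage_choice=lineage_choice,
    )
    return simulate_gene_trees(cfg)


def backbone_tree() -> PhyloNetwork:
    """Six-taxon species tree used as the search starting point."""
    nodes = {0: None, 1: None, 2: None, 3: None, 4: None,
             5: "O", 6: "A", 7: "B", 8: "E", 9: "C", 10: "D"}
    edges = [
        NetEdge(0, parent=0, child=5, length=3.0),   # O
        NetEdge(1, parent=0, child=1, length=1.0),
        NetEdge(2, parent=1, child=2, length=1.0),   # (A,B) stem
        NetEdge(3, parent=2, child=6, length=1.0),   # A
        NetEdge(4, parent=2, child=7, length=1.0),   # B
        NetEdge(5, parent=1, child=3, length=1.0),
        NetEdge(6, parent=3, child=8, length=1.5),   # E
        NetEdge(7, parent=3, child=4, length=0.5),   # (C,D) stem
        NetEdge(8, parent=4, child=9, length=1.0),   # C
        NetEdge(9, parent=4, child=10, length=1.0),  # D
    ]
    return PhyloNetwork(nodes, edges, root=0)


def backbone_network(gamma: float = 0.3) -> PhyloNetwork:
    """Six-taxon level-1 network: leaf D is a hybrid, minor parent toward E.

    A small synthetic caricature of a backbone-with-one-reticulation
    analysis: D is sister to C on the major side (inheritance 1 - gamma)
    and attaches toward E on the minor side (inheritance ``gamma``, the
    conventional minor-edge parameter).  Internal branches are short
    enough (0.5-1 coalescent units) that quartet CFs are informative.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    nodes = {0: None, 1: None, 2: None, 3: None, 4: None, 11: None, 12: None,
             5: "O", 6: "A", 7: "B", 8: "E", 9: "C", 10: "D"}
    edges = [
        NetEdge(0, parent=0, child=5, length=3.0),   # O
        NetEdge(1, parent=0, child=1, length=1.0),
        NetEdge(2, parent=1, child=2, length=1.0),   # (A,B) stem
        NetEdge(3, parent=2, child=6, length=1.0),   # A
        NetEdge(4, parent=2, child=7, length=1.0),   # B
        NetEdge(5, parent=1, child=3, length=1.0),   # stem of ((C,D),E) group
        NetEdge(6, parent=3, child=11, length=0.5),  # toward E / minor source
        NetEdge(7, parent=11, child=8, length=1.0),  # E
        NetEdge(8, parent=3, child=4, length=0.5),   # (C, D) stem
        NetEdge(9, parent=4, child=9, length=1.0),   # C
        NetEdge(10, parent=4, child=12, length=0.5, gamma=1.0 - gamma),  # major
        NetEdge(11, parent=11, child=12, length=0.5, gamma=gamma),       # minor
        NetEdge(12, parent=12, child=10, length=1.0),  # D
    ]
    return PhyloNetwork(nodes, edges, root=0, hybrid_tags={12: "H1"})


def simulate_counts(model: ILSNullModel, seed: int,
                    size: Optional[int] = None) -> np.ndarray:
    """Multinomial draw(s) of per-locus topology counts under the ILS null."""
    rng = np.random.default_rng(seed)
    draw = rng.multinomial(model.n, model.probs, size=size)
    return draw
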