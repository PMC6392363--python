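"""Expected quartet CFs, pseudolikelihood and AIC on level-1 networks.

Under the multispecies coalescent, a species-tree quartet whose induced
unrooted tree has internal branch length ``t`` (coalescent units) yields
concordance factors ``(1 - (2/3) e^-t, (1/3) e^-t, (1/3) e^-t)``.  On a
level-1 network the expected CF of a quartet is the gamma-weighted mixture
of this formula over the displayed trees; this is exact whenever each
hybrid node relevant to the quartet subtends exactly one sampled leaf of
it, and an approximation (flagged by a warning) otherwise.

Networks are scored against an observed CF table with a weighted
multinomial cross-entropy pseudo-log-likelihood

    sum_q n_eff(q) * sum_r cf_obs(q, r) * ln cf_model(q, r)

and ranked with AIC = -2 * pseudolik + 2k, k the number of hybrid edges.
This pseudolikelihood is this package's own analog of composite-likelihood
network scoring; its absolute values are not comparable across scoring
conventions of other tools -- only rankings within one analysis are.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .concordance import QuartetCFTable, canonical_quartet
from .treeio import (ApproximationWarning, NetEdge, NetworkStructureError,
                     PhyloNetwork, TreeIOError)

__all__ = [
    "expected_cf_quartet_tree",
    "expected_cf_network",
    "expected_cf_table",
    "pseudolik",
    "aic",
    "fit_r2",
    "NetworkFit",
    "optimize_params",
    "remove_hybrid_edge",
    "add_hybrid_edge",
    "search_hybrid_edges",
    "flag_geography",
]

CF_FLOOR = 1e-12
T_MAX_DEFAULT = 20.0


def expected_cf_quartet_tree(t: float) -> np.ndarray:
    """CFs (major, minor, minor) for internal branch length ``t`` >= 0."""
    if t < 0:
        raise ValueError("internal branch length must be >= 0")
    e = math.exp(-t)
    return np.array([1.0 - 2.0 * e / 3.0, e / 3.0, e / 3.0])


# ---------------------------------------------------------------------------
# expected CFs on a network: precomputed displayed-tree structure
# ---------------------------------------------------------------------------

class _CFEngine:
    """Vectorized expected-CF evaluator for fixed topology and quartet list.

    For every displayed-tree combination and quartet it precomputes the
    resolution index and the set of edges on the internal path, so that
    expected CFs become a cheap function of the edge-length vector and the
    per-hybrid major-edge gammas (used heavily by the optimizer).
    """

    def __init__(self, net: PhyloNetwork, quartets: Sequence[tuple[str, ...]]):
        self.net = net
        self.quartets = [canonical_quartet(q) for q in quartets]
        leaf_ids = net.leaves
        labels = [net.nodes[n] for n in leaf_ids]
        missing = [lab for q in self.quartets for lab in q if lab not in labels]
        if missing:
            raise ValueError(f"quartet taxa absent from network: {sorted(set(missing))}")
        bit_of = {lab: i for i, lab in enumerate(labels)}
        leaf_bit = {nid: 1 << bit_of[net.nodes[nid]] for nid in leaf_ids}

        self.hybrids = net.hybrid_nodes
        self.major_edge_ids = [net.major_edge(h).id for h in self.hybrids]
        self.edge_ids = sorted(net.edges)
        eidx = {eid: i for i, eid in enumerate(self.edge_ids)}
        E = len(self.edge_ids)

        combos = list(net.displayed_combinations())
        C, Q = len(combos), len(self.quartets)
        self.choice_major = np.zeros((C, len(self.hybrids)), dtype=bool)
        self.res = np.zeros((C, Q), dtype=np.intp)
        self.path = np.zeros((C, Q, E))

        order = net.topological_order()
        qbits = []
        for q in self.quartets:
            bits = [1 << bit_of[x] for x in q]
            qbits.append(bits)

        for ci, (kept, dropped, _w) in enumerate(combos):
            for hi, e in enumerate(kept):
                self.choice_major[ci, hi] = (e.id == self.major_edge_ids[hi])
            below: dict[int, int] = {}
            for nid in order:
                if nid in leaf_bit:
                    below[nid] = leaf_bit[nid]
                else:
                    m = 0
                    for e in net.children_edges[nid]:
                        if e.id not in dropped:
                            m |= below[e.child]
                    below[nid] = m
            for qi, bits in enumerate(qbits):
                qmask = bits[0] | bits[1] | bits[2] | bits[3]
                res = 0
                for e in net.edges.values():
                    if e.id in dropped:
                        continue
                    mm = below[e.child] & qmask
                    if mm.bit_count() == 2:
                        self.path[ci, qi, eidx[e.id]] = 1.0
                        pair = mm if (mm & bits[0]) else (qmask & ~mm)
                        for i in (1, 2, 3):
                            if pair & bits[i]:
                                res = i - 1
                                break
                self.res[ci, qi] = res
                # an unresolved (all-zero path) row falls back to t = 0,
                # i.e. a uniform 1/3 CF, which is the star-tree limit

    def lengths_vector(self, lengths: Optional[Mapping[int, float]] = None) -> np.ndarray:
        src = self.net.edges
        out = np.empty(len(self.edge_ids))
        for i, eid in enumerate(self.edge_ids):
            if lengths is not None and eid in lengths:
                out[i] = lengths[eid]
            else:
                out[i] = src[eid].length if src[eid].length is not None else 0.0
        return out

    def gammas_vector(self) -> np.ndarray:
        return np.array([
            self.net.edges[eid].gamma if self.net.edges[eid].gamma is not None else 0.5
            for eid in self.major_edge_ids
        ])

    def free_edge_positions(self) -> list[int]:
        """Positions (into edge_ids) of edges on some quartet internal path."""
        used = self.path.any(axis=(0, 1))
        return [i for i in range(len(self.edge_ids)) if used[i]]

    def expected(self, lengths: np.ndarray, gammas: np.ndarray) -> np.ndarray:
        """Expected CFs, shape (n_quartets, 3), given edge lengths and gammas."""
        t = self.path @ lengths                      # (C, Q)
        if gammas.size:
            w = np.prod(np.where(self.choice_major, gammas, 1.0 - gammas), axis=1)
        else:
            w = np.ones(t.shape[0])
        e = np.exp(-t)
        minor = e / 3.0                              # (C, Q)
        out = (w[:, None] * minor).sum(axis=0)[None, :].T @ np.ones((1, 3))
        boost = w[:, None] * (1.0 - e)               # major - minor = 1 - e^-t
        nq = t.shape[1]
        np.add.at(out, (np.broadcast_to(np.arange(nq), self.res.shape), self.res),
                  boost)
        return out


def _exactness_check(net: PhyloNetwork, quartets: Sequence[tuple[str, ...]]) -> None:
    for h in net.hybrid_nodes:
        sub = net.descendant_leaf_labels(h)
        for q in quartets:
            if len(sub & set(q)) > 1:
                warnings.warn(
                    f"hybrid node #{net.hybrid_tags[h]} subtends "
                    f"{sorted(sub & set(q))} of quartet {q}; the displayed-tree "
                    "mixture CF is an approximation here",
                    ApproximationWarning,
                    stacklevel=3,
                )
                return


def expected_cf_network(net: PhyloNetwork, quartet: Iterable[str]) -> np.ndarray:
    """Expected CFs of one quartet under the coalescent on the network.

    Returns the 3-vector in canonical (sorted-quartet) resolution order.
    Unset branch lengths are treated as zero.
    """
    q = canonical_quartet(quartet)
    _exactness_check(net, [q])
    eng = _CFEngine(net, [q])
    return eng.expected(eng.lengths_vector(), eng.gammas_vector())[0]


def expected_cf_table(net: PhyloNetwork,
                      quartets: Union[str, Sequence[Iterable[str]]] = "all",
                      n_eff: Optional[np.ndarray] = None) -> QuartetCFTable:
    """Model CF table over the requested quartets (``"all"`` = every 4-subset)."""
    if quartets == "all":
        qlist = [tuple(c) for c in itertools.combinations(sorted(net.leaf_labels), 4)]
    else:
        qlist = [canonical_quartet(q) for q in quartets]
    _exactness_check(net, qlist)
    eng = _CFEngine(net, qlist)
    cf = eng.expected(eng.lengths_vector(), eng.gammas_vector())
    if n_eff is None:
        n_eff = np.zeros(len(qlist))
    return QuartetCFTable(qlist, cf, np.asarray(n_eff, dtype=float))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def pseudolik(net: PhyloNetwork, cfs: QuartetCFTable) -> float:
    """Weighted multinomial cross-entropy pseudo-log-likelihood (larger = better)."""
    if len(cfs) == 0:
        raise ValueError("empty CF table")
    eng = _CFEngine(net, cfs.quartets)
    model = eng.expected(eng.lengths_vector(), eng.gammas_vector())
    return _pseudolik_arrays(cfs.cf, cfs.n_eff, model)


def _pseudolik_arrays(obs: np.ndarray, n_eff: np.ndarray, model: np.ndarray) -> float:
    logm = np.log(np.maximum(model, CF_FLOOR))
    return float(np.sum(n_eff[:, None] * obs * logm))  # 0 * log 0 == 0 via obs == 0


def aic(pseudolik_value: float, k: int) -> float:
    """AIC = -2 * pseudolik + 2k, k the number of hybrid edges."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * pseudolik_value + 2.0 * k


def fit_r2(cfs: QuartetCFTable, net: PhyloNetwork, method: str = "identity") -> float:
    """R-squared of observed vs fitted CFs over all (quartet, resolution) pairs.

    ``identity`` (default) measures residuals against the y = x line:
    ``1 - SS_res / SS_tot``; ``pearson`` returns the squared correlation.
    """
    if method not in ("identity", "pearson"):
        raise ValueError("method must be 'identity' or 'pearson'")
    if len(cfs) == 0:
        raise ValueError("empty CF table")
    eng = _CFEngine(net, cfs.quartets)
    model = eng.expected(eng.lengths_vector(), eng.gammas_vector())
    return _r2_arrays(cfs.cf, model, method)


def _r2_arrays(obs: np.ndarray, model: np.ndarray, method: str) -> float:
    o, m = obs.ravel(), model.ravel()
    if np.ptp(o) < 1e-12:
        raise ValueError("observed CFs are constant; R^2 undefined")
    if method == "pearson":
        return float(np.corrcoef(o, m)[0, 1] ** 2)
    ss_res = np.sum((o - m) ** 2)
    ss_tot = np.sum((o - o.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# parameter optimization on a fixed topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkFit:
    """A scored network: topology, optimized parameters and fit measures."""

    network: PhyloNetwork
    pseudolik: float
    k: int
    aic: float
    r2: float
    fitted: Optional[QuartetCFTable] = None
    non_identifiable: list[int] = field(default_factory=list)

    def __post_init__(self):
        assert self.k == self.network.k
        assert abs(self.aic - (-2.0 * self.pseudolik + 2.0 * self.k)) < 1e-9


def optimize_params(topology: PhyloNetwork, cfs: QuartetCFTable, seed: int = 0,
                    n_starts: int = 10, t_max: float = T_MAX_DEFAULT,
                    ftol: float = 1e-8) -> NetworkFit:
    """Maximize the pseudolikelihood over branch lengths and gammas.

    The topology is fixed; free parameters are the branch lengths of edges
    that lie on some quartet's internal path (others are not identifiable
    from quartet CFs: they are flagged and pinned to ``t_max`` when
    internal, left untouched when pendant) plus one gamma per hybrid node.
    Bounded L-BFGS-B with ``n_starts`` seeded restarts; deterministic given
    ``seed``.
    """
    if len(cfs) == 0:
        raise ValueError("empty CF table")
    net = topology.copy()
    eng = _CFEngine(net, cfs.quartets)
    free = eng.free_edge_positions()
    base = eng.lengths_vector()
    nfree, nh = len(free), len(eng.hybrids)

    obs, n_eff = cfs.cf, cfs.n_eff

    def neg(x: np.ndarray) -> float:
        lengths = base.copy()
        lengths[free] = x[:nfree]
        g = np.clip(x[nfree:], 0.0, 1.0)
        model = eng.expected(lengths, g)
        return -_pseudolik_arrays(obs, n_eff, model)

    x0 = np.concatenate([np.clip(base[free], 1e-3, t_max), eng.gammas_vector()])
    bounds = [(0.0, t_max)] * nfree + [(0.0, 1.0)] * nh

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.concatenate([
            rng.uniform(0.01, 5.0, size=nfree),
            rng.uniform(0.05, 0.95, size=nh),
        ]))

    best = None
    for s in starts:
        if nfree + nh == 0:
            best = (neg(np.empty(0)), np.empty(0))
            break
        r = minimize(neg, s, method="L-BFGS-B", bounds=bounds,
                     options={"ftol": ftol, "maxiter": 500})
        if best is None or r.fun < best[0] - 1e-12:
            best = (r.fun, r.x)
    fun, x = best

    lengths = base.copy()
    lengths[free] = x[:nfree]
    gammas = np.clip(x[nfree:], 0.0, 1.0)

    non_ident: list[int] = []
    free_ids = {eng.edge_ids[i] for i in free}
    for i, eid in enumerate(eng.edge_ids):
        e = net.edges[eid]
        if i in free:
            e.length = float(lengths[i])
        elif net.children_edges[e.child]:  # internal but CF-insensitive
            non_ident.append(eid)
            e.length = t_max
    for h, eid, g in zip(eng.hybrids, eng.major_edge_ids, gammas):
        for pe in net.parent_edges[h]:
            pe.gamma = float(g) if pe.id == eid else float(1.0 - g)

    pl = -fun
    model = eng.expected(eng.lengths_vector(), np.asarray(
        [net.edges[eid].gamma for eid in eng.major_edge_ids], dtype=float))
    fitted = QuartetCFTable(list(cfs.quartets), model, cfs.n_eff.copy())
    return NetworkFit(
        network=net, pseudolik=pl, k=net.k, aic=aic(pl, net.k),
        r2=_r2_arrays(obs, model, "identity"), fitted=fitted,
        non_identifiable=non_ident,
    )


# ---------------------------------------------------------------------------
# edge editing
# ---------------------------------------------------------------------------

def _suppress_degree2(net: PhyloNetwork) -> None:
    """Remove unlabelled degree-2 nodes in place, summing branch lengths."""
    changed = True
    while changed:
        changed = False
        for nid in list(net.nodes):
            if nid == net.root:
                ces = net.children_edges[nid]
                if len(ces) == 1 and net.nodes[nid] is None:
                    e = ces[0]
                    del net.edges[e.id]
                    del net.nodes[nid]
                    net.root = e.child
                    net._rebuild()
                    changed = True
                    break
                continue
            pes, ces = net.parent_edges[nid], net.children_edges[nid]
            if len(pes) == 1 and len(ces) == 1 and net.nodes[nid] is None:
                pe, ce = pes[0], ces[0]
                merged = NetEdge(
                    id=pe.id, parent=pe.parent, child=ce.child,
                    length=(None if pe.length is None and ce.length is None
                            else (pe.length or 0.0) + (ce.length or 0.0)),
                    gamma=ce.gamma if ce.gamma is not None else pe.gamma,
                )
                del net.edges[ce.id]
                net.edges[pe.id] = merged
                del net.nodes[nid]
                net._rebuild()
                changed = True
                break
            if len(pes) == 1 and not ces and net.nodes[nid] is None:
                del net.edges[pes[0].id]
                del net.nodes[nid]
                net._rebuild()
                changed = True
                break


def remove_hybrid_edge(net: PhyloNetwork, hybrid_id: Union[str, int]) -> PhyloNetwork:
    """Delete a hybrid node's minor parent edge and suppress the node.

    ``hybrid_id`` may be the hybrid tag (e.g. ``"H1"``) or node id.  The
    remaining parent edge becomes an ordinary tree edge and ``k`` drops by
    one.  Other hybrid nodes and their gammas are untouched.
    """
    out = net.copy()
    if isinstance(hybrid_id, str):
        h = out.node_by_tag(hybrid_id)
    else:
        h = hybrid_id
        if h not in out.nodes or len(out.parent_edges[h]) != 2:
            raise KeyError(f"no hybrid node {hybrid_id!r}")
    minor = out.minor_edge(h)
    major = out.major_edge(h)
    del out.edges[minor.id]
    out.edges[major.id].gamma = None
    del out.hybrid_tags[h]
    out._rebuild()
    _suppress_degree2(out)
    out.validate()
    return out


def add_hybrid_edge(net: PhyloNetwork, source_edge: int, target_edge: int,
                    gamma: float = 0.1, length: float = 0.0,
                    tag: Optional[str] = None) -> PhyloNetwork:
    """Attach a new minor hybrid edge from ``source_edge`` to ``target_edge``.

    Both edges are split at their midpoint by new nodes ``u`` (on the
    source) and ``v`` (on the target); the new edge ``u -> v`` carries the
    minor inheritance probability ``gamma`` and ``v`` becomes a hybrid
    node whose original parent edge is the major one.  Raises
    :class:`NetworkStructureError` if the result is cyclic or not level-1.
    """
    if source_edge == target_edge:
        raise ValueError("source and target edges must differ")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    out = net.copy()
    es, et = out.edges[source_edge], out.edges[target_edge]
    nid = max(out.nodes) + 1
    u, v = nid, nid + 1
    eid = max(out.edges) + 1
    out.nodes[u] = None
    out.nodes[v] = None

    def half(x):
        return None if x is None else x / 2.0

    # split source: parent -> u -> child
    out.edges[eid] = NetEdge(id=eid, parent=es.parent, child=u, length=half(es.length))
    es.parent = u
    es.length = half(es.length)
    # split target: parent -> v -> child
    out.edges[eid + 1] = NetEdge(id=eid + 1, parent=et.parent, child=v,
                                 length=half(et.length), gamma=1.0 - gamma)
    et.parent = v
    et.length = half(et.length)
    # the new minor edge
    out.edges[eid + 2] = NetEdge(id=eid + 2, parent=u, child=v,
                                 length=length, gamma=gamma)
    out._rebuild()
    if tag is not None:
        out.hybrid_tags[v] = tag
    out._assign_missing_tags()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# small-scale greedy hybrid-edge search
# ---------------------------------------------------------------------------

def search_hybrid_edges(start: PhyloNetwork, cfs: QuartetCFTable, hmax: int,
                        seed: int = 0, n_starts: int = 4,
                        t_max: float = T_MAX_DEFAULT) -> list[NetworkFit]:
    """Greedy hybrid-edge search, one optimized fit per k = 0..hmax.

    At each level every level-1-preserving minor-edge attachment between
    two non-adjacent edges of the current best network is optimized and
    the best pseudolikelihood kept (ties broken by enumeration order,
    which is lexicographic in edge ids).  Desk-scale only: refuses more
    than 10 taxa.
    """
    if hmax < 0:
        raise ValueError("hmax must be >= 0")
    n_taxa = len(start.leaf_labels)
    if n_taxa > 10:
        raise ValueError(
            f"{n_taxa} taxa is beyond this desk-scale search; restrict the "
            "taxon set to <= 10 or use a dedicated network-inference tool"
        )
    fits = [optimize_params(start, cfs, seed=seed, n_starts=n_starts, t_max=t_max)]
    current = fits[0].network
    for level in range(1, hmax + 1):
        best: Optional[NetworkFit] = None
        edge_ids = sorted(current.edges)
        for es, et in itertools.permutations(edge_ids, 2):
            a, b = current.edges[es], current.edges[et]
            if len({a.parent, a.child} & {b.parent, b.child}) > 0:
                continue  # adjacent edges cannot host a new cycle
            try:
                cand = add_hybrid_edge(current, es, et, gamma=0.1)
            except (NetworkStructureError, TreeIOError):
                continue
            fit = optimize_params(cand, cfs, seed=seed + 104729 * level,
                                  n_starts=max(2, n_starts // 2), t_max=t_max)
            if best is None or fit.pseudolik > best.pseudolik + 1e-9:
                best = fit
        if best is None:
            break
        fits.append(best)
        current = best.network
    return fits


# ---------------------------------------------------------------------------
# geographic plausibility
# ---------------------------------------------------------------------------

def flag_geography(net: PhyloNetwork,
                   regions: Mapping[str, Iterable[str]]) -> list[str]:
    """Hybrid tags whose edge connects clades with disjoint region sets.

    For each hybrid node, the union of region labels over the recipient
    clade (leaves below the hybrid node) is compared with the union over
    the donor clade (leaves below the minor edge's source, excluding the
    minor edge itself); disjoint unions flag the edge as geographically
    implausible.  Every network leaf must be assigned at least one region.
    """
    missing = [lab for lab in net.leaf_labels if lab not in regions]
    if missing:
        raise ValueError(f"leaves without a region assignment: {missing}")
    reg = {lab: frozenset(regions[lab]) for lab in net.leaf_labels}

    flagged: list[str] = []
    for h in net.hybrid_nodes:
        minor = net.minor_edge(h)
        recipient = net.descendant_leaf_labels(h)
        donor = net.descendant_leaf_labels(minor.parent, skip_edge=minor.id)
        rec_regions = frozenset().union(*(reg[lab] for lab in recipient))
        don_regions = frozenset().union(*(reg[lab] for lab in donor))
        if rec_regions.isdisjoint(don_regions):
            flagged.append(net.hybrid_tags[h])
    return flagged
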