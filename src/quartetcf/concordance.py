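"""Quartet topology counts, concordance factors, bootstrap, consensus.

The concordance factor (CF) of a quartet resolution is the proportion of
loci whose gene tree displays that resolution of the four taxa.  With a
posterior sample of trees per locus, a locus contributes its
sample-frequency vector instead of a 0/1 tally; this is a sample-average
analog of Bayesian concordance analysis, not a reimplementation of it.
"""
from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .treeio import GeneTreeSet, leaf_labels

__all__ = [
    "RESOLUTION_NAMES",
    "TICR_COLUMNS",
    "canonical_quartet",
    "resolution_index",
    "quartet_resolution",
    "QuartetCounts",
    "QuartetCFTable",
    "quartet_counts",
    "cf_table",
    "bootstrap_cf",
    "majority_consensus",
]

#: resolution order for a sorted quartet (t1, t2, t3, t4)
RESOLUTION_NAMES = ("12|34", "13|24", "14|23")

#: TICR-compatible CSV column order
TICR_COLUMNS = ["taxon1", "taxon2", "taxon3", "taxon4",
                "CF12_34", "CF13_24", "CF14_23", "ngenes"]


def canonical_quartet(labels: Iterable[str]) -> tuple[str, str, str, str]:
    labs = tuple(labels)
    if len(labs) != 4:
        raise ValueError(f"a quartet needs exactly 4 labels, got {len(labs)}")
    if len(set(labs)) != 4:
        raise ValueError(f"duplicate labels in quartet: {labs}")
    return tuple(sorted(labs))  # type: ignore[return-value]


def resolution_index(quartet: Sequence[str], pair: frozenset) -> int:
    """Index (0, 1, 2) of the resolution pairing ``pair`` within a sorted quartet."""
    if quartet[0] in pair:
        (partner,) = pair - {quartet[0]}
    else:
        (partner,) = set(quartet[1:]) - pair
    return quartet.index(partner) - 1


# ---------------------------------------------------------------------------
# per-tree quartet resolution via bipartition bitmasks
# ---------------------------------------------------------------------------

def _split_masks(tree: dendropy.Tree, bit_of: dict[str, int]) -> list[int]:
    """Leaf-set bitmask below each edge of the tree (internal nodes only)."""
    masks: list[int] = []
    below: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = 1 << bit_of[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= below[id(c)]
            below[id(node)] = m
            masks.append(m)
    return masks


def _resolution_from_masks(masks: Iterable[int], qbits: Sequence[int]) -> Optional[int]:
    qmask = qbits[0] | qbits[1] | qbits[2] | qbits[3]
    for m in masks:
        mm = m & qmask
        if mm.bit_count() == 2:
            if mm & qbits[0]:
                pairmask = mm
            else:
                pairmask = qmask & ~mm
            # partner of the first taxon determines the resolution index
            for i in (1, 2, 3):
                if pairmask & qbits[i]:
                    return i - 1
    return None


def quartet_resolution(tree: dendropy.Tree, quartet: Iterable[str]) -> Optional[int]:
    """Induced resolution (0, 1, 2) of a quartet in one tree; None if unresolved."""
    q = canonical_quartet(quartet)
    labs = leaf_labels(tree)
    if not set(q) <= labs:
        raise ValueError(f"tree lacks quartet taxa {sorted(set(q) - labs)}")
    bit_of = {lab: i for i, lab in enumerate(sorted(labs))}
    qbits = [1 << bit_of[x] for x in q]
    return _resolution_from_masks(_split_masks(tree, bit_of), qbits)


# ---------------------------------------------------------------------------
# counts and CF tables
# ---------------------------------------------------------------------------

@dataclass
class QuartetCounts:
    """Per-quartet tally of the three resolutions across loci.

    ``counts`` are integers in single-tree mode and fractional in
    posterior-sample mode (each locus contributes its within-sample
    resolution frequencies).  ``sum(counts) == n_resolved <= n_loci``.
    """

    quartet: tuple[str, str, str, str]
    counts: np.ndarray
    n_resolved: float
    n_loci: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3,):
            raise ValueError("counts must have exactly 3 entries")
        if not np.isclose(self.counts.sum(), self.n_resolved, atol=1e-9):
            raise ValueError("counts must sum to n_resolved")
        if self.n_resolved > self.n_loci + 1e-9:
            raise ValueError("n_resolved cannot exceed n_loci")


@dataclass
class QuartetCFTable:
    """Observed (or model) concordance factors, one row per 4-taxon set."""

    quartets: list[tuple[str, str, str, str]]
    cf: np.ndarray        # shape (n, 3), rows sum to 1
    n_eff: np.ndarray     # effective number of loci per row

    def __post_init__(self):
        self.cf = np.asarray(self.cf, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=float)
        n = len(self.quartets)
        if self.cf.shape != (n, 3) or self.n_eff.shape != (n,):
            raise ValueError("CF table shape mismatch")
        if n and (np.any(self.cf < -1e-12) or np.any(self.cf > 1 + 1e-12)):
            raise ValueError("CF entries must lie in [0, 1]")
        if n and np.any(np.abs(self.cf.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each CF row must sum to 1")
        self._row_of = {q: i for i, q in enumerate(self.quartets)}

    def __len__(self) -> int:
        return len(self.quartets)

    def row(self, quartet: Iterable[str]) -> tuple[np.ndarray, float]:
        q = canonical_quartet(quartet)
        i = self._row_of[q]
        return self.cf[i], float(self.n_eff[i])

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for q, cf, ne in zip(self.quartets, self.cf, self.n_eff):
            recs.append(dict(zip(TICR_COLUMNS, [*q, *cf, ne])))
        return pd.DataFrame(recs, columns=TICR_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "QuartetCFTable":
        missing = [c for c in TICR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CF table missing columns: {missing}")
        quartets = [canonical_quartet(row) for row in
                    df[TICR_COLUMNS[:4]].astype(str).itertuples(index=False)]
        cf = df[TICR_COLUMNS[4:7]].to_numpy(dtype=float)
        n_eff = df["ngenes"].to_numpy(dtype=float)
        return cls(quartets, cf, n_eff)

    @classmethod
    def from_csv(cls, path) -> "QuartetCFTable":
        return cls.from_dataframe(pd.read_csv(path))


def _locus_info(gts: GeneTreeSet, bit_of: dict[str, int]):
    """Precompute per-locus leaf masks and per-tree split masks."""
    info = []
    for locus_id, trees in gts.loci:
        labs = leaf_labels(trees[0])
        lmask = 0
        for lab in labs:
            lmask |= 1 << bit_of[lab]
        info.append((lmask, [_split_masks(t, bit_of) for t in trees]))
    return info


def _tally(info, quartet_bits: Sequence[int], unresolved: str
           ) -> tuple[np.ndarray, float, bool]:
    qmask = quartet_bits[0] | quartet_bits[1] | quartet_bits[2] | quartet_bits[3]
    counts = np.zeros(3)
    n_res = 0.0
    found = False
    for lmask, per_tree in info:
        if (lmask & qmask) != qmask:
            continue  # locus lacks one of the four taxa
        found = True
        freq = np.zeros(3)
        nr = 0
        for masks in per_tree:
            r = _resolution_from_masks(masks, quartet_bits)
            if r is None:
                if unresolved == "split":
                    freq += 1.0 / 3.0
                    nr += 1
            else:
                freq[r] += 1
                nr += 1
        if nr:
            counts += freq / nr
            n_res += 1
    return counts, n_res, found


def quartet_counts(gts: GeneTreeSet, quartet: Iterable[str],
                   unresolved: str = "exclude") -> QuartetCounts:
    """Tally the three induced resolutions of one quartet across loci.

    Loci missing any of the four taxa count toward ``n_loci`` but not
    ``n_resolved``.  ``unresolved="exclude"`` (default) drops loci whose
    induced quartet is a polytomy; ``"split"`` spreads them 1/3 each.
    """
    if unresolved not in ("exclude", "split"):
        raise ValueError("unresolved must be 'exclude' or 'split'")
    q = canonical_quartet(quartet)
    universe = gts.labels()
    missing = set(q) - set(universe)
    if missing:
        raise ValueError(f"quartet taxa absent from every locus: {sorted(missing)}")
    bit_of = {lab: i for i, lab in enumerate(universe)}
    qbits = [1 << bit_of[x] for x in q]
    counts, n_res, found = _tally(_locus_info(gts, bit_of), qbits, unresolved)
    if not found:
        raise ValueError(f"no locus contains all four taxa of {q}")
    return QuartetCounts(q, counts, n_res, gts.n_loci)


def cf_table(gts: GeneTreeSet,
             quartets: Union[str, Iterable[Iterable[str]]] = "all",
             unresolved: str = "exclude") -> QuartetCFTable:
    """Observed concordance factors for the requested quartets.

    ``quartets="all"`` enumerates every 4-subset of the taxon universe.
    Rows are ``cf = counts / n_resolved`` with ``n_eff = n_resolved``.
    """
    if unresolved not in ("exclude", "split"):
        raise ValueError("unresolved must be 'exclude' or 'split'")
    universe = gts.labels()
    if quartets == "all":
        qlist = [tuple(c) for c in itertools.combinations(universe, 4)]
        if not qlist:
            raise ValueError("fewer than 4 taxa; no quartets to tabulate")
    else:
        qlist = [canonical_quartet(q) for q in quartets]
    bit_of = {lab: i for i, lab in enumerate(universe)}
    info = _locus_info(gts, bit_of)

    rows_cf = np.empty((len(qlist), 3))
    n_eff = np.empty(len(qlist))
    for i, q in enumerate(qlist):
        qbits = [1 << bit_of[x] for x in q]
        counts, n_res, found = _tally(info, qbits, unresolved)
        if not found or n_res == 0:
            raise ValueError(f"no resolved locus for quartet {q}")
        rows_cf[i] = counts / n_res
        n_eff[i] = n_res
    return QuartetCFTable(qlist, rows_cf, n_eff)


def bootstrap_cf(gts: GeneTreeSet, quartet: Iterable[str], n_boot: int,
                 seed: int, resample_posterior: bool = True,
                 unresolved: str = "exclude"
                 ) -> list[tuple[float, float]]:
    """Percentile 95% bootstrap intervals for the three CFs of one quartet.

    Loci are resampled with replacement; in posterior-sample mode each
    resampled locus additionally draws one tree from its sample per
    replicate (disable with ``resample_posterior=False`` to keep the
    within-locus frequency vector).  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    q = canonical_quartet(quartet)
    universe = gts.labels()
    bit_of = {lab: i for i, lab in enumerate(universe)}
    qbits = [1 << bit_of[x] for x in q]
    qmask = qbits[0] | qbits[1] | qbits[2] | qbits[3]

    # per locus: None (missing taxa) | list of per-tree resolutions
    per_locus: list[Optional[list[Optional[int]]]] = []
    n_contrib = 0
    for lmask, per_tree in _locus_info(gts, bit_of):
        if (lmask & qmask) != qmask:
            per_locus.append(None)
            continue
        res = [_resolution_from_masks(masks, qbits) for masks in per_tree]
        per_locus.append(res)
        n_contrib += 1
    if n_contrib == 0:
        raise ValueError(f"no locus contains all four taxa of {q}")
    if n_contrib == 1:
        warnings.warn(
            "only one locus contains this quartet; bootstrap intervals are degenerate",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    L = len(per_locus)
    reps = np.full((n_boot, 3), np.nan)
    for b in range(n_boot):
        counts = np.zeros(3)
        n_res = 0.0
        for i in rng.integers(0, L, size=L):
            res = per_locus[i]
            if res is None:
                continue
            if len(res) > 1 and resample_posterior:
                r = res[rng.integers(0, len(res))]
                if r is None:
                    if unresolved == "split":
                        counts += 1.0 / 3.0
                        n_res += 1
                    continue
                counts[r] += 1
                n_res += 1
            else:
                freq = np.zeros(3)
                nr = 0
                for r in res:
                    if r is None:
                        if unresolved == "split":
                            freq += 1.0 / 3.0
                            nr += 1
                    else:
                        freq[r] += 1
                        nr += 1
                if nr:
                    counts += freq / nr
                    n_res += 1
        if n_res > 0:
            reps[b] = counts / n_res
    good = reps[~np.isnan(reps[:, 0])]
    if good.size == 0:
        raise ValueError("every bootstrap replicate lacked the quartet")
    lo = np.percentile(good, 2.5, axis=0)
    hi = np.percentile(good, 97.5, axis=0)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


# ---------------------------------------------------------------------------
# thresholded majority-rule consensus
# ---------------------------------------------------------------------------

def majority_consensus(trees: Sequence[dendropy.Tree], threshold: float
                       ) -> dendropy.Tree:
    """Majority-rule consensus containing bipartitions at frequency >= threshold.

    ``threshold`` must lie in (0.5, 1]; frequencies exactly at the
    threshold are included.  Conflicting splits (possible only at exactly
    0.5, excluded here) can therefore never co-occur, and the retained
    splits always form a tree, with polytomies where splits were dropped.
    Internal nodes of the result are labelled with their split frequency.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    ref = leaf_labels(trees[0])
    for t in trees[1:]:
        other = leaf_labels(t)
        if other != ref:
            raise ValueError(
                f"trees differ in leaf sets; symmetric difference: "
                f"{sorted(ref ^ other)}"
            )
    labels = sorted(ref)
    n = len(labels)
    bit_of = {lab: i for i, lab in enumerate(labels)}
    full = (1 << n) - 1

    counter: Counter[int] = Counter()
    for t in trees:
        seen: set[int] = set()
        for m in _split_masks(t, bit_of):
            pc = m.bit_count()
            if pc < 2 or pc > n - 2:
                continue
            if m & 1:  # canonical side excludes the first label
                m ^= full
            seen.add(m)
        counter.update(seen)

    ntrees = len(trees)
    selected = [(m, c / ntrees) for m, c in counter.items()
                if c / ntrees + 1e-12 >= threshold]
    selected.sort(key=lambda mf: (-mf[0].bit_count(), mf[0]))

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    root = tree.seed_node

    node_of: list[tuple[int, dendropy.Node]] = []  # (mask, node), decreasing size

    def attach_parent(mask: int) -> dendropy.Node:
        # smallest already-placed cluster containing mask (insertion order is
        # decreasing size, so scan from the back)
        for pm, pnode in reversed(node_of):
            if pm & mask == mask:
                return pnode
        return root

    for mask, freq in selected:
        node = dendropy.Node()
        node.label = f"{freq:g}"
        attach_parent(mask).add_child(node)
        node_of.append((mask, node))
    node_of.sort(key=lambda mn: mn[0].bit_count())

    for lab in labels:
        bit = 1 << bit_of[lab]
        leaf = dendropy.Node()
        leaf.taxon = ns.require_taxon(label=lab)
        parent = root
        for pm, pnode in node_of:
            if pm & bit:
                parent = pnode
                break
        parent.add_child(leaf)
    return tree
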