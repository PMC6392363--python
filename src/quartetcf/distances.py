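"""Uncorrected p-distances from partitioned multiple alignments.

The p-distance between two aligned sequences is the fraction of differing
sites among pairwise-comparable columns, i.e. columns where both
characters are unambiguous nucleotides (A, C, G, T).  Gaps and IUPAC
ambiguity codes are excluded by pairwise deletion and never counted as
differences.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PartitionedAlignment",
    "parse_raxml_partitions",
    "p_distance",
    "p_distance_matrix",
]

_VALID = frozenset(b"ACGT")


@dataclass
class PartitionedAlignment:
    """Equal-length sequences with named, non-overlapping column partitions.

    Partition intervals are 0-based half-open; the RAxML partition-file
    reader converts from the 1-based inclusive convention.
    """

    names: list[str]
    sequences: list[str]
    partitions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.names:
            raise ValueError("alignment is empty")
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("sequences are not aligned (unequal lengths)")
        occupied: list[tuple[int, int]] = []
        for name, ivs in self.partitions.items():
            for a, b in ivs:
                if not (0 <= a < b <= L):
                    raise ValueError(f"partition {name!r} interval ({a},{b}) "
                                     f"outside alignment of length {L}")
                occupied.append((a, b))
        occupied.sort()
        for (a1, b1), (a2, b2) in zip(occupied, occupied[1:]):
            if a2 < b1:
                raise ValueError("partitions overlap")
        self._arr = {
            name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for name, seq in zip(self.names, self.sequences)
        }

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path, partitions: Optional[Mapping[str, list]] = None
                   ) -> "PartitionedAlignment":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(names, seqs, dict(partitions or {}))

    def columns(self, partition: str = "all") -> np.ndarray:
        if partition == "all":
            return np.arange(self.length)
        if partition not in self.partitions:
            raise KeyError(f"unknown partition {partition!r}")
        idx = [np.arange(a, b) for a, b in self.partitions[partition]]
        return np.concatenate(idx)


_PART_LINE = re.compile(
    r"^\s*(?:[A-Za-z0-9+]+\s*,\s*)?([^=\s]+)\s*=\s*(.+?)\s*$"
)


def parse_raxml_partitions(text: str) -> dict[str, list[tuple[int, int]]]:
    """Parse RAxML-style partition lines, e.g. ``DNA, mt = 1-1140, 2000-2500``.

    Ranges are 1-based inclusive and converted to 0-based half-open.
    Codon-position strides (``1-99\\3``) are not supported.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _PART_LINE.match(line)
        if not m:
            raise ValueError(f"cannot parse partition line: {line!r}")
        name, ranges = m.group(1), m.group(2)
        if name in out:
            raise ValueError(f"duplicate partition name {name!r}")
        ivs: list[tuple[int, int]] = []
        for piece in ranges.split(","):
            piece = piece.strip()
            if "\\" in piece or "/" in piece:
                raise ValueError(
                    f"codon-position strides are not supported: {piece!r}"
                )
            if "-" in piece:
                a, b = piece.split("-", 1)
                ivs.append((int(a) - 1, int(b)))
            else:
                ivs.append((int(piece) - 1, int(piece)))
        out[name] = ivs
    if not out:
        raise ValueError("no partitions found")
    return out


def _pair_distance(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    vx = np.isin(x, np.frombuffer(b"ACGT", dtype=np.uint8))
    vy = np.isin(y, np.frombuffer(b"ACGT", dtype=np.uint8))
    ok = vx & vy
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no pairwise-comparable sites")
    mism = int(((x != y) & ok).sum())
    return mism / n, n


def p_distance(aln: PartitionedAlignment, a: str, b: str,
               partition: str = "all", per_partition_average: bool = False
               ) -> float:
    """Uncorrected p-distance between taxa ``a`` and ``b``.

    ``partition`` selects a named partition or ``"all"`` columns.  With
    ``per_partition_average`` and ``partition="all"``, the unweighted mean
    of per-partition distances is returned instead of the distance over
    the concatenated columns (the two conventions for summarising
    multi-gene distances).
    """
    for t in (a, b):
        if t not in aln._arr:
            raise KeyError(f"taxon {t!r} not in alignment")
    if per_partition_average:
        if partition != "all":
            raise ValueError("per_partition_average applies to partition='all'")
        if not aln.partitions:
            raise ValueError("alignment has no named partitions to average")
        vals = [p_distance(aln, a, b, partition=name)
                for name in aln.partitions]
        return float(np.mean(vals))
    cols = aln.columns(partition)
    d, _ = _pair_distance(aln._arr[a][cols], aln._arr[b][cols])
    return d


def p_distance_matrix(aln: PartitionedAlignment, partition: str = "all"
                      ) -> pd.DataFrame:
    """Symmetric matrix of pairwise p-distances (NaN where incomparable)."""
    n = len(aln.names)
    cols = aln.columns(partition)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, _ = _pair_distance(aln._arr[aln.names[i]][cols],
                                      aln._arr[aln.names[j]][cols])
            except ValueError:
                d = np.nan
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=aln.names, columns=aln.names)
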