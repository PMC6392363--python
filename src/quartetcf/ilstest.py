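"""Reticulation test against an incomplete-lineage-sorting null.

Under the multispecies coalescent with no reticulation, a quartet's two
minor resolutions are equally probable.  Given per-locus topology counts
``(c1, c2, c3)`` over ``n`` loci, the maximum-likelihood ILS null assigns
the major tree probability ``max(c)/n`` and each minor tree
``(n - max(c)) / (2n)``.  The test statistic is the difference between the
two minor-category counts; a large observed difference (e.g. counts
(4, 4, 0): two resolutions at half the loci each and the third at none)
is unlikely under pure ILS and points to reticulation.

By default the major tree is re-identified per dataset as the largest
count (statistic = middle - smallest of the sorted counts); pass
``fixed_major=True`` to fix the major category a priori instead
(statistic = absolute difference of the two remaining counts).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "ILSNullModel",
    "ILSTestResult",
    "fit_ils_null",
    "observed_statistic",
    "pvalue_exact",
    "pvalue_mc",
    "run_ils_test",
]


@dataclass(frozen=True)
class ILSNullModel:
    """Maximum-likelihood ILS multinomial null: (p_major, p_minor, p_minor)."""

    p_major: float
    p_minor: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(self.p_major + 2 * self.p_minor - 1.0) > 1e-9:
            raise ValueError("p_major + 2*p_minor must equal 1")
        if self.p_major < 1.0 / 3.0 - 1e-12 or not (0 <= self.p_minor <= 1.0 / 3.0 + 1e-12):
            raise ValueError("need p_major >= 1/3 and p_minor in [0, 1/3]")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.p_major, self.p_minor, self.p_minor)


@dataclass(frozen=True)
class ILSTestResult:
    counts: tuple[int, int, int]
    model: ILSNullModel
    d_obs: int
    p_exact: float
    p_mc: float
    mc_se: float
    n_sims: int
    seed: int
    fixed_major: bool

    def to_dict(self) -> dict:
        return {
            "counts": list(self.counts),
            "p_major": self.model.p_major,
            "p_minor": self.model.p_minor,
            "D_obs": self.d_obs,
            "p_exact": self.p_exact,
            "p_mc": self.p_mc,
            "se": self.mc_se,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "fixed_major": self.fixed_major,
        }


def _check_counts(counts: Sequence[int]) -> tuple[int, int, int]:
    c = tuple(int(x) for x in counts)
    if len(c) != 3:
        raise ValueError("counts must have exactly 3 entries")
    if any(x < 0 for x in c):
        raise ValueError("counts must be nonnegative")
    if sum(c) == 0:
        raise ValueError("counts must not all be zero")
    return c  # type: ignore[return-value]


def fit_ils_null(counts: Sequence[int]) -> ILSNullModel:
    """ML fit of the ILS null: p_major = max(c)/n, p_minor = (n - max(c))/(2n)."""
    c = _check_counts(counts)
    n = sum(c)
    cmax = max(c)
    return ILSNullModel(p_major=cmax / n, p_minor=(n - cmax) / (2 * n), n=n)


def observed_statistic(counts: Sequence[int], fixed_major: bool = False) -> int:
    """Minor-count difference statistic.

    Default: sort the counts, take middle minus smallest (the major tree is
    whichever category is largest in this dataset).  With ``fixed_major``
    the major category is the first maximal index of the *observed* data
    convention, i.e. category 0 is taken as fixed and the statistic is
    ``|c2 - c3|``.
    """
    c = _check_counts(counts)
    if fixed_major:
        return abs(c[1] - c[2])
    s = sorted(c)
    return s[1] - s[0]


def _stat_of_composition(n1: int, n2: int, n3: int, fixed_major: bool) -> int:
    if fixed_major:
        return abs(n2 - n3)
    a, b, _ = sorted((n1, n2, n3))
    return b - a


def pvalue_exact(model: ILSNullModel, d_obs: int, fixed_major: bool = False) -> float:
    """P(statistic >= d_obs) by full enumeration of the multinomial.

    Sums the exact multinomial probability (rational arithmetic, converted
    to float at the end) over all compositions of ``n`` into three
    categories with probabilities (p_major, p_minor, p_minor).
    """
    if d_obs < 0:
        raise ValueError("d_obs must be >= 0")
    if d_obs == 0:
        return 1.0
    n = model.n
    p1 = Fraction(model.p_major)
    p2 = Fraction(model.p_minor)
    total = Fraction(0)
    for n1 in range(n + 1):
        for n2 in range(n - n1 + 1):
            n3 = n - n1 - n2
            if _stat_of_composition(n1, n2, n3, fixed_major) < d_obs:
                continue
            coef = math.comb(n, n1) * math.comb(n - n1, n2)
            total += coef * p1**n1 * p2**(n2 + n3)
    return float(total)


def pvalue_mc(model: ILSNullModel, d_obs: int, n_sims: int, seed: int,
              fixed_major: bool = False) -> tuple[float, float]:
    """Monte-Carlo P(statistic >= d_obs) with its binomial standard error."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if d_obs < 0:
        raise ValueError("d_obs must be >= 0")
    if d_obs == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(model.n, model.probs, size=n_sims)
    if fixed_major:
        stat = np.abs(draws[:, 1] - draws[:, 2])
    else:
        s = np.sort(draws, axis=1)
        stat = s[:, 1] - s[:, 0]
    p = float(np.mean(stat >= d_obs))
    se = math.sqrt(p * (1.0 - p) / n_sims)
    return p, se


def run_ils_test(counts: Sequence[int], n_sims: int = 100_000, seed: int = 0,
                 fixed_major: bool = False) -> ILSTestResult:
    """Fit the ILS null to the counts and compute exact and MC p-values."""
    c = _check_counts(counts)
    model = fit_ils_null(c)
    d_obs = observed_statistic(c, fixed_major=fixed_major)
    p_exact = pvalue_exact(model, d_obs, fixed_major=fixed_major)
    p_mc, se = pvalue_mc(model, d_obs, n_sims, seed, fixed_major=fixed_major)
    return ILSTestResult(
        counts=c, model=model, d_obs=d_obs, p_exact=p_exact,
        p_mc=p_mc, mc_se=se, n_sims=n_sims, seed=seed, fixed_major=fixed_major,
    )
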