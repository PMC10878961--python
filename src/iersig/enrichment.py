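"""Gene-list overlap statistics: Fisher's exact test, odds ratios, BH, combined score.

Given two gene lists A and B inside a declared universe U (for the reference
signature work, 78 signature genes inside the 19,570-gene array universe), the
2x2 table is

    a = |A n B|,  b = |A \\ B|,  c = |B \\ A|,  d = |U \\ (A u B)|

The two-sided p value sums hypergeometric probabilities (at fixed margins) of
tables no more probable than the observed one (the minimum-likelihood
definition); the one-sided "greater" p sums the upper tail a' >= a.  The odds
ratio is the sample OR ``a*d / (b*c)`` with a Haldane-Anscombe +0.5 added to
every cell only when some cell is zero.

Over-representation against a whole collection mirrors an Enrichr-style
report: one-sided Fisher p per set, Benjamini-Hochberg q across the
collection, and a combined score ``-ln(p) * OR``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSet, GeneSetCollection

# relative tolerance when comparing table probabilities for the two-sided sum;
# guards against float noise deciding inclusion of an equal-probability table
_REL_TOL = 1e-7


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap table with Fisher p values and odds ratio."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    p_one_sided_greater: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: OverlapResult
    q_value: float
    combined_score: float


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_overlap_counts(a: int, b: int, c: int, d: int) -> OverlapResult:
    """Fisher's exact test from the four cells of a 2x2 table.

    Margins are held fixed; the two-sided p uses the minimum-likelihood
    definition.  Zero cells trigger the Haldane-Anscombe correction for the
    odds ratio only (p values are always exact).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    M = a + b + c + d
    if M == 0:
        raise ValueError("empty 2x2 table")
    n_a = a + b  # size of list A
    n_b = a + c  # size of list B
    lo = max(0, n_a + n_b - M)
    hi = min(n_a, n_b)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, M, n_a, n_b)
    p_obs = pmf[support == a][0]
    p_two = float(min(1.0, pmf[pmf <= p_obs * (1 + _REL_TOL)].sum()))
    p_one = float(min(1.0, pmf[support >= a].sum()))
    return OverlapResult(a, b, c, d, _odds_ratio(a, b, c, d), p_two, p_one)


def fisher_overlap(A: GeneSet, B: GeneSet, universe) -> OverlapResult:
    """Overlap test between two gene sets inside a declared universe.

    Genes outside the universe are trimmed with a warning (cross-platform
    symbol drift is routine); an empty universe is an error.
    """
    universe = frozenset(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    ga, gb = set(A.genes), set(B.genes)
    for name, g in ((A.name, ga), (B.name, gb)):
        outside = g - universe
        if outside:
            warnings.warn(
                f"{len(outside)} genes of set {name!r} outside the universe "
                "were trimmed"
            )
    ga &= universe
    gb &= universe
    a = len(ga & gb)
    b = len(ga - gb)
    c = len(gb - ga)
    d = len(universe) - a - b - c
    return fisher_overlap_counts(a, b, c, d)


def bh_adjust(pvals) -> list:
    """Benjamini-Hochberg step-up adjusted q values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_collection(query: GeneSet, coll: GeneSetCollection) -> list:
    """Over-representation of ``query`` against every set in a collection.

    Returns one :class:`EnrichmentRow` per set, sorted by combined score
    descending (ties broken by set name).  The combined score is
    ``-ln(p_one_sided) * odds_ratio`` and is defined as 0 when p = 1.
    """
    if len(coll) == 0:
        raise ValueError("empty gene-set collection")
    universe = coll.universe
    usable = set(query.genes) & universe
    if not usable:
        raise ValueError(
            f"query set {query.name!r} is disjoint from the collection universe"
        )
    overlaps = [fisher_overlap(query, s, universe) for s in coll]
    qvals = bh_adjust([ov.p_one_sided_greater for ov in overlaps])
    rows = []
    for s, ov, q in zip(coll, overlaps, qvals):
        p = ov.p_one_sided_greater
        combined = 0.0 if p >= 1.0 else -math.log(p) * ov.odds_ratio
        rows.append(EnrichmentRow(s.name, ov, float(q), float(combined)))
    rows.sort(key=lambda r: (-r.combined_score, r.set_name))
    return rows
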