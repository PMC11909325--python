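"""Rank statistics for cross-surface screen comparison.

Spearman's rank correlation and the Mann-Whitney U test are implemented
here directly (mid-rank tie convention throughout, exact small-sample
enumeration for the U test) rather than delegated, so their conventions are
pinned down and testable against brute-force oracles; scipy is used only as
an independent cross-check in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "midranks", "spearman", "mann_whitney", "MannWhitneyResult",
    "rank_compare", "RankComparison", "venn", "HitVenn",
]


def midranks(values: Sequence[float]) -> np.ndarray:
    """1-based ranks with ties sharing the average (mid) rank."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average of 1-based i+1..j+1
        i = j + 1
    return ranks


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's r_s: Pearson correlation of mid-ranks.

    Returns NaN (with a warning) when either vector is constant, where the
    coefficient is undefined. Tie-free co-/anti-monotone inputs give exactly
    +1 / -1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires length >= 3")
    rx = midranks(x)
    ry = midranks(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    sx = float(np.sqrt((dx ** 2).sum()))
    sy = float(np.sqrt((dy ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        warnings.warn("spearman undefined for a constant vector; returning NaN",
                      stacklevel=2)
        return float("nan")
    return float((dx * dy).sum() / (sx * sy))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" or "normal"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample ``a`` from pooled mid-ranks: R1 - n1(n1+1)/2."""
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    r1 = float(ranks[: a.size].sum())
    return r1 - a.size * (a.size + 1) / 2.0


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    exact_max_n: int = 12,
) -> MannWhitneyResult:
    """Mann-Whitney U test (two-sided) with mid-rank ties.

    For tie-free samples with ``n1 + n2 <= exact_max_n`` the p-value is exact
    by enumerating all C(n1+n2, n1) labelings:
    ``p = min(1, 2 min(P(U <= u), P(U >= u)))`` under the null. Otherwise a
    normal approximation with tie correction and a 0.5 continuity correction
    is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= exact_max_n:
        total = math.comb(n1 + n2, n1)
        le = ge = 0
        eps = 1e-12
        for combo in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u_i = _u_statistic(pooled[mask], pooled[~mask])
            if u_i <= u + eps:
                le += 1
            if u_i >= u - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le / total, ge / total))
        return MannWhitneyResult(u, p, n1, n2, "exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u, 1.0, n1, n2, "normal")
    diff = u - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
    return MannWhitneyResult(u, p, n1, n2, "normal")


@dataclass
class RankComparison:
    """Paired-rank data of several surfaces against a reference surface.

    ``ranks`` maps surface -> (reference ranks, surface ranks) paired by
    fragment; ``rs`` maps surface -> Spearman r_s against the reference;
    ``sorted_occupancies`` maps every surface (reference included) to its
    occupancies sorted ascending (the ordered-overlay plot data).
    """

    reference: str
    fragment_ids: list[str]
    ranks: dict[str, tuple[np.ndarray, np.ndarray]]
    rs: dict[str, float]
    sorted_occupancies: dict[str, np.ndarray]


def rank_compare(
    occupancies: Mapping[str, Mapping[str, float]],
    reference: str,
) -> RankComparison:
    """Rank fragments per surface and correlate each surface with ``reference``.

    ``occupancies`` maps surface -> {fragment_id -> occupancy%}; every
    surface must cover the same fragment set.
    """
    if reference not in occupancies:
        raise ValueError(f"reference surface {reference!r} not in input")
    frag_sets = {s: frozenset(d) for s, d in occupancies.items()}
    base = frag_sets[reference]
    for s, ids in frag_sets.items():
        if ids != base:
            missing = sorted(base ^ ids)[:5]
            raise ValueError(
                f"fragment sets differ between {reference!r} and {s!r} "
                f"(e.g. {missing})"
            )
    frag_ids = sorted(base)
    ref_vals = [occupancies[reference][f] for f in frag_ids]
    ref_ranks = midranks(ref_vals)
    ranks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rs: dict[str, float] = {}
    sorted_occ = {
        s: np.sort(np.array([d[f] for f in frag_ids], dtype=float))
        for s, d in occupancies.items()
    }
    for s, d in occupancies.items():
        if s == reference:
            continue
        vals = [d[f] for f in frag_ids]
        ranks[s] = (ref_ranks.copy(), midranks(vals))
        rs[s] = spearman(ref_vals, vals)
    return RankComparison(
        reference=reference,
        fragment_ids=frag_ids,
        ranks=ranks,
        rs=rs,
        sorted_occupancies=sorted_occ,
    )


@dataclass
class HitVenn:
    """Disjoint membership regions over up to four named hit sets.

    ``regions`` maps a boolean membership pattern (aligned with ``names``)
    to the set of fragment ids in exactly those hit sets; patterns with no
    members map to empty sets. Region contents are invariant under input
    order and their union equals the union of the inputs.
    """

    names: tuple[str, ...]
    regions: dict[tuple[bool, ...], frozenset[str]]

    def counts(self) -> dict[tuple[bool, ...], int]:
        return {pattern: len(ids) for pattern, ids in self.regions.items()}


def venn(hit_sets: Mapping[str, Iterable[str]]) -> HitVenn:
    """Decompose up to four named hit sets into their 2^k - 1 disjoint regions."""
    names = tuple(hit_sets)
    if not 1 <= len(names) <= 4:
        raise ValueError("venn supports 1 to 4 hit sets")
    sets = {name: frozenset(ids) for name, ids in hit_sets.items()}
    universe = frozenset().union(*sets.values()) if sets else frozenset()
    regions: dict[tuple[bool, ...], frozenset[str]] = {}
    for pattern in itertools.product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        members = set(universe)
        for name, included in zip(names, pattern):
            if included:
                members &= sets[name]
            else:
                members -= sets[name]
        regions[pattern] = frozenset(members)
    return HitVenn(names=names, regions=regions)
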