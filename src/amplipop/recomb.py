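"""Infinite-sites compliance filtering of per-locus alignments.

Coalescent samplers that assume an infinite-sites, nonrecombining locus
require alignments in which every column is biallelic and every pair of
segregating sites passes the four-gamete test.  This module drops columns
with more than two alleles, computes pairwise four-gamete compatibility,
and extracts the longest contiguous nonrecombinant block, optionally
removing a bounded number of recombinant individuals.

The block objective is explicit and fixed: maximize the number of
segregating sites retained in a contiguous interval, with ties broken by
more retained individuals, then by the leftmost start.  Published tools for
this step optimize a weighted individuals-times-sites score whose weighting
varies; the objective here is deliberately simpler and is oracle-tested
against exhaustive search at small sizes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCompatibilityMatrix",
    "NonrecombinantBlock",
    "drop_multiallelic_sites",
    "pairwise_compatibility",
    "longest_nonrecombinant_block",
    "filter_alignment",
]

_EXACT_SUBSET_LIMIT = 200_000  # max removal subsets tried exhaustively


def _codes(alignment) -> np.ndarray:
    """Accept an (n, L) uint8 code matrix or an object exposing ``.codes``."""
    m = getattr(alignment, "codes", alignment)
    m = np.asarray(m, dtype=np.uint8)
    if m.ndim != 2:
        raise ValueError("alignment must be a 2-D matrix of base codes")
    return m


def _column_states(col: np.ndarray) -> np.ndarray:
    """Distinct non-missing, non-gap states in one column."""
    return np.unique(col[col < 4])


def drop_multiallelic_sites(alignment) -> Tuple[np.ndarray, np.ndarray]:
    """Remove every column with more than two distinct base states.

    Gap and missing characters do not count as states.  Returns the
    filtered matrix and the kept original column indices (the coordinate
    map back to the input alignment).
    """
    m = _codes(alignment)
    keep = np.array([_column_states(m[:, j]).size <= 2
                     for j in range(m.shape[1])], dtype=bool)
    kept = np.nonzero(keep)[0]
    return m[:, kept], kept


def _segregating_sites(m: np.ndarray, rows: Optional[np.ndarray] = None
                       ) -> np.ndarray:
    sub = m if rows is None else m[rows]
    return np.array([j for j in range(m.shape[1])
                     if _column_states(sub[:, j]).size == 2], dtype=np.int64)


def _four_gamete_ok(a: np.ndarray, b: np.ndarray) -> bool:
    """Four-gamete test on two biallelic columns; a gamete requires both
    sites observed in the same row."""
    ok = (a < 4) & (b < 4)
    pairs = {(int(x), int(y)) for x, y in zip(a[ok], b[ok])}
    return len(pairs) <= 3


@dataclass
class SiteCompatibilityMatrix:
    """Pairwise four-gamete compatibility over segregating sites."""

    positions: np.ndarray    # alignment coordinates of segregating sites
    compatible: np.ndarray   # (S, S) bool, symmetric, True on the diagonal

    @property
    def n_incompatible_pairs(self) -> int:
        return int((~self.compatible).sum() // 2)


def pairwise_compatibility(alignment,
                           rows: Optional[np.ndarray] = None
                           ) -> SiteCompatibilityMatrix:
    """Apply the four-gamete test to every pair of segregating sites.

    Columns with more than two states must have been dropped first
    (:func:`drop_multiallelic_sites`).  ``rows`` optionally restricts the
    test to a subset of individuals.
    """
    m = _codes(alignment)
    sub = m if rows is None else m[rows]
    for j in range(m.shape[1]):
        if _column_states(sub[:, j]).size > 2:
            raise ValueError(f"column {j} has >2 alleles; filter first")
    seg = _segregating_sites(m, rows)
    S = seg.size
    comp = np.ones((S, S), dtype=bool)
    for i in range(S):
        for j in range(i + 1, S):
            ok = _four_gamete_ok(sub[:, seg[i]], sub[:, seg[j]])
            comp[i, j] = comp[j, i] = ok
    return SiteCompatibilityMatrix(positions=seg, compatible=comp)


@dataclass
class NonrecombinantBlock:
    """The retained alignment interval and individuals of one locus."""

    start: int                       # [start, end) in alignment coordinates
    end: int
    retained_rows: np.ndarray        # indices of retained individuals/rows
    n_segregating: int               # segregating sites inside the block

    @property
    def width(self) -> int:
        return self.end - self.start


def _interval_objective(m: np.ndarray, seg: np.ndarray, rows: np.ndarray,
                        a: int, b: int) -> int:
    """Number of sites in seg[a..b] still segregating among ``rows``."""
    count = 0
    for j in seg[a:b + 1]:
        if _column_states(m[rows, j]).size == 2:
            count += 1
    return count


def _pairs_ok(m: np.ndarray, seg: np.ndarray, rows: np.ndarray,
              a: int, b: int) -> bool:
    for i in range(a, b + 1):
        for j in range(i + 1, b + 1):
            if not _four_gamete_ok(m[rows, seg[i]], m[rows, seg[j]]):
                return False
    return True


def _min_removal(m: np.ndarray, seg: np.ndarray, a: int, b: int,
                 max_remove: int) -> Optional[np.ndarray]:
    """Smallest row subset (size <= max_remove) whose removal makes every
    site pair in seg[a..b] compatible; None if impossible within the bound.

    Subsets are tried exhaustively in increasing size over the rows that
    actually carry an incompatibility, falling back to a greedy
    most-incompatibilities-resolved heuristic when the exhaustive budget
    would be exceeded.
    """
    n = m.shape[0]
    all_rows = np.arange(n)
    if _pairs_ok(m, seg, all_rows, a, b):
        return np.array([], dtype=np.int64)
    if max_remove == 0:
        return None

    # candidate pool: rows carrying a gamete rare enough that removing
    # <= max_remove rows could eliminate it from some incompatible pair
    # (any row of a minimal working subset must be such a carrier)
    pool = set()
    for i in range(a, b + 1):
        for j in range(i + 1, b + 1):
            ci, cj = m[:, seg[i]], m[:, seg[j]]
            ok = (ci < 4) & (cj < 4)
            if not _four_gamete_ok(ci, cj):
                pairs: Dict[Tuple[int, int], List[int]] = {}
                for r in np.nonzero(ok)[0]:
                    pairs.setdefault((int(ci[r]), int(cj[r])), []).append(int(r))
                for carriers in pairs.values():
                    if len(carriers) <= max_remove:
                        pool.update(carriers)
    pool_list = sorted(pool)

    # exhaustive search in increasing subset size
    budget = sum(math.comb(len(pool_list), r)
                 for r in range(1, max_remove + 1))
    if budget <= _EXACT_SUBSET_LIMIT:
        for r in range(1, max_remove + 1):
            working = [subset for subset in
                       itertools.combinations(pool_list, r)
                       if _pairs_ok(m, seg, np.setdiff1d(all_rows, subset),
                                    a, b)]
            if working:
                # among minimal subsets prefer the one retaining the most
                # segregating sites, then the lexicographically smallest
                best = max(working, key=lambda s: (
                    _interval_objective(m, seg, np.setdiff1d(all_rows, s),
                                        a, b),
                    tuple(-x for x in s)))
                return np.array(best, dtype=np.int64)
        return None

    # greedy fallback for large alignments: repeatedly drop the row whose
    # removal resolves the most incompatible pairs
    removed: List[int] = []
    rows = all_rows
    for _ in range(max_remove):
        base = _count_bad_pairs(m, seg, rows, a, b)
        if base == 0:
            break
        best_row, best_bad = None, base
        for rrow in rows:
            trial = rows[rows != rrow]
            bad = _count_bad_pairs(m, seg, trial, a, b)
            if bad < best_bad:
                best_row, best_bad = int(rrow), bad
        if best_row is None:
            return None
        removed.append(best_row)
        rows = rows[rows != best_row]
    if _pairs_ok(m, seg, rows, a, b):
        return np.array(sorted(removed), dtype=np.int64)
    return None


def _count_bad_pairs(m: np.ndarray, seg: np.ndarray, rows: np.ndarray,
                     a: int, b: int) -> int:
    bad = 0
    for i in range(a, b + 1):
        for j in range(i + 1, b + 1):
            if not _four_gamete_ok(m[rows, seg[i]], m[rows, seg[j]]):
                bad += 1
    return bad


def longest_nonrecombinant_block(alignment,
                                 allow_individual_removal: bool = False,
                                 min_keep_fraction: float = 0.9
                                 ) -> NonrecombinantBlock:
    """Extract the longest contiguous four-gamete-compatible block.

    Among all contiguous intervals of segregating sites (optionally after
    removing individuals, never keeping fewer than ``min_keep_fraction`` of
    the rows), the block maximizing the number of retained segregating
    sites wins; ties go to more retained individuals, then the leftmost
    start.  Multiallelic sites must already be dropped.
    """
    m = _codes(alignment)
    n, L = m.shape
    if n == 0 or L == 0:
        return NonrecombinantBlock(0, 0, np.arange(n), 0)
    seg = _segregating_sites(m)
    all_rows = np.arange(n)
    if seg.size == 0:
        return NonrecombinantBlock(0, L, all_rows, 0)
    # epsilon guards the floor against float error, e.g. (1-0.8)*5 = 0.999...
    max_remove = (int(np.floor((1.0 - min_keep_fraction) * n + 1e-9))
                  if allow_individual_removal else 0)

    best = None  # (n_sites, n_rows, -start, a, b, removed)
    S = seg.size
    for a in range(S):
        for b in range(a, S):
            removed = _min_removal(m, seg, a, b, max_remove)
            if removed is None:
                continue
            rows = np.setdiff1d(all_rows, removed)
            n_sites = _interval_objective(m, seg, rows, a, b)
            start = 0 if a == 0 else int(seg[a - 1]) + 1
            key = (n_sites, rows.size, -start)
            if best is None or key > best[0]:
                best = (key, a, b, removed)
    assert best is not None  # the single-site interval always succeeds
    _, a, b, removed = best
    rows = np.setdiff1d(all_rows, removed)
    start = 0 if a == 0 else int(seg[a - 1]) + 1
    end = L if b == S - 1 else int(seg[b + 1])
    n_sites = _interval_objective(m, seg, rows, a, b)
    return NonrecombinantBlock(start=start, end=end, retained_rows=rows,
                               n_segregating=n_sites)


def filter_alignment(alignment, allow_individual_removal: bool = False,
                     min_keep_fraction: float = 0.9
                     ) -> Tuple[np.ndarray, np.ndarray, NonrecombinantBlock]:
    """Full infinite-sites filter: drop >2-allele columns, then return the
    longest nonrecombinant block as a (rows, columns)-subset code matrix.

    Returns ``(submatrix, kept_columns, block)`` where ``kept_columns`` are
    original alignment coordinates of the block's columns.
    """
    m, kept = drop_multiallelic_sites(alignment)
    block = longest_nonrecombinant_block(
        m, allow_individual_removal=allow_individual_removal,
        min_keep_fraction=min_keep_fraction)
    cols = np.arange(block.start, block.end)
    sub = m[np.ix_(block.retained_rows, cols)]
    return sub, kept[cols], block
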