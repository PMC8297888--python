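"""0-dimensional sublevel-set persistence of an RR tachogram.

The tachogram is the piecewise-linear interpolation f of the sequence
(r_0, ..., r_n) over beat indices 0..n.  Sweeping a threshold t upward,
connected components of the sublevel set f^{-1}((-inf, t]) are born at
local minima and die when they merge at local maxima; the elder rule
keeps the component with the earlier birth.  The surviving global
component is paired with max f.  Because linear interpolation adds no
critical points, this equals the lower-star filtration persistence of
the path graph on the beat indices, computed here by a union-find sweep.

:func:`oracle_persistence` recomputes the same diagram definitionally —
sweeping thresholds and labelling components of the sublevel set by
interval arithmetic on the x-axis — and exists purely as an independent
cross-check for the fast implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .series import RRSeries

__all__ = [
    "PersistencePair",
    "PersistenceDiagram",
    "compute_persistence",
    "oracle_persistence",
]


@dataclass(frozen=True, order=True)
class PersistencePair:
    """A birth-death pair (b, d) of one connected component, in ms."""

    birth: float
    death: float

    def __post_init__(self) -> None:
        if self.death < self.birth:
            raise ValueError("death must be >= birth")

    @property
    def length(self) -> float:
        """Persistence d - b of the component, ms."""
        return self.death - self.birth

    @property
    def middle(self) -> float:
        """Midpoint (b + d) / 2 of the persistence interval, ms."""
        return 0.5 * (self.birth + self.death)


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of birth-death pairs of one tachogram.

    ``pairs`` are stored sorted by interval length ascending (ties by
    birth then death), matching the ordering l_1 <= ... <= l_k used by
    all the index definitions.  ``n_beats`` records the length of the
    originating RR series, used by the per-beat normalisation of the
    total persistence.
    """

    pairs: tuple[PersistencePair, ...]
    n_beats: int | None = None

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.pairs, key=lambda p: (p.length, p.birth, p.death))
        )
        object.__setattr__(self, "pairs", ordered)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_intervals(self) -> int:
        """Number of persistence intervals k."""
        return len(self.pairs)

    @property
    def lengths(self) -> np.ndarray:
        """Interval lengths l_1 <= ... <= l_k, ms."""
        return np.asarray([p.length for p in self.pairs], dtype=float)

    @property
    def births(self) -> np.ndarray:
        return np.asarray([p.birth for p in self.pairs], dtype=float)

    @property
    def deaths(self) -> np.ndarray:
        return np.asarray([p.death for p in self.pairs], dtype=float)

    @property
    def total_length(self) -> float:
        """Total persistence L = sum of all interval lengths, ms."""
        return float(self.lengths.sum())

    def as_multiset(self) -> tuple[tuple[float, float], ...]:
        """Sorted (birth, death) tuples — canonical form for comparison."""
        return tuple(sorted((p.birth, p.death) for p in self.pairs))

    def points(self) -> np.ndarray:
        """(k, 2) array of (birth, death) points, multiplicity preserved."""
        return np.column_stack([self.births, self.deaths])


def _validated_values(series: RRSeries | Sequence[float]) -> np.ndarray:
    if isinstance(series, RRSeries):
        return series.values
    vals = np.asarray(series, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(vals)):
        raise ValueError("invalid RR value: non-finite value")
    return vals


def compute_persistence(series: RRSeries | Sequence[float]) -> PersistenceDiagram:
    """Persistence diagram of the sublevel-set filtration of a tachogram.

    Vertices (beat indices) are processed in ascending (value, index)
    order.  A vertex with no previously-processed neighbour on the path
    graph starts a new component (a birth at its value); a vertex
    joining two distinct components merges them at its value, and the
    component with the larger birth dies (elder rule; birth ties broken
    by keeping the component whose originating index is smaller — the
    resulting multiset does not depend on this choice).  The last
    surviving component is paired with the maximum value.

    Parameters
    ----------
    series
        RR series or plain value sequence; values must be finite.

    Returns
    -------
    PersistenceDiagram
        All (birth, death) pairs, including the global pair
        (min values, max values).
    """
    vals = _validated_values(series)
    n = vals.shape[0]
    if n == 1:
        return PersistenceDiagram(
            (PersistencePair(float(vals[0]), float(vals[0])),), n_beats=1
        )

    order = np.lexsort((np.arange(n), vals))  # ascending (value, index)
    parent = np.full(n, -1, dtype=np.int64)  # -1: not yet in filtration
    # per-root component record: (birth value, originating index)
    birth_val = np.empty(n, dtype=float)
    birth_idx = np.empty(n, dtype=np.int64)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    pairs: list[PersistencePair] = []
    for v in order:
        val = float(vals[v])
        parent[v] = v
        birth_val[v] = val
        birth_idx[v] = v
        for nb in (v - 1, v + 1):
            if nb < 0 or nb >= n or parent[nb] == -1:
                continue
            ra, rb = find(v), find(nb)
            if ra == rb:
                continue
            # elder rule: survivor has the smaller (birth, index)
            if (birth_val[ra], birth_idx[ra]) <= (birth_val[rb], birth_idx[rb]):
                elder, younger = ra, rb
            else:
                elder, younger = rb, ra
            if birth_val[younger] < val:
                pairs.append(PersistencePair(float(birth_val[younger]), val))
            # birth == merge value only happens on plateaus / descending
            # shoulders, where the continuous sublevel set never has a
            # separate component: merge silently, no zero-length pair
            parent[younger] = elder

    pairs.append(PersistencePair(float(vals.min()), float(vals.max())))
    return PersistenceDiagram(tuple(pairs), n_beats=n)


def _sublevel_intervals(vals: np.ndarray, t: float) -> list[tuple[float, float]]:
    """Maximal x-intervals where the PL interpolation of ``vals`` is <= t.

    The interpolation is linear between integer x-coordinates.  Returns
    disjoint closed intervals, sorted, possibly degenerate (points).
    """
    n = vals.shape[0]
    segs: list[tuple[float, float]] = []
    for i in range(n):
        if vals[i] <= t:
            segs.append((float(i), float(i)))
    for i in range(n - 1):
        a, b = vals[i], vals[i + 1]
        lo, hi = float(i), float(i + 1)
        if a <= t and b <= t:
            segs.append((lo, hi))
        elif a <= t < b:
            x = lo + (t - a) / (b - a)
            segs.append((lo, x))
        elif b <= t < a:
            x = lo + (a - t) / (a - b)
            segs.append((x, hi))
    if not segs:
        return []
    segs.sort()
    merged = [segs[0]]
    for lo, hi in segs[1:]:
        mlo, mhi = merged[-1]
        if lo <= mhi:
            merged[-1] = (mlo, max(mhi, hi))
        else:
            merged.append((lo, hi))
    return merged


def oracle_persistence(series: RRSeries | Sequence[float]) -> PersistenceDiagram:
    """Definitional threshold-sweep computation of the same diagram.

    Sweeps the sorted distinct values; at each threshold the sublevel
    set of the piecewise-linear graph is decomposed into x-intervals,
    and components are tracked by containment between consecutive
    thresholds.  Births are recorded at new intervals, deaths at merges
    under the elder rule, and the survivor is paired with max f.
    Intended for small series (independent verification oracle).
    """
    vals = _validated_values(series)
    n = vals.shape[0]
    if n == 1:
        return PersistenceDiagram(
            (PersistencePair(float(vals[0]), float(vals[0])),), n_beats=1
        )

    # live components: list of dicts {lo, hi, birth, anchor}
    live: list[dict] = []
    pairs: list[PersistencePair] = []
    for t in np.unique(vals):
        t = float(t)
        new_live: list[dict] = []
        for lo, hi in _sublevel_intervals(vals, t):
            # components only grow, so overlap with a previous-threshold
            # component is equivalent to containment (overlap is robust
            # to rounding of the crossing coordinates)
            eps = 1e-9
            inside = [
                c for c in live if c["lo"] <= hi + eps and lo <= c["hi"] + eps
            ]
            if not inside:
                # new component born at this threshold; anchor at the
                # smallest beat index inside the interval
                anchor = int(np.ceil(lo - 1e-12))
                new_live.append({"lo": lo, "hi": hi, "birth": t, "anchor": anchor})
            else:
                elder = min(inside, key=lambda c: (c["birth"], c["anchor"]))
                for c in inside:
                    if c is elder:
                        continue
                    pairs.append(PersistencePair(c["birth"], t))
                new_live.append(
                    {"lo": lo, "hi": hi, "birth": elder["birth"],
                     "anchor": elder["anchor"]}
                )
        live = new_live
    assert len(live) == 1, "sublevel set must be connected at max f"
    pairs.append(PersistencePair(live[0]["birth"], float(vals.max())))
    return PersistenceDiagram(tuple(pairs), n_beats=n)


def strict_local_min_count(values: Iterable[float]) -> int:
    """Number of strict local minima of the plateau-collapsed sequence.

    Runs of equal consecutive values are collapsed to one sample; an
    interior sample counts if smaller than both neighbours, a boundary
    sample if smaller than its single neighbour.  Equals the number of
    persistence intervals of the tachogram.
    """
    vals = [float(v) for v in values]
    collapsed = [vals[0]]
    for v in vals[1:]:
        if v != collapsed[-1]:
            collapsed.append(v)
    m = len(collapsed)
    if m == 1:
        return 1
    count = 0
    for i, v in enumerate(collapsed):
        left_ok = i == 0 or collapsed[i - 1] > v
        right_ok = i == m - 1 or collapsed[i + 1] > v
        if left_ok and right_ok:
            count += 1
    return count
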