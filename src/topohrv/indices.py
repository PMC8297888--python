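"""Scalar topological descriptors of a persistence diagram.

Given the persistence intervals of a tachogram sorted by length,
l_1 <= ... <= l_k with total persistence L = sum l_i, this module
computes the index families used for HRV characterisation:

* length statistics (longest interval, mean/median/stdev/sum, and the
  2/1 and 3/1 ratios of the longest intervals),
* persistent entropy h = -sum (l_i/L) log2(l_i/L) and its normed
  variant h / log2(L),
* threshold-based counts: with the length threshold set at 5% of the
  longest interval and p the first index with l_p above it, frac5% =
  (k - p + 1)/k, plus the absolute-length fractions frac100 / frac200,
* signal-to-noise: total supra-threshold length over total
  sub-threshold length,
* location statistics (mean / stdev of midpoints, births and deaths of
  the supra-threshold intervals).

Undefined quantities (ratios with k too small or a zero longest
interval, entropy of an empty diagram, ...) are reported as NaN, never
as 0, so that they propagate as missing values into feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
import math

import numpy as np

from .persistence import PersistenceDiagram

__all__ = [
    "TopoIndexSet",
    "TOPO_FEATURE_COLUMNS",
    "length_indices",
    "entropy_indices",
    "threshold_indices",
    "location_indices",
    "topological_indices",
    "split_index",
]

#: Feature-table column order for the topological descriptors.
TOPO_FEATURE_COLUMNS = [
    "number_of_intervals",
    "longest_interval",
    "ratio_2_1",
    "ratio_3_1",
    "length_mean",
    "length_median",
    "length_stdev",
    "length_sum",
    "length_sum_per_rr",
    "pers_entropy",
    "normed_entropy",
    "length_threshold",
    "frac5",
    "frac100",
    "frac200",
    "middle_mean",
    "middle_stdev",
    "signal_to_noise",
    "birth_mean",
    "birth_stdev",
    "death_mean",
    "death_stdev",
]


@dataclass
class TopoIndexSet:
    """Named topological descriptors of one recording (NaN = undefined)."""

    number_of_intervals: float = math.nan
    longest_interval: float = math.nan
    ratio_2_1: float = math.nan
    ratio_3_1: float = math.nan
    length_mean: float = math.nan
    length_median: float = math.nan
    length_stdev: float = math.nan
    length_sum: float = math.nan
    length_sum_per_rr: float = math.nan
    pers_entropy: float = math.nan
    normed_entropy: float = math.nan
    length_threshold: float = math.nan
    frac5: float = math.nan
    frac100: float = math.nan
    frac200: float = math.nan
    middle_mean: float = math.nan
    middle_stdev: float = math.nan
    signal_to_noise: float = math.nan
    birth_mean: float = math.nan
    birth_stdev: float = math.nan
    death_mean: float = math.nan
    death_stdev: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def update(self, other: "TopoIndexSet") -> "TopoIndexSet":
        """Merge non-NaN fields of ``other`` into self (in place)."""
        for f in fields(other):
            v = getattr(other, f.name)
            if not (isinstance(v, float) and math.isnan(v)):
                setattr(self, f.name, v)
        return self


def _sample_std(x: np.ndarray) -> float:
    """Sample standard deviation (ddof=1); 0 for a single element."""
    if x.size <= 1:
        return 0.0
    return float(np.std(x, ddof=1))


def length_indices(diagram: PersistenceDiagram) -> TopoIndexSet:
    """Length statistics and 2/1, 3/1 ratios of the longest intervals."""
    ls = diagram.lengths
    k = ls.size
    if k == 0:
        raise ValueError("empty diagram")
    out = TopoIndexSet(
        number_of_intervals=float(k),
        longest_interval=float(ls[-1]),
        length_mean=float(ls.mean()),
        length_median=float(np.median(ls)),
        length_stdev=_sample_std(ls),
        length_sum=float(ls.sum()),
    )
    if diagram.n_beats:
        out.length_sum_per_rr = out.length_sum / diagram.n_beats
    if ls[-1] > 0:
        if k >= 2:
            out.ratio_2_1 = float(ls[-2] / ls[-1])
        if k >= 3:
            out.ratio_3_1 = float(ls[-3] / ls[-1])
    return out


def entropy_indices(diagram: PersistenceDiagram) -> TopoIndexSet:
    """Persistent entropy (bits) and its L-normed variant.

    Zero-length intervals contribute nothing (0 * log 0 := 0).  The
    normed entropy divides by log2(L) and is therefore undefined when
    L = 1 ms exactly (and negative-denominator for L < 1 ms).
    """
    ls = diagram.lengths
    L = float(ls.sum())
    out = TopoIndexSet()
    if L <= 0:
        return out
    pos = ls[ls > 0]
    q = pos / L
    out.pers_entropy = float(-(q * np.log2(q)).sum())
    log_l = math.log2(L)
    if log_l != 0.0:
        out.normed_entropy = out.pers_entropy / log_l
    return out


def split_index(lengths: np.ndarray, threshold: float) -> int:
    """First 1-based index p with l_p > threshold in the sorted lengths.

    Ties at exactly the threshold fall on the noise side (strict
    inequality defines the signal set).  Returns k + 1 when no length
    exceeds the threshold.
    """
    return int(np.searchsorted(lengths, threshold, side="right")) + 1


def threshold_indices(
    diagram: PersistenceDiagram, threshold_fraction: float = 0.05
) -> TopoIndexSet:
    """Length threshold, frac5% / frac100 / frac200, and signal-to-noise.

    The threshold is ``threshold_fraction`` (default 5%) of the longest
    interval; frac5 is the fraction of intervals strictly longer than
    it, frac100/frac200 the fractions of intervals of length at least
    100 ms / 200 ms (inclusive).  signal_to_noise is the total
    supra-threshold length divided by the total sub-threshold length
    (+inf when there is no sub-threshold interval).
    """
    ls = diagram.lengths
    k = ls.size
    if k == 0:
        raise ValueError("empty diagram")
    out = TopoIndexSet()
    thr = threshold_fraction * float(ls[-1])
    out.length_threshold = thr
    out.frac100 = float((ls >= 100.0).sum() / k)
    out.frac200 = float((ls >= 200.0).sum() / k)
    if ls[-1] <= 0:
        return out  # all lengths zero: frac5 / snr undefined
    p = split_index(ls, thr)
    out.frac5 = (k - p + 1) / k
    signal = float(ls[p - 1 :].sum())
    noise = float(ls[: p - 1].sum())
    out.signal_to_noise = signal / noise if noise > 0 else math.inf
    return out


def location_indices(
    diagram: PersistenceDiagram, threshold_fraction: float = 0.05
) -> TopoIndexSet:
    """Midpoint, birth and death statistics of supra-threshold intervals.

    Only intervals strictly longer than the length threshold are used;
    standard deviations are sample standard deviations, reported as 0
    when a single interval qualifies.
    """
    ls = diagram.lengths
    if ls.size == 0:
        raise ValueError("empty diagram")
    thr = threshold_fraction * float(ls[-1])
    mask = ls > thr
    out = TopoIndexSet()
    if not mask.any():
        return out
    births = diagram.births[mask]
    deaths = diagram.deaths[mask]
    middles = 0.5 * (births + deaths)
    out.middle_mean = float(middles.mean())
    out.middle_stdev = _sample_std(middles)
    out.birth_mean = float(births.mean())
    out.birth_stdev = _sample_std(births)
    out.death_mean = float(deaths.mean())
    out.death_stdev = _sample_std(deaths)
    return out


def topological_indices(
    diagram: PersistenceDiagram, threshold_fraction: float = 0.05
) -> TopoIndexSet:
    """All scalar topological descriptors of one diagram."""
    out = length_indices(diagram)
    out.update(entropy_indices(diagram))
    out.update(threshold_indices(diagram, threshold_fraction))
    out.update(location_indices(diagram, threshold_fraction))
    return out
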