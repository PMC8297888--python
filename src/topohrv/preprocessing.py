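"""RR-series editing before analysis.

Two editing paths are used, matching how each analysis tolerates
artifacts:

* spectral analysis needs an evenly long, gap-free tachogram, so beats
  not classified as normal are replaced by linear interpolation between
  the flanking normal beats (runs at the recording boundary, which have
  no flank, are dropped);
* topological and time-domain analyses use normal beats only, and
  additionally remove extreme outliers, which 0-dimensional persistence
  is sensitive to.  The outlier rule removes values falling outside
  [Q1 - m/4, Q3 + m/4] (quartiles and median m of the normal beats) —
  but only when at most 4 such values exist; a larger number of
  "outliers" is taken to be a genuine feature of the rhythm and is
  kept in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import RRSeries

__all__ = ["edit_for_spectral", "edit_for_topology", "OutlierReport"]

#: maximum number of beats the outlier rule may remove
MAX_OUTLIERS = 4


@dataclass(frozen=True)
class OutlierReport:
    """Positions (within the normal-beat subsequence) and values removed."""

    removed_positions: tuple[int, ...]
    removed_values: tuple[float, ...]
    lower_bound: float
    upper_bound: float
    applied: bool


def edit_for_spectral(series: RRSeries) -> RRSeries:
    """Interpolate non-normal beats for frequency-domain analysis.

    Each maximal run of non-normal beats flanked by normal beats is
    replaced by values linearly interpolated between the flanking
    normal RRs; unflanked runs at either boundary are dropped.
    """
    mask = series.normal_mask
    if not mask.any():
        raise ValueError("no normal beats to anchor interpolation")
    if mask.all():
        return series.replace(series.values)
    vals = series.values.astype(float).copy()
    idx = np.arange(vals.size)
    normal_idx = idx[mask]
    first, last = normal_idx[0], normal_idx[-1]
    interior = (idx >= first) & (idx <= last)
    filled = vals[interior].copy()
    m_int = mask[interior]
    x = np.arange(filled.size)
    filled[~m_int] = np.interp(x[~m_int], x[m_int], filled[m_int])
    return series.replace(filled)


def find_outliers(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Indices of values strictly outside [Q1 - m/4, Q3 + m/4]."""
    q1, q3 = np.percentile(values, [25, 75])
    m = float(np.median(values))
    lo, hi = q1 - m / 4.0, q3 + m / 4.0
    mask = (values < lo) | (values > hi)
    return np.flatnonzero(mask), float(lo), float(hi)


def edit_for_topology(
    series: RRSeries, remove_outliers: bool = True
) -> tuple[RRSeries, OutlierReport]:
    """Keep normal beats and apply the bounded outlier-removal rule.

    Quartiles and the median are computed on the normal beats (after
    dropping annotated beats).  At most ``MAX_OUTLIERS`` beats are
    removed; if more values violate the bounds, all are kept as part
    of the pattern.
    """
    vals = series.normal_values()
    if vals.size == 0:
        raise ValueError("no normal beats left after filtering")
    out_idx, lo, hi = find_outliers(vals)
    applied = remove_outliers and 0 < out_idx.size <= MAX_OUTLIERS
    if applied:
        kept = np.delete(vals, out_idx)
        if kept.size == 0:
            raise ValueError("outlier removal emptied the series")
        report = OutlierReport(
            tuple(int(i) for i in out_idx),
            tuple(float(vals[i]) for i in out_idx),
            lo, hi, True,
        )
        return series.replace(kept), report
    report = OutlierReport((), (), lo, hi, False)
    return series.replace(vals), report
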