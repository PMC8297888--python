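"""Classical time-domain and frequency-domain HRV parameters.

Time-domain indices are computed on normal-to-normal (NN) intervals:
mean/median/range, sdnn, the successive-difference family (rmssd, sdsd,
pnni50, pnni20), coefficient-of-variation forms (cvnni, cvsd) and the
per-beat instantaneous heart-rate statistics.

Frequency-domain indices follow the standard short-term analysis
pipeline: the tachogram is resampled evenly on its cumulative-time axis
(cubic spline, 4 Hz by default), the mean is removed, the power
spectral density is estimated by Welch's method, and the band powers
are integrated over VLF (0.003-0.04 Hz), LF (0.04-0.15 Hz) and HF
(0.15-0.4 Hz).  Normalised units express LF and HF as percentages of
LF + HF.  Total power is reported as the variance of the RR intervals
themselves (so that total_power = sdnn^2 exactly), not as a PSD
integral.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
import math

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .series import RRSeries

__all__ = [
    "SpectralConfig",
    "ClassicalIndexSet",
    "CLASSICAL_FEATURE_COLUMNS",
    "time_domain",
    "frequency_domain",
    "classical_indices",
]

CLASSICAL_FEATURE_COLUMNS = [
    "mean_nni",
    "sdnn",
    "sdsd",
    "pnni_50",
    "pnni_20",
    "rmssd",
    "median_nni",
    "range_nni",
    "cvsd",
    "cvnni",
    "mean_hr",
    "max_hr",
    "min_hr",
    "std_hr",
    "lf",
    "hf",
    "vlf",
    "total_power",
    "lfnu",
    "hfnu",
    "lf_hf_ratio",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Welch PSD settings for the frequency-domain analysis."""

    resample_rate_hz: float = 4.0
    nperseg: int = 256
    overlap: float = 0.5
    window: str = "hann"
    vlf_band: tuple[float, float] = (0.003, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    min_beats: int = 64


@dataclass
class ClassicalIndexSet:
    """Classical HRV parameters of one recording (NaN = undefined)."""

    mean_nni: float = math.nan
    sdnn: float = math.nan
    sdsd: float = math.nan
    pnni_50: float = math.nan
    pnni_20: float = math.nan
    rmssd: float = math.nan
    median_nni: float = math.nan
    range_nni: float = math.nan
    cvsd: float = math.nan
    cvnni: float = math.nan
    mean_hr: float = math.nan
    max_hr: float = math.nan
    min_hr: float = math.nan
    std_hr: float = math.nan
    lf: float = math.nan
    hf: float = math.nan
    vlf: float = math.nan
    total_power: float = math.nan
    lfnu: float = math.nan
    hfnu: float = math.nan
    lf_hf_ratio: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def update(self, other: "ClassicalIndexSet") -> "ClassicalIndexSet":
        for f in fields(other):
            v = getattr(other, f.name)
            if not (isinstance(v, float) and math.isnan(v)):
                setattr(self, f.name, v)
        return self


def time_domain(series: RRSeries) -> ClassicalIndexSet:
    """Time-domain HRV indices over the normal beats of a series.

    Successive differences are taken over adjacent normal beats only;
    sdnn and sdsd use the sample standard deviation (ddof=1).
    Heart-rate statistics are computed per beat as HR_i = 60000 / r_i.
    """
    rr = series.normal_values()
    if rr.size < 2:
        raise ValueError("time-domain indices need at least 2 normal RRs")
    out = ClassicalIndexSet(
        mean_nni=float(rr.mean()),
        median_nni=float(np.median(rr)),
        range_nni=float(rr.max() - rr.min()),
        sdnn=float(np.std(rr, ddof=1)),
    )
    # adjacency within the normal-beat subsequence of the original series
    mask = series.normal_mask
    idx = np.flatnonzero(mask)
    adjacent = np.diff(idx) == 1
    diffs = np.diff(series.values[idx])[adjacent]
    if diffs.size:
        out.rmssd = float(np.sqrt(np.mean(np.square(diffs))))
        out.sdsd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
        out.pnni_50 = 100.0 * float((np.abs(diffs) > 50.0).sum() / diffs.size)
        out.pnni_20 = 100.0 * float((np.abs(diffs) > 20.0).sum() / diffs.size)
        out.cvsd = out.rmssd / out.mean_nni
    out.cvnni = out.sdnn / out.mean_nni
    hr = 60000.0 / rr
    out.mean_hr = float(hr.mean())
    out.max_hr = float(hr.max())
    out.min_hr = float(hr.min())
    out.std_hr = float(np.std(hr, ddof=1))
    return out


def frequency_domain(
    series: RRSeries, config: SpectralConfig | None = None
) -> ClassicalIndexSet:
    """Frequency-domain HRV indices of a (spectrally edited) series.

    The caller is expected to pass a series whose non-normal beats have
    already been interpolated (see :func:`topohrv.preprocessing.
    edit_for_spectral`); all values present are used.
    """
    config = config or SpectralConfig()
    rr = series.values
    if rr.size < config.min_beats:
        raise ValueError(
            f"frequency-domain analysis needs >= {config.min_beats} beats"
        )
    t = series.cumulative_time_s()
    fs = config.resample_rate_hz
    t_even = np.arange(t[0], t[-1], 1.0 / fs)
    rr_even = CubicSpline(t, rr)(t_even)
    rr_even = rr_even - rr_even.mean()
    nperseg = min(config.nperseg, rr_even.size)
    freqs, psd = sps.welch(
        rr_even,
        fs=fs,
        window=config.window,
        nperseg=nperseg,
        noverlap=int(config.overlap * nperseg),
        detrend="constant",
    )

    def band_power(band: tuple[float, float]) -> float:
        mask = (freqs >= band[0]) & (freqs < band[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    out = ClassicalIndexSet(
        vlf=band_power(config.vlf_band),
        lf=band_power(config.lf_band),
        hf=band_power(config.hf_band),
        total_power=float(np.var(rr, ddof=1)),
    )
    denom = out.lf + out.hf
    if denom > 0:
        out.lfnu = 100.0 * out.lf / denom
        out.hfnu = 100.0 * out.hf / denom
    out.lf_hf_ratio = out.lf / out.hf if out.hf > 0 else math.inf
    return out


def classical_indices(
    series_for_time: RRSeries,
    series_for_spectral: RRSeries | None = None,
    config: SpectralConfig | None = None,
) -> ClassicalIndexSet:
    """Combined time- and frequency-domain index set.

    ``series_for_time`` should contain annotations (normal beats are
    selected internally); ``series_for_spectral`` defaults to the same
    series and should be the interpolation-edited version when
    annotations carry artifacts.
    """
    out = time_domain(series_for_time)
    spectral = series_for_spectral or series_for_time
    try:
        out.update(frequency_domain(spectral, config))
    except ValueError:
        pass  # too short for spectral analysis: leave NaN
    return out
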