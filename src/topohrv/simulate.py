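"""Synthetic RR-interval series with controllable structure.

The generator emulates short resting recordings of 512 beats: a mean RR
level modulated by two sinusoids — one in the low-frequency band
(default 0.1 Hz, baroreflex/Mayer-wave range) and one in the
high-frequency band (default 0.25 Hz, respiratory sinus arrhythmia) —
plus i.i.d. Gaussian beat-to-beat noise, an optional linear trend, and
randomly placed ectopic events.  An ectopic event replaces one beat by
a premature short beat (0.6 x the local RR) followed by a compensatory
long beat (1.4 x the local RR), both annotated as non-normal.

Sinusoid phases are sampled per subject, and the modulation is
evaluated at each beat's cumulative occurrence time, so the spectral
content lands in the intended frequency bands of the resampled
tachogram.

Two cohort presets provide a healthy-like group (``con_like``: larger
LF/HF modulation, moderate noise) and a reduced-variability group
(``str_like``: weak modulation, stronger beat-to-beat noise, which
raises the number of short persistence intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .series import RRSeries, NORMAL, NON_NORMAL

__all__ = [
    "CohortSpec",
    "generate_rr",
    "generate_cohort",
    "generate_cohorts",
    "con_like",
    "str_like",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    All amplitudes and noise levels are in ms; frequencies in Hz;
    ``trend_slope`` in ms per beat; ``ectopic_rate`` is the per-beat
    probability of starting an ectopic couplet.

    Subjects within a cohort differ: each subject's mean RR is drawn
    from N(mean_rr, mean_rr_sd) and the modulation amplitudes and the
    noise level are multiplied by subject-specific lognormal factors
    (unit mean, coefficients of variation ``amplitude_cv`` and
    ``noise_cv``), emulating inter-individual variability of resting
    heart rate and autonomic modulation.
    """

    n_subjects: int = 50
    n_beats: int = 512
    mean_rr: float = 850.0
    lf_amplitude: float = 30.0
    hf_amplitude: float = 25.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    noise_sd: float = 10.0
    trend_slope: float = 0.0
    ectopic_rate: float = 0.002
    mean_rr_sd: float = 70.0
    amplitude_cv: float = 0.5
    noise_cv: float = 0.45
    seed: int = 0
    label: str = "cohort"

    def __post_init__(self) -> None:
        if self.lf_amplitude < 0 or self.hf_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        nyquist = 1000.0 / (2.0 * self.mean_rr)
        for f in (self.lf_freq, self.hf_freq):
            if not (0.0 < f < nyquist):
                raise ValueError(
                    f"modulation frequency {f} Hz outside (0, {nyquist:.3f}) Hz"
                )


def con_like(**overrides) -> CohortSpec:
    """Healthy-like preset: pronounced LF/HF modulation, moderate noise."""
    spec = CohortSpec(
        mean_rr=900.0, lf_amplitude=35.0, hf_amplitude=25.0,
        noise_sd=15.0, ectopic_rate=0.002, label="con",
    )
    return replace(spec, **overrides)


def str_like(**overrides) -> CohortSpec:
    """Reduced-variability preset: weak modulation, high beat-to-beat noise.

    The stronger uncorrelated noise produces many short persistence
    intervals (a higher interval count) while the organised oscillatory
    variability (LF/HF modulation) is much weaker than in the
    healthy-like preset.  The mean RR is slightly shorter (faster
    resting heart rate).  The noise level (24 ms) is chosen so that the
    expected successive-difference power matches the healthy-like
    preset (whose rmssd is dominated by the respiratory oscillation):
    the two groups differ in the *composition* of their variability,
    not primarily in its beat-to-beat magnitude.
    """
    spec = CohortSpec(
        mean_rr=870.0, lf_amplitude=12.0, hf_amplitude=10.0,
        noise_sd=24.0, ectopic_rate=0.002, label="str",
    )
    return replace(spec, **overrides)


def generate_rr(spec: CohortSpec, subject_index: int = 0) -> RRSeries:
    """Generate one synthetic RR series, reproducible from the spec seed.

    The beat time axis is built incrementally: each beat's modulation is
    evaluated at the cumulative time of the preceding beats.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(subject_index)])
    )
    # subject-level physiology: resting RR and lognormal (unit-mean)
    # scaling of modulation amplitudes and beat-to-beat noise
    mean_rr = rng.normal(spec.mean_rr, spec.mean_rr_sd)
    mean_rr = max(mean_rr, 0.4 * spec.mean_rr)
    # LF and HF tone vary independently across subjects
    lf_scale, hf_scale, noise_scale = np.exp(
        rng.normal(
            [-0.5 * spec.amplitude_cv**2] * 2 + [-0.5 * spec.noise_cv**2],
            [spec.amplitude_cv, spec.amplitude_cv, spec.noise_cv],
        )
    )
    lf_amp = spec.lf_amplitude * lf_scale
    hf_amp = spec.hf_amplitude * hf_scale
    # subject draws are floored at 6 ms (R-peak jitter and quantization
    # contribute several ms in any real recording), but never above the
    # nominal level the caller asked for
    noise_sd = max(spec.noise_sd * noise_scale, min(spec.noise_sd, 6.0))
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    noise = rng.normal(0.0, noise_sd, size=spec.n_beats)
    values = np.empty(spec.n_beats)
    t = 0.0  # seconds
    for i in range(spec.n_beats):
        r = (
            mean_rr
            + lf_amp * np.sin(2 * np.pi * spec.lf_freq * t + phase1)
            + hf_amp * np.sin(2 * np.pi * spec.hf_freq * t + phase2)
            + spec.trend_slope * i
            + noise[i]
        )
        values[i] = r
        t += r / 1000.0
    if np.any(values <= 0):
        raise ValueError("spec parameters produced non-positive RR values")

    annotations = np.array([NORMAL] * spec.n_beats, dtype=object)
    if spec.ectopic_rate > 0:
        hits = np.flatnonzero(rng.random(spec.n_beats) < spec.ectopic_rate)
        for i in hits:
            if i + 1 >= spec.n_beats or annotations[i] != NORMAL:
                continue
            local = values[i]
            values[i] = 0.6 * local
            values[i + 1] = 1.4 * local
            annotations[i] = NON_NORMAL
            annotations[i + 1] = NON_NORMAL
    return RRSeries(
        values,
        annotations,
        subject_id=f"{spec.label}-{subject_index:03d}",
        group=spec.label,
    )


def generate_cohort(spec: CohortSpec) -> list[RRSeries]:
    """All subjects of one cohort."""
    return [generate_rr(spec, i) for i in range(spec.n_subjects)]


def generate_cohorts(
    spec_a: CohortSpec, spec_b: CohortSpec
) -> tuple[list[RRSeries], list[RRSeries]]:
    """Two labeled cohorts (e.g. healthy-like vs reduced-variability)."""
    return generate_cohort(spec_a), generate_cohort(spec_b)
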