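"""End-to-end feature extraction pipeline.

For each recording: edit the series (interpolation for the spectral
path, normal-beats + outlier rule for the topological path), compute
the persistence diagram, the topological indices, the triangle
descriptors, and the classical time/frequency indices, and aggregate
everything into one feature table with one row per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Iterable, Sequence

import pandas as pd

from .classical import CLASSICAL_FEATURE_COLUMNS, SpectralConfig, classical_indices
from .indices import TOPO_FEATURE_COLUMNS, topological_indices
from .persistence import PersistenceDiagram, compute_persistence
from .preprocessing import edit_for_spectral, edit_for_topology
from .series import RRSeries
from .triangle import (
    TRIANGLE_FEATURE_COLUMNS,
    TriangleConfig,
    fit_triangle,
    triangle_descriptors,
)

__all__ = ["PipelineConfig", "FEATURE_COLUMNS", "extract_features", "feature_table"]

logger = logging.getLogger("topohrv")

#: full column set of the pipeline feature table
FEATURE_COLUMNS = (
    ["subject_id", "group", "n_beats", "n_removed_outliers"]
    + TOPO_FEATURE_COLUMNS
    + TRIANGLE_FEATURE_COLUMNS
    + CLASSICAL_FEATURE_COLUMNS
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the full pipeline."""

    threshold_fraction: float = 0.05
    remove_outliers: bool = True
    triangle: TriangleConfig = field(default_factory=TriangleConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    def as_dict(self) -> dict:
        return {
            "threshold_fraction": self.threshold_fraction,
            "remove_outliers": self.remove_outliers,
            "triangle": {
                "n_angle_candidates": self.triangle.n_angle_candidates,
                "outer_fraction": self.triangle.outer_fraction,
                "zone_fraction": self.triangle.zone_fraction,
            },
            "spectral": {
                "resample_rate_hz": self.spectral.resample_rate_hz,
                "nperseg": self.spectral.nperseg,
                "overlap": self.spectral.overlap,
                "window": self.spectral.window,
                "vlf_band": list(self.spectral.vlf_band),
                "lf_band": list(self.spectral.lf_band),
                "hf_band": list(self.spectral.hf_band),
                "min_beats": self.spectral.min_beats,
            },
        }


def extract_features(
    series: RRSeries, config: PipelineConfig | None = None
) -> tuple[dict, PersistenceDiagram]:
    """One feature row (dict) plus the persistence diagram of a series."""
    config = config or PipelineConfig()
    topo_series, report = edit_for_topology(
        series, remove_outliers=config.remove_outliers
    )
    diagram = compute_persistence(topo_series)
    row: dict = {
        "subject_id": series.subject_id,
        "group": series.group,
        "n_beats": len(series),
        "n_removed_outliers": len(report.removed_positions),
    }
    row.update(topological_indices(diagram, config.threshold_fraction).as_dict())
    fit = fit_triangle(diagram, config.triangle)
    row.update(triangle_descriptors(fit).as_dict())
    try:
        spectral_series = edit_for_spectral(series)
    except ValueError:
        spectral_series = None
    # time-domain indices use normal beats; the outlier rule is specific
    # to the topological path and is not applied here
    row.update(
        classical_indices(series, spectral_series, config.spectral).as_dict()
    )
    logger.info(
        "%s: %d beats, %d outliers removed, k=%d, threshold=%.3f ms",
        series.subject_id, len(series), len(report.removed_positions),
        diagram.n_intervals, row["length_threshold"],
    )
    return row, diagram


def feature_table(
    recordings: Iterable[RRSeries], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature table over recordings, columns in canonical order."""
    rows = [extract_features(s, config)[0] for s in recordings]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
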