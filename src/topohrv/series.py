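"""RR-interval series container.

An RR series is the ordered sequence of inter-beat intervals (in
milliseconds) extracted from an ECG recording, optionally carrying a
per-beat annotation distinguishing normal sinus beats from artifacts or
ectopic beats.  All downstream analysis (persistence diagrams,
topological indices, classical HRV parameters) starts from this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["RRSeries", "NORMAL", "NON_NORMAL"]

#: Annotation label for a normal (sinus) beat.
NORMAL = "N"
#: Canonical label used for any beat that is not normal.
NON_NORMAL = "A"


@dataclass(frozen=True)
class RRSeries:
    """Ordered RR intervals in milliseconds with optional annotations.

    Parameters
    ----------
    values
        RR-interval lengths in ms, in temporal order.  Must be strictly
        positive and finite.
    annotations
        Optional per-beat labels, same length as ``values``.  ``"N"``
        marks a normal beat; any other label marks an artifact or
        ectopic beat.
    subject_id
        Opaque recording identifier.
    group
        Optional cohort label (e.g. ``"con"`` / ``"str"``).
    """

    values: np.ndarray
    annotations: np.ndarray | None = None
    subject_id: str = ""
    group: str | None = None

    def __init__(
        self,
        values: Sequence[float] | np.ndarray,
        annotations: Sequence[str] | np.ndarray | None = None,
        subject_id: str = "",
        group: str | None = None,
    ) -> None:
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("empty input")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("invalid RR value: all RRs must be finite and > 0")
        ann = None
        if annotations is not None:
            ann = np.asarray([str(a) for a in annotations], dtype=object)
            if ann.shape[0] != vals.shape[0]:
                raise ValueError(
                    "annotations length does not match number of RR values"
                )
        vals.setflags(write=False)
        if ann is not None:
            ann.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "annotations", ann)
        object.__setattr__(self, "subject_id", subject_id)
        object.__setattr__(self, "group", group)

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def normal_mask(self) -> np.ndarray:
        """Boolean mask of normal beats (all True when unannotated)."""
        if self.annotations is None:
            return np.ones(len(self), dtype=bool)
        return np.asarray([a == NORMAL for a in self.annotations], dtype=bool)

    def normal_values(self) -> np.ndarray:
        """RR values of normal beats only."""
        return self.values[self.normal_mask]

    def replace(self, values: np.ndarray, annotations=None) -> "RRSeries":
        """Return a copy with new values (metadata preserved)."""
        return RRSeries(
            values, annotations, subject_id=self.subject_id, group=self.group
        )

    def cumulative_time_s(self) -> np.ndarray:
        """Time of occurrence of each beat, seconds from the first beat.

        Beat *i* is placed at the cumulative sum of the preceding RR
        intervals; the first beat is at t = 0.
        """
        t_ms = np.concatenate([[0.0], np.cumsum(self.values[:-1])])
        return t_ms / 1000.0
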