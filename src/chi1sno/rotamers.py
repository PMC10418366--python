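"""Rotamer-state classification and violation counting for chi1 traces.

The catalytic histidine of a papain-family protease is catalytically
competent only in its "native" in-site rotamer (chi1 near 190 degrees); at
acidic pH it can flip to an out-of-site rotamer near 285 degrees.  Frames
are classified into configurable angular windows (circular containment, so
windows may straddle the stacking cut), occupancies are tallied, and
sustained excursions from the native state — the violation events marked by
arrows in trajectory plots — are counted with a minimum dwell time to
ignore single-frame noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .angle_io import DihedralSeries, StackedSeries

__all__ = [
    "RotamerWindows",
    "StateTrace",
    "classify_states",
    "occupancy",
    "count_violations",
    "mean_native_dwell",
    "summarize_stability",
    "DEFAULT_WINDOWS",
]

OTHER = "other"


class WindowError(ValueError):
    """Overlapping or degenerate rotamer windows."""


def _circdist(a: np.ndarray | float, b: float) -> np.ndarray | float:
    """Absolute angular distance on the circle, in [0, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 360.0)
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class RotamerWindows:
    """Labelled angular windows (center +/- halfwidth), one flagged native.

    Windows must be pairwise disjoint on the circle; frames outside every
    window are labelled ``"other"``.
    """

    states: tuple[tuple[str, float, float], ...]
    native: str = "native"

    def __post_init__(self) -> None:
        labels = [s[0] for s in self.states]
        if len(set(labels)) != len(labels):
            raise WindowError("duplicate state labels")
        if self.native not in labels:
            raise WindowError(f"no state labelled {self.native!r}")
        if OTHER in labels:
            raise WindowError(f"{OTHER!r} is reserved")
        for _, _, hw in self.states:
            if hw <= 0:
                raise WindowError("halfwidth must be positive")
        for i, (la, ca, ha) in enumerate(self.states):
            for lb, cb, hb in self.states[i + 1:]:
                if _circdist(ca, cb) < ha + hb:
                    raise WindowError(f"windows {la!r} and {lb!r} overlap")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.states)


#: In-site well 190 deg +/- 45 and out-of-site well 285 deg +/- 45: generous
#: margins around the observed 190 +/- 9 and 285 +/- 12 spreads.
DEFAULT_WINDOWS = RotamerWindows(
    states=(("native", 190.0, 45.0), ("out_of_site", 285.0, 45.0)),
)


@dataclass(frozen=True)
class StateTrace:
    """Per-frame rotamer-state labels aligned with a time grid (ns)."""

    times: np.ndarray
    labels: np.ndarray = field(repr=False)
    native: str = "native"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        l = np.asarray(self.labels, dtype=object)
        if t.size != l.size or t.size == 0:
            raise ValueError("times and labels must be equal-length, non-empty")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "labels", l)

    def __len__(self) -> int:
        return int(self.times.size)

    def frame_durations(self) -> np.ndarray:
        """Per-frame durations: forward time differences, the last frame
        inheriting the previous step (a lone frame gets duration 0)."""
        t = self.times
        if t.size == 1:
            return np.zeros(1)
        d = np.diff(t)
        return np.append(d, d[-1])


def classify_states(
    series: StackedSeries | DihedralSeries, windows: RotamerWindows = DEFAULT_WINDOWS
) -> StateTrace:
    """Label every frame by the window containing its angle (mod 360)."""
    angles = series.angles
    times = series.times
    labels = np.full(angles.shape, OTHER, dtype=object)
    for label, center, halfwidth in windows.states:
        inside = _circdist(angles, center) <= halfwidth
        labels[inside] = label
    return StateTrace(times=times, labels=labels, native=windows.native)


def occupancy(trace: StateTrace) -> dict[str, float]:
    """Fraction of frames per state label; fractions sum to 1."""
    labels, counts = np.unique(trace.labels.astype(str), return_counts=True)
    total = counts.sum()
    return {l: c / total for l, c in zip(labels, counts)}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) slices."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def count_violations(trace: StateTrace, min_dwell: float = 1.0) -> int:
    """Number of maximal non-native excursions lasting >= min_dwell ns."""
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    durations = trace.frame_durations()
    non_native = trace.labels != trace.native
    return sum(
        1
        for start, stop in _runs(non_native)
        if durations[start:stop].sum() >= min_dwell
    )


def mean_native_dwell(trace: StateTrace) -> float:
    """Mean duration (ns) of maximal native-state runs; 0 if never native."""
    durations = trace.frame_durations()
    runs = _runs(trace.labels == trace.native)
    if not runs:
        return 0.0
    return float(np.mean([durations[a:b].sum() for a, b in runs]))


def summarize_stability(
    traces: Mapping[tuple, StateTrace] | Mapping[tuple, Sequence[StateTrace]],
    min_dwell: float = 1.0,
) -> pd.DataFrame:
    """Stability table per (variant, condition, replicate) trace.

    Keys are (variant, condition, replicate) tuples (shorter keys are
    padded).  Columns: native occupancy fraction, violation event count and
    mean native dwell time in ns.
    """
    rows = []
    for key, trace in traces.items():
        key = tuple(key) if isinstance(key, tuple) else (key,)
        variant, condition, replicate = (list(key) + [None, None, None])[:3]
        occ = occupancy(trace)
        rows.append(
            {
                "variant": variant,
                "condition": condition,
                "replicate": replicate,
                "native_occupancy": occ.get(trace.native, 0.0),
                "violations": count_violations(trace, min_dwell),
                "mean_native_dwell_ns": mean_native_dwell(trace),
            }
        )
    return pd.DataFrame(rows)
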