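"""Reading and circular normalization of per-residue chi1 dihedral time series.

Angle data extracted from MD trajectories (e.g. by the GROMACS ``gmx chi``
utility) arrive as a time/angle table with angles on either the [-180, 180)
or the [0, 360) convention.  Because chi1 wells can straddle the +180/-180
seam, all downstream analysis works on *stacked* angles: every angle is
duplicated at ``a`` and ``a + 360`` and a contiguous 360-degree window is cut
through the least-populated region of the circle, so the dominant rotamer
well is never split across the window boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DihedralSeries",
    "StackedSeries",
    "read_chi_xvg",
    "read_angle_table",
    "write_chi_xvg",
    "stack_angles",
    "choose_window_start",
]


class AngleIOError(ValueError):
    """Malformed or empty dihedral input."""


@dataclass(frozen=True)
class DihedralSeries:
    """One residue's chi1 angle time series from one trajectory replicate.

    Parameters
    ----------
    residue_id : int
        Residue label in precursor numbering (the numbering that places the
        catalytic triad at 138/275/295).
    residue_name : str
        Three-letter amino-acid code, e.g. ``"HIS"``.
    times : ndarray of float
        Frame times in nanoseconds, strictly increasing.
    angles : ndarray of float
        Dihedral angles in degrees, one per frame.
    chi_index : int
        Which side-chain torsion this is (1 for chi1).
    dialect : str
        Raw-angle convention of the source, ``"signed"`` for [-180, 180) or
        ``"positive"`` for [0, 360).
    """

    residue_id: int
    residue_name: str
    times: np.ndarray
    angles: np.ndarray
    chi_index: int = 1
    dialect: str = "signed"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if t.size == 0 or a.size == 0:
            raise AngleIOError("empty dihedral series")
        if t.shape != a.shape:
            raise AngleIOError(
                f"times ({t.size}) and angles ({a.size}) differ in length"
            )
        if np.any(np.diff(t) <= 0):
            raise AngleIOError("times must be strictly increasing")
        if self.dialect not in ("signed", "positive"):
            raise AngleIOError(f"unknown angle dialect {self.dialect!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angles", a)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StackedSeries:
    """A dihedral series normalized onto one contiguous 360-degree window.

    Every stacked angle is congruent (mod 360) to its source angle and lies
    in ``[window_start, window_start + 360)``.
    """

    source: DihedralSeries
    window_start: float
    angles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        lo = self.window_start
        if np.any(a < lo) or np.any(a >= lo + 360.0):
            raise AngleIOError("stacked angles fall outside the window")
        object.__setattr__(self, "angles", a)

    @property
    def times(self) -> np.ndarray:
        return self.source.times

    def __len__(self) -> int:
        return int(self.angles.size)


_RESID_RE = re.compile(r"chi1([A-Z]{3})(\d+)", re.IGNORECASE)


def _residue_from_filename(path: Path) -> tuple[str, int] | None:
    # gmx chi writes files like chi1HIS275.xvg
    m = _RESID_RE.search(path.stem)
    if m:
        return m.group(1).upper(), int(m.group(2))
    return None


def _infer_dialect(angles: np.ndarray) -> str:
    return "signed" if np.any(angles < 0) else "positive"


def read_chi_xvg(
    path: str | Path,
    residue_id: int | None = None,
    residue_name: str | None = None,
    chi_index: int = 1,
) -> DihedralSeries:
    """Read a GROMACS chi-utility ``.xvg`` file into a :class:`DihedralSeries`.

    Lines beginning with ``#`` or ``@`` are metadata and skipped.  Data rows
    need at least two numeric columns (time, angle); whitespace or comma
    delimiters are accepted.  Residue identity is taken from an explicit
    argument or from the ``chi1XXXnnn`` filename convention.
    """
    path = Path(path)
    times: list[float] = []
    angles: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            fields = stripped.replace(",", " ").split()
            if len(fields) < 2:
                raise AngleIOError(
                    f"{path}:{lineno}: expected >=2 numeric columns, "
                    f"got {stripped!r}"
                )
            try:
                times.append(float(fields[0]))
                angles.append(float(fields[1]))
            except ValueError as exc:
                raise AngleIOError(
                    f"{path}:{lineno}: malformed numeric row {stripped!r}"
                ) from exc
    if not times:
        raise AngleIOError(f"{path}: no data rows")
    if residue_id is None or residue_name is None:
        guess = _residue_from_filename(path)
        if guess is not None:
            residue_name = residue_name or guess[0]
            residue_id = residue_id if residue_id is not None else guess[1]
    if residue_id is None:
        raise AngleIOError(
            f"{path}: residue identity not in filename; pass residue_id"
        )
    arr = np.asarray(angles, dtype=float)
    return DihedralSeries(
        residue_id=residue_id,
        residue_name=residue_name or "UNK",
        times=np.asarray(times, dtype=float),
        angles=arr,
        chi_index=chi_index,
        dialect=_infer_dialect(arr),
    )


def read_angle_table(
    path: str | Path,
    time_col: str = "time_ns",
    angle_col: str = "chi1_deg",
    residue_id: int | None = None,
    residue_name: str | None = None,
    **read_csv_kwargs,
) -> DihedralSeries:
    """Read a delimited table with a header row into a :class:`DihedralSeries`."""
    path = Path(path)
    df = pd.read_csv(path, **read_csv_kwargs)
    for col in (time_col, angle_col):
        if col not in df.columns:
            raise AngleIOError(
                f"{path}: column {col!r} not found (have {list(df.columns)})"
            )
    if df.empty:
        raise AngleIOError(f"{path}: no data rows")
    if residue_id is None:
        guess = _residue_from_filename(path)
        if guess is not None:
            residue_name = residue_name or guess[0]
            residue_id = guess[1]
    if residue_id is None:
        raise AngleIOError(f"{path}: residue identity required")
    arr = df[angle_col].to_numpy(dtype=float)
    return DihedralSeries(
        residue_id=residue_id,
        residue_name=residue_name or "UNK",
        times=df[time_col].to_numpy(dtype=float),
        angles=arr,
        dialect=_infer_dialect(arr),
    )


def write_chi_xvg(series: DihedralSeries, path: str | Path) -> None:
    """Serialize a series in the chi-utility xvg dialect (for fixtures)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# chi{series.chi_index} time series, angles in degrees\n")
        fh.write('@    title "Dihedral angle"\n')
        fh.write(f'@    subtitle "{series.residue_name}{series.residue_id}"\n')
        fh.write('@    xaxis  label "Time (ns)"\n')
        for t, a in zip(series.times, series.angles):
            fh.write(f"{t:.6f} {a:.9f}\n")


def choose_window_start(angles: Sequence[float] | np.ndarray) -> float:
    """Cut point for stacking: center of the widest empty gap on the circle.

    Angles are reduced mod 360; the largest circular gap between consecutive
    sorted values is found and the window starts at its midpoint, so the
    densest region of the data is contiguous in the resulting window.  Ties
    go to the first (lowest-angle) widest gap.  The returned start is the
    representative in (-180, 180], so data already clear of the seam keeps
    its original values.
    """
    a = np.sort(np.unique(np.mod(np.asarray(angles, dtype=float), 360.0)))
    if a.size == 0:
        raise AngleIOError("cannot choose a window for empty data")
    if a.size == 1:
        cut = np.mod(a[0] + 180.0, 360.0)
    else:
        gaps = np.diff(a)
        wrap_gap = a[0] + 360.0 - a[-1]
        if wrap_gap > gaps.max():
            cut = a[-1] + wrap_gap / 2.0
        else:
            i = int(np.argmax(gaps))
            cut = a[i] + gaps[i] / 2.0
        cut = np.mod(cut, 360.0)
    return float(cut if cut <= 180.0 else cut - 360.0)


def stack_angles(
    series: DihedralSeries, window_start: float | None = None
) -> StackedSeries:
    """Normalize a series onto one contiguous 360-degree window.

    Equivalent to doubling the data at ``a`` and ``a + 360`` and keeping the
    copy that falls inside ``[window_start, window_start + 360)``.  When
    *window_start* is None it is chosen by :func:`choose_window_start` from
    the series itself; pass an explicit value to put several series (e.g.
    the two replicates being compared) on a common window.
    """
    if isinstance(series, StackedSeries):
        source = series.source
        raw = series.angles
    else:
        source = series
        raw = series.angles
    if window_start is None:
        window_start = choose_window_start(raw)
    a = np.mod(np.asarray(raw, dtype=float) - window_start, 360.0)
    return StackedSeries(
        source=source, window_start=float(window_start), angles=a + window_start
    )
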