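"""Trajectory data model: loading, validation and per-frame kinematics.

The empirical input is a per-frame table of tracked individuals — columns
``frame, id, x, y, vx, vy`` — at a known frame rate, recorded in a rectangular
tank with the origin at one corner.  Units are centimetres and seconds
throughout; the time of frame *f* is ``f / fps``.

Headings (unit direction vectors) and speeds are derived from the velocities.
A fish whose speed falls below ``speed_floor`` keeps its most recent valid
heading (carry-forward); a fish that has never moved has no defined heading
and is flagged invalid, which excludes it from order-parameter sums for that
frame.  Missing fish in a frame are simply absent — tracking dropouts are
expected — and all per-frame statistics normalise by the number of valid
individuals actually present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ParameterError,
    TrajectoryValidationError,
)

REQUIRED_COLUMNS = ("frame", "id", "x", "y", "vx", "vy")

#: Default golden-shiner body length in cm.
DEFAULT_BODY_LENGTH_CM = 5.2


@dataclass(frozen=True)
class TrajectoryMeta:
    """Recording metadata: frame rate, tank dimensions and fish body length."""

    fps: float
    tank_width: float
    tank_height: float
    body_length: float = DEFAULT_BODY_LENGTH_CM

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.tank_width <= 0 or self.tank_height <= 0:
            raise ParameterError("tank dimensions must be > 0")
        if self.body_length <= 0:
            raise ParameterError("body_length must be > 0")


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from :func:`load_trajectories`."""

    n_rows: int
    dropped: int


@dataclass
class FrameView:
    """All individuals recorded in one frame.

    ``headings``/``speeds``/``valid`` are populated by
    :func:`derive_kinematics`; ``valid`` is False exactly for individuals
    whose speed is below the floor and who have no prior valid heading.
    """

    frame_index: int
    ids: np.ndarray
    positions: np.ndarray  # (n, 2) cm
    velocities: np.ndarray  # (n, 2) cm/s
    headings: np.ndarray | None = None  # (n, 2) unit vectors, NaN where invalid
    speeds: np.ndarray | None = None  # (n,) cm/s
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.ids), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


class TrajectoryDataset:
    """Ordered per-frame positions/velocities of identified individuals.

    Wraps a :class:`pandas.DataFrame` sorted by ``(frame, id)`` together with
    :class:`TrajectoryMeta`.  Frame indices are strictly increasing with gaps
    allowed; within one frame ids are unique; all positions lie inside the
    tank.
    """

    def __init__(self, df: pd.DataFrame, meta: TrajectoryMeta, *, validate: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)
        df["frame"] = df["frame"].astype(np.int64)
        df["id"] = df["id"].astype(np.int64)
        for c in ("x", "y", "vx", "vy"):
            df[c] = df[c].astype(float)
        self._df = df
        self.meta = meta
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            raise EmptyInputError("trajectory table contains no rows")
        out = (
            (df["x"] < 0)
            | (df["x"] > self.meta.tank_width)
            | (df["y"] < 0)
            | (df["y"] > self.meta.tank_height)
        )
        if out.any():
            rows = df.index[out].tolist()[:10]
            raise TrajectoryValidationError(
                f"{int(out.sum())} position(s) outside the tank "
                f"[0, {self.meta.tank_width}] x [0, {self.meta.tank_height}]; "
                f"first offending rows: {rows}"
            )
        dup = df.duplicated(subset=["frame", "id"])
        if dup.any():
            rows = df.index[dup].tolist()[:10]
            raise TrajectoryValidationError(
                f"duplicate (frame, id) pairs; first offending rows: {rows}"
            )

    # -- accessors -----------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def fps(self) -> float:
        return self.meta.fps

    @property
    def frame_index(self) -> np.ndarray:
        """Sorted unique frame indices present in the dataset."""
        return self._df["frame"].unique()

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def has_kinematics(self) -> bool:
        return "ux" in self._df.columns

    def frame(self, frame_index: int) -> FrameView:
        sub = self._df[self._df["frame"] == frame_index]
        if len(sub) == 0:
            raise KeyError(f"no such frame: {frame_index}")
        return self._to_view(frame_index, sub)

    def frames(self) -> Iterator[FrameView]:
        for fi, sub in self._df.groupby("frame", sort=True):
            yield self._to_view(int(fi), sub)

    def _to_view(self, frame_index: int, sub: pd.DataFrame) -> FrameView:
        headings = speeds = None
        valid = None
        if self.has_kinematics:
            headings = sub[["ux", "uy"]].to_numpy()
            speeds = sub["speed"].to_numpy()
            valid = sub["valid"].to_numpy(dtype=bool)
        return FrameView(
            frame_index=frame_index,
            ids=sub["id"].to_numpy(),
            positions=sub[["x", "y"]].to_numpy(),
            velocities=sub[["vx", "vy"]].to_numpy(),
            headings=headings,
            speeds=speeds,
            valid=valid,
        )

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, *, sep: str = ",") -> None:
        """Write the trajectory table (base columns only) for interchange."""
        self._df[list(REQUIRED_COLUMNS)].to_csv(path, sep=sep, index=False)


def _detect_sep(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_trajectories(path: str | Path, meta: TrajectoryMeta) -> tuple[TrajectoryDataset, LoadReport]:
    """Read a delimited trajectory table (comma or tab, header row).

    Rows with non-finite or non-numeric values in any required column are
    dropped and counted in the returned :class:`LoadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path} has a header but no data rows")
    df = df[list(REQUIRED_COLUMNS)]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(numeric.to_numpy(dtype=float)).all(axis=1)
    dropped = int((~keep).sum())
    cleaned = numeric[keep]
    if len(cleaned) == 0:
        raise EmptyInputError(f"{path}: all rows dropped as non-finite")
    ds = TrajectoryDataset(cleaned, meta)
    return ds, LoadReport(n_rows=len(df), dropped=dropped)


def derive_kinematics(dataset: TrajectoryDataset, speed_floor: float = 1e-6) -> TrajectoryDataset:
    """Attach speed, heading and validity columns to a dataset.

    heading = v/|v| where |v| >= ``speed_floor``; below the floor the most
    recent valid heading of that individual is carried forward.  Individuals
    with no valid heading yet are flagged invalid.  Idempotent: headings are
    always recomputed from the stored velocities.
    """
    if speed_floor < 0:
        raise ParameterError("speed_floor must be >= 0")
    df = dataset.df.copy()
    v = df[["vx", "vy"]].to_numpy()
    speed = np.hypot(v[:, 0], v[:, 1])
    moving = speed >= speed_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(moving, v[:, 0] / speed, np.nan)
        uy = np.where(moving, v[:, 1] / speed, np.nan)
    df["speed"] = speed
    df["ux"] = ux
    df["uy"] = uy
    # carry the last valid heading forward within each individual's track
    order = df.sort_values(["id", "frame"], kind="mergesort").index
    by_id = df.loc[order].groupby("id")
    df.loc[order, "ux"] = by_id["ux"].ffill().to_numpy()
    df.loc[order, "uy"] = by_id["uy"].ffill().to_numpy()
    df["valid"] = np.isfinite(df["ux"].to_numpy())
    out = TrajectoryDataset(df, dataset.meta, validate=False)
    return out
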