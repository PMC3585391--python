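"""Global and local order parameters of a schooling group.

Two scalars summarise the macroscopic structure of a planar group of *N*
individuals with unit headings ``u_i``:

* **Polarization** ``O_p = | (1/N) sum_i u_i |`` — 1 when all fish are
  aligned, ~N^(-1/2) for independent random headings.

* **Rotation** ``O_r = | (1/N) sum_i (r_ic x u_i) . z |`` where ``r_ic`` is
  the unit vector from the group's centre of mass to fish *i* — the mean
  normalised angular momentum about the centre of mass; 1 for a coherent
  mill.  The signed value (positive = counter-clockwise) carries the mill's
  handedness.

Both are computed over the *valid* individuals of a frame (those with a
defined heading) and are invariant under global translation and rotation.
A frame with no valid individuals yields NaN (the undefined-value signal);
the rotation additionally requires at least 2 valid individuals.

Also here: centred moving-average smoothing of order-parameter time series,
the local (neighbourhood-restricted) polarization around a focal fish, and
the radial-shell decomposition of the milling state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .io import FrameView, TrajectoryDataset

_COM_TOL = 1e-12


# -- array-level kernels (also used by the simulator) ------------------------


def polarization_xy(headings: np.ndarray) -> float:
    """``|mean of unit headings|`` for an (n, 2) array; NaN if n == 0."""
    if len(headings) == 0:
        return math.nan
    m = headings.mean(axis=0)
    # guard against 1 + eps from rounding in the unit headings
    return min(float(np.hypot(m[0], m[1])), 1.0)


def rotation_xy(positions: np.ndarray, headings: np.ndarray) -> tuple[float, float]:
    """Signed and absolute mean normalised angular momentum.

    Centre of mass is the unweighted mean of ``positions``.  Individuals
    located exactly at the centre of mass contribute zero to the sum but
    still count in *N*.  Returns ``(signed, magnitude)``; NaNs if n < 2.
    """
    n = len(positions)
    if n < 2:
        return math.nan, math.nan
    com = positions.mean(axis=0)
    r = positions - com
    d = np.hypot(r[:, 0], r[:, 1])
    at_com = d < _COM_TOL
    d_safe = np.where(at_com, 1.0, d)
    cross = (r[:, 0] * headings[:, 1] - r[:, 1] * headings[:, 0]) / d_safe
    cross[at_com] = 0.0
    signed = max(-1.0, min(1.0, float(cross.mean())))
    return signed, abs(signed)


# -- frame-level operations --------------------------------------------------


def _valid_arrays(frame: FrameView) -> tuple[np.ndarray, np.ndarray]:
    if frame.headings is None:
        raise ParameterError("frame has no derived headings; run derive_kinematics first")
    m = frame.valid
    return frame.positions[m], frame.headings[m]


def polarization(frame: FrameView) -> float:
    """Polarization order parameter of one frame (NaN if no valid fish)."""
    _, u = _valid_arrays(frame)
    return polarization_xy(u)


def rotation(frame: FrameView) -> tuple[float, float]:
    """(signed, magnitude) rotation order parameter of one frame.

    The centre of mass is taken over the positions of *all* recorded fish in
    the frame (the shoal's centre), while the momentum sum runs over the
    valid ones.
    """
    if frame.headings is None:
        raise ParameterError("frame has no derived headings; run derive_kinematics first")
    m = frame.valid
    if int(np.count_nonzero(m)) < 2:
        return math.nan, math.nan
    com = frame.positions.mean(axis=0)
    r = frame.positions[m] - com
    u = frame.headings[m]
    d = np.hypot(r[:, 0], r[:, 1])
    at_com = d < _COM_TOL
    d_safe = np.where(at_com, 1.0, d)
    cross = (r[:, 0] * u[:, 1] - r[:, 1] * u[:, 0]) / d_safe
    cross[at_com] = 0.0
    signed = max(-1.0, min(1.0, float(cross.mean())))
    return signed, abs(signed)


def local_polarization(frame: FrameView, focal_id: int, radius: float = 15.6) -> float:
    """Polarization restricted to a disc of ``radius`` cm around a focal fish.

    The default radius, 15.6 cm, is roughly three body lengths.  All valid
    fish within Euclidean distance <= radius of the focal (focal included)
    enter the average; a focal fish with no neighbours in range scores 1.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if frame.headings is None:
        raise ParameterError("frame has no derived headings; run derive_kinematics first")
    idx = np.flatnonzero(frame.ids == focal_id)
    if len(idx) == 0:
        raise LookupError(f"id {focal_id} not present in frame {frame.frame_index}")
    i = int(idx[0])
    if not frame.valid[i]:
        raise ParameterError(f"focal id {focal_id} has no valid heading in frame {frame.frame_index}")
    d = np.hypot(*(frame.positions - frame.positions[i]).T)
    sel = frame.valid & (d <= radius)
    return polarization_xy(frame.headings[sel])


# -- smoothing ---------------------------------------------------------------


def smooth_series(x: np.ndarray, span: int = 30) -> np.ndarray:
    """Centred moving average with a symmetric window.

    ``span`` is in frames (default 30, i.e. 1 s at 30 fps); an even span is
    widened by one so the window is centred.  At the edges the window is
    truncated symmetrically (half-width ``min(h, i, n-1-i)``) so the output
    keeps the input length and no phase shift is introduced.  NaN samples are
    excluded from the windows they fall in and remain NaN in the output.  A
    span larger than the series degenerates to the global (nan)mean.
    """
    if span < 1:
        raise ParameterError("span must be >= 1")
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    if span % 2 == 0:
        span += 1
    h = span // 2
    finite = np.isfinite(x)
    xf = np.where(finite, x, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(xf)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    i = np.arange(n)
    hw = np.minimum(h, np.minimum(i, n - 1 - i))
    lo, hi = i - hw, i + hw + 1
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / cnt, np.nan)
    out[~finite] = np.nan
    return out


# -- radial shells of the mill ----------------------------------------------


@dataclass
class ShellProfile:
    """Occupancy-weighted radial profile of speed and rotational order.

    The group is divided into ``n_shells`` concentric shells about its centre
    of mass.  Per frame, the outer radius *R* is the median distance of the
    five most peripheral fish; every shell is *R*/n_shells wide and the
    outermost shell also absorbs fish beyond *R*.
    """

    n_shells: int
    outer_radius: float  # mean R over the analysed frames, cm
    mean_speed: np.ndarray  # (n_shells,) cm/s, NaN where never occupied
    rotation: np.ndarray  # (n_shells,) in [0, 1], NaN where never occupied
    occupancy: np.ndarray  # (n_shells,) fish-frame counts


def shell_profile(frames, n_shells: int = 6) -> ShellProfile:
    """Radial-shell decomposition over a window of frames.

    The shell rotation order is the rotation equation restricted to the
    valid fish of that shell, with the radial unit vectors still taken from
    the full-group centre of mass; shell values are averaged over frames
    weighted by shell occupancy.  Frames need at least 5 fish.
    """
    occ = np.zeros(n_shells, dtype=np.int64)
    speed_sum = np.zeros(n_shells)
    rot_sum = np.zeros(n_shells)
    r_sum = 0.0
    n_frames = 0
    for frame in frames:
        if frame.n < 5:
            raise InsufficientDataError(
                f"frame {frame.frame_index}: shell profile needs >= 5 fish, got {frame.n}"
            )
        if frame.headings is None:
            raise ParameterError("frame has no derived headings; run derive_kinematics first")
        com = frame.positions.mean(axis=0)
        rel = frame.positions - com
        d = np.hypot(rel[:, 0], rel[:, 1])
        R = float(np.median(np.sort(d)[-5:]))
        if R <= 0:
            raise InsufficientDataError(f"frame {frame.frame_index}: degenerate group radius")
        width = R / n_shells
        shell = np.minimum((d / width).astype(np.int64), n_shells - 1)
        at_com = d < _COM_TOL
        d_safe = np.where(at_com, 1.0, d)
        cross = (rel[:, 0] * frame.headings[:, 1] - rel[:, 1] * frame.headings[:, 0]) / d_safe
        cross[at_com] = 0.0
        for s in range(n_shells):
            sel = (shell == s) & frame.valid
            ns = int(np.count_nonzero(sel))
            if ns == 0:
                continue
            occ[s] += ns
            speed_sum[s] += float(frame.speeds[sel].sum())
            rot_sum[s] += ns * abs(float(cross[sel].mean()))
        r_sum += R
        n_frames += 1
    if n_frames == 0:
        raise InsufficientDataError("shell profile needs at least one frame")
    with np.errstate(invalid="ignore"):
        mean_speed = np.where(occ > 0, speed_sum / np.maximum(occ, 1), np.nan)
        rot = np.where(occ > 0, rot_sum / np.maximum(occ, 1), np.nan)
    return ShellProfile(
        n_shells=n_shells,
        outer_radius=r_sum / n_frames,
        mean_speed=mean_speed,
        rotation=rot,
        occupancy=occ,
    )


# -- dataset-level series ----------------------------------------------------


def compute_order_series(dataset: TrajectoryDataset) -> "pd.DataFrame":
    """Per-frame O_p, signed rotation, O_r and mean speed for a dataset.

    Returns a DataFrame with columns ``frame, O_p, signed_r, O_r,
    mean_speed`` (one row per frame present in the dataset; NaN where a
    quantity is undefined).  Smoothing is the caller's responsibility:
    ``O_p`` and ``signed_r`` are smoothed directly while ``O_r`` is smoothed
    from its own magnitude series, not taken as the absolute value of the
    smoothed signed series.
    """
    import pandas as pd

    rows = []
    for frame in dataset.frames():
        op = polarization(frame)
        signed, mag = rotation(frame)
        sp = float(frame.speeds[frame.valid].mean()) if frame.n_valid else math.nan
        rows.append((frame.frame_index, op, signed, mag, sp))
    return pd.DataFrame(rows, columns=["frame", "O_p", "signed_r", "O_r", "mean_speed"])
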