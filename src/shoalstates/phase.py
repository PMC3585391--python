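"""Phase-space summaries over the (O_r, O_p) plane.

Everything here operates on the unit square with the rotation order O_r on
the first axis and the polarization O_p on the second.  The square is
divided into 30 x 30 bins (half-open ``[a, b)`` except the final bin, which
is closed); bins supported by fewer than ``min_count`` samples are masked
and never interpolated from.  Defaults follow the conventions used for
occupancy maps (min_count = 100) and transition maps (min_count = 20);
values can be interpolated to a finer 300 x 300 mesh for display.

Transition paths are resampled to a common length in normalised time,
averaged pointwise, and differentiated (forward differences) to build a
coarse-grained phase-space velocity field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
)

N_BINS = 30
REFINED_BINS = 300
DEFAULT_MIN_COUNT = 100
TRANSITION_MIN_COUNT = 20


@dataclass
class PhaseGrid:
    """Binned (O_r, O_p) summary: counts or conditional means.

    ``values[i, j]`` refers to the bin with O_r in ``edges[i:i+2]`` and O_p
    in ``edges[j:j+2]``.  ``mask`` is True where support >= ``min_count``.
    """

    values: np.ndarray  # (nbins, nbins)
    counts: np.ndarray  # (nbins, nbins) support
    mask: np.ndarray  # (nbins, nbins) bool
    min_count: int
    mode: str  # "count" or "mean"
    edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, N_BINS + 1))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class VectorField:
    """Coarse-grained phase-velocity field (dO_r, dO_p per unit path time)."""

    u: np.ndarray  # (nbins, nbins) mean dO_r
    v: np.ndarray  # (nbins, nbins) mean dO_p
    counts: np.ndarray
    mask: np.ndarray
    min_count: int
    edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, N_BINS + 1))


def _check_unit_square(o_r: np.ndarray, o_p: np.ndarray) -> None:
    if np.any((o_r < 0) | (o_r > 1) | (o_p < 0) | (o_p > 1)):
        raise ParameterError("phase-space points must lie in [0,1] x [0,1]")


def _split_points(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array of (O_r, O_p)")
    return points[:, 0], points[:, 1]


def phase_histogram(
    points: np.ndarray, min_count: int = DEFAULT_MIN_COUNT, n_bins: int = N_BINS
) -> PhaseGrid:
    """Occupancy counts of (O_r, O_p) points on the phase-space grid."""
    o_r, o_p = _split_points(points)
    _check_unit_square(o_r, o_p)
    counts, xe, _ = np.histogram2d(o_r, o_p, bins=n_bins, range=[[0, 1], [0, 1]])
    counts = counts.astype(np.int64)
    return PhaseGrid(
        values=counts.astype(float),
        counts=counts,
        mask=counts >= min_count,
        min_count=min_count,
        mode="count",
        edges=xe,
    )


def phase_mean_map(
    points: np.ndarray,
    values: np.ndarray,
    min_count: int = DEFAULT_MIN_COUNT,
    n_bins: int = N_BINS,
) -> PhaseGrid:
    """Per-bin arithmetic mean of a scalar (speed, packing fraction, d_b...).

    Samples with a NaN value are ignored; bins are masked below
    ``min_count`` supporting samples.
    """
    o_r, o_p = _split_points(points)
    values = np.asarray(values, dtype=float)
    if len(values) != len(o_r):
        raise ParameterError(
            f"length mismatch: {len(o_r)} points vs {len(values)} values"
        )
    keep = np.isfinite(values)
    o_r, o_p, values = o_r[keep], o_p[keep], values[keep]
    _check_unit_square(o_r, o_p)
    counts, xe, _ = np.histogram2d(o_r, o_p, bins=n_bins, range=[[0, 1], [0, 1]])
    sums, _, _ = np.histogram2d(
        o_r, o_p, bins=n_bins, range=[[0, 1], [0, 1]], weights=values
    )
    counts = counts.astype(np.int64)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PhaseGrid(
        values=means,
        counts=counts,
        mask=counts >= min_count,
        min_count=min_count,
        mode="mean",
        edges=xe,
    )


def refine_grid(grid: PhaseGrid, n_fine: int = REFINED_BINS) -> np.ndarray:
    """Bilinear interpolation of unmasked bin values onto a finer mesh.

    Returns an (n_fine, n_fine) array; NaN outside the supported region —
    values are interpolated between unmasked bin centres, and fine cells
    that fall inside an unmasked coarse bin but outside the centre hull take
    that bin's value.  No extrapolation beyond supported bins ever occurs,
    and refined values stay within the range of the contributing bins.
    """
    if not grid.mask.any():
        raise EmptyInputError("all bins are masked; nothing to refine")
    centers = grid.centers
    ii, jj = np.nonzero(grid.mask)
    pts = np.column_stack((centers[ii], centers[jj]))
    vals = grid.values[ii, jj]
    fine_centers = (np.arange(n_fine) + 0.5) / n_fine
    fr, fp = np.meshgrid(fine_centers, fine_centers, indexing="ij")
    fine = np.full((n_fine, n_fine), np.nan)
    if len(pts) >= 3:
        fine = griddata(pts, vals, (fr, fp), method="linear")
    # fill fine cells lying inside an unmasked coarse bin that got no value
    width = grid.edges[1] - grid.edges[0]
    ci = np.minimum((fr / width).astype(int), len(centers) - 1)
    cj = np.minimum((fp / width).astype(int), len(centers) - 1)
    inside = grid.mask[ci, cj]
    hole = inside & ~np.isfinite(fine)
    fine[hole] = grid.values[ci[hole], cj[hole]]
    fine[~inside & ~np.isfinite(fine)] = np.nan
    return fine


def conditional_mean_curves(
    x: np.ndarray, y: np.ndarray, n_bins: int = N_BINS
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """The two conditional-mean readings of a joint (speed, local-order) cloud.

    ``x`` is a per-fish scalar (speed, binned over its observed range) and
    ``y`` an order parameter in [0, 1].  Returns
    ``((y_centers, mean_x_per_y_bin), (x_centers, mean_y_per_x_bin))``
    with empty bins omitted from each curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 2:
        raise InsufficientDataError("need at least 2 distinct x values")
    y_edges = np.linspace(0, 1, n_bins + 1)
    x_edges = np.linspace(x.min(), x.max(), n_bins + 1)

    def _binned_mean(coord, edges, val):
        idx = np.clip(np.digitize(coord, edges) - 1, 0, n_bins - 1)
        sums = np.bincount(idx, weights=val, minlength=n_bins)
        cnts = np.bincount(idx, minlength=n_bins)
        sel = cnts > 0
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers[sel], sums[sel] / cnts[sel]

    curve_x_of_y = _binned_mean(y, y_edges, x)  # mean x per y-bin
    curve_y_of_x = _binned_mean(x, x_edges, y)  # mean y per x-bin
    return curve_x_of_y, curve_y_of_x


def resample_path(path: np.ndarray, length: int = 100) -> np.ndarray:
    """Linearly resample a phase-space path to a common length.

    The path is parameterised by normalised time (frame index / (n-1));
    endpoints are preserved exactly.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise ParameterError("path must contain at least 2 points")
    t_old = np.linspace(0.0, 1.0, len(path))
    t_new = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(t_new, t_old, path[:, c]) for c in range(path.shape[1])])


def average_transition_path(paths, length: int = 100) -> np.ndarray:
    """Pointwise mean of resampled transition paths of one type."""
    paths = [getattr(p, "path", p) for p in paths]
    if len(paths) == 0:
        raise InsufficientDataError("no transition paths to average")
    stacked = np.stack([resample_path(p, length) for p in paths])
    return stacked.mean(axis=0)


def phase_velocity_field(
    paths,
    min_count: int = TRANSITION_MIN_COUNT,
    n_bins: int = N_BINS,
    length: int = 100,
) -> VectorField:
    """Coarse-grained mean phase-velocity vectors from transition paths.

    Each path is resampled to a common length; forward differences are
    assigned to the bin of their starting point and averaged per bin.
    """
    paths = [getattr(p, "path", p) for p in paths]
    if len(paths) == 0:
        raise InsufficientDataError("no transition paths")
    starts = []
    vecs = []
    for p in paths:
        rp = resample_path(p, length)
        d = np.diff(rp, axis=0)
        starts.append(rp[:-1])
        vecs.append(d)
    starts = np.concatenate(starts)
    vecs = np.concatenate(vecs)
    o_r = np.clip(starts[:, 0], 0.0, 1.0)
    o_p = np.clip(starts[:, 1], 0.0, 1.0)
    edges = np.linspace(0, 1, n_bins + 1)
    bi = np.clip(np.digitize(o_r, edges) - 1, 0, n_bins - 1)
    bj = np.clip(np.digitize(o_p, edges) - 1, 0, n_bins - 1)
    flat = bi * n_bins + bj
    cnt = np.bincount(flat, minlength=n_bins * n_bins)
    su = np.bincount(flat, weights=vecs[:, 0], minlength=n_bins * n_bins)
    sv = np.bincount(flat, weights=vecs[:, 1], minlength=n_bins * n_bins)
    cnt2 = cnt.reshape(n_bins, n_bins)
    with np.errstate(invalid="ignore"):
        u = np.where(cnt2 > 0, su.reshape(n_bins, n_bins) / np.maximum(cnt2, 1), np.nan)
        v = np.where(cnt2 > 0, sv.reshape(n_bins, n_bins) / np.maximum(cnt2, 1), np.nan)
    return VectorField(
        u=u, v=v, counts=cnt2, mask=cnt2 >= min_count, min_count=min_count, edges=edges
    )


# -- rendering (convenience only) -------------------------------------------


def plot_grid(grid: PhaseGrid, ax=None, refined: bool = True, **imshow_kw):
    """Render a phase grid (masked bins blacked out); returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if refined:
        img = refine_grid(grid)
    else:
        img = np.where(grid.mask, grid.values, np.nan)
    imshow_kw.setdefault("origin", "lower")
    imshow_kw.setdefault("extent", (0, 1, 0, 1))
    ax.imshow(np.ma.masked_invalid(img).T, **imshow_kw)
    ax.set_xlabel("$O_r$")
    ax.set_ylabel("$O_p$")
    return ax


def plot_vector_field(field: VectorField, ax=None, **quiver_kw):
    """Quiver plot of a phase-velocity field; returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (field.edges[:-1] + field.edges[1:])
    rr, pp = np.meshgrid(centers, centers, indexing="ij")
    m = field.mask
    ax.quiver(rr[m], pp[m], field.u[m], field.v[m], **quiver_kw)
    ax.set_xlabel("$O_r$")
    ax.set_ylabel("$O_p$")
    return ax
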