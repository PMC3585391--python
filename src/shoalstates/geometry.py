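"""Group geometry: centre of mass, alpha-shape area, packing fraction,
distance to the tank boundary.

The area spanned by the group is measured with a 2D alpha shape — a
generalisation of the convex hull that follows concavities.  We keep every
Delaunay triangle whose circumradius is at most the probe radius
``alpha_radius`` and take the union of the kept triangles; as
``alpha_radius -> inf`` this is exactly the convex hull.  The packing
fraction is ``phi = N * body_area / area``.

The fish body area is parameterised in cm^2; the default 3.38 cm^2 comes
from a 5.2 cm x 0.65 cm body (8:1 aspect).  Any constant choice rescales
phi uniformly, so state-dependent density *patterns* are insensitive to it.
The default probe radius is one body length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import DegenerateGeometryError, ParameterError, TrajectoryValidationError
from .io import DEFAULT_BODY_LENGTH_CM, FrameView

#: Default fish body area (cm^2): 5.2 cm x 0.65 cm.
DEFAULT_BODY_AREA_CM2 = 3.38


@dataclass(frozen=True)
class TankGeometry:
    """Rectangular tank with origin at one corner; dimensions in cm."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("tank dimensions must be > 0")


@dataclass
class GroupShape:
    """Alpha-shape summary of one frame's spatial configuration."""

    area: float  # cm^2 (0 if no triangle survives the alpha filter)
    n_components: int  # connected pieces, isolated fish counted singly
    alpha_radius: float
    packing_fraction: float | None = None


def center_of_mass(frame: FrameView) -> np.ndarray:
    """Unweighted mean position of all recorded fish in the frame."""
    if frame.n == 0:
        raise DegenerateGeometryError("empty frame has no centre of mass")
    return frame.positions.mean(axis=0)


def boundary_distance(frame: FrameView, tank: TankGeometry) -> float:
    """Smallest distance from the group's centre of mass to the tank walls."""
    cx, cy = center_of_mass(frame)
    if not (0 <= cx <= tank.width and 0 <= cy <= tank.height):
        raise TrajectoryValidationError(
            f"centre of mass ({cx:.2f}, {cy:.2f}) lies outside the tank"
        )
    return float(min(cx, tank.width - cx, cy, tank.height - cy))


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.hypot(*(b - c).T)
    lb = np.hypot(*(a - c).T)
    lc = np.hypot(*(a - b).T)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def alpha_shape(points: np.ndarray, alpha_radius: float):
    """Alpha shape of a 2D point cloud.

    Returns ``(geometry, n_components)`` where ``geometry`` is a shapely
    (Multi)Polygon union of the Delaunay triangles with circumradius <=
    ``alpha_radius``.  Points belonging to no kept triangle count as
    singleton components.
    """
    if alpha_radius <= 0:
        raise ParameterError("alpha_radius must be > 0")
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise DegenerateGeometryError("alpha shape needs at least 3 points")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    radii = _circumradii(points, tri.simplices)
    kept = tri.simplices[radii <= alpha_radius]
    if len(kept) == 0:
        return None, len(points)
    geom = unary_union([Polygon(points[s]) for s in kept])
    polys = getattr(geom, "geoms", [geom])
    n_poly = len(list(polys))
    covered = np.zeros(len(points), dtype=bool)
    covered[np.unique(kept)] = True
    return geom, n_poly + int(np.count_nonzero(~covered))


def group_area(
    frame: FrameView, alpha_radius: float = DEFAULT_BODY_LENGTH_CM
) -> GroupShape:
    """Alpha-shape area spanned by the group (union of all components)."""
    geom, n_comp = alpha_shape(frame.positions, alpha_radius)
    area = 0.0 if geom is None else float(geom.area)
    return GroupShape(area=area, n_components=n_comp, alpha_radius=alpha_radius)


def packing_fraction(
    frame: FrameView,
    body_area: float = DEFAULT_BODY_AREA_CM2,
    alpha_radius: float = DEFAULT_BODY_LENGTH_CM,
) -> float:
    """phi = N x body_area / alpha-shape area of the frame."""
    if body_area <= 0:
        raise ParameterError("body_area must be > 0")
    shape = group_area(frame, alpha_radius)
    if shape.area <= 0:
        raise DegenerateGeometryError(
            "group area is zero under this alpha radius; packing fraction undefined"
        )
    return frame.n * body_area / shape.area
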