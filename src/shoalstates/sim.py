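"""Constant-speed zonal model of schooling and its speed-sweep experiment.

Each of N agents moves at a fixed common speed and reorients in response to
neighbours sorted into three concentric, non-overlapping behavioural zones
(spherical in the default 3D formulation; circular in the planar variant):

* repulsion  (r < 1):  move away from everyone this close — overrides all;
* orientation (1 <= r < 3): align with the mean heading of these neighbours;
* attraction (3 <= r < 15): move towards these neighbours.

A blind cone behind the agent (field of perception 270 degrees, so a
90-degree blind sector) hides neighbours in every zone — an agent cannot
react to what it cannot see.  When both the orientation and attraction sets
are non-empty their normalised contributions are averaged; an agent with no
visible neighbours keeps its heading.  The desired direction is perturbed
by a Gaussian angle (sd 0.2 rad; in 3D the perturbation axis is uniform
around the desired direction) and the heading then rotates towards it by
at most ``turn_rate * dt`` (60 deg per unit time x dt = 0.1 -> 6 deg per
step).  All agents update synchronously; lengths and times are model units
with no mapping to cm; there is no boundary.

The sweep experiment varies the speed from 0.1 to 4.1 in steps of 0.1,
runs independent replicates of 2500 steps from random initial conditions
(positions uniform in a ball of the attraction radius, headings uniform),
and records the final-step order parameters (in 3D the rotation order is
the norm of the mean angular-momentum vector).  At high speed the model is
bistable between milling and polarized motion, with the milling side
strengthening as N grows until it excludes polarized outcomes entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .errors import ParameterError
from .order import polarization_xy, rotation_xy


@dataclass(frozen=True)
class SimConfig:
    """Zonal-model parameters (model length/time units)."""

    n: int
    speed: float
    r_repulsion: float = 1.0
    r_orientation: float = 3.0
    r_attraction: float = 15.0
    field_of_perception: float = 270.0  # degrees
    turn_rate: float = 60.0  # degrees per unit time
    noise_sd: float = 0.2  # radians
    dt: float = 0.1
    steps: int = 2500
    seed: int = 0
    dimension: int = 3  # spherical zones; 2 selects the planar variant

    def __post_init__(self) -> None:
        if not 0 < self.r_repulsion < self.r_orientation < self.r_attraction:
            raise ParameterError("zone radii must satisfy 0 < r_rep < r_ori < r_att")
        if not 0 < self.field_of_perception <= 360:
            raise ParameterError("field_of_perception must lie in (0, 360] degrees")
        if self.speed <= 0:
            raise ParameterError("speed must be > 0")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.dimension not in (2, 3):
            raise ParameterError("dimension must be 2 or 3")

    @property
    def max_turn_per_step(self) -> float:
        """Turn-limit per step, radians."""
        return math.radians(self.turn_rate) * self.dt

    @property
    def cos_half_blind(self) -> float:
        """Cosine of the half field of perception (visibility threshold)."""
        return math.cos(math.radians(self.field_of_perception) / 2.0)


@dataclass
class AgentSet:
    """Positions and unit headings of the agents, shape (n, dimension)."""

    positions: np.ndarray
    headings: np.ndarray

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]


# -- planar kernel -----------------------------------------------------------


@njit(cache=True)
def _desired_2d(pos, head, rr2, ro2, ra2, cos_vis):  # pragma: no cover
    n = pos.shape[0]
    des = np.empty((n, 2))
    for i in range(n):
        rx = ry = 0.0
        nrep = 0
        ox = oy = 0.0
        nori = 0
        ax = ay = 0.0
        natt = 0
        hx = head[i, 0]
        hy = head[i, 1]
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            d2 = dx * dx + dy * dy
            if d2 > ra2 or d2 == 0.0:
                continue
            d = math.sqrt(d2)
            if (hx * dx + hy * dy) / d < cos_vis:
                continue  # inside the blind cone
            if d2 < rr2:
                rx -= dx / d
                ry -= dy / d
                nrep += 1
            elif d2 < ro2:
                ox += head[j, 0]
                oy += head[j, 1]
                nori += 1
            else:
                ax += dx / d
                ay += dy / d
                natt += 1
        if nrep > 0:
            norm = math.sqrt(rx * rx + ry * ry)
            if norm > 1e-12:
                des[i, 0] = rx / norm
                des[i, 1] = ry / norm
            else:
                des[i, 0] = hx
                des[i, 1] = hy
            continue
        dx = dy = 0.0
        nterm = 0
        if nori > 0:
            norm = math.sqrt(ox * ox + oy * oy)
            if norm > 1e-12:
                dx += ox / norm
                dy += oy / norm
                nterm += 1
        if natt > 0:
            norm = math.sqrt(ax * ax + ay * ay)
            if norm > 1e-12:
                dx += ax / norm
                dy += ay / norm
                nterm += 1
        norm = math.sqrt(dx * dx + dy * dy) if nterm > 0 else 0.0
        if norm > 1e-12:
            des[i, 0] = dx / norm
            des[i, 1] = dy / norm
        else:
            des[i, 0] = hx
            des[i, 1] = hy
    return des


@njit(cache=True)
def _advance_2d(pos, head, noise, rr2, ro2, ra2, cos_vis, max_turn, step_len):  # pragma: no cover
    n = pos.shape[0]
    des = _desired_2d(pos, head, rr2, ro2, ra2, cos_vis)
    for i in range(n):
        target = math.atan2(des[i, 1], des[i, 0]) + noise[i]
        cur = math.atan2(head[i, 1], head[i, 0])
        delta = target - cur
        while delta <= -math.pi:
            delta += 2.0 * math.pi
        while delta > math.pi:
            delta -= 2.0 * math.pi
        if delta > max_turn:
            delta = max_turn
        elif delta < -max_turn:
            delta = -max_turn
        ang = cur + delta
        head[i, 0] = math.cos(ang)
        head[i, 1] = math.sin(ang)
    for i in range(n):
        pos[i, 0] += step_len * head[i, 0]
        pos[i, 1] += step_len * head[i, 1]


# -- spherical kernel --------------------------------------------------------


@njit(cache=True)
def _desired_3d(pos, head, rr2, ro2, ra2, cos_vis):  # pragma: no cover
    n = pos.shape[0]
    des = np.empty((n, 3))
    for i in range(n):
        rx = ry = rz = 0.0
        nrep = 0
        ox = oy = oz = 0.0
        nori = 0
        ax = ay = az = 0.0
        natt = 0
        hx = head[i, 0]
        hy = head[i, 1]
        hz = head[i, 2]
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > ra2 or d2 == 0.0:
                continue
            d = math.sqrt(d2)
            if (hx * dx + hy * dy + hz * dz) / d < cos_vis:
                continue
            if d2 < rr2:
                rx -= dx / d
                ry -= dy / d
                rz -= dz / d
                nrep += 1
            elif d2 < ro2:
                ox += head[j, 0]
                oy += head[j, 1]
                oz += head[j, 2]
                nori += 1
            else:
                ax += dx / d
                ay += dy / d
                az += dz / d
                natt += 1
        if nrep > 0:
            norm = math.sqrt(rx * rx + ry * ry + rz * rz)
            if norm > 1e-12:
                des[i, 0] = rx / norm
                des[i, 1] = ry / norm
                des[i, 2] = rz / norm
            else:
                des[i, 0] = hx
                des[i, 1] = hy
                des[i, 2] = hz
            continue
        dx = dy = dz = 0.0
        nterm = 0
        if nori > 0:
            norm = math.sqrt(ox * ox + oy * oy + oz * oz)
            if norm > 1e-12:
                dx += ox / norm
                dy += oy / norm
                dz += oz / norm
                nterm += 1
        if natt > 0:
            norm = math.sqrt(ax * ax + ay * ay + az * az)
            if norm > 1e-12:
                dx += ax / norm
                dy += ay / norm
                dz += az / norm
                nterm += 1
        norm = math.sqrt(dx * dx + dy * dy + dz * dz) if nterm > 0 else 0.0
        if norm > 1e-12:
            des[i, 0] = dx / norm
            des[i, 1] = dy / norm
            des[i, 2] = dz / norm
        else:
            des[i, 0] = hx
            des[i, 1] = hy
            des[i, 2] = hz
    return des


@njit(cache=True)
def _advance_3d(
    pos, head, polar, azimuth, rr2, ro2, ra2, cos_vis, max_turn, step_len
):  # pragma: no cover
    n = pos.shape[0]
    des = _desired_3d(pos, head, rr2, ro2, ra2, cos_vis)
    for i in range(n):
        dx = des[i, 0]
        dy = des[i, 1]
        dz = des[i, 2]
        # orthonormal basis perpendicular to the desired direction
        if abs(dx) < 0.9:
            e1x, e1y, e1z = 1.0 - dx * dx, -dx * dy, -dx * dz
        else:
            e1x, e1y, e1z = -dy * dx, 1.0 - dy * dy, -dy * dz
        norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= norm
        e1y /= norm
        e1z /= norm
        e2x = dy * e1z - dz * e1y
        e2y = dz * e1x - dx * e1z
        e2z = dx * e1y - dy * e1x
        # rotate desired by the noise polar angle about a uniform azimuth
        s = math.sin(polar[i])
        c = math.cos(polar[i])
        ca = math.cos(azimuth[i])
        sa = math.sin(azimuth[i])
        px = c * dx + s * (ca * e1x + sa * e2x)
        py = c * dy + s * (ca * e1y + sa * e2y)
        pz = c * dz + s * (ca * e1z + sa * e2z)
        # rotate the heading towards the perturbed target by at most max_turn
        hx = head[i, 0]
        hy = head[i, 1]
        hz = head[i, 2]
        dot = hx * px + hy * py + hz * pz
        if dot > 1.0:
            dot = 1.0
        elif dot < -1.0:
            dot = -1.0
        theta = math.acos(dot)
        if theta > 1e-12:
            t = max_turn / theta
            if t > 1.0:
                t = 1.0
            st = math.sin(theta)
            a = math.sin((1.0 - t) * theta) / st
            b = math.sin(t * theta) / st
            nx = a * hx + b * px
            ny = a * hy + b * py
            nz = a * hz + b * pz
            norm = math.sqrt(nx * nx + ny * ny + nz * nz)
            head[i, 0] = nx / norm
            head[i, 1] = ny / norm
            head[i, 2] = nz / norm
    for i in range(n):
        pos[i, 0] += step_len * head[i, 0]
        pos[i, 1] += step_len * head[i, 1]
        pos[i, 2] += step_len * head[i, 2]


# -- public operations -------------------------------------------------------


def order_parameters(agents: AgentSet) -> tuple[float, float]:
    """(O_p, O_r) of an agent configuration in either dimension.

    O_p is the norm of the mean heading.  O_r is the norm of the mean
    normalised angular momentum about the centre of mass (in 2D, the
    absolute z-component).
    """
    head = agents.headings
    pos = agents.positions
    if agents.dimension == 2:
        o_p = polarization_xy(head)
        _, o_r = rotation_xy(pos, head)
        return o_p, o_r
    o_p = min(float(np.linalg.norm(head.mean(axis=0))), 1.0)
    rel = pos - pos.mean(axis=0)
    d = np.linalg.norm(rel, axis=1)
    d[d < 1e-12] = 1.0
    ang = np.cross(rel / d[:, None], head)
    o_r = min(float(np.linalg.norm(ang.mean(axis=0))), 1.0)
    return o_p, o_r


def desired_direction(focal: int, agents: AgentSet, cfg: SimConfig) -> np.ndarray:
    """Desired heading of one agent given the current configuration.

    Exposed mainly for inspection and testing; :func:`step` computes all
    agents' desired directions in one pass.
    """
    if not 0 <= focal < agents.n:
        raise IndexError(f"focal index {focal} out of range for {agents.n} agents")
    pos = np.ascontiguousarray(agents.positions, dtype=np.float64)
    head = np.ascontiguousarray(agents.headings, dtype=np.float64)
    kern = _desired_2d if agents.dimension == 2 else _desired_3d
    des = kern(
        pos,
        head,
        cfg.r_repulsion**2,
        cfg.r_orientation**2,
        cfg.r_attraction**2,
        cfg.cos_half_blind,
    )
    return des[focal]


def _draw_noise(cfg: SimConfig, rng: np.random.Generator, n: int):
    if cfg.dimension == 2:
        return (rng.normal(0.0, cfg.noise_sd, n),)
    return np.abs(rng.normal(0.0, cfg.noise_sd, n)), rng.uniform(0, 2 * np.pi, n)


def _advance(pos, head, cfg: SimConfig, noise) -> None:
    args = (
        cfg.r_repulsion**2,
        cfg.r_orientation**2,
        cfg.r_attraction**2,
        cfg.cos_half_blind,
        cfg.max_turn_per_step,
        cfg.speed * cfg.dt,
    )
    if cfg.dimension == 2:
        _advance_2d(pos, head, noise[0], *args)
    else:
        _advance_3d(pos, head, noise[0], noise[1], *args)


def step(agents: AgentSet, cfg: SimConfig, rng: np.random.Generator) -> AgentSet:
    """One synchronous update of all agents; returns a new AgentSet."""
    pos = np.ascontiguousarray(agents.positions, dtype=np.float64).copy()
    head = np.ascontiguousarray(agents.headings, dtype=np.float64).copy()
    _advance(pos, head, cfg, _draw_noise(cfg, rng, agents.n))
    return AgentSet(pos, head)


def init_agents(cfg: SimConfig, rng: np.random.Generator) -> AgentSet:
    """Random start: positions uniform in a ball of the attraction radius,
    headings uniform on the circle/sphere.  The ball radius guarantees
    initial connectivity for all group sizes."""
    dim = cfg.dimension
    r = cfg.r_attraction * rng.random(cfg.n) ** (1.0 / dim)
    v = rng.normal(size=(cfg.n, dim))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pos = r[:, None] * v
    h = rng.normal(size=(cfg.n, dim))
    head = h / np.linalg.norm(h, axis=1)[:, None]
    return AgentSet(pos, head)


def run(
    cfg: SimConfig,
    *,
    record_every: int = 0,
    init: AgentSet | None = None,
):
    """Run one simulation and return its final-step order parameters.

    Returns ``(o_p, o_r, agents)``; with ``record_every > 0`` additionally a
    DataFrame of the order-parameter time series (columns
    ``step, O_p, O_r``) as a fourth element.
    """
    rng = np.random.default_rng(cfg.seed)
    agents = init if init is not None else init_agents(cfg, rng)
    if agents.dimension != cfg.dimension:
        raise ParameterError("agent dimension does not match the configuration")
    pos = np.ascontiguousarray(agents.positions, dtype=np.float64).copy()
    head = np.ascontiguousarray(agents.headings, dtype=np.float64).copy()
    records = []
    for t in range(cfg.steps):
        _advance(pos, head, cfg, _draw_noise(cfg, rng, cfg.n))
        if record_every and ((t + 1) % record_every == 0 or t == cfg.steps - 1):
            op, orr = order_parameters(AgentSet(pos, head))
            records.append((t + 1, op, orr))
    out = AgentSet(pos, head)
    o_p, o_r = order_parameters(out)
    if record_every:
        series = pd.DataFrame(records, columns=["step", "O_p", "O_r"])
        return o_p, o_r, out, series
    return o_p, o_r, out


def replicate_seed(base_seed: int, speed_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from a base seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(speed_index, replicate))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def speed_sweep(
    base_cfg: SimConfig,
    speeds: np.ndarray | None = None,
    replicates: int = 500,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Final-state order parameters across a grid of speeds.

    Default grid: 0.1 to 4.1 in increments of 0.1, with independent seeded
    replicates of 2500 steps at each speed.  Returns a DataFrame with
    columns ``speed, replicate, O_p, O_r``.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if speeds is None:
        speeds = np.round(np.arange(0.1, 4.1 + 1e-9, 0.1), 10)
    if base_seed is None:
        base_seed = base_cfg.seed
    rows = []
    for si, s in enumerate(speeds):
        for rep in range(replicates):
            cfg = replace(base_cfg, speed=float(s), seed=replicate_seed(base_seed, si, rep))
            o_p, o_r, _ = run(cfg)
            rows.append((float(s), rep, o_p, o_r))
    return pd.DataFrame(rows, columns=["speed", "replicate", "O_p", "O_r"])


def to_trajectory_frame(agents: AgentSet, cfg: SimConfig, frame: int) -> pd.DataFrame:
    """One frame of agent state in the standard trajectory-table layout.

    For 3D simulations the x/y components are exported (a planar
    projection); the table is for interchange with the analysis pipeline,
    which is two-dimensional.
    """
    v = agents.headings * cfg.speed
    return pd.DataFrame(
        {
            "frame": frame,
            "id": np.arange(agents.n),
            "x": agents.positions[:, 0],
            "y": agents.positions[:, 1],
            "vx": v[:, 0],
            "vy": v[:, 1],
        }
    )
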