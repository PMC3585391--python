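"""Synthetic shoal data: analytic archetype frames, scripted order-parameter
series, and noisy bounded-tank school trajectories.

Three generators with increasing realism make every pipeline stage testable
without experimental recordings:

* :func:`make_archetype` — single frames realising each collective state
  exactly (common heading; tangential concentric rings; uniform disorder);
* :func:`make_state_series` — an (O_p, O_r) time series that dwells near
  per-state anchor points with Gaussian fluctuations and ramps linearly
  between them, with per-frame ground-truth labels;
* :func:`make_bounded_school` — a full trajectory table inside a rectangular
  tank realising a state script: polarized segments translate and reflect
  off the walls, milling segments rotate about the group centre, swarm
  segments jitter slowly at reduced spacing, so the qualitative
  state-dependent speed and density of real shoals (slow dense swarms,
  fast ordered mills and polarized groups) is built in.

Default anchors sit at the centres of the empirical hotspot regions:
P (0.85, 0.10), M (0.10, 0.85), S (0.15, 0.15) in (O_p, O_r).  All
generators take an explicit seed or Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ScriptError
from .io import FrameView, TrajectoryDataset, TrajectoryMeta
from .states import classify_point

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

DEFAULT_ANCHORS: dict[str, tuple[float, float]] = {
    "P": (0.85, 0.10),
    "M": (0.10, 0.85),
    "S": (0.15, 0.15),
}

#: State-dependent mean individual speed (cm/s): swarms are slow.
DEFAULT_SPEEDS: dict[str, float] = {"P": 10.0, "M": 10.0, "S": 2.0}


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# -- analytic archetype frames ----------------------------------------------


def _sunflower(n: int, radius: float) -> np.ndarray:
    """Evenly filled disc (sunflower/phyllotaxis arrangement)."""
    i = np.arange(n) + 0.5
    r = radius * np.sqrt(i / n)
    th = i * GOLDEN_ANGLE
    return np.column_stack((r * np.cos(th), r * np.sin(th)))


def _mill_layout(n: int, r_inner: float, r_outer: float) -> np.ndarray:
    """Concentric rings filled proportionally to their circumference."""
    if n <= 36:
        radii = np.full(n, r_outer)
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack((radii * np.cos(theta), radii * np.sin(theta)))
    n_rings = max(2, int(round(math.sqrt(n) / 1.8)))
    ring_r = np.linspace(r_inner, r_outer, n_rings)
    weights = ring_r / ring_r.sum()
    counts = np.maximum(1, np.round(weights * n).astype(int))
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n:
        counts[np.argmax(ring_r)] += 1
    pts = []
    for r, c in zip(ring_r, counts):
        th = np.linspace(0, 2 * np.pi, c, endpoint=False) + (r * 17.0) % 1.0
        pts.append(np.column_stack((r * np.cos(th), r * np.sin(th))))
    return np.concatenate(pts)


def make_archetype(
    kind: str,
    n: int,
    rng: np.random.Generator | int | None = None,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    radius: float = 20.0,
    speed: float = 10.0,
    handedness: int = 1,
    heading_angle: float | None = None,
    jitter: float = 0.0,
) -> FrameView:
    """A single frame realising one collective state exactly.

    kind 'polarized': positions in a jittered disc, one common heading
    (O_p = 1).  kind 'mill': concentric rings with tangential headings of
    one handedness (+1 = counter-clockwise; rotation magnitude 1).  kind
    'swarm': uniform positions in a disc, independent uniform headings
    (both order parameters ~ n^-1/2).
    """
    rng = _rng(rng)
    if kind == "mill" and n < 3:
        raise ParameterError("a mill needs at least 3 fish")
    if n < 1:
        raise ParameterError("n must be >= 1")
    cx, cy = center
    if kind == "polarized":
        pos = _sunflower(n, radius)
        ang = rng.uniform(0, 2 * np.pi) if heading_angle is None else heading_angle
        u = np.tile([math.cos(ang), math.sin(ang)], (n, 1))
    elif kind == "mill":
        pos = _mill_layout(n, 0.4 * radius, radius)
        rr = np.hypot(pos[:, 0], pos[:, 1])
        u = handedness * np.column_stack((-pos[:, 1] / rr, pos[:, 0] / rr))
    elif kind == "swarm":
        r = radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        pos = np.column_stack((r * np.cos(th), r * np.sin(th)))
        phi = rng.uniform(0, 2 * np.pi, n)
        u = np.column_stack((np.cos(phi), np.sin(phi)))
    else:
        raise ParameterError(f"unknown archetype kind: {kind!r}")
    if jitter > 0:
        pos = pos + rng.normal(0, jitter, pos.shape)
    pos = pos + np.array([cx, cy])
    return FrameView(
        frame_index=0,
        ids=np.arange(n),
        positions=pos,
        velocities=speed * u,
        headings=u,
        speeds=np.full(n, float(speed)),
        valid=np.ones(n, dtype=bool),
    )


# -- scripted order-parameter series ----------------------------------------


@dataclass
class StateScript:
    """An ordered dwell plan through the collective states.

    ``segments`` is a list of ``(label, dwell_seconds)`` with labels in
    {'S', 'P', 'M'}.  Consecutive anchors are joined by linear ramps of
    ``ramp_s`` seconds; Gaussian fluctuations of sd ``sd`` ride on top.
    Anchors are (O_p, O_r) points and must classify as their own label.
    """

    segments: list[tuple[str, float]]
    fps: float = 30.0
    anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    sd: float = 0.02
    ramp_s: float = 2.0
    k: float = 0.35

    def __post_init__(self) -> None:
        if not self.segments:
            raise ScriptError("script needs at least one segment")
        for lab, dwell in self.segments:
            if lab not in self.anchors:
                raise ScriptError(f"no anchor for label {lab!r}")
            if dwell <= 0:
                raise ScriptError("dwell times must be > 0")
        for lab, (op, orr) in self.anchors.items():
            if classify_point(op, orr, self.k) != lab:
                raise ScriptError(
                    f"anchor {lab}=({op}, {orr}) does not classify as {lab} at k={self.k}"
                )

    @property
    def n_scripted_transitions(self) -> int:
        labs = [lab for lab, _ in self.segments]
        return sum(1 for a, b in zip(labs, labs[1:]) if a != b)


def make_state_series(
    script: StateScript, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Realise a script as an order-parameter time series.

    Returns ``(series, truth)`` where ``series`` has columns
    ``frame, O_p, signed_r, O_r`` (noisy, clipped to [0,1]) and ``truth``
    holds per-frame ground-truth labels obtained by classifying the
    *noiseless* series — ramp frames that leave the source region are 'T'.
    Each segment's signed rotation takes a random handedness.
    """
    rng = _rng(rng)
    fps = script.fps
    ramp_frames = int(round(script.ramp_s * fps))
    op_clean: list[np.ndarray] = []
    orr_clean: list[np.ndarray] = []
    signs: list[np.ndarray] = []
    prev_anchor: tuple[float, float] | None = None
    prev_sign = 1.0
    for lab, dwell in script.segments:
        a_op, a_or = script.anchors[lab]
        sign = float(rng.choice([-1.0, 1.0]))
        nf = int(round(dwell * fps))
        if prev_anchor is not None and ramp_frames > 0:
            t = np.linspace(0, 1, ramp_frames + 2)[1:-1]
            op_clean.append(prev_anchor[0] + t * (a_op - prev_anchor[0]))
            orr_clean.append(prev_anchor[1] + t * (a_or - prev_anchor[1]))
            signs.append(np.where(t < 0.5, prev_sign, sign))
        op_clean.append(np.full(nf, a_op))
        orr_clean.append(np.full(nf, a_or))
        signs.append(np.full(nf, sign))
        prev_anchor = (a_op, a_or)
        prev_sign = sign
    op0 = np.concatenate(op_clean)
    orr0 = np.concatenate(orr_clean)
    sgn = np.concatenate(signs)
    truth = np.array([classify_point(p, r, script.k) for p, r in zip(op0, orr0)])
    op = np.clip(op0 + rng.normal(0, script.sd, len(op0)), 0, 1)
    orr = np.clip(orr0 + rng.normal(0, script.sd, len(orr0)), 0, 1)
    series = pd.DataFrame(
        {
            "frame": np.arange(len(op)),
            "O_p": op,
            "signed_r": sgn * orr,
            "O_r": orr,
        }
    )
    return series, truth


# -- bounded-tank school trajectories ---------------------------------------


def make_bounded_school(
    script: StateScript,
    tank_width: float,
    tank_height: float,
    n: int,
    rng: np.random.Generator | int | None = None,
    *,
    spacing: float = 4.0,
    speeds: dict[str, float] | None = None,
    body_length: float = 5.2,
) -> tuple[TrajectoryDataset, pd.DataFrame]:
    """A full trajectory table realising a state script inside a tank.

    Milling segments rotate rings about the group centre; polarized
    segments translate the group, reflecting off the walls; swarm segments
    jitter slowly at 60% spacing (denser and slower, as in real shoals).
    Ramps between segments morph positions linearly.  Velocities come from
    central differences of the positions, so the derived headings are
    consistent with the motion.  Returns ``(dataset, truth)`` with ``truth``
    a DataFrame of per-frame ground-truth labels (ramp frames 'T').
    """
    rng = _rng(rng)
    speeds = dict(DEFAULT_SPEEDS if speeds is None else speeds)
    fps = script.fps
    dt = 1.0 / fps
    radius = spacing * math.sqrt(n / math.pi)
    margin = radius + 2.0 * spacing
    if 2 * margin >= tank_width or 2 * margin >= tank_height:
        raise ParameterError(
            f"tank {tank_width} x {tank_height} cm too small for a group of "
            f"radius {radius:.1f} cm"
        )
    base_disc = _sunflower(n, radius) + rng.normal(0, 0.15 * spacing, (n, 2))
    base_mill = _mill_layout(n, 0.4 * radius, radius)
    base_swarm = 0.6 * base_disc
    ramp_frames = int(round(script.ramp_s * fps))

    def _match(layout: np.ndarray, target_rel: np.ndarray | None) -> np.ndarray:
        """Permute pattern slots to minimise fish displacement at hand-over."""
        if target_rel is None:
            return layout
        from scipy.optimize import linear_sum_assignment

        d2 = ((target_rel[:, None, :] - layout[None, :, :]) ** 2).sum(-1)
        _, cols = linear_sum_assignment(d2)
        return layout[cols]

    def _pattern_block(
        lab: str, center0: np.ndarray, length: int, target_rel: np.ndarray | None
    ) -> np.ndarray:
        """Positions of one state's motion pattern over ``length`` frames."""
        out = np.empty((length, n, 2))
        if lab == "P":
            layout = _match(base_disc, target_rel)
            ang = rng.uniform(0, 2 * np.pi)
            vel = speeds["P"] * np.array([math.cos(ang), math.sin(ang)])
            c = center0.copy()
            for t in range(length):
                c = c + vel * dt
                if c[0] < margin or c[0] > tank_width - margin:
                    vel[0] = -vel[0]
                    c[0] = np.clip(c[0], margin, tank_width - margin)
                if c[1] < margin or c[1] > tank_height - margin:
                    vel[1] = -vel[1]
                    c[1] = np.clip(c[1], margin, tank_height - margin)
                out[t] = c + layout
        elif lab == "M":
            layout = _match(base_mill, target_rel)
            rr = np.hypot(layout[:, 0], layout[:, 1])
            omega = float(rng.choice([-1.0, 1.0])) * speeds["M"] / rr.mean()
            for t in range(length):
                a = omega * t * dt
                ca, sa = math.cos(a), math.sin(a)
                out[t] = center0 + layout @ np.array([[ca, sa], [-sa, ca]])
        elif lab == "S":
            layout = _match(base_swarm, target_rel)
            amp = speeds["S"] / 1.5  # wiggle amplitude giving ~speeds['S'] cm/s
            w = rng.uniform(1.0, 2.0, (n, 2))
            ph = rng.uniform(0, 2 * np.pi, (n, 2))
            tt = np.arange(length)[:, None, None] * dt
            out[:] = center0 + layout + amp * np.sin(w * tt + ph)
        else:
            raise ScriptError(f"bounded school cannot realise label {lab!r}")
        return out

    # Each segment's pattern runs for ramp + dwell + ramp frames: a blend-in
    # prefix, the dwell itself, and a blend-out extension.  During a ramp the
    # outgoing and incoming patterns BOTH keep moving and positions are
    # smoothstep-blended between them, so the derived velocity field morphs
    # from one coherent motion to the other and the order-parameter path runs
    # through the transition band rather than collapsing through disorder.
    blocks: list[np.ndarray] = []
    dwell_frames: list[int] = []
    center = np.array([tank_width / 2.0, tank_height / 2.0])
    target_rel = None
    for lab, dwell in script.segments:
        nf = int(round(dwell * fps))
        block = _pattern_block(lab, center, ramp_frames + nf + ramp_frames, target_rel)
        blocks.append(block)
        dwell_frames.append(nf)
        handover = block[ramp_frames + nf - 1]
        center = handover.mean(axis=0)
        target_rel = handover - center

    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i, (lab, _) in enumerate(script.segments):
        nf = dwell_frames[i]
        if i > 0 and ramp_frames > 0:
            w = np.linspace(0, 1, ramp_frames + 2)[1:-1, None, None]
            w = w * w * (3 - 2 * w)  # smoothstep eases velocity hand-over
            prev_ext = blocks[i - 1][
                ramp_frames + dwell_frames[i - 1] : ramp_frames + dwell_frames[i - 1] + ramp_frames
            ]
            chunks.append((1 - w) * prev_ext + w * blocks[i][:ramp_frames])
            labels.append(np.full(ramp_frames, "T"))
        chunks.append(blocks[i][ramp_frames : ramp_frames + nf])
        labels.append(np.full(nf, lab))

    pos = np.concatenate(chunks)
    truth_labels = np.concatenate(labels)
    pos[..., 0] = np.clip(pos[..., 0], 0.0, tank_width)
    pos[..., 1] = np.clip(pos[..., 1], 0.0, tank_height)

    vel = np.empty_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) * (fps / 2.0)
    vel[0] = (pos[1] - pos[0]) * fps
    vel[-1] = (pos[-1] - pos[-2]) * fps

    n_frames = len(pos)
    frames = np.repeat(np.arange(n_frames), n)
    ids = np.tile(np.arange(n), n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "id": ids,
            "x": pos.reshape(-1, 2)[:, 0],
            "y": pos.reshape(-1, 2)[:, 1],
            "vx": vel.reshape(-1, 2)[:, 0],
            "vy": vel.reshape(-1, 2)[:, 1],
        }
    )
    meta = TrajectoryMeta(
        fps=fps, tank_width=tank_width, tank_height=tank_height, body_length=body_length
    )
    truth = pd.DataFrame({"frame": np.arange(n_frames), "true_label": truth_labels})
    return TrajectoryDataset(df, meta), truth
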