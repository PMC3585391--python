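"""End-to-end analysis: trajectory table in, state statistics out.

:class:`SchoolAnalysis` ties the stages together — kinematics, per-frame
order parameters and geometry, smoothing, state classification, visit and
transition extraction, phase-space maps, the radial mill profile and the
speed/local-order conditional curves — under a single
:class:`AnalysisConfig` whose defaults are the conventions used throughout
the package (k = 0.35, smoothing span 30 frames, local radius 15.6 cm,
occupancy/transition map support thresholds 100/20, 1 s minimum dwell for
the transition-zone completion statistic).

``SchoolAnalysis(dataset, config).run()`` returns an
:class:`AnalysisResult` carrying all tables and summaries, with
``summary()`` for a human-readable digest and ``write_bundle()`` for a
reproducible on-disk report (every file stamped with the manifest hash, so
identical inputs and config give byte-identical bundles).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, order, phase, states
from .errors import DegenerateGeometryError, InsufficientDataError
from .io import TrajectoryDataset, derive_kinematics
from .sim import SimConfig, speed_sweep

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis constants in one place."""

    k: float = 0.35  # state-region threshold
    smoothing_span: int = 30  # frames (1 s at 30 fps)
    local_radius: float = 15.6  # cm, ~3 body lengths
    alpha_radius: float = 5.2  # cm, 1 body length
    body_area: float = 3.38  # cm^2
    min_count_density: int = 100
    min_count_transitions: int = 20
    min_t_duration: float = 1.0  # s
    bridge_gap_s: float = 1.0  # s
    speed_floor: float = 1e-6  # cm/s
    local_stride: int = 5  # sample every k-th frame for per-fish curves
    shell_max_frames: int = 500  # cap on milling frames entering the shell profile
    seed: int = 0

    def manifest_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """Everything :class:`SchoolAnalysis` computes, plus export helpers."""

    config: AnalysisConfig
    order_series: pd.DataFrame  # frame, O_p, signed_r, O_r, mean_speed, packing_fraction, d_b (smoothed)
    labels: np.ndarray
    visits: list
    events: list
    summary_stats: dict
    density_grid: phase.PhaseGrid
    mean_speed_grid: phase.PhaseGrid
    packing_grid: phase.PhaseGrid | None
    boundary_grid: phase.PhaseGrid | None
    shell: order.ShellProfile | None
    conditional_curves: tuple | None
    survival: dict[str, states.SurvivalCurve]

    def summary(self) -> str:
        s = self.summary_stats
        lines = ["School collective-state analysis", "=" * 34]
        lines.append(
            f"frames: {s['n_frames']}  duration: {s['total_minutes']:.2f} min  "
            f"fish (median/frame): {s['median_group_size']}"
        )
        fr = s["state_fractions"]
        lines.append(
            "time fractions  S: {S:.3f}  P: {P:.3f}  M: {M:.3f}  T: {T:.3f}".format(**fr)
        )
        lines.append(
            f"completed transitions: {s['n_transitions']} "
            f"({s['transition_rate_per_min']:.2f} per min)"
        )
        if s["completion_fraction"] is not None:
            lines.append(
                "transition-zone completion: {0:.0%} ({1} of {2} visits > "
                "{3:g} s)".format(
                    s["completion_fraction"],
                    s["n_completed"],
                    s["n_qualifying_T_visits"],
                    self.config.min_t_duration,
                )
            )
        cw, ccw = s["handedness"]
        lines.append(f"milling handedness  CW: {cw}  CCW: {ccw}")
        for lab in states.ALL_LABELS:
            lv = s["longest_visit_s"].get(lab)
            if lv is not None:
                lines.append(f"longest {lab} visit: {lv:.1f} s")
        return "\n".join(lines)

    # -- export --------------------------------------------------------------

    def write_bundle(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = self.config.manifest_hash()
        stamp = f"# manifest: {h}\n"

        def _csv(df: pd.DataFrame, name: str) -> None:
            with open(outdir / name, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, index=False)

        _csv(self.order_series, "order_series.csv")
        _csv(
            pd.DataFrame(
                [
                    (v.label, v.start, v.end, v.n_frames, v.duration)
                    for v in self.visits
                ],
                columns=["label", "start", "end", "n_frames", "duration_s"],
            ),
            "visits.csv",
        )
        _csv(
            pd.DataFrame(
                [(e.from_label, e.to_label, e.start, e.end) for e in self.events],
                columns=["from", "to", "start", "end"],
            ),
            "transitions.csv",
        )
        export_grid(self.density_grid, outdir / "phase_density.csv", h)
        if self.shell is not None:
            _csv(
                pd.DataFrame(
                    {
                        "shell": np.arange(1, self.shell.n_shells + 1),
                        "mean_speed": self.shell.mean_speed,
                        "rotation": self.shell.rotation,
                        "occupancy": self.shell.occupancy,
                    }
                ),
                "shell_profile.csv",
            )
        else:
            (outdir / "shell_profile.csv").write_text(stamp + "shell,mean_speed,rotation,occupancy\n")
        if self.conditional_curves is not None:
            (yc, xm), (xc, ym) = self.conditional_curves
            n = max(len(yc), len(xc))

            def _pad(a):
                return np.concatenate((a, np.full(n - len(a), np.nan)))

            _csv(
                pd.DataFrame(
                    {
                        "local_order_bin": _pad(yc),
                        "mean_speed_at_order": _pad(xm),
                        "speed_bin": _pad(xc),
                        "mean_order_at_speed": _pad(ym),
                    }
                ),
                "conditional_curves.csv",
            )
        else:
            (outdir / "conditional_curves.csv").write_text(
                stamp + "local_order_bin,mean_speed_at_order,speed_bin,mean_order_at_speed\n"
            )
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"manifest": h, **_jsonable(self.summary_stats)}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "manifest": h,
                    "config": dataclasses.asdict(self.config),
                    "version": __version__,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def export_grid(grid: phase.PhaseGrid, path: str | Path, manifest_hash: str = "") -> None:
    """Delimited matrix with a JSON header line (axis order O_r, O_p)."""
    header = {
        "manifest": manifest_hash,
        "axis0": "O_r",
        "axis1": "O_p",
        "mode": grid.mode,
        "min_count": grid.min_count,
        "n_bins": len(grid.centers),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        np.savetxt(fh, np.where(grid.mask, grid.values, np.nan), delimiter=",", fmt="%.8g")


class SchoolAnalysis:
    """High-level driver over one trajectory dataset."""

    def __init__(self, dataset: TrajectoryDataset, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        if not dataset.has_kinematics:
            dataset = derive_kinematics(dataset, self.config.speed_floor)
        self.dataset = dataset

    def run(self) -> AnalysisResult:
        cfg = self.config
        ds = self.dataset
        tank = geometry.TankGeometry(ds.meta.tank_width, ds.meta.tank_height)

        rows = []
        group_sizes = []
        fish_speed: list[np.ndarray] = []
        fish_localp: list[np.ndarray] = []
        frame_views = {}
        for i, fv in enumerate(ds.frames()):
            op = order.polarization(fv)
            signed, mag = order.rotation(fv)
            sp = float(fv.speeds[fv.valid].mean()) if fv.n_valid else math.nan
            try:
                phi = geometry.packing_fraction(fv, cfg.body_area, cfg.alpha_radius)
            except DegenerateGeometryError:
                phi = math.nan
            try:
                db = geometry.boundary_distance(fv, tank)
            except Exception:
                db = math.nan
            rows.append((fv.frame_index, op, signed, mag, sp, phi, db))
            group_sizes.append(fv.n)
            frame_views[i] = fv
            if i % cfg.local_stride == 0 and fv.n_valid >= 2:
                s, lp = _local_polarization_samples(fv, cfg.local_radius)
                fish_speed.append(s)
                fish_localp.append(lp)

        raw = pd.DataFrame(
            rows,
            columns=["frame", "O_p", "signed_r", "O_r", "mean_speed", "packing_fraction", "d_b"],
        )
        n_frames = len(raw)
        logger.info("order series: %d frames", n_frames)

        sm = raw.copy()
        sm["O_p"] = order.smooth_series(raw["O_p"].to_numpy(), cfg.smoothing_span)
        sm["signed_r"] = order.smooth_series(raw["signed_r"].to_numpy(), cfg.smoothing_span)
        # O_r is smoothed from its own magnitude series, not |smoothed signed|
        sm["O_r"] = order.smooth_series(raw["O_r"].to_numpy(), cfg.smoothing_span)

        labels = states.label_series(
            sm["O_p"].to_numpy(), sm["O_r"].to_numpy(), cfg.k
        )
        visits = states.extract_visits(labels, ds.fps, bridge_gap_s=cfg.bridge_gap_s)
        events = states.completed_transitions(
            visits, sm["O_r"].to_numpy(), sm["O_p"].to_numpy()
        )
        logger.info("%d visits, %d completed transitions", len(visits), len(events))

        labelled_s = sum(v.duration for v in visits)
        total_minutes = labelled_s / 60.0
        fractions = states.state_time_fractions(visits)
        tstats = states.transition_stats(events, total_minutes)
        try:
            comp, n_c, n_q = states.transition_completion_fraction(visits, cfg.min_t_duration)
        except InsufficientDataError:
            comp, n_c, n_q = None, 0, 0
        handed = states.milling_handedness(sm["signed_r"].to_numpy(), visits)
        survival = {}
        for lab in states.ALL_LABELS:
            try:
                survival[lab] = states.persistence_survival(visits, lab)
            except InsufficientDataError:
                pass
        longest = {
            lab: max((v.duration for v in visits if v.label == lab), default=None)
            for lab in states.ALL_LABELS
        }

        pts_ok = np.isfinite(sm["O_r"].to_numpy()) & np.isfinite(sm["O_p"].to_numpy())
        pts = np.column_stack((sm["O_r"].to_numpy()[pts_ok], sm["O_p"].to_numpy()[pts_ok]))
        pts = np.clip(pts, 0.0, 1.0)
        density_grid = phase.phase_histogram(pts, cfg.min_count_density)
        mean_speed_grid = phase.phase_mean_map(
            pts, sm["mean_speed"].to_numpy()[pts_ok], cfg.min_count_density
        )
        packing_grid = phase.phase_mean_map(
            pts, sm["packing_fraction"].to_numpy()[pts_ok], cfg.min_count_density
        )
        boundary_grid = phase.phase_mean_map(
            pts, sm["d_b"].to_numpy()[pts_ok], cfg.min_count_density
        )

        shell = None
        m_pos = np.flatnonzero(labels == "M")
        if len(m_pos) > 0:
            step_ = max(1, len(m_pos) // cfg.shell_max_frames)
            try:
                shell = order.shell_profile(
                    (frame_views[int(i)] for i in m_pos[::step_] if frame_views[int(i)].n >= 5)
                )
            except InsufficientDataError:
                shell = None

        curves = None
        if fish_speed:
            try:
                curves = phase.conditional_mean_curves(
                    np.concatenate(fish_speed), np.concatenate(fish_localp)
                )
            except InsufficientDataError:
                curves = None

        summary_stats = {
            "n_frames": n_frames,
            "total_minutes": total_minutes,
            "median_group_size": int(np.median(group_sizes)),
            "state_fractions": fractions,
            "n_transitions": len(events),
            "transition_rate_per_min": tstats.rate_per_min,
            "destination_fractions": tstats.destination_fractions,
            "completion_fraction": comp,
            "n_completed": n_c,
            "n_qualifying_T_visits": n_q,
            "handedness": handed,
            "longest_visit_s": longest,
            "n_visits": len(visits),
        }
        return AnalysisResult(
            config=cfg,
            order_series=sm,
            labels=labels,
            visits=visits,
            events=events,
            summary_stats=summary_stats,
            density_grid=density_grid,
            mean_speed_grid=mean_speed_grid,
            packing_grid=packing_grid,
            boundary_grid=boundary_grid,
            shell=shell,
            conditional_curves=curves,
            survival=survival,
        )


def _local_polarization_samples(fv, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-fish (speed, local polarization) for all valid fish of a frame."""
    m = fv.valid
    pos = fv.positions[m]
    u = fv.headings[m]
    sp = fv.speeds[m]
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    nb = d2 <= radius * radius  # includes self
    sums = nb @ u
    cnt = nb.sum(axis=1)
    lp = np.hypot(sums[:, 0], sums[:, 1]) / cnt
    return sp, lp


def analyze(dataset: TrajectoryDataset, config: AnalysisConfig | None = None) -> AnalysisResult:
    """Functional one-liner over :class:`SchoolAnalysis`."""
    return SchoolAnalysis(dataset, config).run()


def sweep_and_phase(
    base_cfg: SimConfig,
    n_values=(30, 70, 150, 300),
    replicates: int = 500,
    speeds=None,
    base_seed: int | None = None,
    min_count: int = 1,
) -> dict[int, dict]:
    """Speed sweeps across group sizes plus their phase-space density grids.

    For each N the zonal-model sweep is run and the final (O_r, O_p) points
    of all replicates and speeds are binned into an occupancy grid
    (``min_count`` defaults to 1 because scaled-down sweeps have far fewer
    samples per bin than a full 500-replicate campaign).
    """
    out: dict[int, dict] = {}
    for n in n_values:
        cfg = dataclasses.replace(base_cfg, n=int(n))
        table = speed_sweep(cfg, speeds=speeds, replicates=replicates, base_seed=base_seed)
        pts = np.clip(table[["O_r", "O_p"]].to_numpy(), 0.0, 1.0)
        out[int(n)] = {
            "sweep": table,
            "density": phase.phase_histogram(pts, min_count=min_count),
        }
        logger.info("sweep N=%d: %d runs", n, len(table))
    return out
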