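"""State classification and transition statistics.

The (O_r, O_p) phase space is partitioned with a single threshold ``k``
(default 0.35, with 0 < k < 0.5 so the regions are disjoint):

* polarized  (P): O_p > 1-k and O_r < k
* milling    (M): O_p < k   and O_r > 1-k
* swarm      (S): O_p < k   and O_r < k
* transition (T): everything else, including exact threshold values
  (inequalities are strict).

Classification is applied to the *smoothed* order-parameter series.  Runs of
equal labels become visits; a *completed transition* is a move from one of
S/P/M to a different one of S/P/M, regardless of intervening T frames — a
group that dips into T and returns to its previous state has not
transitioned.  From the visits we derive occupancy fractions, transition
rates and per-source destination fractions, persistence (survival) curves,
the completion fraction of excursions into T, and the handedness of milling
bouts.

Frames whose order parameters are undefined are labelled as gaps ('G');
gaps are excluded from duration accounting, short gaps (<= 1 s) flanked by
the same label are bridged, and longer gaps split visits and break
transition pairing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

STATE_LABELS = ("S", "P", "M")
ALL_LABELS = ("S", "P", "M", "T")
GAP = "G"


@dataclass(frozen=True)
class StateThresholds:
    """Single threshold k defining the S/P/M corner regions."""

    k: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.k < 0.5:
            raise ParameterError("k must satisfy 0 < k < 0.5 so regions are disjoint")


_DOMAIN_TOL = 1e-9  # rounding slack on the unit interval


def classify_point(o_p: float, o_r: float, thresholds: StateThresholds | float = 0.35) -> str:
    """Classify one (O_p, O_r) point into 'S', 'P', 'M' or 'T'."""
    k = thresholds.k if isinstance(thresholds, StateThresholds) else StateThresholds(thresholds).k
    if not (-_DOMAIN_TOL <= o_p <= 1 + _DOMAIN_TOL) or not (-_DOMAIN_TOL <= o_r <= 1 + _DOMAIN_TOL):
        raise ParameterError(f"order parameters must lie in [0,1], got ({o_p}, {o_r})")
    o_p = min(max(o_p, 0.0), 1.0)
    o_r = min(max(o_r, 0.0), 1.0)
    if o_p > 1 - k and o_r < k:
        return "P"
    if o_p < k and o_r > 1 - k:
        return "M"
    if o_p < k and o_r < k:
        return "S"
    return "T"


def label_series(
    o_p: np.ndarray, o_r: np.ndarray, thresholds: StateThresholds | float = 0.35
) -> np.ndarray:
    """Vectorised classification of a (smoothed) series; NaN frames -> 'G'."""
    k = thresholds.k if isinstance(thresholds, StateThresholds) else StateThresholds(thresholds).k
    o_p = np.asarray(o_p, dtype=float)
    o_r = np.asarray(o_r, dtype=float)
    if o_p.shape != o_r.shape:
        raise ParameterError("O_p and O_r series must have equal length")
    finite = np.isfinite(o_p) & np.isfinite(o_r)
    if np.any(
        (o_p[finite] < -_DOMAIN_TOL)
        | (o_p[finite] > 1 + _DOMAIN_TOL)
        | (o_r[finite] < -_DOMAIN_TOL)
        | (o_r[finite] > 1 + _DOMAIN_TOL)
    ):
        raise ParameterError("order parameters must lie in [0,1]")
    o_p = np.clip(o_p, 0.0, 1.0)
    o_r = np.clip(o_r, 0.0, 1.0)
    out = np.full(o_p.shape, "T", dtype="<U1")
    out[(o_p > 1 - k) & (o_r < k)] = "P"
    out[(o_p < k) & (o_r > 1 - k)] = "M"
    out[(o_p < k) & (o_r < k)] = "S"
    out[~finite] = GAP
    return out


@dataclass
class StateVisit:
    """A maximal run of one label.

    ``start``/``end`` are inclusive positions in the label array;
    ``n_frames`` counts the labelled (non-gap) frames inside the run, so
    ``duration = n_frames / fps`` — equal to ``(end - start + 1)/fps`` when
    no gap was bridged.  ``after_break`` marks a visit preceded by a gap too
    long to bridge; transition pairing does not cross such breaks.
    """

    label: str
    start: int
    end: int
    n_frames: int
    fps: float
    after_break: bool = False

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class TransitionEvent:
    """A completed move between two distinct states among S/P/M.

    ``path`` (optional) holds the (O_r, O_p) points from the last frame of
    the source visit through any T frames to the first frame of the
    destination visit.
    """

    from_label: str
    to_label: str
    start: int  # last frame position of the source visit
    end: int  # first frame position of the destination visit
    path: np.ndarray | None = field(default=None, repr=False)


def extract_visits(
    labels: np.ndarray, fps: float, *, bridge_gap_s: float = 1.0
) -> list[StateVisit]:
    """Run-length encode a label sequence into visits.

    Gap frames ('G') never form visits.  A gap run of at most
    ``bridge_gap_s`` seconds flanked by the same label is bridged into a
    single visit (its frames excluded from the duration); a longer gap, or a
    gap between different labels, closes the current visit and marks the
    next one ``after_break``.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    # run-length encode
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(labels) - 1]))
    runs = [(str(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]

    max_gap_frames = int(round(bridge_gap_s * fps))
    visits: list[StateVisit] = []
    cur: StateVisit | None = None
    pending_break = False
    i = 0
    while i < len(runs):
        lab, s, e = runs[i]
        if lab == GAP:
            gap_len = e - s + 1
            prev_lab = cur.label if cur is not None else None
            next_lab = runs[i + 1][0] if i + 1 < len(runs) else None
            if (
                gap_len <= max_gap_frames
                and prev_lab is not None
                and next_lab == prev_lab
            ):
                # bridge: extend current visit across the gap
                nlab, ns, ne = runs[i + 1]
                cur.end = ne
                cur.n_frames += ne - ns + 1
                i += 2
                continue
            if cur is not None:
                visits.append(cur)
                cur = None
            pending_break = True
            i += 1
            continue
        if cur is not None and lab == cur.label and not pending_break:
            cur.end = e
            cur.n_frames += e - s + 1
        else:
            if cur is not None:
                visits.append(cur)
            cur = StateVisit(lab, s, e, e - s + 1, fps, after_break=pending_break)
            pending_break = False
        i += 1
    if cur is not None:
        visits.append(cur)
    return visits


def completed_transitions(
    visits: list[StateVisit],
    o_r: np.ndarray | None = None,
    o_p: np.ndarray | None = None,
) -> list[TransitionEvent]:
    """Extract completed transitions from a visit sequence.

    Consecutive non-T visits (T visits in between are skipped, tracking
    breaks are not crossed) produce an event iff their labels differ.  If the
    smoothed ``o_r``/``o_p`` series are given, each event carries its
    phase-space path.
    """
    events: list[TransitionEvent] = []
    prev: StateVisit | None = None
    for v in visits:
        if v.after_break:
            prev = None
        if v.label == "T":
            continue
        if prev is not None and v.label != prev.label:
            path = None
            if o_r is not None and o_p is not None:
                seg = slice(prev.end, v.start + 1)
                path = np.column_stack((np.asarray(o_r)[seg], np.asarray(o_p)[seg]))
            events.append(TransitionEvent(prev.label, v.label, prev.end, v.start, path))
        prev = v
    return events


def state_time_fractions(visits: list[StateVisit]) -> dict[str, float]:
    """Fraction of (labelled) time per label; fractions sum to 1."""
    totals = {lab: 0.0 for lab in ALL_LABELS}
    for v in visits:
        totals[v.label] += v.duration
    total = sum(totals.values())
    if total <= 0:
        raise InsufficientDataError("zero total duration")
    return {lab: t / total for lab, t in totals.items()}


@dataclass
class TransitionStats:
    rate_per_min: float
    n_events: int
    #: per source label: {destination: fraction} or None if no events from it
    destination_fractions: dict[str, dict[str, float] | None]


def transition_stats(events: list[TransitionEvent], total_minutes: float) -> TransitionStats:
    """Transition rate per minute and per-source destination fractions."""
    if total_minutes <= 0:
        raise ParameterError("total_minutes must be > 0")
    frac: dict[str, dict[str, float] | None] = {}
    for src in STATE_LABELS:
        outs = [e.to_label for e in events if e.from_label == src]
        if not outs:
            frac[src] = None
            continue
        frac[src] = {
            dst: outs.count(dst) / len(outs) for dst in STATE_LABELS if dst != src
        }
    return TransitionStats(len(events) / total_minutes, len(events), frac)


@dataclass
class SurvivalCurve:
    """Empirical survival function of visit durations: P(T_s > t)."""

    durations: np.ndarray  # sorted, seconds

    def prob_longer(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        p = (self.durations[None, ...] > t[..., None]).mean(axis=-1)
        return float(p) if p.ndim == 0 else p

    def curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, P(T_s > t)) evaluated at 0 and every observed duration."""
        t = np.concatenate(([0.0], np.unique(self.durations)))
        return t, np.asarray(self.prob_longer(t))


def persistence_survival(visits: list[StateVisit], label: str) -> SurvivalCurve:
    """Survival curve of the durations of one label's visits."""
    durs = np.sort([v.duration for v in visits if v.label == label])
    if len(durs) == 0:
        raise InsufficientDataError(f"no visits with label {label!r}")
    return SurvivalCurve(durs)


def transition_completion_fraction(
    visits: list[StateVisit], min_T_duration: float = 1.0
) -> tuple[float, int, int]:
    """Fraction of qualifying excursions into T that complete a transition.

    Qualifying: T visits lasting strictly longer than ``min_T_duration``
    seconds, flanked on both sides by non-T visits with no tracking break in
    between.  Returns ``(fraction, n_completed, n_qualifying)``.
    """
    n_q = 0
    n_c = 0
    for i, v in enumerate(visits):
        if v.label != "T" or v.duration <= min_T_duration:
            continue
        if i == 0 or i == len(visits) - 1:
            continue
        prev, nxt = visits[i - 1], visits[i + 1]
        if prev.label == "T" or nxt.label == "T":
            continue
        if v.after_break or nxt.after_break:
            continue
        n_q += 1
        if prev.label != nxt.label:
            n_c += 1
    if n_q == 0:
        raise InsufficientDataError("no qualifying visits into the transition zone")
    return n_c / n_q, n_c, n_q


def milling_handedness(
    signed_r: np.ndarray, visits: list[StateVisit]
) -> tuple[int, int]:
    """Count clockwise vs counter-clockwise milling bouts.

    Each M visit takes the sign of its mean signed rotation (positive =
    counter-clockwise).  An exact zero mean — a probability-zero event — is
    tie-broken to counter-clockwise and logged.  Returns
    ``(n_clockwise, n_counterclockwise)``.
    """
    signed_r = np.asarray(signed_r, dtype=float)
    n_cw = n_ccw = 0
    for v in visits:
        if v.label != "M":
            continue
        m = float(np.nanmean(signed_r[v.start : v.end + 1]))
        if math.isnan(m):
            continue
        if m < 0:
            n_cw += 1
        else:
            if m == 0:
                logger.warning(
                    "milling visit [%d, %d] has exactly zero mean rotation; "
                    "tie-broken to counter-clockwise",
                    v.start,
                    v.end,
                )
            n_ccw += 1
    return n_cw, n_ccw
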