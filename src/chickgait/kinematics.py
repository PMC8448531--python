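"""Per-stride kinematic scoring for overground bipedal stepping.

A stride cycle runs from one toe-off of a leg to its next toe-off; the swing
phase is toe-off → foot-contact (foot airborne) and the stance phase is
foot-contact → next toe-off (foot loaded). The scores computed here follow
the stability analysis of chick stepping: left-right phase (degrees of the
right stride cycle at which the left toe lifts), swing trajectories resampled
to percent-of-swing, whole-body collapses (knee height dropping strictly
below 85 % of the step's stance-phase mean), overshoots (abnormally high
swing peaks), stride width, landing angle and swing velocity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import (
    InsufficientDataError,
    NoGaitError,
    ResolutionError,
    ValidationError,
)
from .io import TrackedSequence

__all__ = [
    "GaitEvents",
    "Stride",
    "SwingProfile",
    "StepScore",
    "detect_gait_events",
    "segment_strides",
    "compute_lr_phase",
    "normalize_swing",
    "joint_angle_series",
    "detect_collapses",
    "detect_overshoots",
    "classify_collapse_context",
    "landing_angle",
    "stride_width",
    "swing_velocity",
    "score_steps",
]

DEFAULT_LIFT_THRESHOLD_CM = 0.2


@dataclasses.dataclass
class GaitEvents:
    """Ordered toe-off and foot-contact times (seconds) per leg."""

    toe_off: dict[str, np.ndarray]
    foot_contact: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for leg in self.toe_off:
            to = np.asarray(self.toe_off[leg], float)
            fc = np.asarray(self.foot_contact.get(leg, []), float)
            self.toe_off[leg], self.foot_contact[leg] = to, fc
            if np.any(np.diff(to) <= 0) or np.any(np.diff(fc) <= 0):
                raise ValidationError(f"event times for leg {leg!r} not strictly increasing")
            # alternation: each toe-off is followed by a foot-contact before
            # the next toe-off (the trailing toe-off may be unpaired)
            for i, t in enumerate(to[:-1]):
                nxt = fc[(fc > t)]
                if len(nxt) == 0 or nxt[0] >= to[i + 1]:
                    raise ValidationError(
                        f"leg {leg!r}: no foot-contact between toe-offs {t:.4f} and {to[i + 1]:.4f}"
                    )

    def legs(self) -> list[str]:
        return sorted(self.toe_off)


@dataclasses.dataclass
class Stride:
    """One stride cycle of one leg with its per-frame metric traces."""

    leg: str
    t_toe_off: float
    t_foot_contact: float | None
    t_next_toe_off: float
    times: np.ndarray
    knee_height: np.ndarray
    tmp_angle: np.ndarray | None = None
    toe_x: np.ndarray | None = None
    incomplete: bool = False
    has_missing: bool = False

    @property
    def duration(self) -> float:
        return self.t_next_toe_off - self.t_toe_off

    @property
    def swing_mask(self) -> np.ndarray:
        if self.t_foot_contact is None:
            return np.zeros(len(self.times), bool)
        return (self.times >= self.t_toe_off) & (self.times < self.t_foot_contact)

    @property
    def stance_mask(self) -> np.ndarray:
        if self.t_foot_contact is None:
            return np.zeros(len(self.times), bool)
        return (self.times >= self.t_foot_contact) & (self.times < self.t_next_toe_off)

    @property
    def stance_baseline(self) -> float:
        """Mean knee height over this cycle's stance frames (cm)."""
        mask = self.stance_mask
        if not mask.any():
            return float("nan")
        return float(np.nanmean(self.knee_height[mask]))


@dataclasses.dataclass
class SwingProfile:
    """A swing-phase trajectory resampled onto a uniform 0–100 % grid."""

    grid: np.ndarray
    values: np.ndarray
    kind: str = "knee_height"
    chick_id: str = ""
    group: str = ""
    step_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.values = np.asarray(self.values, float)
        if len(self.grid) != len(self.values):
            raise ValidationError("grid and values must have equal length")
        if len(self.grid) >= 2:
            if np.any(np.diff(self.grid) <= 0):
                raise ValidationError("grid must be strictly increasing")
            if not (abs(self.grid[0]) < 1e-9 and abs(self.grid[-1] - 100.0) < 1e-9):
                raise ValidationError("grid endpoints must be 0 and 100")

    @property
    def range(self) -> float:
        """max − min of the trajectory (the per-step variability metric)."""
        return float(np.nanmax(self.values) - np.nanmin(self.values))


@dataclasses.dataclass
class StepScore:
    """All per-stride scores for one stride."""

    stride_id: int
    leg: str
    collapse: bool = False
    collapse_fraction: float = float("nan")
    collapse_frame: int = -1
    overshoot: bool = False
    overshoot_fraction: float = float("nan")
    overshoot_frame: int = -1
    collapse_context: str = ""
    knee_range: float = float("nan")
    tmp_range: float = float("nan")
    landing_angle: float = float("nan")
    stride_width: float = float("nan")
    swing_velocity: float = float("nan")
    lr_phase: float = float("nan")


# ---------------------------------------------------------------------------
# event detection and stride segmentation


def _estimate_noise_sd(y: np.ndarray) -> float:
    """Robust tracker-jitter estimate from first differences (MAD-based)."""
    d = np.diff(y[np.isfinite(y)])
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _drop_short_runs(mask: np.ndarray, min_frames: int = 3) -> np.ndarray:
    """Suppress jitter: flip runs shorter than ``min_frames``, True runs first."""
    out = mask.copy()
    for target in (True, False):
        padded = np.concatenate([[not target], out == target, [not target]])
        edges = np.diff(padded.astype(int))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s < min_frames:
                out[s:e] = not target
    return out


def detect_gait_events(
    seq: TrackedSequence,
    lift_threshold: float | None = None,
    legs: tuple[str, ...] = ("left", "right"),
) -> GaitEvents:
    """Detect toe-off and foot-contact times from side-view toe height.

    Toe-off is the first frame of a bout in which the toe rises above
    ``ground_y + lift_threshold`` after a stance bout; foot-contact the first
    frame at which it returns within the threshold of the ground. The default
    threshold is max(0.2 cm, 2 × a robust jitter estimate).
    """
    if seq.view != "side":
        raise ValidationError("event detection needs the side view")
    toe_off: dict[str, np.ndarray] = {}
    foot_contact: dict[str, np.ndarray] = {}
    for leg in legs:
        if not seq.has_marker(leg, "toe"):
            continue
        y = seq.marker_xy(leg, "toe")[:, 1]
        thr = lift_threshold
        if thr is None:
            thr = max(DEFAULT_LIFT_THRESHOLD_CM, 2.0 * _estimate_noise_sd(y))
        height = y - seq.ground_y
        finite = np.isfinite(height)
        if not finite.any() or np.nanmax(height) - np.nanmin(height) < thr:
            raise NoGaitError(f"no gait detected on leg {leg!r}: flat toe trajectory")
        airborne = height > thr
        airborne[~finite] = False
        airborne = _drop_short_runs(airborne, min_frames=3)
        edges = np.diff(airborne.astype(int))
        ups = np.flatnonzero(edges == 1) + 1  # stance -> swing
        downs = np.flatnonzero(edges == -1) + 1  # swing -> stance
        # require a stance bout before the first toe-off
        ups = ups[ups > 0]
        to_frames, fc_frames = [], []
        for up in ups:
            after = downs[downs > up]
            if len(after) == 0:
                break
            to_frames.append(up)
            fc_frames.append(after[0])
        if len(to_frames) < 2:
            raise InsufficientDataError(
                f"leg {leg!r}: fewer than 2 toe-offs detected"
            )
        toe_off[leg] = np.asarray(to_frames) / seq.fps
        foot_contact[leg] = np.asarray(fc_frames) / seq.fps
    if not toe_off:
        raise InsufficientDataError("no toe markers present in the side view")
    return GaitEvents(toe_off=toe_off, foot_contact=foot_contact)


def segment_strides(seq: TrackedSequence, events: GaitEvents) -> list[Stride]:
    """Cut the sequence into strides, one per consecutive toe-off pair per leg.

    Each stride carries the knee-height trace, the TMP-angle trace (when the
    ankle/tmp/toe markers are all present) and the toe x-trace over its
    cycle. Strides with no foot-contact inside the cycle are flagged
    ``incomplete``; strides containing NaN marker frames are flagged
    ``has_missing`` — neither is dropped.
    """
    times = seq.times
    strides: list[Stride] = []
    for leg in events.legs():
        to = events.toe_off[leg]
        fc = events.foot_contact[leg]
        knee = (
            seq.marker_xy(leg, "knee")[:, 1] if seq.has_marker(leg, "knee") else None
        )
        tmp_angle = None
        if all(seq.has_marker(leg, m) for m in ("ankle", "tmp", "toe")):
            tmp_angle = joint_angle_series(seq, "ankle", "tmp", "toe", leg=leg)
        toe_x = seq.marker_xy(leg, "toe")[:, 0] if seq.has_marker(leg, "toe") else None
        for i in range(len(to) - 1):
            t0, t1 = to[i], to[i + 1]
            inside = (times >= t0) & (times < t1)
            contacts = fc[(fc > t0) & (fc < t1)]
            t_contact = float(contacts[0]) if len(contacts) else None
            kh = knee[inside] if knee is not None else np.full(inside.sum(), np.nan)
            strides.append(
                Stride(
                    leg=leg,
                    t_toe_off=float(t0),
                    t_foot_contact=t_contact,
                    t_next_toe_off=float(t1),
                    times=times[inside],
                    knee_height=kh,
                    tmp_angle=tmp_angle[inside] if tmp_angle is not None else None,
                    toe_x=toe_x[inside] if toe_x is not None else None,
                    incomplete=t_contact is None,
                    has_missing=bool(np.isnan(kh).any()),
                )
            )
    return strides


# ---------------------------------------------------------------------------
# per-stride scores


def compute_lr_phase(
    left_toe_off: float, right_toe_off_1: float, right_toe_off_2: float
) -> float:
    """Left-right phase in degrees of the right stride cycle.

    ``((LeftToeOff_1 − RightToeOff_1) / (RightToeOff_2 − RightToeOff_1)) · 360``,
    with 360 mapped to 0. 180° is perfect alternation.
    """
    if right_toe_off_2 <= right_toe_off_1:
        raise ValidationError("right toe-offs must be increasing")
    if not (right_toe_off_1 <= left_toe_off < right_toe_off_2):
        raise ValidationError("left toe-off lies outside the right stride cycle")
    phase = (left_toe_off - right_toe_off_1) / (right_toe_off_2 - right_toe_off_1) * 360.0
    return float(phase % 360.0)


def normalize_swing(
    stride: Stride, metric: str = "knee_height", n_points: int = 101
) -> SwingProfile:
    """Resample a stride's swing-phase metric onto a uniform percent grid.

    Linear interpolation; the first and last swing samples map to 0 % and
    100 % so endpoint values are preserved. Requires >= 4 swing frames.
    """
    mask = stride.swing_mask
    if mask.sum() < 4:
        raise ResolutionError("swing interval shorter than 4 frames")
    if metric == "knee_height":
        values = stride.knee_height[mask]
    elif metric == "tmp_angle":
        if stride.tmp_angle is None:
            raise ValidationError("stride has no TMP angle trace")
        values = stride.tmp_angle[mask]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    t = stride.times[mask]
    pct = (t - t[0]) / (t[-1] - t[0]) * 100.0
    grid = np.linspace(0.0, 100.0, n_points)
    return SwingProfile(grid=grid, values=np.interp(grid, pct, values), kind=metric)


def joint_angle_series(
    seq: TrackedSequence,
    proximal: str,
    vertex: str,
    distal: str,
    leg: str = "right",
) -> np.ndarray:
    """Interior joint angle at ``vertex`` per frame, in degrees [0, 180].

    The angle between the vertex→proximal and vertex→distal segments, so a
    straight (collinear) limb reads 180°. Frames where the vertex coincides
    with a neighbour return NaN.
    """
    p = seq.marker_xy(leg, proximal)
    v = seq.marker_xy(leg, vertex)
    d = seq.marker_xy(leg, distal)
    a = p - v
    b = d - v
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", a, b) / (na * nb)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angle[(na == 0) | (nb == 0)] = np.nan
    return angle


def detect_collapses(
    strides: list[Stride],
    threshold_fraction: float = 0.85,
    window: str = "cycle",
) -> list[StepScore]:
    """Flag whole-body collapses: min knee height strictly below
    ``threshold_fraction`` × the step's stance-phase mean knee height.

    ``window`` selects the evaluation window — the full stride cycle
    (default) or the swing phase only. Returns one StepScore per stride with
    the collapse fields filled in.
    """
    scores = []
    for i, stride in enumerate(strides):
        baseline = stride.stance_baseline
        if not np.isfinite(baseline) or baseline <= 0:
            raise ValidationError(f"stride {i}: stance baseline not positive")
        if window == "cycle":
            values = stride.knee_height
            offset = 0
        elif window == "swing":
            mask = stride.swing_mask
            values = stride.knee_height[mask]
            offset = int(np.flatnonzero(mask)[0]) if mask.any() else 0
        else:
            raise ValueError(f"unknown collapse window {window!r}")
        score = StepScore(stride_id=i, leg=stride.leg)
        if np.isfinite(values).any():
            imin = int(np.nanargmin(values))
            frac = float(values[imin] / baseline)
            score.collapse_fraction = frac
            score.collapse = frac < threshold_fraction
            score.collapse_frame = imin + offset
        scores.append(score)
    return scores


def detect_overshoots(
    strides: list[Stride],
    scores: list[StepScore] | None = None,
    overshoot_threshold_fraction: float = 1.15,
) -> list[StepScore]:
    """Flag overshoots: swing-peak knee height strictly above the threshold
    fraction of the chick's reference peak (mean of stride swing maxima).

    Needs >= 3 strides to form the reference. Fills the overshoot fields of
    the provided scores (or fresh ones) and returns them.
    """
    if len(strides) < 3:
        raise InsufficientDataError("need >= 3 strides to form an overshoot reference")
    peaks = []
    peak_frames = []
    for stride in strides:
        mask = stride.swing_mask
        vals = stride.knee_height[mask] if mask.any() else stride.knee_height
        offset = int(np.flatnonzero(mask)[0]) if mask.any() else 0
        if np.isfinite(vals).any():
            imax = int(np.nanargmax(vals))
            peaks.append(float(vals[imax]))
            peak_frames.append(imax + offset)
        else:
            peaks.append(np.nan)
            peak_frames.append(-1)
    reference = float(np.nanmean(peaks))
    if scores is None:
        scores = [StepScore(stride_id=i, leg=s.leg) for i, s in enumerate(strides)]
    for score, peak, frame in zip(scores, peaks, peak_frames):
        if np.isfinite(peak) and reference > 0:
            frac = peak / reference
            score.overshoot_fraction = float(frac)
            score.overshoot = frac > overshoot_threshold_fraction
            score.overshoot_frame = frame
    return scores


def classify_collapse_context(
    scores: list[StepScore], window: int = 1
) -> dict[str, float]:
    """Label each collapse by its relation to overshoots within ``window``
    strides: followed_by_overshoot, preceded_by_overshoot or isolated.

    If overshoots occur on both sides, the nearer one wins; ties go to
    "followed". Returns the proportion of collapses in each category (labels
    are written onto the scores in place).
    """
    overshoot_idx = np.array([i for i, s in enumerate(scores) if s.overshoot])
    n_collapse = 0
    counts = {"isolated": 0, "followed_by_overshoot": 0, "preceded_by_overshoot": 0}
    for i, score in enumerate(scores):
        if not score.collapse:
            continue
        n_collapse += 1
        after = overshoot_idx[(overshoot_idx > i) & (overshoot_idx <= i + window)]
        before = overshoot_idx[(overshoot_idx < i) & (overshoot_idx >= i - window)]
        if len(after) and len(before):
            d_after = after[0] - i
            d_before = i - before[-1]
            label = "followed_by_overshoot" if d_after <= d_before else "preceded_by_overshoot"
        elif len(after):
            label = "followed_by_overshoot"
        elif len(before):
            label = "preceded_by_overshoot"
        else:
            label = "isolated"
        score.collapse_context = label
        counts[label] += 1
    if n_collapse == 0:
        return {k: float("nan") for k in counts}
    return {k: v / n_collapse for k, v in counts.items()}


def landing_angle(knee_xy: np.ndarray, tmp_xy: np.ndarray) -> float:
    """Angle (degrees) between the knee→TMP line and the horizontal ground.

    Positive when the knee is above the TMP joint; a signed (negative) angle
    is returned with a warning when it is not.
    """
    import warnings

    dx = abs(float(knee_xy[0]) - float(tmp_xy[0]))
    dy = float(knee_xy[1]) - float(tmp_xy[1])
    if dy < 0:
        warnings.warn("knee below TMP joint at end of swing; returning signed angle",
                      stacklevel=2)
    return float(np.degrees(np.arctan2(dy, dx)))


def stride_width(seq_top: TrackedSequence, events: GaitEvents) -> np.ndarray:
    """Mediolateral distance between the feet per double-stance bout (cm).

    Double stance is the overlap of the two legs' stance intervals
    (foot-contact → next toe-off). Each bout reports the maximum foot
    separation over its frames, matching a "maximum stride width" summary.
    Returns an empty array (with a warning) when the gait has no
    double-stance overlap.
    """
    import warnings

    if seq_top.view != "top":
        raise ValidationError("stride width needs the top view")
    for leg in ("left", "right"):
        if leg not in events.toe_off:
            raise InsufficientDataError("stride width needs events for both legs")
        if not seq_top.has_marker(leg, "toe"):
            raise InsufficientDataError(f"top view missing {leg} toe marker")

    def stance_intervals(leg: str) -> list[tuple[float, float]]:
        to, fc = events.toe_off[leg], events.foot_contact[leg]
        out = []
        for c in fc:
            nxt = to[to > c]
            if len(nxt):
                out.append((float(c), float(nxt[0])))
        return out

    left_iv = stance_intervals("left")
    right_iv = stance_intervals("right")
    times = seq_top.times
    yl = seq_top.marker_xy("left", "toe")[:, 1]
    yr = seq_top.marker_xy("right", "toe")[:, 1]
    widths = []
    for l0, l1 in left_iv:
        for r0, r1 in right_iv:
            lo, hi = max(l0, r0), min(l1, r1)
            if hi <= lo:
                continue
            mask = (times >= lo) & (times < hi)
            if mask.any():
                sep = np.abs(yl[mask] - yr[mask])
                if np.isfinite(sep).any():
                    widths.append(float(np.nanmax(sep)))
    if not widths:
        warnings.warn("no double-stance overlap found (running gait?)", stacklevel=2)
        return np.array([])
    return np.asarray(widths)


def swing_velocity(stride: Stride) -> float:
    """Horizontal toe displacement over the swing divided by swing duration (cm/s)."""
    if stride.t_foot_contact is None:
        raise ValidationError("stride has no foot-contact; swing undefined")
    duration = stride.t_foot_contact - stride.t_toe_off
    if duration <= 0:
        raise ValidationError("zero-duration swing")
    if stride.toe_x is None:
        raise ValidationError("stride has no toe x-trace")
    mask = stride.swing_mask
    x = stride.toe_x[mask]
    if len(x) < 2 or not np.isfinite(x[[0, -1]]).all():
        raise ValidationError("too few finite toe samples in swing")
    return float(abs(x[-1] - x[0]) / duration)


# ---------------------------------------------------------------------------
# assembly


def score_steps(
    seq_side: TrackedSequence,
    events: GaitEvents,
    seq_top: TrackedSequence | None = None,
    config=None,
):
    """Score every stride of a session and return a per-stride DataFrame.

    Runs segmentation, collapse and overshoot detection, context
    classification, swing velocity, landing angle, left-right phase (right-leg
    strides) and, when a top view is supplied, stride width (session maxima
    broadcast per stride are not reported; widths come back separately).

    Returns ``(scores_df, widths)``.
    """
    import pandas as pd

    from .config import RunConfig

    cfg = config or RunConfig()
    strides = segment_strides(seq_side, events)
    by_leg: dict[str, list[int]] = {}
    for i, s in enumerate(strides):
        by_leg.setdefault(s.leg, []).append(i)
    scores = detect_collapses(
        strides, cfg.collapse_threshold_fraction, cfg.collapse_window
    )
    # overshoot reference is per leg (a chick-level reference per trace)
    for leg, idx in by_leg.items():
        leg_strides = [strides[i] for i in idx]
        leg_scores = [scores[i] for i in idx]
        if len(leg_strides) >= 3:
            detect_overshoots(leg_strides, leg_scores, cfg.overshoot_threshold_fraction)
    classify_collapse_context(scores)
    for i, (stride, score) in enumerate(zip(strides, scores)):
        try:
            prof = normalize_swing(stride, "knee_height", cfg.swing_grid_points)
            score.knee_range = prof.range
        except (ResolutionError, ValidationError):
            pass
        if stride.tmp_angle is not None:
            try:
                prof = normalize_swing(stride, "tmp_angle", cfg.swing_grid_points)
                score.tmp_range = prof.range
            except (ResolutionError, ValidationError):
                pass
        try:
            score.swing_velocity = swing_velocity(stride)
        except ValidationError:
            pass
        # landing angle at the end-of-swing frame
        if (
            stride.t_foot_contact is not None
            and seq_side.has_marker(stride.leg, "knee")
            and seq_side.has_marker(stride.leg, "tmp")
        ):
            frame = min(
                int(round(stride.t_foot_contact * seq_side.fps)),
                seq_side.n_frames - 1,
            )
            knee = seq_side.marker_xy(stride.leg, "knee")[frame]
            tmp = seq_side.marker_xy(stride.leg, "tmp")[frame]
            if np.isfinite(knee).all() and np.isfinite(tmp).all():
                score.landing_angle = landing_angle(knee, tmp)
    # left-right phase for right-leg strides containing a left toe-off
    if "left" in events.toe_off and "right" in events.toe_off:
        left_to = events.toe_off["left"]
        for i in by_leg.get("right", []):
            s = strides[i]
            inside = left_to[(left_to >= s.t_toe_off) & (left_to < s.t_next_toe_off)]
            if len(inside):
                scores[i].lr_phase = compute_lr_phase(
                    float(inside[0]), s.t_toe_off, s.t_next_toe_off
                )
    widths = (
        stride_width(seq_top, events) if seq_top is not None else np.array([])
    )
    df = pd.DataFrame([dataclasses.asdict(s) for s in scores])
    return df, widths
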