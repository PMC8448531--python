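"""Synthetic gait recordings and hemicord point clouds with ground truth.

The gait generator produces kinematically shaped (not dynamically simulated)
marker trajectories: a flat stance-phase knee plateau with a raised-cosine
swing bump, a smooth TMP-angle excursion realised through actual
ankle/tmp/toe marker geometry, configurable left-right lag, Gaussian marker
noise, and injectable whole-body collapses (knee dips to a stated fraction of
stance height) and overshoots (inflated swing peaks). Every injection is
recorded in the returned labels so downstream detectors can be scored
against truth. The anatomy generator draws hemicord point clouds from
Gaussian mixtures with bimodal soma diameters and lognormal bouton volumes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import ResolutionError, ValidationError
from .io import PointTable, TrackedSequence
from .kinematics import GaitEvents

__all__ = [
    "GaitParams",
    "GroundTruthLabels",
    "MixtureComponent",
    "AnatomyParams",
    "generate_gait",
    "generate_cross_section_points",
    "generate_boutons",
]


@dataclasses.dataclass
class GaitParams:
    """Stride-level shape parameters for the gait generator.

    Defaults are tuned to a healthy P8 chick walking at 240 fps: 0.5 s
    strides with a 0.6 duty factor, ~3 cm stance knee height with a 2 cm
    swing amplitude (knee range ≈ 2 cm), a 50° TMP excursion, a 10 cm
    toe advance per stride (swing velocity ≈ 50 cm/s) and 0.05 cm of
    Gaussian tracker jitter. Injection probabilities default to zero (a
    control chick).
    """

    n_strides: int = 20
    stride_duration: float = 0.5
    duty_factor: float = 0.6
    fps: float = 240.0
    knee_stance_height: float = 3.0
    knee_swing_amplitude: float = 2.0
    tmp_angle_base: float = 90.0
    tmp_angle_excursion: float = 50.0
    lr_lag_fraction: float = 0.5
    noise_sd: float = 0.05
    collapse_prob: float = 0.0
    collapse_depth_fraction: float = 0.70
    collapse_placement: float = 0.85  # centre of the dip, as a cycle fraction
    collapse_width_fraction: float = 0.15
    overshoot_prob: float = 0.0
    overshoot_gain: float = 1.6
    toe_lift_height: float = 1.5
    step_length: float = 10.0
    stance_width: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_factor < 1.0):
            raise ValidationError("duty_factor must lie in (0, 1)")
        for name in ("collapse_prob", "overshoot_prob", "lr_lag_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_strides < 1:
            raise ValidationError("n_strides must be >= 1")
        if self.fps * self.stride_duration < 10:
            raise ResolutionError(
                "fewer than 10 frames per stride; raise fps or stride_duration"
            )


@dataclasses.dataclass
class GroundTruthLabels:
    """Per-stride injection record plus the true event times."""

    events: GaitEvents
    strides: pd.DataFrame  # leg, stride, collapse, collapse_frame, overshoot,
    #                        overshoot_frame, knee_range_true, tmp_range_true


def _bump(s: np.ndarray) -> np.ndarray:
    """Raised cosine on [0, 1]: 0 at the ends, 1 at the centre."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(s, 0.0, 1.0)))


def _toe_lift_profile(s: np.ndarray) -> np.ndarray:
    """Toe-height shape over the swing: brisk lift-off and touch-down.

    sin(pi s)^0.7 — the sub-linear exponent gives the sharp initial rise of
    a physiological toe-off so threshold detectors localise events to the
    frame.
    """
    return np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 0.7


def generate_gait(
    params: GaitParams,
    chick_id: str = "sim",
    session_id: str = "s0",
) -> tuple[dict[str, TrackedSequence], GaitEvents, GroundTruthLabels]:
    """Generate side- and top-view tracked sequences with known events.

    Returns ``({"side": seq, "top": seq}, events, labels)``. Left-leg events
    lag right-leg events by ``lr_lag_fraction`` of the stride duration.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    T = p.stride_duration
    swing_dur = (1.0 - p.duty_factor) * T
    lead = p.duty_factor * T  # stance bout before the first toe-off
    total = lead + (p.n_strides + 1) * T
    n_frames = int(round(total * p.fps))
    t = np.arange(n_frames) / p.fps

    lag = {"right": 0.0, "left": p.lr_lag_fraction * T}
    toe_off_times: dict[str, np.ndarray] = {}
    foot_contact_times: dict[str, np.ndarray] = {}
    side_cols: dict[tuple[str, str, str], np.ndarray] = {}
    top_cols: dict[tuple[str, str, str], np.ndarray] = {}
    label_rows = []

    for leg in ("right", "left"):
        offs = lead + lag[leg] + np.arange(p.n_strides + 1) * T
        keep = offs + swing_dur < total + 1e-9
        offs = offs[keep]
        toe_off_times[leg] = offs
        foot_contact_times[leg] = offs + swing_dur

        n_cycles = len(offs) - 1
        collapse = rng.random(n_cycles) < p.collapse_prob
        overshoot = rng.random(n_cycles) < p.overshoot_prob
        # the trailing toe-off starts a final (unlabelled) swing: render it
        # uninjected so the event list and the trajectory agree
        collapse = np.append(collapse, False)
        overshoot = np.append(overshoot, False)

        # cycle coordinates per frame
        rel = t - offs[0]
        k = np.floor(rel / T).astype(int)  # cycle index, negative before first toe-off
        u = (rel - k * T) / T  # fraction of cycle in [0, 1)
        in_cycle = (k >= 0) & (k <= n_cycles)
        swinging = in_cycle & (u < (1.0 - p.duty_factor))
        s = np.where(swinging, u / (1.0 - p.duty_factor), 0.0)

        amp = np.full(n_frames, p.knee_swing_amplitude)
        amp[in_cycle] = np.where(
            overshoot[np.clip(k[in_cycle], 0, n_cycles - 1)],
            p.knee_swing_amplitude * p.overshoot_gain,
            p.knee_swing_amplitude,
        )
        knee_y = p.knee_stance_height + np.where(swinging, amp * _bump(s), 0.0)

        # collapse dip: pull the knee toward depth * stance height inside a
        # raised-cosine window centred at collapse_placement of the cycle
        target = p.collapse_depth_fraction * p.knee_stance_height
        half_w = p.collapse_width_fraction / 2.0
        in_dip = in_cycle & collapse[np.clip(k, 0, n_cycles - 1)] & (
            np.abs(u - p.collapse_placement) < half_w
        )
        dip_s = (u - (p.collapse_placement - half_w)) / p.collapse_width_fraction
        knee_y = np.where(in_dip, knee_y - (knee_y - target) * _bump(dip_s), knee_y)

        toe_y = np.where(swinging, p.toe_lift_height * _toe_lift_profile(s), 0.0)
        cyc = np.where(swinging, s - np.sin(2 * np.pi * s) / (2 * np.pi), 0.0)
        strides_done = np.clip(k, 0, None) + np.where(
            in_cycle & ~swinging, 1.0, 0.0
        )
        strides_done[k >= n_cycles] = n_cycles
        toe_x = p.step_length * (strides_done + cyc) + (0.5 if leg == "left" else 0.0)

        # TMP geometry: tmp sits up-and-back of the toe; the ankle is placed
        # so that the interior angle at the tmp equals the target excursion
        theta = p.tmp_angle_base + np.where(swinging, p.tmp_angle_excursion * _bump(s), 0.0)
        alpha = np.deg2rad(115.0)
        l_tmp, l_tarso = 1.2, 2.0
        tmp_x = toe_x + l_tmp * np.cos(alpha)
        tmp_y = toe_y + l_tmp * np.sin(alpha)
        # unit vector tmp -> toe, rotated by +theta, gives tmp -> ankle
        ux, uy = (toe_x - tmp_x), (toe_y - tmp_y)
        norm = np.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        th = np.deg2rad(theta)
        ankle_x = tmp_x + l_tarso * (ux * np.cos(th) - uy * np.sin(th))
        ankle_y = tmp_y + l_tarso * (ux * np.sin(th) + uy * np.cos(th))
        knee_x = tmp_x + 0.4

        for marker, (mx, my) in {
            "toe": (toe_x, toe_y),
            "tmp": (tmp_x, tmp_y),
            "ankle": (ankle_x, ankle_y),
            "knee": (knee_x, knee_y),
        }.items():
            side_cols[(leg, marker, "x")] = mx.copy()
            side_cols[(leg, marker, "y")] = my.copy()
        ml = (p.stance_width / 2.0) * (1.0 if leg == "left" else -1.0)
        top_cols[(leg, "toe", "x")] = toe_x.copy()
        top_cols[(leg, "toe", "y")] = np.full(n_frames, ml)

        # ground truth per stride, taken from the clean traces
        for kk in range(n_cycles):
            t0, t1 = offs[kk], offs[kk + 1]
            inside = (t >= t0) & (t < t1)
            kr = float(np.max(knee_y[inside]) - np.min(knee_y[inside]))
            tr = float(np.max(theta[inside]) - np.min(theta[inside]))
            c_frame = o_frame = -1
            if collapse[kk]:
                c_frame = int(np.flatnonzero(inside)[np.argmin(knee_y[inside])])
            if overshoot[kk]:
                sw = inside & swinging
                if sw.any():
                    o_frame = int(np.flatnonzero(sw)[np.argmax(knee_y[sw])])
            label_rows.append(
                {
                    "leg": leg, "stride": kk,
                    "collapse": bool(collapse[kk]), "collapse_frame": c_frame,
                    "overshoot": bool(overshoot[kk]), "overshoot_frame": o_frame,
                    "knee_range_true": kr, "tmp_range_true": tr,
                    "toe_off_true": float(t0), "foot_contact_true": float(t0 + swing_dur),
                }
            )

    # body markers shared between legs
    body_x = 0.5 * (side_cols[("left", "toe", "x")] + side_cols[("right", "toe", "x")])
    for leg in ("left", "right"):
        side_cols[(leg, "eye", "x")] = body_x + 3.0
        side_cols[(leg, "eye", "y")] = np.full(n_frames, 9.0)
        side_cols[(leg, "tail", "x")] = body_x - 4.0
        side_cols[(leg, "tail", "y")] = np.full(n_frames, 6.0)

    if p.noise_sd > 0:
        for cols in (side_cols, top_cols):
            for key in cols:
                cols[key] = cols[key] + rng.normal(0.0, p.noise_sd, n_frames)

    def build(cols: dict, view: str) -> TrackedSequence:
        df = pd.DataFrame({k: v for k, v in sorted(cols.items())})
        df.columns = pd.MultiIndex.from_tuples(sorted(cols))
        return TrackedSequence(
            chick_id=chick_id, session_id=session_id, view=view,
            data=df, fps=p.fps, ground_y=0.0,
        )

    events = GaitEvents(
        toe_off={leg: v for leg, v in toe_off_times.items()},
        foot_contact={leg: v for leg, v in foot_contact_times.items()},
    )
    labels = GroundTruthLabels(events=events, strides=pd.DataFrame(label_rows))
    return {"side": build(side_cols, "side"), "top": build(top_cols, "top")}, events, labels


# ---------------------------------------------------------------------------
# anatomy


@dataclasses.dataclass
class MixtureComponent:
    mean: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]
    weight: float = 1.0


def _default_components() -> dict[str, list[MixtureComponent]]:
    # schematic dI2 populations in template coordinates (µm): small-diameter
    # cells in the dorsal aspect of lamina VII, large-diameter cells ventrally
    return {
        "small": [MixtureComponent((450.0, 780.0), ((130.0**2, 0.0), (0.0, 110.0**2)))],
        "large": [MixtureComponent((350.0, 480.0), ((100.0**2, 0.0), (0.0, 90.0**2)))],
    }


@dataclasses.dataclass
class AnatomyParams:
    """Gaussian-mixture point cloud plus soma-diameter / bouton-volume laws.

    Default counts mirror a labelled hemicord: 344 small- and 33
    large-diameter somata (large fraction ≈ 9 %), diameters bimodal at
    7 ± 1.5 and 20 ± 1.5 µm, bouton volumes lognormal (median 0.2 µm³,
    σ_log 0.9) and an 84 % synaptotagmin-positive probability.
    """

    components: dict[str, list[MixtureComponent]] = dataclasses.field(
        default_factory=_default_components
    )
    n_points: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"small": 344, "large": 33}
    )
    diam_small_mean: float = 7.0
    diam_small_sd: float = 1.5
    diam_large_mean: float = 20.0
    diam_large_sd: float = 1.5
    large_fraction: float = 0.09
    volume_log_mean: float = float(np.log(0.2))
    volume_log_sd: float = 0.9
    syn_prob: float = 0.84
    seed: int = 0

    def __post_init__(self) -> None:
        for label, comps in self.components.items():
            w = sum(c.weight for c in comps)
            if abs(w - 1.0) > 1e-9:
                raise ValidationError(f"weights for label {label!r} must sum to 1")
        if not (0.0 <= self.large_fraction <= 1.0):
            raise ValidationError("large_fraction must lie in [0, 1]")
        if not (0.0 <= self.syn_prob <= 1.0):
            raise ValidationError("syn_prob must lie in [0, 1]")


def generate_cross_section_points(
    params: AnatomyParams,
    template=None,
) -> PointTable:
    """Draw a hemicord soma point cloud from the configured mixtures.

    Each row carries its spatial label, its mixture-component index, a
    diameter drawn from the bimodal soma-size law and the true size class
    (``size_class_true``). Points falling outside the template bounding box
    are flagged ``clipped`` (and a warning is emitted for components whose
    mean lies outside it).
    """
    rng = np.random.default_rng(params.seed)
    if template is None:
        from .density import load_default_template

        template = load_default_template()
    minx, miny, maxx, maxy = template.bounds
    rows = []
    for label, comps in params.components.items():
        n = params.n_points.get(label, 0)
        weights = np.array([c.weight for c in comps])
        counts = rng.multinomial(n, weights)
        for ci, (comp, cn) in enumerate(zip(comps, counts)):
            mx, my = comp.mean
            if not (minx <= mx <= maxx and miny <= my <= maxy):
                warnings.warn(
                    f"component mean {comp.mean} outside template bounding box",
                    stacklevel=2,
                )
            pts = rng.multivariate_normal(comp.mean, np.asarray(comp.cov), size=cn)
            for x, y in pts:
                rows.append({"x": x, "y": y, "label": label, "component": ci})
    df = pd.DataFrame(rows, columns=["x", "y", "label", "component"])
    n_total = len(df)
    is_large = rng.random(n_total) < params.large_fraction
    diam = np.where(
        is_large,
        rng.normal(params.diam_large_mean, params.diam_large_sd, n_total),
        rng.normal(params.diam_small_mean, params.diam_small_sd, n_total),
    )
    df["diameter"] = np.clip(diam, 0.1, None)
    df["size_class_true"] = np.where(is_large, "large", "small")
    df["clipped"] = ~(
        (df["x"] >= minx) & (df["x"] <= maxx) & (df["y"] >= miny) & (df["y"] <= maxy)
    )
    return PointTable(data=df, section_id="synthetic", side="ipsi")


def generate_boutons(
    n: int,
    volume_params: tuple[float, float] | None = None,
    syn_prob: float = 0.84,
    seed: int = 0,
    center: tuple[float, float] = (400.0, 600.0),
    spread: float = 150.0,
) -> PointTable:
    """Draw ``n`` synaptic boutons with lognormal volumes and syn flags.

    ``volume_params`` is (mean, sd) of log-volume; flags are independent
    Bernoulli(``syn_prob``). The generated flag is also stored as
    ``syn_positive_true`` so QC recovery can be scored.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    mu, sigma = volume_params if volume_params is not None else (float(np.log(0.2)), 0.9)
    xy = rng.normal(center, spread, size=(n, 2)) if n else np.empty((0, 2))
    vol = rng.lognormal(mu, sigma, n)
    syn = rng.random(n) < syn_prob
    df = pd.DataFrame(
        {
            "x": xy[:, 0], "y": xy[:, 1], "volume": vol,
            "syn_positive": syn, "syn_positive_true": syn,
        }
    )
    return PointTable(data=df, section_id="synthetic", side="ipsi")
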