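import numpy as np
import pandas as pd
import pytest

from chickgait import kinematics as kin, simulate as sim
from chickgait.io import TrackedSequence


@pytest.fixture(scope="session")
def clean_gait():
    """A noise-free 12-stride session: (sequences, true events, labels)."""
    params = sim.GaitParams(n_strides=12, noise_sd=0.0, seed=7)
    return sim.generate_gait(params)


@pytest.fixture(scope="session")
def noisy_gait():
    """A jittered 15-stride session at the default 0.05 cm noise."""
    params = sim.GaitParams(n_strides=15, seed=11)
    return sim.generate_gait(params)


def make_sequence(columns: dict, fps: float = 240.0, view: str = "side") -> TrackedSequence:
    """Build a TrackedSequence from {(leg, marker): (n, 2) array} pairs."""
    cols = {}
    for (leg, marker), xy in columns.items():
        xy = np.asarray(xy, float)
        cols[(leg, marker, "x")] = xy[:, 0]
        cols[(leg, marker, "y")] = xy[:, 1]
    df = pd.DataFrame({k: v for k, v in sorted(cols.items())})
    df.columns = pd.MultiIndex.from_tuples(sorted(cols))
    return TrackedSequence(
        chick_id="t", session_id="s", view=view, data=df, fps=fps
    )


def make_stride(
    knee_height,
    fps: float = 240.0,
    swing_frac: float = 0.4,
    leg: str = "right",
    toe_x=None,
) -> kin.Stride:
    """Build a Stride whose first ``swing_frac`` of frames is the swing."""
    knee = np.asarray(knee_height, float)
    n = len(knee)
    times = np.arange(n) / fps
    idx = int(round(swing_frac * n))
    t_contact = times[idx] if idx < n else n / fps
    return kin.Stride(
        leg=leg,
        t_toe_off=0.0,
        t_foot_contact=float(t_contact),
        t_next_toe_off=float(n / fps),
        times=times,
        knee_height=knee,
        toe_x=np.asarray(toe_x, float) if toe_x is not None else None,
    )
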