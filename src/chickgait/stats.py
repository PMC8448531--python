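"""Group-level descriptive statistics and the hypothesis tests of the study.

Conventions: descriptive standard deviations default to the population
divisor n (the convention the printed per-group collapse rates follow);
combined group statistics are unweighted means of per-chick means, not
step-weighted pools. Angular data (left-right phase, TMP excursions) use
circular statistics — mean direction and circular SD from the resultant
vector, and the Watson–Williams high-concentration F test for comparing
angular means between groups.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "GroupSummary",
    "summarize",
    "group_summary",
    "two_proportion_z_test",
    "welch_t_test",
    "circular_mean_sd",
    "watson_williams_test",
    "dunnett_test",
    "trajectory_density_band",
]


def summarize(values, sd_convention: str = "population") -> tuple[float, float]:
    """Arithmetic mean ± SD with an explicit divisor convention.

    ``population`` divides by n, ``sample`` by n−1 (a single value returns
    SD 0 under either convention).
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValidationError("summarize needs at least one value")
    mean = float(np.mean(v))
    if sd_convention == "population":
        sd = float(np.std(v, ddof=0))
    elif sd_convention == "sample":
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    else:
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    return mean, sd


@dataclasses.dataclass
class GroupSummary:
    """Per-group roll-up: chick means, their unweighted combined mean ± SD."""

    group: str
    chick_means: dict[str, float]
    combined_mean: float
    dispersion: float
    n_chicks: int
    n_steps: int
    sd_convention: str = "population"


def group_summary(
    per_step: pd.DataFrame,
    value_col: str,
    group: str,
    chick_col: str = "chick_id",
    sd_convention: str = "population",
) -> GroupSummary:
    """Summarise a per-step table into the combined (mean-of-chick-means) form."""
    df = per_step.dropna(subset=[value_col])
    chick_means = df.groupby(chick_col)[value_col].mean().to_dict()
    means = np.array(list(chick_means.values()), float)
    combined, sd = summarize(means, sd_convention)
    return GroupSummary(
        group=group,
        chick_means={str(k): float(v) for k, v in chick_means.items()},
        combined_mean=combined,
        dispersion=sd,
        n_chicks=len(means),
        n_steps=len(df),
        sd_convention=sd_convention,
    )


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test (two-sided).

    Degenerate pooled proportions (0 or 1) return z = 0, p = 1 with a
    warning.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValidationError("need 0 <= x <= n and n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z test undefined", stacklevel=2)
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, df, two-sided p)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("welch_t_test needs n >= 2 per sample")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf), float(len(a) + len(b) - 2), 0.0
    sa, sb = va / len(a), vb / len(b)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def circular_mean_sd(angles_deg) -> tuple[float, float]:
    """Mean direction and circular SD (degrees) from the resultant vector.

    Circular SD is sqrt(−2 ln R̄) converted to degrees. A zero resultant
    (perfectly balanced angles) returns NaN mean with a warning.
    """
    a = np.deg2rad(np.asarray(angles_deg, float))
    if a.size == 0:
        raise ValidationError("circular_mean_sd needs at least one angle")
    if not np.isfinite(a).all():
        raise ValidationError("angles must be finite")
    C, S = np.mean(np.cos(a)), np.mean(np.sin(a))
    R = np.hypot(C, S)
    if R < 1e-12:
        warnings.warn("zero resultant length; mean direction undefined", stacklevel=2)
        return float("nan"), float("inf")
    mean = np.rad2deg(np.arctan2(S, C)) % 360.0
    if mean >= 360.0 - 1e-9:
        mean = 0.0
    sd = np.rad2deg(np.sqrt(-2.0 * np.log(R)))
    return float(mean), float(sd)


def _resultant_length(a_rad: np.ndarray) -> float:
    return float(np.hypot(np.mean(np.cos(a_rad)), np.mean(np.sin(a_rad))) * len(a_rad))


def _kappa_from_rbar(rbar: float) -> float:
    """ML von Mises concentration from the mean resultant length (Fisher)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams_test(*groups) -> tuple[float, float]:
    """Watson–Williams test for equality of mean directions across groups.

    High-concentration F approximation with the standard 1 + 3/(8κ̂)
    correction; p from F(k−1, N−k). Emits an applicability warning when the
    weighted mean resultant length falls below 0.7. Identical angles across
    all groups return F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    rads = [np.deg2rad(np.asarray(g, float)) for g in groups]
    for g in rads:
        if len(g) < 2:
            raise InsufficientDataError("each group needs n >= 2")
    N = sum(len(g) for g in rads)
    k = len(rads)
    Ri = [_resultant_length(g) for g in rads]
    R = _resultant_length(np.concatenate(rads))
    rbar_w = sum(Ri) / N
    if rbar_w < 0.7:
        warnings.warn(
            "mean resultant length < 0.7; Watson-Williams approximation unreliable",
            stacklevel=2,
        )
    denom = N - sum(Ri)
    if denom <= 1e-12:  # all angles identical within groups
        if abs(sum(Ri) - R) < 1e-12:
            return 0.0, 1.0
        return float(np.inf), 0.0
    kappa = _kappa_from_rbar(rbar_w)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    F = correction * ((N - k) * (sum(Ri) - R)) / ((k - 1) * denom)
    F = max(F, 0.0)
    p = float(sps.f.sf(F, k - 1, N - k))
    return float(F), p


def dunnett_test(control, *treatments) -> np.ndarray:
    """Two-sided many-to-one comparisons against a control group.

    Returns one adjusted p value per treatment group, using the
    multivariate-t distribution of the many-to-one maximum statistic.
    """
    if len(treatments) < 1:
        raise ValidationError("need at least one treatment group")
    control = np.asarray(control, float)
    samples = [np.asarray(tr, float) for tr in treatments]
    for i, g in enumerate([control, *samples]):
        if len(g) < 2 or np.var(g, ddof=1) < 0:
            raise ValidationError(f"group {i} degenerate (n < 2)")
    res = sps.dunnett(*samples, control=control, alternative="two-sided")
    return np.asarray(res.pvalue, float)


def trajectory_density_band(
    profiles,
    low: float = 0.20,
    high: float = 0.80,
    n_eval: int = 256,
) -> pd.DataFrame:
    """Pointwise density band across swing profiles on a common grid.

    At each percent-of-swing point a 1D Gaussian KDE is taken over the
    profile values; the band is the value interval where the density exceeds
    ``low`` (outer band) and ``high`` (inner band) fractions of that point's
    density range, mirroring the 2D contour convention. Pointwise 10–90 %
    quantile envelopes are returned alongside as a cross-check. Profiles with
    (numerically) identical values at a point yield a zero-width band there.
    """
    if len(profiles) < 5:
        raise ValidationError("need at least 5 profiles")
    grids = [np.asarray(p.grid, float) for p in profiles]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise ValidationError("profiles are on mismatched grids; resample first")
    grid = grids[0]
    values = np.vstack([np.asarray(p.values, float) for p in profiles])
    rows = []
    for j, pct in enumerate(grid):
        v = values[:, j]
        vmin, vmax = float(np.min(v)), float(np.max(v))
        if vmax - vmin < 1e-12 or np.std(v) < 1e-12:
            band = dict(band_lo=vmin, band_hi=vmax, inner_lo=vmin, inner_hi=vmax)
        else:
            kde = sps.gaussian_kde(v)
            xs = np.linspace(vmin, vmax, n_eval)
            d = kde(xs)
            dmin, dmax = float(d.min()), float(d.max())
            lv_lo = dmin + low * (dmax - dmin)
            lv_hi = dmin + high * (dmax - dmin)
            sel_lo = xs[d >= lv_lo]
            sel_hi = xs[d >= lv_hi]
            band = dict(
                band_lo=float(sel_lo.min()), band_hi=float(sel_lo.max()),
                inner_lo=float(sel_hi.min()) if len(sel_hi) else float("nan"),
                inner_hi=float(sel_hi.max()) if len(sel_hi) else float("nan"),
            )
        q10, q90 = np.quantile(v, [0.10, 0.90])
        rows.append({"pct": float(pct), **band, "q10": float(q10), "q90": float(q90)})
    return pd.DataFrame(rows)
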