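"""Standardized hemicord coordinates, 2D KDE density maps and laminar scoring.

Cross-section coordinate tables are brought into a common template frame by
a least-squares similarity transform over landmark pairs. Density fields are
Gaussian product-kernel KDEs with per-axis normal-reference bandwidths,
normalised to unit integral; contour sets follow the field convention of
levels equally spaced between two fractions (default 20 % and 80 %, six
lines) of the density value range. Laminar membership is scored by
point-in-polygon assignment against a schematic hemicord template that ships
as editable package data — a synthetic stand-in for the atlas-derived
polygons, not a measured atlas.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shp_wkt
from shapely.geometry import Point, Polygon
from skimage import measure
from skimage.transform import SimilarityTransform

from .errors import ValidationError
from .io import PointTable

__all__ = [
    "CrossSectionTemplate",
    "DensityField",
    "ContourSet",
    "load_default_template",
    "standardize_coordinates",
    "kde2d_density",
    "contour_set",
    "assign_laminae",
    "classify_soma_size",
    "density_overlap",
]


@dataclasses.dataclass
class CrossSectionTemplate:
    """Canonical hemicord outline, named lamina polygons and landmarks."""

    outline: Polygon
    laminae: dict[str, Polygon]
    lamina_order: list[str]
    landmarks: dict[str, np.ndarray]
    units: str = "um"

    def __post_init__(self) -> None:
        for name, poly in self.laminae.items():
            if not poly.is_valid:
                raise ValidationError(f"lamina {name!r} polygon is not simple/valid")
            if poly.difference(self.outline.buffer(1e-6)).area > 1e-3 * poly.area:
                raise ValidationError(f"lamina {name!r} extends outside the outline")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.outline.bounds

    def landmark_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or sorted(self.landmarks)
        return np.array([self.landmarks[n] for n in names], float)


def load_default_template() -> CrossSectionTemplate:
    """Load the packaged schematic hemicord template."""
    data = resources.files("chickgait") / "data"
    index = json.loads((data / "hemicord_template.json").read_text())
    outline = None
    laminae: dict[str, Polygon] = {}
    for line in (data / "hemicord_laminae.wkt").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        name, wkt_text = line.split("\t", 1)
        poly = shp_wkt.loads(wkt_text)
        if name == "outline":
            outline = poly
        else:
            laminae[name] = poly
    return CrossSectionTemplate(
        outline=outline,
        laminae=laminae,
        lamina_order=index["lamina_order"],
        landmarks={k: np.asarray(v, float) for k, v in index["landmarks"].items()},
        units=index.get("units", "um"),
    )


def standardize_coordinates(
    points: PointTable,
    observed_landmarks: np.ndarray,
    template_landmarks: np.ndarray,
) -> tuple[PointTable, np.ndarray]:
    """Map observed coordinates into the template frame.

    Fits the least-squares similarity transform (translation + rotation +
    isotropic scale) taking observed landmarks onto template landmarks,
    applies it to the points and returns (transformed table, per-landmark
    residual distances). Requires >= 3 non-collinear landmark pairs.
    """
    obs = np.asarray(observed_landmarks, float)
    tmp = np.asarray(template_landmarks, float)
    if obs.shape != tmp.shape or obs.shape[0] < 3 or obs.shape[1] != 2:
        raise ValidationError("need >= 3 landmark pairs of shape (n, 2)")
    spread = obs - obs.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9 * max(1.0, np.abs(spread).max())) < 2:
        raise ValidationError("landmarks are collinear; transform ill-posed")
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(obs, tmp)
        if not tf:
            raise ValidationError("similarity transform estimation failed")
    else:  # skimage < 0.26
        tf = SimilarityTransform()
        if not tf.estimate(obs, tmp):
            raise ValidationError("similarity transform estimation failed")
    residuals = np.linalg.norm(tf(obs) - tmp, axis=1)
    out = points.data.copy()
    out[["x", "y"]] = tf(points.xy)
    return (
        PointTable(data=out, section_id=points.section_id, side=points.side),
        residuals,
    )


@dataclasses.dataclass
class DensityField:
    """Gridded 2D density: x/y cell-centre axes and nonnegative values.

    ``values`` has shape (len(y), len(x)) and integrates to 1 over the grid.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    bandwidth: tuple[float, float]
    n_points: int

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.values, self.x, axis=1), self.y))

    def mode_xy(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.x[ix]), float(self.y[iy])

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "density": self.values.ravel()}
        )


def _normal_reference_bandwidth(v: np.ndarray) -> float:
    """Per-axis normal-reference (Scott) bandwidth for a 2D product kernel."""
    n = len(v)
    sd = np.std(v, ddof=1) if n > 1 else 0.0
    return float(sd * n ** (-1.0 / 6.0))


def kde2d_density(
    points: PointTable | np.ndarray,
    bandwidth: tuple[float, float] | None = None,
    grid_shape: tuple[int, int] = (128, 128),
    bounds: tuple[float, float, float, float] | None = None,
) -> DensityField:
    """Gaussian product-kernel KDE of a point cloud on a regular grid.

    The default bandwidth is the per-axis normal-reference rule; coincident
    points trigger a bandwidth floor with a warning. The grid spans the data
    (or the supplied ``bounds``) padded by four bandwidths, and the field is
    renormalised to unit integral.
    """
    xy = points.xy if isinstance(points, PointTable) else np.asarray(points, float)
    if len(xy) < 5:
        raise ValidationError("kde2d_density needs at least 5 points")
    if bandwidth is None:
        hx = _normal_reference_bandwidth(xy[:, 0])
        hy = _normal_reference_bandwidth(xy[:, 1])
    else:
        hx, hy = bandwidth
    floor = 1e-3 * max(1.0, float(np.abs(xy).max()))
    if hx <= 0 or hy <= 0:
        warnings.warn("degenerate spread; applying bandwidth floor", stacklevel=2)
        hx, hy = max(hx, floor), max(hy, floor)
    ny, nx = grid_shape
    if bounds is None:
        x0, x1 = xy[:, 0].min() - 4 * hx, xy[:, 0].max() + 4 * hx
        y0, y1 = xy[:, 1].min() - 4 * hy, xy[:, 1].max() + 4 * hy
    else:
        x0, y0, x1, y1 = bounds
    gx = np.linspace(x0, x1, nx)
    gy = np.linspace(y0, y1, ny)
    # product kernel: field = (1/n) * Ky @ Kx^T
    kx = np.exp(-0.5 * ((gx[:, None] - xy[None, :, 0]) / hx) ** 2) / (
        hx * np.sqrt(2 * np.pi)
    )
    ky = np.exp(-0.5 * ((gy[:, None] - xy[None, :, 1]) / hy) ** 2) / (
        hy * np.sqrt(2 * np.pi)
    )
    field = ky @ kx.T / len(xy)
    out = DensityField(x=gx, y=gy, values=field, bandwidth=(hx, hy), n_points=len(xy))
    integral = out.integral()
    if integral > 0:
        out.values = out.values / integral
    return out


@dataclasses.dataclass
class ContourSet:
    """Level values and their closed curves for a density field."""

    levels: np.ndarray
    curves: list[list[np.ndarray]]  # per level, list of (n, 2) x/y polylines
    low: float
    high: float

    def region_mask(self, field: DensityField, level_index: int) -> np.ndarray:
        return field.values >= self.levels[level_index]


def contour_set(
    field: DensityField, low: float = 0.20, high: float = 0.80, n: int = 6
) -> ContourSet:
    """Contour levels equally spaced on [min + low·range, min + high·range].

    ``low == high`` yields a single level. A constant field returns an empty
    ContourSet with a warning.
    """
    vmin, vmax = float(field.values.min()), float(field.values.max())
    if vmax - vmin < 1e-15:
        warnings.warn("constant density field; no contours", stacklevel=2)
        return ContourSet(levels=np.array([]), curves=[], low=low, high=high)
    if low == high:
        levels = np.array([vmin + low * (vmax - vmin)])
    else:
        levels = vmin + np.linspace(low, high, n) * (vmax - vmin)
    curves: list[list[np.ndarray]] = []
    for level in levels:
        polylines = []
        for contour in measure.find_contours(field.values, level):
            # (row, col) -> physical (x, y)
            xs = np.interp(contour[:, 1], np.arange(len(field.x)), field.x)
            ys = np.interp(contour[:, 0], np.arange(len(field.y)), field.y)
            polylines.append(np.column_stack([xs, ys]))
        curves.append(polylines)
    return ContourSet(levels=levels, curves=curves, low=low, high=high)


def assign_laminae(
    points: PointTable | np.ndarray, template: CrossSectionTemplate
) -> tuple[np.ndarray, pd.DataFrame]:
    """Point-in-polygon laminar assignment in template coordinates.

    Boundary points go to the first lamina in template order; points in no
    lamina are labelled "unassigned". Returns (per-point labels, per-lamina
    count/fraction table); counts always sum to the number of points.
    """
    xy = points.xy if isinstance(points, PointTable) else np.asarray(points, float)
    labels = np.full(len(xy), "unassigned", dtype=object)
    prepared = [(name, template.laminae[name]) for name in template.lamina_order]
    for i, (px, py) in enumerate(xy):
        pt = Point(px, py)
        for name, poly in prepared:
            if poly.covers(pt):  # covers: boundary counts as inside
                labels[i] = name
                break
    order = template.lamina_order + ["unassigned"]
    counts = pd.Series(labels).value_counts().reindex(order, fill_value=0)
    table = pd.DataFrame(
        {
            "lamina": order,
            "count": counts.to_numpy(int),
            "fraction": counts.to_numpy(float) / max(len(xy), 1),
        }
    )
    return np.asarray(labels), table


def classify_soma_size(
    diameters, threshold: float | None = None
) -> tuple[np.ndarray, float]:
    """Split soma diameters into {large, small} at a threshold.

    With ``threshold`` given, diameters >= threshold are "large". Otherwise a
    two-component 1D Gaussian mixture is fitted and the threshold set at the
    posterior crossover between the components; visibly unimodal diameters
    produce a single-class output with a warning.
    """
    d = np.asarray(diameters, float)
    if threshold is None:
        if len(d) < 2:
            raise ValidationError("automatic thresholding needs >= 2 diameters")
        if np.ptp(d) < 1e-12:
            warnings.warn("all diameters equal; single-class output", stacklevel=2)
            return np.full(len(d), "small", dtype=object), float(d[0])
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
            d.reshape(-1, 1)
        )
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        lo, hi = np.argsort(means)
        if (means[hi] - means[lo]) < 2.0 * max(sds):
            warnings.warn(
                "diameter distribution looks unimodal; single-class output",
                stacklevel=2,
            )
            return np.full(len(d), "small", dtype=object), float(np.mean(means))
        # posterior crossover between the component means
        xs = np.linspace(means[lo], means[hi], 2048)
        post = gm.predict_proba(xs.reshape(-1, 1))
        cross = xs[np.argmin(np.abs(post[:, lo] - post[:, hi]))]
        threshold = float(cross)
    labels = np.where(d >= threshold, "large", "small").astype(object)
    return labels, float(threshold)


def density_overlap(
    field_a: DensityField,
    field_b: DensityField,
    level_fraction: float = 0.20,
) -> dict[str, float]:
    """Overlap between two density fields on a common grid.

    Returns the Bhattacharyya coefficient of the (cell-mass normalised)
    fields and the intersection-over-union of their superlevel regions at
    ``level_fraction`` of each field's own value range.
    """
    if (
        len(field_a.x) != len(field_b.x)
        or len(field_a.y) != len(field_b.y)
        or not np.allclose(field_a.x, field_b.x)
        or not np.allclose(field_a.y, field_b.y)
    ):
        raise ValidationError("density fields are on mismatched grids")
    pa = field_a.values / field_a.values.sum()
    pb = field_b.values / field_b.values.sum()
    bhattacharyya = float(np.sum(np.sqrt(pa * pb)))

    def mask(f: DensityField) -> np.ndarray:
        vmin, vmax = f.values.min(), f.values.max()
        return f.values >= vmin + level_fraction * (vmax - vmin)

    ma, mb = mask(field_a), mask(field_b)
    union = np.logical_or(ma, mb).sum()
    iou = float(np.logical_and(ma, mb).sum() / union) if union else 0.0
    return {"bhattacharyya": bhattacharyya, "contour_region_iou": iou}
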