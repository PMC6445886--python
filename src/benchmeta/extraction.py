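"""Calibration-based digitization of plotted data.

Graphical results are digitized by marking axis reference points and
data points in pixel coordinates (a CSV of clicked or detected pixels);
a least-squares affine map from pixel space to (optionally log10) data
space then converts marked pixels to data values, including error-bar
end points. A synthetic-figure rendering harness with known ground truth
and an automatic marker-centroid detector validates the whole pipeline:
on an unbiased pipeline the regression of extracted on true values has
unit slope and R^2 near 1, the percent-error distribution is centered on
zero, and the absolute error is independent of marker size.

Pixel convention: origin at the top-left of the raster, y increasing
downward, coordinates referring to pixel centers. The calibration
absorbs the vertical flip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from scipy import stats
from scipy.spatial import cKDTree
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "AxisCalibration",
    "ExtractedPoint",
    "RenderedFigure",
    "ValidationReport",
    "calibrate",
    "extract_points",
    "render_synthetic_figure",
    "detect_markers",
    "validate_extraction",
]


@dataclass
class AxisCalibration:
    """Affine pixel-to-data map fitted to >= 3 reference points."""

    refs: List[Tuple[Tuple[float, float], Tuple[float, float]]]
    x_scale: str
    y_scale: str
    matrix: np.ndarray  # 3x2; [px, py, 1] @ matrix = (u, v) in (log-)data space
    residual_px: float

    def pixel_to_data(self, pixel: Sequence[float]) -> Tuple[float, float]:
        px, py = pixel
        u, v = np.array([px, py, 1.0]) @ self.matrix
        x = 10.0 ** u if self.x_scale == "log10" else u
        y = 10.0 ** v if self.y_scale == "log10" else v
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(f"pixel {pixel} maps outside the finite range")
        return float(x), float(y)

    def data_to_pixel(self, point: Sequence[float]) -> Tuple[float, float]:
        x, y = point
        u = math.log10(x) if self.x_scale == "log10" else x
        v = math.log10(y) if self.y_scale == "log10" else y
        A = self.matrix[:2, :]  # 2x2 linear part
        b = self.matrix[2, :]
        px, py = np.linalg.solve(A.T, np.array([u, v]) - b)
        return float(px), float(py)


@dataclass
class ExtractedPoint:
    """One digitized point with optional error-bar bounds on y."""

    pixel: Tuple[float, float]
    data: Tuple[float, float]
    err_low: Optional[float] = None
    err_high: Optional[float] = None


@dataclass
class RenderedFigure:
    """Synthetic scatter figure with ground truth for validation."""

    image: np.ndarray  # grayscale uint8, (H, W)
    truth: pd.DataFrame  # x, y, px, py, marker_size, marker_radius_px
    refs: List[Tuple[Tuple[float, float], Tuple[float, float]]]
    axes_spec: dict


@dataclass
class ValidationReport:
    """Extraction-pipeline validation statistics."""

    slope: float
    slope_ci: Tuple[float, float]
    intercept: float
    r2: float
    mean_pct_error: float
    pct_error_ci: Tuple[float, float]
    median_pct_error: float
    min_pct_error: float
    max_pct_error: float
    marker_size_slope: float
    marker_size_slope_ci: Tuple[float, float]
    n_matched: int
    n_unmatched: int


def calibrate(refs: Sequence[Tuple[Sequence[float], Sequence[float]]],
              x_scale: str = "linear", y_scale: str = "linear") -> AxisCalibration:
    """Fit the affine pixel-to-data transform from reference pairs.

    Parameters
    ----------
    refs
        At least 3 non-collinear ((px, py), (x, y)) pairs. Log-scale data
        values must be positive; they are log10-transformed before the
        affine fit.

    Using three (or more) references, rather than two per axis, lets the
    affine fit absorb slight axis skew; a fit residual above 2 px in
    pixel space triggers a warning.
    """
    for scale in (x_scale, y_scale):
        if scale not in ("linear", "log10"):
            raise ValueError(f"axis scale must be 'linear' or 'log10', got {scale!r}")
    if len(refs) < 3:
        raise ValueError("calibration requires at least 3 reference points")
    P = np.array([[r[0][0], r[0][1]] for r in refs], dtype=float)
    D = np.array([[r[1][0], r[1][1]] for r in refs], dtype=float)
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("reference points are collinear in pixel space")
    if x_scale == "log10":
        if np.any(D[:, 0] <= 0):
            raise ValueError("log10 x-axis requires positive reference data values")
        D[:, 0] = np.log10(D[:, 0])
    if y_scale == "log10":
        if np.any(D[:, 1] <= 0):
            raise ValueError("log10 y-axis requires positive reference data values")
        D[:, 1] = np.log10(D[:, 1])

    A = np.column_stack([P, np.ones(len(refs))])  # n x 3
    matrix, *_ = np.linalg.lstsq(A, D, rcond=None)
    cal = AxisCalibration(refs=[((float(p[0]), float(p[1])),
                                 (float(r[1][0]), float(r[1][1])))
                                for p, r in zip(P, refs)],
                          x_scale=x_scale, y_scale=y_scale, matrix=matrix,
                          residual_px=0.0)
    # residuals measured in pixel space through the inverse map
    res = 0.0
    for (ppx, ppy), (dx, dy) in cal.refs:
        bx, by = cal.data_to_pixel((dx, dy))
        res = max(res, math.hypot(bx - ppx, by - ppy))
    cal.residual_px = res
    if res > 2.0:
        logger.warning("calibration residual %.2f px exceeds 2 px; check the "
                       "reference points", res)
    return cal


def extract_points(calibration: AxisCalibration,
                   marked_pixels: Sequence[Sequence[float]],
                   error_bar_pixels: Optional[Sequence[Tuple[Sequence[float], Sequence[float]]]] = None
                   ) -> List[ExtractedPoint]:
    """Map marked pixels (and optional error-bar end pixels) to data values.

    ``error_bar_pixels`` aligns with ``marked_pixels``: each entry is a
    pair of pixels at the lower/upper bar ends; their y data values are
    reported as ordered (err_low, err_high) bounds, asymmetric on log
    axes after back-transformation.
    """
    if error_bar_pixels is not None and len(error_bar_pixels) != len(marked_pixels):
        raise ValueError("error_bar_pixels must align with marked_pixels")
    out = []
    for i, pix in enumerate(marked_pixels):
        data = calibration.pixel_to_data(pix)
        err_low = err_high = None
        if error_bar_pixels is not None:
            a = calibration.pixel_to_data(error_bar_pixels[i][0])[1]
            b = calibration.pixel_to_data(error_bar_pixels[i][1])[1]
            err_low, err_high = (a, b) if a <= b else (b, a)
        out.append(ExtractedPoint(pixel=(float(pix[0]), float(pix[1])),
                                  data=data, err_low=err_low, err_high=err_high))
    return out


DEFAULT_AXES_SPEC = {
    "xlim": (10.0, 100.0),
    "ylim": (10.0, 100.0),
    "x_scale": "linear",
    "y_scale": "linear",
    "figsize": (6.4, 4.8),
    "dpi": 150,
}


def render_synthetic_figure(n_points: int,
                            marker_size_range: Tuple[float, float] = (10.0, 100.0),
                            axes_spec: Optional[dict] = None,
                            seed: int = 0) -> RenderedFigure:
    """Render a scatter figure with known ground truth.

    Points are placed uniformly inside the axes, rejecting positions that
    would overlap an earlier marker (the detector needs one connected
    component per marker); marker areas are drawn uniformly from
    ``marker_size_range`` (matplotlib points^2). Deterministic given
    ``seed``. Returns the grayscale raster, the per-point ground truth
    (data and pixel coordinates, marker size) and three axes-corner
    reference pairs for calibration.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    spec = dict(DEFAULT_AXES_SPEC)
    if axes_spec:
        spec.update(axes_spec)
    xlo, xhi = spec["xlim"]
    ylo, yhi = spec["ylim"]
    if not (xhi > xlo and yhi > ylo):
        raise ValueError("degenerate axes ranges")
    dpi = spec["dpi"]
    rng = np.random.default_rng(seed)

    fig = Figure(figsize=spec["figsize"], dpi=dpi)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes([0.08, 0.08, 0.87, 0.87])
    if spec["x_scale"] == "log10":
        ax.set_xscale("log")
    if spec["y_scale"] == "log10":
        ax.set_yscale("log")
    ax.set_xlim(xlo, xhi)
    ax.set_ylim(ylo, yhi)
    ax.set_axis_off()
    canvas.draw()  # realize the transforms
    height = int(round(fig.bbox.height))

    def to_pixel(points: np.ndarray) -> np.ndarray:
        disp = ax.transData.transform(points)
        return np.column_stack([disp[:, 0] - 0.5, height - disp[:, 1] - 0.5])

    sizes = rng.uniform(*marker_size_range, size=n_points)
    radii_px = np.sqrt(sizes) / 2.0 * dpi / 72.0
    # keep markers off the axes edges
    mx = 0.03 * (xhi - xlo)
    my = 0.03 * (yhi - ylo)

    placed_px: List[np.ndarray] = []
    xs, ys = [], []
    max_attempts = 500 * n_points
    attempts = 0
    i = 0
    while i < n_points:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not place non-overlapping markers; "
                               "reduce n_points or marker sizes")
        x = rng.uniform(xlo + mx, xhi - mx)
        y = rng.uniform(ylo + my, yhi - my)
        p = to_pixel(np.array([[x, y]]))[0]
        ok = True
        for j, q in enumerate(placed_px):
            if np.hypot(*(p - q)) < radii_px[i] + radii_px[j] + 3.0:
                ok = False
                break
        if ok:
            placed_px.append(p)
            xs.append(x)
            ys.append(y)
            i += 1

    xs = np.array(xs)
    ys = np.array(ys)
    ax.scatter(xs, ys, s=sizes, c="black", marker="o", linewidths=0)
    canvas.draw()
    rgba = np.asarray(canvas.buffer_rgba())
    gray = np.asarray(np.round(rgba[:, :, :3].mean(axis=2)), dtype=np.uint8)

    pix = to_pixel(np.column_stack([xs, ys]))
    truth = pd.DataFrame({
        "x": xs, "y": ys,
        "px": pix[:, 0], "py": pix[:, 1],
        "marker_size": sizes, "marker_radius_px": radii_px,
    })
    corners = np.array([[xlo, ylo], [xhi, ylo], [xlo, yhi]])
    corner_px = to_pixel(corners)
    refs = [((float(cp[0]), float(cp[1])), (float(c[0]), float(c[1])))
            for cp, c in zip(corner_px, corners)]
    return RenderedFigure(image=gray, truth=truth, refs=refs, axes_spec=spec)


def detect_markers(image: np.ndarray, threshold: int = 200,
                   min_area: int = 4) -> pd.DataFrame:
    """Detect marker centroids as intensity-weighted connected components.

    Dark-on-light rasters are binarized at ``threshold``; each connected
    component of at least ``min_area`` pixels contributes one centroid,
    weighted by darkness so antialiased edges give sub-pixel precision.
    Returns a DataFrame with columns px, py, area.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[:, :, :3].mean(axis=2)
    binary = img < threshold
    labels = measure.label(binary)
    darkness = 255.0 - img.astype(float)
    rows = []
    for region in measure.regionprops(labels, intensity_image=darkness):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        rows.append({"px": cx, "py": cy, "area": int(region.area)})
    return pd.DataFrame(rows, columns=["px", "py", "area"])


def validate_extraction(rendered: RenderedFigure,
                        detections: Optional[pd.DataFrame] = None,
                        alpha: float = 0.05) -> ValidationReport:
    """Run the full digitization pipeline against the rendered ground truth.

    Detected centroids are matched to the nearest ground-truth point
    (greedy unique matching within the marker radius plus 3 px); the x
    and y values of matched points are pooled and regressed on the true
    values. Reports the regression slope with CI and R^2, the
    percent-error distribution with the CI of its mean, and the slope of
    absolute error against marker size.
    """
    truth = rendered.truth
    if len(truth) < 30:
        raise ValueError("validation needs at least 30 points for a stable regression")
    if detections is None:
        detections = detect_markers(rendered.image)
    cal = calibrate(rendered.refs,
                    x_scale=rendered.axes_spec["x_scale"],
                    y_scale=rendered.axes_spec["y_scale"])

    det_px = detections[["px", "py"]].to_numpy()
    truth_px = truth[["px", "py"]].to_numpy()
    tree = cKDTree(truth_px)
    dist, idx = tree.query(det_px)
    order = np.argsort(dist)
    matched_truth: dict = {}
    for d in order:
        t = idx[d]
        tol = truth["marker_radius_px"].iloc[t] + 3.0
        if t not in matched_truth and dist[d] <= tol:
            matched_truth[t] = d
    n_unmatched = len(truth) - len(matched_truth)
    if n_unmatched:
        logger.warning("%d of %d ground-truth points unmatched by the detector",
                       n_unmatched, len(truth))

    t_idx = np.array(sorted(matched_truth))
    d_idx = np.array([matched_truth[t] for t in t_idx])
    extracted = np.array([cal.pixel_to_data(p) for p in det_px[d_idx]])
    true_vals = truth[["x", "y"]].to_numpy()[t_idx]
    sizes = truth["marker_size"].to_numpy()[t_idx]

    ext_flat = extracted.ravel()
    true_flat = true_vals.ravel()
    reg = stats.linregress(true_flat, ext_flat)
    n = len(true_flat)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    slope_ci = (reg.slope - tcrit * reg.stderr, reg.slope + tcrit * reg.stderr)

    pct = (ext_flat - true_flat) / true_flat * 100.0
    mean_pct = float(np.mean(pct))
    sem = float(np.std(pct, ddof=1) / math.sqrt(n))
    tm = stats.t.ppf(1 - alpha / 2, n - 1)
    pct_ci = (mean_pct - tm * sem, mean_pct + tm * sem)

    abs_err = np.abs(extracted - true_vals).ravel()
    sizes2 = np.repeat(sizes, 2)
    mreg = stats.linregress(sizes2, abs_err)
    m_ci = (mreg.slope - tcrit * mreg.stderr, mreg.slope + tcrit * mreg.stderr)

    return ValidationReport(
        slope=float(reg.slope), slope_ci=slope_ci, intercept=float(reg.intercept),
        r2=float(reg.rvalue ** 2),
        mean_pct_error=mean_pct, pct_error_ci=pct_ci,
        median_pct_error=float(np.median(pct)),
        min_pct_error=float(np.min(pct)), max_pct_error=float(np.max(pct)),
        marker_size_slope=float(mreg.slope), marker_size_slope_ci=m_ci,
        n_matched=len(t_idx), n_unmatched=n_unmatched)
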