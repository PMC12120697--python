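"""Side-view droplet measurement pipeline.

The pipeline mirrors a goniometer-style workflow: a raw photograph is
reduced to three views (grayscale, Canny edge map, binary threshold) that
are merged into one analysis image; a Hough accumulator finds the droplet
circle; the substrate baseline is located as the strongest horizontal edge
run below the circle centre; and the geometry module turns circle +
baseline into base diameter, contact angle and spherical-cap volume.

Coordinate conventions: detection happens in the image's y-down pixel
frame; before any geometry, coordinates are converted to the y-up physical
frame via ``y_physical = (image_height - 1 - y_pixel)`` and scaled by the
pixel calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_gradient_magnitude, map_coordinates, sobel
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .geometry import (
    Baseline,
    Calibration,
    Circle,
    DropletMeasurement,
    cap_height,
    cap_volume,
    circle_baseline_geometry,
)
from .synthetic import RawImage

__all__ = [
    "PipelineError",
    "NoCircleFoundError",
    "BaselineNotFoundError",
    "PreprocessingConfig",
    "DetectorConfig",
    "ProcessedViews",
    "DetectedCircle",
    "MeasurementResult",
    "preprocess",
    "detect_circle",
    "detect_baseline",
    "measure_droplet",
    "measure_batch",
]


class PipelineError(RuntimeError):
    """Pipeline failure carrying the name of the failing stage."""

    def __init__(self, message: str, stage: str = "") -> None:
        super().__init__(message)
        self.stage = stage


class NoCircleFoundError(PipelineError):
    def __init__(self, message: str) -> None:
        super().__init__(message, stage="detect_circle")


class BaselineNotFoundError(PipelineError):
    def __init__(self, message: str) -> None:
        super().__init__(message, stage="detect_baseline")


@dataclass(frozen=True)
class PreprocessingConfig:
    """Three-stage preprocessing parameters.

    Canny hysteresis thresholds are on the 0-255 intensity scale; the
    binary threshold is Otsu's method unless ``binary_threshold`` is set.
    """

    gaussian_sigma: float = 1.4
    canny_low: float = 50.0
    canny_high: float = 150.0
    binary_threshold: float | None = None  # 0-255 scale; None -> Otsu


@dataclass(frozen=True)
class DetectorConfig:
    """Hough circle detector parameters.

    Search radii span ``[min_radius_frac, max_radius_frac] * min(H, W)``.
    The coarse accumulator runs on a downscaled edge map with at most
    ``max_coarse_radii`` radius bins; candidates are then refined on a
    half-pixel grid scored by smoothed edge support along the perimeter.
    """

    min_radius_frac: float = 0.05
    max_radius_frac: float = 0.60
    max_coarse_radii: int = 40
    coarse_downscale: int = 2
    n_candidates: int = 6
    min_accumulator_score: float = 0.12
    edge_sigma: float = 1.4
    # a bulging droplet (theta > 90 deg) occludes most of the substrate
    # line, so only short runs survive at the frame edges
    baseline_min_run_frac: float = 0.05


@dataclass(frozen=True)
class ProcessedViews:
    """The three extraction views plus their merged composite (all uint8,
    same height/width as the input; edge and binary views are two-valued)."""

    gray: np.ndarray
    edges: np.ndarray
    binary: np.ndarray
    merged: np.ndarray


@dataclass(frozen=True)
class DetectedCircle:
    """A fitted circle in the y-down pixel frame with its detector score."""

    circle: Circle
    score: float


@dataclass(frozen=True)
class MeasurementResult:
    """A droplet measurement plus the pixel-frame intermediates for audit."""

    measurement: DropletMeasurement
    detected_circle: DetectedCircle
    baseline_row_px: float
    calibration: Calibration


# ---------------------------------------------------------------------------
# stage 1: preprocessing
# ---------------------------------------------------------------------------

def _as_pixel_array(image) -> np.ndarray:
    if isinstance(image, RawImage):
        image = image.pixels
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-channel image, got shape {arr.shape}")
    return arr


def preprocess(image, params: PreprocessingConfig | None = None) -> ProcessedViews:
    """Reduce a raw image to grayscale, edge, binary and merged views.

    The binary view renders the droplet foreground black (0) on white
    (255).  The merged composite is the pixel-wise maximum of the inverted
    binary view and the edge map overlaid on the grayscale view, which
    reinforces the droplet boundary for the circle accumulator while
    keeping interior contrast.
    """
    arr = _as_pixel_array(image)
    cfg = params or PreprocessingConfig()

    if arr.ndim == 3:
        gray_f = rgb2gray(arr[..., :3])
    else:
        gray_f = arr.astype(float)
        if gray_f.max() > 1.0:
            gray_f = gray_f / 255.0
    gray_f = np.clip(gray_f, 0.0, 1.0)

    edge_mask = canny(
        gray_f,
        sigma=cfg.gaussian_sigma,
        low_threshold=cfg.canny_low / 255.0,
        high_threshold=cfg.canny_high / 255.0,
    )

    if cfg.binary_threshold is not None:
        thr = cfg.binary_threshold / 255.0
    else:
        thr = threshold_otsu(gray_f) if gray_f.min() < gray_f.max() else 0.5
    binary = np.where(gray_f < thr, 0, 255).astype(np.uint8)  # droplet dark

    gray_u8 = np.round(gray_f * 255.0).astype(np.uint8)
    edges_u8 = np.where(edge_mask, 255, 0).astype(np.uint8)
    merged = np.maximum(gray_u8, np.maximum(255 - binary, edges_u8))

    return ProcessedViews(gray=gray_u8, edges=edges_u8, binary=binary, merged=merged)


# ---------------------------------------------------------------------------
# stage 2: circle detection
# ---------------------------------------------------------------------------

def _downscale_max(mask: np.ndarray, f: int) -> np.ndarray:
    h, w = mask.shape
    hp, wp = h - h % f, w - w % f
    return mask[:hp, :wp].reshape(hp // f, f, wp // f, f).max(axis=(1, 3))


def _perimeter_score(
    support: np.ndarray, cx: np.ndarray, cy: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Mean smoothed-edge support along each candidate circle's perimeter."""
    n_angles = 360
    ang = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    xs = cx[:, None] + r[:, None] * np.cos(ang)[None, :]
    ys = cy[:, None] + r[:, None] * np.sin(ang)[None, :]
    h, w = support.shape
    inb = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    vals = map_coordinates(
        support, [ys.ravel(), xs.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(xs.shape)
    vals[~inb] = 0.0
    return vals.mean(axis=1)


def _refine_grid(support, cx0, cy0, r0, span, step):
    offs = np.arange(-span, span + step / 2, step)
    gx, gy, gr = np.meshgrid(offs, offs, offs, indexing="ij")
    cx = cx0 + gx.ravel()
    cy = cy0 + gy.ravel()
    r = np.maximum(r0 + gr.ravel(), 2.0)
    scores = _perimeter_score(support, cx, cy, r)
    k = int(np.argmax(scores))
    return cx[k], cy[k], r[k], scores[k]


def detect_circle(
    views: ProcessedViews, params: DetectorConfig | None = None
) -> DetectedCircle:
    """Find the droplet circle in the merged analysis view.

    A Hough accumulator over a coarse radius grid (on a downscaled edge
    map) proposes candidates; each is refined on an integer then a
    half-pixel local grid, maximising mean edge support along the visible
    perimeter.  Ties (scores equal to 2 decimals) are broken toward the
    larger radius, then the topmost centre.  Deterministic for identical
    inputs and configuration.

    Raises
    ------
    NoCircleFoundError
        If no accumulator peak clears ``min_accumulator_score``.
    """
    cfg = params or DetectorConfig()
    edge = canny(views.merged.astype(float) / 255.0, sigma=cfg.edge_sigma)
    h, w = edge.shape
    if not edge.any():
        raise NoCircleFoundError("no edges in merged view")

    rmin = max(5, int(round(cfg.min_radius_frac * min(h, w))))
    rmax = int(round(cfg.max_radius_frac * min(h, w)))
    if rmax <= rmin:
        raise NoCircleFoundError(f"degenerate radius range [{rmin}, {rmax}]")

    f = max(1, cfg.coarse_downscale)
    edge_small = _downscale_max(edge, f) if f > 1 else edge
    lo, hi = max(3, rmin // f), max(4, rmax // f)
    step = max(1, (hi - lo) // cfg.max_coarse_radii)
    radii = np.arange(lo, hi + 1, step)
    # padded accumulator: a shallow cap's centre can lie outside the frame
    acc = hough_circle(edge_small, radii, full_output=True)
    pad = int(radii.max())
    accums, cxs, cys, rads = hough_circle_peaks(
        acc, radii, total_num_peaks=cfg.n_candidates
    )
    cxs = cxs - pad
    cys = cys - pad
    if len(accums) == 0 or accums[0] < cfg.min_accumulator_score:
        best = accums[0] if len(accums) else 0.0
        raise NoCircleFoundError(
            f"no circle above accumulator threshold "
            f"({best:.3f} < {cfg.min_accumulator_score})"
        )

    # refinement support: smoothed gradient magnitude of the gray view —
    # continuous and symmetric about the true boundary, so the half-pixel
    # grid search is not biased by the Canny mask's integer rasterisation
    support = gaussian_gradient_magnitude(
        views.gray.astype(float) / 255.0, sigma=1.0
    )
    if support.max() > 0:
        support = support / support.max()

    candidates = []
    for a, x, y, r in zip(accums, cxs, cys, rads):
        if a < cfg.min_accumulator_score:
            continue
        cx0, cy0, r0 = float(x * f), float(y * f), float(r * f)
        cx1, cy1, r1, _ = _refine_grid(support, cx0, cy0, r0, span=f + 2, step=1.0)
        cx2, cy2, r2, s2 = _refine_grid(support, cx1, cy1, r1, span=1.0, step=0.5)
        candidates.append((round(float(s2), 2), float(r2), -float(cy2),
                           float(cx2), float(cy2), float(s2)))

    # highest score, then largest radius, then topmost centre
    candidates.sort(reverse=True)
    score_r, r_best, neg_cy, cx_best, cy_best, raw_score = candidates[0]
    return DetectedCircle(
        circle=Circle(cx=cx_best, cy=cy_best, radius=r_best),
        score=raw_score,
    )


# ---------------------------------------------------------------------------
# stage 3: baseline detection
# ---------------------------------------------------------------------------

def _max_run_length(row: np.ndarray) -> int:
    if not row.any():
        return 0
    padded = np.concatenate(([0], row.view(np.uint8), [0]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return int((ends - starts).max())


def detect_baseline(
    views: ProcessedViews,
    override: float | None = None,
    circle: DetectedCircle | None = None,
    params: DetectorConfig | None = None,
) -> Baseline:
    """Locate the substrate line as a pixel row (y-down frame).

    If ``override`` is given it is returned as-is.  Otherwise the row with
    the longest horizontal edge run below the detected circle's apex
    (topmost point) is selected and refined to half-pixel resolution with
    a parabolic fit to the column-averaged vertical gradient magnitude.
    (The apex, not the centre, bounds the search: for contact angles below
    90 deg the circle centre sits below the substrate line.)

    Raises
    ------
    BaselineNotFoundError
        If no row has an edge run of at least
        ``baseline_min_run_frac * width`` pixels.
    """
    if override is not None:
        return Baseline(a=float(override))
    cfg = params or DetectorConfig()
    edges = views.edges > 0
    h, w = edges.shape
    start_row = 0
    if circle is not None:
        apex = circle.circle.cy - circle.circle.radius
        start_row = max(0, int(math.ceil(apex)))

    runs = np.array([_max_run_length(edges[i]) for i in range(start_row, h)])
    if runs.size == 0 or runs.max() < cfg.baseline_min_run_frac * w:
        raise BaselineNotFoundError(
            "no horizontal edge run long enough for a substrate line; "
            "supply an override row"
        )
    row = start_row + int(np.argmax(runs))

    # half-pixel refinement on the vertical gradient profile
    grad = np.abs(sobel(views.gray.astype(float), axis=0)).mean(axis=1)
    lo, hi = max(row - 2, 1), min(row + 2, h - 2)
    local = int(lo + np.argmax(grad[lo : hi + 1]))
    y0, y1, y2 = grad[local - 1], grad[local], grad[local + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    refined = round((local + delta) * 2.0) / 2.0
    return Baseline(a=refined)


# ---------------------------------------------------------------------------
# stage 4: full per-image measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    baseline_override: float | None = None


def measure_droplet(
    image,
    calibration: Calibration,
    config: PipelineConfig | None = None,
) -> MeasurementResult:
    """Measure one droplet image end to end.

    Composes preprocess -> detect_circle -> detect_baseline, converts the
    pixel-frame circle and baseline to the y-up physical frame in mm, then
    applies the circle-baseline geometry and the spherical-cap volume
    formula.  Errors from any stage propagate with the stage named.
    """
    cfg = config or PipelineConfig()
    arr = _as_pixel_array(image)
    h = arr.shape[0]
    s = calibration.mm_per_px

    views = preprocess(arr, cfg.preprocessing)
    detected = detect_circle(views, cfg.detector)
    baseline_px = detect_baseline(
        views, override=cfg.baseline_override, circle=detected, params=cfg.detector
    )

    # y-down pixel frame -> y-up physical frame (mm)
    circle_mm = Circle(
        cx=detected.circle.cx * s,
        cy=(h - 1 - detected.circle.cy) * s,
        radius=detected.circle.radius * s,
    )
    baseline_mm = Baseline(a=(h - 1 - baseline_px.a) * s)
    try:
        pt_a, pt_b, chord, theta = circle_baseline_geometry(circle_mm, baseline_mm)
    except ValueError as exc:
        exc.stage = "circle_baseline_geometry"  # type: ignore[attr-defined]
        raise

    measurement = DropletMeasurement(
        diameter_mm=chord,
        theta_deg=theta,
        height_mm=cap_height(chord, theta),
        volume_uL=cap_volume(chord, theta),
        contact_points=(pt_a, pt_b),
    )
    return MeasurementResult(
        measurement=measurement,
        detected_circle=detected,
        baseline_row_px=baseline_px.a,
        calibration=calibration,
    )


def measure_batch(
    image_paths,
    calibration: Calibration,
    config: PipelineConfig | None = None,
    save_merged: bool = False,
):
    """Measure a list of image files; one row per input, failures recorded
    per row.  Returns a pandas DataFrame with columns
    ``image, diameter_mm, contact_angle_deg, volume_uL, status`` in input
    order.  With ``save_merged`` the merged analysis view of each readable
    image is written alongside it with a ``_merged.png`` suffix for audit.
    """
    from pathlib import Path

    import pandas as pd

    from .io import read_image, write_image

    cfg = config or PipelineConfig()
    paths = list(image_paths)
    if not paths:
        raise ValueError("empty image list")
    rows = []
    for path in paths:
        try:
            img = read_image(path)
            if save_merged:
                views = preprocess(img, cfg.preprocessing)
                p = Path(path)
                write_image(views.merged, p.with_name(p.stem + "_merged.png"))
            res = measure_droplet(img, calibration, config)
            m = res.measurement
            rows.append(
                {
                    "image": str(path),
                    "diameter_mm": m.diameter_mm,
                    "contact_angle_deg": m.theta_deg,
                    "volume_uL": m.volume_uL,
                    "status": "OK",
                }
            )
        except Exception as exc:  # per-row failure must not abort the batch
            stage = getattr(exc, "stage", "") or type(exc).__name__
            rows.append(
                {
                    "image": str(path),
                    "diameter_mm": float("nan"),
                    "contact_angle_deg": float("nan"),
                    "volume_uL": float("nan"),
                    "status": f"error:{stage}",
                }
            )
    return pd.DataFrame(
        rows, columns=["image", "diameter_mm", "contact_angle_deg", "volume_uL", "status"]
    )
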