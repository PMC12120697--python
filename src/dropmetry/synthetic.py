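"""Ground-truth generators for testing the metrology and regression stack.

Two independent generators live here:

* :func:`render_droplet` rasterises a side-view photograph of a sessile
  droplet whose geometry (base diameter, contact angle) is known exactly,
  so the imaging pipeline can be validated against analytic ground truth
  instead of hand-annotated photographs.

* :func:`generate_records` draws bioprinting parameter combinations from
  the experimental design grid (two bioink viscosities, three nozzle inner
  diameters, three dispensing times, two pressures, two cell
  concentrations) and assigns each a droplet volume from a smooth
  power-law response surface plus multiplicative noise, emulating the kind
  of parameter-to-volume dataset a droplet bioprinter produces.

The response surface is a surrogate: the real dispensing physics is not
published, so volumes follow

    V = V0 * (P/P0)^aP * (t/t0)^at * (d/d0)^ad * (mu/mu0)^-amu
           * (1 + ac * (c - c0)/c0)

anchored so that the reference parameter combination yields the observed
medium-droplet mean of 6.54 uL.  The default ("empirical") exponents
order the per-parameter response spans as
time > nozzle > pressure > viscosity > cell concentration; the
"poiseuille" preset raises the nozzle exponent to 4 (Hagen-Poiseuille
d^4 flow scaling) for physically motivated stress tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    Baseline,
    Circle,
    DropletMeasurement,
    cap_height,
    cap_volume,
    circle_baseline_geometry,
    circle_from_cap,
)

__all__ = [
    "RenderError",
    "RenderSpec",
    "RawImage",
    "GeneratorConfig",
    "PrintRecord",
    "PRESETS",
    "VISCOSITY_LEVELS",
    "NOZZLE_LEVELS",
    "TIME_LEVELS",
    "PRESSURE_LEVELS",
    "CELL_LEVELS",
    "render_droplet",
    "volume_model",
    "generate_records",
]


class RenderError(ValueError):
    """Raised when a droplet cannot be rendered inside the frame."""


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

#: default intensities (0-1 scale): light background, dark droplet/substrate
_BACKGROUND = 0.85
_FOREGROUND = 0.12
#: supersampling factor for antialiased silhouette rasterisation
_SUPERSAMPLE = 4


@dataclass(frozen=True)
class RawImage:
    """A grayscale or RGB image plus its declared intensity range."""

    pixels: np.ndarray
    intensity_range: tuple[float, float] = (0, 255)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RenderSpec:
    """Specification of one synthetic droplet photograph.

    ``noise`` is the standard deviation of additive Gaussian pixel noise on
    the 0-1 intensity scale (default 5/255, a mild sensor-noise level);
    ``blur_sigma_px`` models optical blur.  ``seed`` fixes all randomness.
    """

    diameter_mm: float
    theta_deg: float
    mm_per_px: float = 0.009728
    image_size_px: tuple[int, int] = (400, 480)
    baseline_row_px: int = 340
    noise: float = 5.0 / 255.0
    blur_sigma_px: float = 1.0
    seed: int = 0


def render_droplet(
    spec: RenderSpec,
) -> tuple[RawImage, DropletMeasurement, Circle, float]:
    """Rasterise a sessile droplet silhouette with exact ground truth.

    The droplet (dark) sits on a dark substrate band whose top surface is
    at ``baseline_row_px``; the background is light.  Returns the image,
    the analytic :class:`DropletMeasurement`, the true circle in the
    y-down pixel frame and the true baseline row.

    Raises
    ------
    RenderError
        If the droplet does not fit inside the frame.
    """
    h_px, w_px = spec.image_size_px
    s = spec.mm_per_px
    if s <= 0:
        raise RenderError(f"mm_per_px must be > 0, got {s}")

    # physical frame: y-up, origin at the bottom-left pixel centre
    a_mm = (h_px - 1 - spec.baseline_row_px) * s
    cx_mm = ((w_px - 1) / 2.0) * s
    circle_mm, baseline_mm = circle_from_cap(
        spec.diameter_mm, spec.theta_deg, baseline_a=a_mm, cx=cx_mm
    )
    pt_a, pt_b, chord, theta = circle_baseline_geometry(circle_mm, baseline_mm)
    height = cap_height(chord, theta)
    truth = DropletMeasurement(
        diameter_mm=chord,
        theta_deg=theta,
        height_mm=height,
        volume_uL=cap_volume(chord, theta),
        contact_points=(pt_a, pt_b),
    )

    # frame-fit check: apex and widest extent must stay inside with margin
    margin_px = 4
    apex_row = spec.baseline_row_px - height / s
    half_width_mm = (
        circle_mm.radius if circle_mm.cy > a_mm else chord / 2.0
    )
    left_px = (cx_mm - half_width_mm) / s
    right_px = (cx_mm + half_width_mm) / s
    if (
        apex_row < margin_px
        or left_px < margin_px
        or right_px > w_px - 1 - margin_px
        or spec.baseline_row_px >= h_px - 1
        or spec.baseline_row_px < margin_px
    ):
        raise RenderError(
            f"droplet (D={spec.diameter_mm} mm, theta={spec.theta_deg} deg) "
            f"does not fit a {h_px}x{w_px} frame at {s} mm/px"
        )

    img = _rasterise(circle_mm, a_mm, h_px, w_px, s)
    if spec.blur_sigma_px > 0:
        img = gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise, img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 255.0).astype(np.uint8)

    true_circle_px = Circle(
        cx=circle_mm.cx / s,
        cy=(h_px - 1) - circle_mm.cy / s,
        radius=circle_mm.radius / s,
    )
    return (
        RawImage(pixels=pixels),
        truth,
        true_circle_px,
        float(spec.baseline_row_px),
    )


def _rasterise(
    circle_mm: Circle, a_mm: float, h_px: int, w_px: int, s: float
) -> np.ndarray:
    """Supersampled silhouette: droplet cap above the baseline + substrate."""
    ss = _SUPERSAMPLE
    # subpixel centres in pixel coordinates
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    rows = (np.arange(h_px)[:, None] + sub[None, :]).ravel()  # (h*ss,)
    cols = (np.arange(w_px)[:, None] + sub[None, :]).ravel()  # (w*ss,)
    y_mm = ((h_px - 1) - rows) * s
    x_mm = cols * s

    dx2 = (x_mm[None, :] - circle_mm.cx) ** 2
    dy2 = (y_mm[:, None] - circle_mm.cy) ** 2
    inside = dx2 + dy2 <= circle_mm.radius**2
    above = (y_mm[:, None] >= a_mm) & np.ones_like(dx2, dtype=bool)
    droplet = inside & above
    substrate = (y_mm[:, None] < a_mm) & np.ones_like(dx2, dtype=bool)
    dark = droplet | substrate

    frac = dark.reshape(h_px, ss, w_px, ss).mean(axis=(1, 3))
    return _BACKGROUND + (_FOREGROUND - _BACKGROUND) * frac


# ---------------------------------------------------------------------------
# tabular parameter -> volume generator
# ---------------------------------------------------------------------------

VISCOSITY_LEVELS = (10.03, 24.66)  # mPa*s (the two bioink formulations)
NOZZLE_LEVELS = (0.337, 0.26, 0.21)  # inner diameter, mm (23G/25G/27G)
TIME_LEVELS = (0.05, 0.1, 0.15)  # dispensing time, s
PRESSURE_LEVELS = (1.5, 2.0)  # printing pressure, psi
#: cell concentrations in cells/mL (2.8e6 and 5.6e6 cells per 3 mL batch)
CELL_LEVELS = (2.8e6 / 3.0, 5.6e6 / 3.0)

#: preset name -> power-law exponents (a_t, a_d, a_P, a_mu, a_c)
PRESETS: dict[str, dict[str, float]] = {
    "empirical": {"a_t": 1.0, "a_d": 1.5, "a_P": 1.0, "a_mu": 0.3, "a_c": 0.02},
    "poiseuille": {"a_t": 1.0, "a_d": 4.0, "a_P": 1.0, "a_mu": 0.3, "a_c": 0.02},
}


@dataclass(frozen=True)
class PrintRecord:
    """One bioprinting run: five print parameters and the droplet volume."""

    viscosity_mPa_s: float
    nozzle_id_mm: float
    printing_time_s: float
    pressure_psi: float
    cell_conc_per_mL: float
    volume_uL: float

    def __post_init__(self) -> None:
        for name in (
            "viscosity_mPa_s",
            "nozzle_id_mm",
            "printing_time_s",
            "pressure_psi",
            "cell_conc_per_mL",
            "volume_uL",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the power-law parameter-to-volume surrogate.

    ``anchor_params`` are the reference levels (subscript-0 values); at
    those levels the noiseless volume equals ``anchor_volume_uL``.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    volume noise.  ``continuous`` samples parameters uniformly within the
    level ranges instead of on the grid.
    """

    preset: str = "empirical"
    a_t: float = field(default=None)  # type: ignore[assignment]
    a_d: float = field(default=None)  # type: ignore[assignment]
    a_P: float = field(default=None)  # type: ignore[assignment]
    a_mu: float = field(default=None)  # type: ignore[assignment]
    a_c: float = field(default=None)  # type: ignore[assignment]
    anchor_volume_uL: float = 6.54
    anchor_params: tuple[float, float, float, float, float] = (
        10.03,  # viscosity mPa*s
        0.26,  # nozzle I.D. mm
        0.1,  # printing time s
        2.0,  # pressure psi (anchoring at the high level keeps the
        #       response surface inside the 0.5-20 uL envelope)
        CELL_LEVELS[0],  # cells/mL
    )
    noise_cv: float = 0.02
    continuous: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )
        for name, value in PRESETS[self.preset].items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)
        if not (self.anchor_volume_uL > 0):
            raise ValueError("anchor_volume_uL must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def volume_model(
    viscosity_mPa_s,
    nozzle_id_mm,
    printing_time_s,
    pressure_psi,
    cell_conc_per_mL,
    config: GeneratorConfig | None = None,
):
    """Noiseless droplet volume (uL) for the given print parameters.

    Accepts scalars or numpy arrays (broadcast).  Raises for non-positive
    parameters.
    """
    cfg = config or GeneratorConfig()
    mu0, d0, t0, p0, c0 = cfg.anchor_params
    params = [
        np.asarray(viscosity_mPa_s, dtype=float),
        np.asarray(nozzle_id_mm, dtype=float),
        np.asarray(printing_time_s, dtype=float),
        np.asarray(pressure_psi, dtype=float),
        np.asarray(cell_conc_per_mL, dtype=float),
    ]
    if any(np.any(p <= 0) for p in params):
        raise ValueError("all print parameters must be strictly positive")
    mu, d, t, p, c = params
    v = (
        cfg.anchor_volume_uL
        * (p / p0) ** cfg.a_P
        * (t / t0) ** cfg.a_t
        * (d / d0) ** cfg.a_d
        * (mu / mu0) ** (-cfg.a_mu)
        * (1.0 + cfg.a_c * (c - c0) / c0)
    )
    return v if v.ndim else float(v)


def generate_records(n: int, config: GeneratorConfig | None = None) -> list[PrintRecord]:
    """Sample ``n`` print records from the design grid.

    The two viscosity levels are exactly balanced (floor(n/2) / ceil(n/2));
    the remaining parameters are drawn uniformly from their levels.  The
    volume is ``volume_model * (1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)``, clipped to stay positive.  Fully
    deterministic given ``config.seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    visc = np.array(
        [VISCOSITY_LEVELS[0]] * (n // 2) + [VISCOSITY_LEVELS[1]] * (n - n // 2)
    )
    visc = visc[rng.permutation(n)]
    if cfg.continuous:
        nozzle = rng.uniform(min(NOZZLE_LEVELS), max(NOZZLE_LEVELS), n)
        time_s = rng.uniform(min(TIME_LEVELS), max(TIME_LEVELS), n)
        press = rng.uniform(min(PRESSURE_LEVELS), max(PRESSURE_LEVELS), n)
        cells = rng.uniform(min(CELL_LEVELS), max(CELL_LEVELS), n)
    else:
        nozzle = rng.choice(NOZZLE_LEVELS, n)
        time_s = rng.choice(TIME_LEVELS, n)
        press = rng.choice(PRESSURE_LEVELS, n)
        cells = rng.choice(CELL_LEVELS, n)

    v = volume_model(visc, nozzle, time_s, press, cells, cfg)
    if cfg.noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, cfg.noise_cv, n))
    v = np.maximum(v, 1e-6)

    return [
        PrintRecord(
            viscosity_mPa_s=float(visc[i]),
            nozzle_id_mm=float(nozzle[i]),
            printing_time_s=float(time_s[i]),
            pressure_psi=float(press[i]),
            cell_conc_per_mL=float(cells[i]),
            volume_uL=float(v[i]),
        )
        for i in range(n)
    ]
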