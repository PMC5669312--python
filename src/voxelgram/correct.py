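"""Signal correction: background-surface removal, despiking, calibration.

Three artefact classes are handled before any geometric processing:

* **Background** — slow instrument drift over a multi-hour run produces a
  smooth additive offset.  Operator-designated regions known to contain no
  tissue constrain a low-order 2D polynomial surface which is subtracted
  from every channel.
* **Spikes** — isolated single-pixel transients from aberrant particles or
  the electron multiplier; detected against the median of the surrounding
  window (default 9x9) and replaced by it.
* **Sensitivity drift** — reference materials of known concentration are
  ablated before and after each scan; the per-line sensitivity (CPS per
  ug/g) is interpolated between the two brackets and each pixel row is
  multiplied by the reciprocal factor to convert CPS to ug/g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .rawio import ChannelImage

__all__ = [
    "BackgroundRegion",
    "BackgroundModel",
    "StandardMeasurement",
    "CalibrationFactorSeries",
    "fit_background",
    "subtract_background",
    "despike",
    "find_spikes",
    "line_calibration_factors",
    "apply_calibration",
    "calibrate_run",
]


@dataclass(frozen=True)
class BackgroundRegion:
    """A tissue-free region, either a rectangle or a polygon.

    ``rect`` is (row0, col0, height, width); ``polygon`` is a vertex list
    of (x, y) = (col, row) pixel coordinates with >= 3 vertices.
    """

    rect: tuple[int, int, int, int] | None = None
    polygon: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("specify exactly one of rect or polygon")
        if self.polygon is not None and len(self.polygon) < 3:
            raise ValueError("polygon needs >= 3 vertices")

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        from .sections import polygon_mask  # local import: avoid cycle
        if self.rect is not None:
            r0, c0, h, w = self.rect
            if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
                raise ValueError(f"rect {self.rect} exceeds image shape {shape}")
            m = np.zeros(shape, dtype=bool)
            m[r0:r0 + h, c0:c0 + w] = True
            return m
        return polygon_mask(shape, self.polygon)


@dataclass
class BackgroundModel:
    """A fitted polynomial background surface congruent with its source."""

    surface: np.ndarray
    method: str
    order: int
    fit_residual: float
    coefficients: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.surface)):
            raise ValueError("background surface must be finite everywhere")


def _poly_design(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int],
                 order: int) -> np.ndarray:
    # coordinates scaled to [-1, 1] for conditioning
    y = 2.0 * rows / max(shape[0] - 1, 1) - 1.0
    x = 2.0 * cols / max(shape[1] - 1, 1) - 1.0
    terms = [x ** i * y ** j for i in range(order + 1)
             for j in range(order + 1 - i)]
    return np.stack(terms, axis=-1)


def n_poly_coeffs(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def fit_background(image: ChannelImage, regions: Sequence[BackgroundRegion],
                   order: int = 2) -> BackgroundModel:
    """Least-squares polynomial surface (total degree <= ``order``) fitted
    to the union of the background-region pixels, evaluated on the full grid.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    shape = image.shape
    mask = np.zeros(shape, dtype=bool)
    for reg in regions:
        mask |= reg.pixel_mask(shape)
    n_pix = int(mask.sum())
    n_coef = n_poly_coeffs(order)
    if n_pix < n_coef:
        raise ValueError(
            f"underdetermined background fit: {n_pix} region pixel(s) for "
            f"{n_coef} coefficients (order {order}); supply >= {n_coef} pixels")
    rows, cols = np.nonzero(mask)
    A = _poly_design(rows, cols, shape, order)
    b = image.values[mask]
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    surface = (_poly_design(rr.ravel(), cc.ravel(), shape, order) @ coef
               ).reshape(shape)
    resid = float(np.sqrt(np.mean((A @ coef - b) ** 2)))
    return BackgroundModel(surface=surface, method="polynomial", order=order,
                           fit_residual=resid, coefficients=coef)


def subtract_background(image: ChannelImage, model: BackgroundModel,
                        clamp_negative: bool = False) -> ChannelImage:
    """Subtract the fitted surface; optionally clamp negatives to 0."""
    if model.surface.shape != image.shape:
        raise ValueError(
            f"surface shape {model.surface.shape} != image shape {image.shape}")
    out = image.values - model.surface
    if clamp_negative:
        out = np.maximum(out, 0.0)
    return image.copy_with(out, background_subtracted=True)


def find_spikes(values: np.ndarray, window: int = 9, factor: float = 5.0,
                floor: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Locate isolated spikes and their replacement values.

    A pixel is a spike iff its value exceeds ``factor * median + floor``,
    where the median is taken over the surrounding ``window x window``
    neighbourhood *excluding the pixel itself*; at edges the window is
    truncated to the image.  Returns ``(spike_mask, medians)``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3:
        raise ValueError("window must be >= 3")
    values = np.asarray(values, dtype=float)
    half = window // 2
    padded = np.pad(values, half, mode="constant", constant_values=np.nan)
    medians = np.empty_like(values)
    # row-chunked to bound the sliding-window memory footprint
    chunk = max(1, int(4e6 // (values.shape[1] * window * window)))
    for r0 in range(0, values.shape[0], chunk):
        r1 = min(r0 + chunk, values.shape[0])
        win = sliding_window_view(padded[r0:r1 + 2 * half], (window, window)).copy()
        win[..., half, half] = np.nan
        medians[r0:r1] = np.nanmedian(win, axis=(-2, -1))
    spikes = values > factor * medians + floor
    return spikes, medians


def despike(image: ChannelImage, window: int = 9, factor: float = 5.0,
            floor: float = 0.0) -> tuple[ChannelImage, int]:
    """Replace isolated spikes by their neighbourhood median.

    Returns the cleaned image and the number of pixels replaced.
    """
    spikes, medians = find_spikes(image.values, window=window, factor=factor,
                                  floor=floor)
    out = image.values.copy()
    out[spikes] = medians[spikes]
    return image.copy_with(out, despiked=True), int(spikes.sum())


@dataclass(frozen=True)
class StandardMeasurement:
    """Mean signal on a reference material bracketing a scan."""

    isotope: str
    mean_cps: float
    concentration: float
    position: str  # "pre" | "post"
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("standard concentration must be > 0")
        if self.mean_cps < 0:
            raise ValueError("mean_cps must be >= 0")
        if self.position not in ("pre", "post"):
            raise ValueError("position must be 'pre' or 'post'")

    @property
    def sensitivity(self) -> float:
        """CPS per ug/g."""
        return self.mean_cps / self.concentration


@dataclass
class CalibrationFactorSeries:
    """Per-scan-line calibration factors (ug/g per CPS).

    The stored factor is the reciprocal of the interpolated sensitivity, so
    multiplying a row of CPS values by its factor yields concentration.
    """

    isotope: str
    factors: np.ndarray
    sensitivity_pre: float
    sensitivity_post: float

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("calibration factors must be strictly positive")


def line_calibration_factors(pre: StandardMeasurement, post: StandardMeasurement,
                             n_rows: int,
                             row_timestamps: np.ndarray | None = None,
                             ) -> CalibrationFactorSeries:
    """Interpolate sensitivity between the bracketing standards.

    Linear in row index by default; if ``row_timestamps`` and both standard
    timestamps are present, linear in acquisition time instead.
    """
    if pre.isotope != post.isotope:
        raise ValueError(f"isotope mismatch: {pre.isotope} vs {post.isotope}")
    s_pre, s_post = pre.sensitivity, post.sensitivity
    if s_pre <= 0 or s_post <= 0:
        raise ValueError(
            f"non-positive sensitivity for {pre.isotope}: pre={s_pre}, post={s_post}")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if (row_timestamps is not None and pre.timestamp is not None
            and post.timestamp is not None):
        t = np.asarray(row_timestamps, dtype=float)
        if len(t) != n_rows:
            raise ValueError("row_timestamps length must equal n_rows")
        span = post.timestamp - pre.timestamp
        frac = (t - pre.timestamp) / span if span != 0 else np.zeros(n_rows)
    else:
        frac = (np.arange(n_rows) / (n_rows - 1)) if n_rows > 1 else np.zeros(1)
    sens = s_pre + (s_post - s_pre) * frac
    return CalibrationFactorSeries(isotope=pre.isotope, factors=1.0 / sens,
                                   sensitivity_pre=s_pre, sensitivity_post=s_post)


def apply_calibration(image: ChannelImage,
                      series: CalibrationFactorSeries) -> ChannelImage:
    """Multiply each pixel row by its calibration factor: CPS -> ug/g."""
    if image.units != "CPS":
        raise ValueError(f"expected CPS input, got units {image.units!r}")
    if len(series.factors) != image.shape[0]:
        raise ValueError(
            f"factor series length {len(series.factors)} != row count "
            f"{image.shape[0]}")
    if series.isotope != image.isotope:
        raise ValueError(
            f"isotope mismatch: series {series.isotope} vs image {image.isotope}")
    out = image.values * series.factors[:, None]
    return image.copy_with(out, units="ug/g", calibrated=True)


def calibrate_run(channels: dict[str, ChannelImage],
                  standards: Sequence[StandardMeasurement],
                  ) -> tuple[dict[str, ChannelImage], list[str]]:
    """Calibrate every channel that has a pre/post standard pair.

    Channels without standards (no tissue-matched reference material, e.g.
    Mn in brain work) pass through unchanged in CPS with an
    ``unquantified`` flag.  Returns the channel map and the list of
    unquantified isotopes.
    """
    by_iso: dict[str, dict[str, StandardMeasurement]] = {}
    for s in standards:
        by_iso.setdefault(s.isotope, {})[s.position] = s
    out: dict[str, ChannelImage] = {}
    unquantified: list[str] = []
    for iso, img in channels.items():
        pair = by_iso.get(iso, {})
        if "pre" in pair and "post" in pair:
            series = line_calibration_factors(
                pair["pre"], pair["post"], img.shape[0],
                row_timestamps=img.row_timestamps)
            out[iso] = apply_calibration(img, series)
        else:
            out[iso] = img.copy_with(img.values, unquantified=True)
            unquantified.append(iso)
    return out, unquantified
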