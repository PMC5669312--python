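"""Pyramidal intensity-based rigid registration of serial sections.

Consecutive sections are mounted with arbitrary in-plane rotation and
offset.  Each section ("test") is aligned to the already-aligned preceding
section ("reference") by minimising the squared intensity difference

    eps^2 = || f_R(x) - Q_P{ f_T(x) } ||^2

where f_R and f_T are 3rd-order spline models of the reference and test
images and Q_P is a rigid transform with parameters P = (theta, tx, ty).
The transform family is deliberately restricted: no scale, skew, shear or
grey-level change, since physical pixel size is fixed by the instrument
and the original intensities must survive the transform.

Optimisation runs coarse-to-fine over an image pyramid (default 4
down-sampling levels, factor 2, coarsest at 1/16 scale); each level seeds
the next, and the coarsest level is additionally seeded by an exhaustive
coarse grid because it has no prior estimate.  The identity transform is
always kept as a candidate, so the returned residual never exceeds the
unregistered residual.

Alignment typically runs on a composite channel: each input channel is
normalised to greyscale 0-255 and averaged with user weights (default
50:50 for two channels, mirroring a tissue-structure channel combined
with an immunolabel channel); the recovered parameter set is then applied
retrospectively to every channel of the section.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .rawio import ChannelImage
from .sections import SectionImage

__all__ = [
    "GreyImage",
    "RigidTransform2D",
    "SplineImage",
    "PyramidConfig",
    "RegistrationResult",
    "normalize_grey",
    "composite_channel",
    "resample",
    "warp_values",
    "warp_mask",
    "register_pair",
    "register_stack",
    "apply_results",
    "alignment_residual",
    "grid_search",
    "save_transforms",
    "load_transforms",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta`` degrees about ``centre`` plus translation.

    Coordinates are (x, y) = (column, row).  The forward map takes test-
    image coordinates to reference-frame coordinates:
    ``p' = R (p - c) + c + t``.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    centre: tuple[float, float] = (0.0, 0.0)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.theta, self.tx, self.ty])

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and self.tx == 0.0 and self.ty == 0.0

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous forward matrix in (x, y) coordinates."""
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        cx, cy = self.centre
        R = np.array([[c, -s], [s, c]])
        t = np.array([cx, cy]) - R @ np.array([cx, cy]) + np.array([self.tx, self.ty])
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = t
        return M

    def inverse(self) -> "RigidTransform2D":
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        # inverse rotation about the same centre; solve for the residual shift
        Rinv = np.array([[c, s], [-s, c]])
        t = -(Rinv @ np.array([self.tx, self.ty]))
        return RigidTransform2D(theta=-self.theta, tx=float(t[0]), ty=float(t[1]),
                                centre=self.centre)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points forward."""
        M = self.matrix()
        pts = np.asarray(xy, dtype=float)
        return pts @ M[:2, :2].T + M[:2, 2]

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``other`` then self."""
        M = self.matrix() @ other.matrix()
        theta = self.theta + other.theta
        # recover the translation that reproduces M about self.centre
        th = math.radians(theta)
        c, s = math.cos(th), math.sin(th)
        R = np.array([[c, -s], [s, c]])
        cx, cy = self.centre
        t = M[:2, 2] - (np.array([cx, cy]) - R @ np.array([cx, cy]))
        return RigidTransform2D(theta=theta, tx=float(t[0]), ty=float(t[1]),
                                centre=self.centre)

    def scaled(self, factor: float) -> "RigidTransform2D":
        """Same rotation with translations and centre scaled by ``factor``."""
        return RigidTransform2D(theta=self.theta, tx=self.tx * factor,
                                ty=self.ty * factor,
                                centre=(self.centre[0] * factor,
                                        self.centre[1] * factor))


@dataclass
class GreyImage:
    """A greyscale [0, 255] image with a tissue mask.

    Out-of-mask pixels are 0 by construction (see :func:`normalize_grey`).
    """

    values: np.ndarray
    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be congruent")
        if self.values.size and (self.values.min() < -1e-9
                                 or self.values.max() > 255 + 1e-9):
            raise ValueError("grey values must lie in [0, 255]")


class SplineImage:
    """3rd-order (default) spline model of an image, evaluable at
    real-valued coordinates.  Evaluation at integer pixel coordinates
    reproduces the source image (to float precision)."""

    def __init__(self, values: np.ndarray, order: int = 3):
        self.order = order
        self.shape = values.shape
        if order > 1:
            self._coeffs = ndimage.spline_filter(
                np.asarray(values, dtype=float), order=order, mode="constant")
        else:
            self._coeffs = np.asarray(values, dtype=float)

    def __call__(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            self._coeffs, np.stack([rows, cols]), order=self.order,
            mode="constant", cval=0.0, prefilter=False)


@dataclass(frozen=True)
class PyramidConfig:
    """Pyramid and optimiser settings.

    ``levels`` halvings below full resolution (coarsest scale
    ``factor**-levels``); the search visits ``levels + 1`` stages ending at
    the original resolution.  The coarse seeding grid spans
    ``±theta_range`` degrees in ``theta_step`` steps and ``±shift_range``
    full-resolution pixels.
    """

    levels: int = 4
    factor: int = 2
    spline_order: int = 3
    tol: float = 1e-3
    max_evals: int = 400
    theta_range: float = 15.0
    theta_step: float = 2.0
    shift_range: float = 16.0
    shift_step: float = 2.0
    min_level_size: int = 8

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.factor < 2:
            raise ValueError("factor must be >= 2")

    @property
    def coarsest_fraction(self) -> float:
        return float(self.factor) ** (-self.levels)


@dataclass
class RegistrationResult:
    """Outcome of one pairwise registration."""

    transform: RigidTransform2D
    residuals: list[float] = field(default_factory=list)
    converged: bool = True
    evaluations: int = 0

    @property
    def residual(self) -> float:
        return self.residuals[-1] if self.residuals else float("nan")


def normalize_grey(image: ChannelImage | np.ndarray,
                   mask: np.ndarray | None = None,
                   label: str | None = None,
                   vrange: tuple[float, float] | None = None) -> GreyImage:
    """Linearly map in-mask intensities to greyscale [0, 255].

    The in-mask minimum maps to 0 and the maximum to 255; a constant
    in-mask image maps to all 0; out-of-mask pixels are set to 0 and never
    influence the scaling.  ``vrange`` overrides the (min, max) anchors —
    used when several sections must share one intensity scale, since
    grey-level change is excluded from the transform family; values are
    clipped into the range.
    """
    if isinstance(image, ChannelImage):
        values = image.values
        if label is None:
            label = image.isotope
    else:
        values = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot normalise an image with an empty mask")
    sel = values[mask]
    if not np.all(np.isfinite(sel)):
        raise ValueError("image must be finite on the mask")
    if vrange is None:
        vmin, vmax = float(sel.min()), float(sel.max())
    else:
        vmin, vmax = float(vrange[0]), float(vrange[1])
    out = np.zeros_like(values, dtype=float)
    if vmax > vmin:
        out[mask] = np.clip((values[mask] - vmin) * (255.0 / (vmax - vmin)),
                            0.0, 255.0)
    return GreyImage(values=out, mask=mask, label=label or "")


def composite_channel(images: Sequence[GreyImage],
                      weights: Sequence[float] | None = None) -> GreyImage:
    """Pixelwise weighted sum of greyscale channels (weights sum to 1).

    Default is equal weighting — for the canonical two-channel case this
    is 0.5/0.5.  The composite mask is the union of the input masks.
    """
    if not images:
        raise ValueError("need at least one image")
    if weights is None:
        weights = [1.0 / len(images)] * len(images)
    weights = [float(w) for w in weights]
    if len(weights) != len(images):
        raise ValueError("one weight per image required")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    shape = images[0].values.shape
    for im in images[1:]:
        if im.values.shape != shape:
            raise ValueError("composite inputs must be congruent")
    values = sum(w * im.values for w, im in zip(weights, images))
    mask = np.zeros(shape, dtype=bool)
    for im in images:
        mask |= im.mask
    label = "+".join(im.label for im in images if im.label)
    return GreyImage(values=np.asarray(values), mask=mask, label=label)


def _inverse_coords(shape: tuple[int, int], transform: RigidTransform2D,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Source (row, col) sample coordinates for every output pixel."""
    Minv = transform.inverse().matrix()
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    x = Minv[0, 0] * cc + Minv[0, 1] * rr + Minv[0, 2]
    y = Minv[1, 0] * cc + Minv[1, 1] * rr + Minv[1, 2]
    return y, x


def warp_values(values: np.ndarray, transform: RigidTransform2D,
                order: int = 3, fill: float = 0.0,
                spline: SplineImage | None = None) -> np.ndarray:
    """Resample an array under a rigid transform (output = input o T^-1)."""
    values = np.asarray(values, dtype=float)
    if transform.is_identity and spline is None:
        return values.copy()
    rows, cols = _inverse_coords(values.shape, transform)
    if spline is not None:
        out = spline(rows.ravel(), cols.ravel()).reshape(values.shape)
    else:
        out = ndimage.map_coordinates(values, np.stack([rows, cols]),
                                      order=order, mode="constant", cval=fill)
    if fill != 0.0:
        inside = ((rows >= -0.5) & (rows <= values.shape[0] - 0.5)
                  & (cols >= -0.5) & (cols <= values.shape[1] - 0.5))
        out[~inside] = fill
    return out


def warp_mask(mask: np.ndarray, transform: RigidTransform2D) -> np.ndarray:
    """Nearest-neighbour transform of a boolean mask."""
    if transform.is_identity:
        return mask.copy()
    rows, cols = _inverse_coords(mask.shape, transform)
    out = ndimage.map_coordinates(mask.astype(np.uint8), np.stack([rows, cols]),
                                  order=0, mode="constant", cval=0)
    return out.astype(bool)


def resample(image: GreyImage, transform: RigidTransform2D, order: int = 3,
             fill: float = 0.0) -> GreyImage:
    """Apply a rigid transform to a greyscale image (spline interpolation;
    mask moved with the nearest-neighbour rule)."""
    values = warp_values(image.values, transform, order=order, fill=fill)
    mask = warp_mask(image.mask, transform)
    values[~mask] = fill
    np.clip(values, 0.0, 255.0, out=values)
    return GreyImage(values=values, mask=mask, label=image.label)


def _downsample(values: np.ndarray, mask: np.ndarray, factor: int,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Mask-aware pyramid reduction: gaussian anti-alias then block mean."""
    m = mask.astype(float)
    sigma = factor / 2.0
    num = ndimage.gaussian_filter(values * m, sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma, mode="constant")
    sm = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
    H, W = values.shape
    Hc, Wc = -(-H // factor), -(-W // factor)
    pad = ((0, Hc * factor - H), (0, Wc * factor - W))
    smp = np.pad(sm, pad)
    mp = np.pad(m, pad)
    blocks_v = smp.reshape(Hc, factor, Wc, factor)
    blocks_m = mp.reshape(Hc, factor, Wc, factor)
    wsum = blocks_m.sum(axis=(1, 3))
    vals = np.where(wsum > 0, (blocks_v * blocks_m).sum(axis=(1, 3))
                    / np.maximum(wsum, 1e-12), 0.0)
    return vals, wsum > 0


def _objective(params: np.ndarray, ref: GreyImage, spline: SplineImage,
               test_mask: np.ndarray, centre: tuple[float, float]) -> float:
    t = RigidTransform2D(theta=float(params[0]), tx=float(params[1]),
                         ty=float(params[2]), centre=centre)
    warped = warp_values(np.empty(ref.values.shape), t, spline=spline)
    wmask = warp_mask(test_mask, t)
    warped[~wmask] = 0.0
    union = ref.mask | wmask
    n = union.sum()
    if n == 0:
        return float("inf")
    diff = ref.values[union] - warped[union]
    return float(np.mean(diff * diff))


def register_pair(ref: GreyImage, test: GreyImage,
                  config: PyramidConfig | None = None) -> RegistrationResult:
    """Recover the rigid transform aligning ``test`` onto ``ref``.

    Coarse-to-fine search over the image pyramid; the coarsest stage is
    seeded by an exhaustive grid over rotation and integer shifts, each
    finer stage by the scaled optimum of the previous one, refined with a
    derivative-free simplex search.  The identity transform always remains
    a candidate, so the final residual cannot exceed the unregistered one.

    The ``residuals`` trace holds, per stage, the full-resolution
    normalised RMS difference achieved by that stage's optimum.
    """
    config = config or PyramidConfig()
    if ref.values.shape != test.values.shape:
        raise ValueError("reference and test frames must be congruent")
    if not ref.mask.any() or not test.mask.any():
        raise ValueError("registration impossible: empty mask")

    H, W = ref.values.shape
    centre = ((W - 1) / 2.0, (H - 1) / 2.0)

    # pyramid, full resolution first; stop before levels get degenerate
    pyr: list[tuple[GreyImage, np.ndarray]] = [(ref, test.values)]
    masks = [test.mask]
    rv, rm, tv, tm = ref.values, ref.mask, test.values, test.mask
    for _ in range(config.levels):
        if min(rv.shape) // config.factor < config.min_level_size:
            break
        rv, rm = _downsample(rv, rm, config.factor)
        tv, tm = _downsample(tv, tm, config.factor)
        pyr.append((GreyImage(np.clip(rv, 0, 255), rm, ref.label), np.clip(tv, 0, 255)))
        masks.append(tm)
    n_stages = len(pyr)

    full_ref = pyr[0][0]
    full_spline = SplineImage(pyr[0][1], order=config.spline_order)
    full_mask = masks[0]

    def full_res_residual(t_full: RigidTransform2D) -> float:
        e2 = _objective(t_full.params, full_ref, full_spline, full_mask, centre)
        return math.sqrt(e2) / 255.0

    evaluations = 0
    residual_trace: list[float] = []
    params = np.zeros(3)
    converged = True

    for stage in range(n_stages - 1, -1, -1):
        scale = config.factor ** (-stage)
        ref_l, test_l = pyr[stage]
        mask_l = masks[stage]
        spline_l = (full_spline if stage == 0
                    else SplineImage(test_l, order=config.spline_order))
        h, w = ref_l.values.shape
        centre_l = ((w - 1) / 2.0, (h - 1) / 2.0)

        if stage == n_stages - 1:
            # no prior estimate at the coarsest level: exhaustive coarse grid
            thetas = np.arange(-config.theta_range,
                               config.theta_range + 1e-9, config.theta_step)
            smax = max(1, math.ceil(config.shift_range * scale))
            step = max(1, round(config.shift_step * scale))
            shifts = np.arange(-smax, smax + 1, step, dtype=float)
            best = (np.inf, np.zeros(3))
            for th in np.concatenate([thetas, [0.0]]):
                for sx in shifts:
                    for sy in shifts:
                        p = np.array([th, sx, sy])
                        e = _objective(p, ref_l, spline_l, mask_l, centre_l)
                        evaluations += 1
                        if e < best[0]:
                            best = (e, p)
            params = best[1]
        else:
            params = params * np.array([1.0, config.factor, config.factor])

        step = max(0.25, scale)  # simplex spread: wider when coarser
        simplex = np.vstack([params] * 4)
        simplex[1, 0] += 2.0 * step
        simplex[2, 1] += step
        simplex[3, 2] += step
        res = optimize.minimize(
            _objective, params, args=(ref_l, spline_l, mask_l, centre_l),
            method="Nelder-Mead",
            options={"xatol": config.tol, "fatol": 1e-12,
                     "maxfev": config.max_evals, "initial_simplex": simplex})
        evaluations += res.nfev
        converged = converged and bool(res.success)
        params = res.x
        t_full = RigidTransform2D(theta=float(params[0]),
                                  tx=float(params[1]) / scale,
                                  ty=float(params[2]) / scale, centre=centre)
        residual_trace.append(full_res_residual(t_full))

    final = RigidTransform2D(theta=float(params[0]), tx=float(params[1]),
                             ty=float(params[2]), centre=centre)
    identity = RigidTransform2D(centre=centre)
    r_final = residual_trace[-1]
    r_id = full_res_residual(identity)
    evaluations += 1
    if r_id < r_final:
        final, r_final = identity, r_id
        residual_trace.append(r_id)
    return RegistrationResult(transform=final, residuals=residual_trace,
                              converged=converged, evaluations=evaluations)


def grid_search(ref: GreyImage, test: GreyImage, thetas: Sequence[float],
                shifts: Sequence[float]) -> tuple[RigidTransform2D, float]:
    """Exhaustive search over a rotation/shift grid; returns the best
    transform and its normalised RMS residual.  Intended as a slow,
    optimiser-free baseline."""
    H, W = ref.values.shape
    centre = ((W - 1) / 2.0, (H - 1) / 2.0)
    spline = SplineImage(test.values, order=3)
    best: tuple[float, RigidTransform2D] = (np.inf, RigidTransform2D(centre=centre))
    for th in thetas:
        for sx in shifts:
            for sy in shifts:
                p = np.array([th, sx, sy])
                e = _objective(p, ref, spline, test.mask, centre)
                if e < best[0]:
                    best = (e, RigidTransform2D(theta=float(th), tx=float(sx),
                                                ty=float(sy), centre=centre))
    return best[1], math.sqrt(best[0]) / 255.0


def _section_composite(section: SectionImage, channels: Sequence[str],
                       weights: Sequence[float] | None,
                       ranges: dict[str, tuple[float, float]] | None = None,
                       ) -> GreyImage:
    greys = []
    for ch in channels:
        if ch not in section.channels:
            raise KeyError(f"alignment channel {ch!r} missing from section "
                           f"{section.spec.order_index}")
        greys.append(normalize_grey(section.channels[ch], section.mask,
                                    vrange=ranges.get(ch) if ranges else None))
    return composite_channel(greys, weights)


def _stack_ranges(sections: Sequence[SectionImage], channels: Sequence[str],
                  ) -> dict[str, tuple[float, float]]:
    """Shared per-channel grey anchors (in-mask min/max over the stack)."""
    ranges = {}
    for ch in channels:
        for k, s in enumerate(sections):
            if ch not in s.channels:
                raise KeyError(f"alignment channel {ch!r} missing from "
                               f"section {k}")
        lo = min(float(s.channels[ch].values[s.mask].min())
                 for s in sections if s.mask.any())
        hi = max(float(s.channels[ch].values[s.mask].max())
                 for s in sections if s.mask.any())
        ranges[ch] = (lo, hi)
    return ranges


def register_stack(sections: Sequence[SectionImage],
                   alignment_channels: Sequence[str],
                   weights: Sequence[float] | None = None,
                   config: PyramidConfig | None = None,
                   ) -> list[RegistrationResult]:
    """Chain-register a section stack on a composite alignment channel.

    Section k (k >= 1) is registered to the *already transformed* section
    k-1, so pairwise errors do not accumulate as frame drift.  All
    sections share one grey scale per channel (stack-wide in-mask
    min/max): grey-level change is excluded from the transform family, so
    genuine intensity differences between sections must survive
    normalisation rather than be rescaled away.  Returns one result per
    non-first section, in order.
    """
    if not sections:
        raise ValueError("need at least one section")
    config = config or PyramidConfig()
    ranges = _stack_ranges(sections, alignment_channels)
    results: list[RegistrationResult] = []
    ref = _section_composite(sections[0], alignment_channels, weights, ranges)
    for section in sections[1:]:
        test = _section_composite(section, alignment_channels, weights, ranges)
        res = register_pair(ref, test, config)
        results.append(res)
        ref = resample(test, res.transform)
    return results


def apply_results(sections: Sequence[SectionImage],
                  results: Sequence[RegistrationResult],
                  order: int = 3) -> list[SectionImage]:
    """Resample every channel of every section with its recovered
    transform (section 0 keeps the identity)."""
    if len(results) != max(len(sections) - 1, 0):
        raise ValueError("expected one result per non-first section")
    out = [sections[0].copy()]
    for section, res in zip(sections[1:], results):
        t = res.transform
        mask = warp_mask(section.mask, t)
        channels = {}
        for iso, img in section.channels.items():
            vals = warp_values(img.values, t, order=order)
            vals[~mask] = 0.0
            channels[iso] = img.copy_with(vals)
        out.append(SectionImage(channels=channels, mask=mask, spec=section.spec))
    return out


def alignment_residual(ref: GreyImage, test: GreyImage) -> float:
    """Normalised mean absolute difference over the union of the masks.

    Both images are rescaled to [0, 1] (value / 255); 0 means identical,
    1 means maximal disagreement everywhere.
    """
    if ref.values.shape != test.values.shape:
        raise ValueError("images must be congruent")
    union = ref.mask | test.mask
    if not union.any():
        raise ValueError("empty union mask")
    diff = np.abs(ref.values[union] - test.values[union]) / 255.0
    return float(diff.mean())


def save_transforms(results: Sequence[RegistrationResult], path: str | Path,
                    frame_shape: tuple[int, int] | None = None) -> Path:
    """Serialise recovered transforms as JSON (exact round trip)."""
    path = Path(path)
    doc = {
        "frame_shape": list(frame_shape) if frame_shape else None,
        "transforms": [
            {"theta_deg": r.transform.theta, "tx_px": r.transform.tx,
             "ty_px": r.transform.ty, "centre": list(r.transform.centre),
             "residual": r.residual, "converged": r.converged,
             "evaluations": r.evaluations, "residual_trace": r.residuals}
            for r in results
        ],
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_transforms(path: str | Path) -> list[RegistrationResult]:
    doc = json.loads(Path(path).read_text())
    out = []
    for rec in doc["transforms"]:
        t = RigidTransform2D(theta=rec["theta_deg"], tx=rec["tx_px"],
                             ty=rec["ty_px"], centre=tuple(rec["centre"]))
        out.append(RegistrationResult(transform=t,
                                      residuals=list(rec["residual_trace"]),
                                      converged=rec["converged"],
                                      evaluations=rec["evaluations"]))
    return out
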