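"""Section segmentation: subdivide a whole-slide scan and mask tissue.

A single ablation run typically covers several serial sections mounted on
one slide.  Each section is cut out by a declarative bounding box, ordered
anterior to posterior, and masked to its tissue boundary with a polygon so
that background anomalies and neighbouring sections cannot leak into the
registration or any downstream statistic.  The masked exterior is stored
as value 0 *plus* an explicit boolean mask: 0 is a legitimate
background-subtracted intensity, so consumers must consult the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .rawio import ChannelImage, RawRun

__all__ = [
    "SectionSpec",
    "SectionImage",
    "polygon_mask",
    "split_sections",
    "apply_mask",
    "pad_to_common_frame",
]


@dataclass(frozen=True)
class SectionSpec:
    """Placement of one section within the parent scan.

    ``bbox`` is (row0, col0, height, width) in parent-image pixels;
    ``order_index`` 0 is the most anterior section and ``z_position`` is
    ``order_index * section_interval`` um.
    """

    order_index: int
    bbox: tuple[int, int, int, int]
    mask_polygon: tuple[tuple[float, float], ...] | None = None
    z_position: float = 0.0

    def __post_init__(self) -> None:
        r0, c0, h, w = self.bbox
        if h <= 0 or w <= 0:
            raise ValueError(f"bbox {self.bbox} has non-positive extent")
        if self.order_index < 0:
            raise ValueError("order_index must be >= 0")


@dataclass
class SectionImage:
    """One section: congruent per-channel grids plus a tissue mask."""

    channels: dict[str, ChannelImage]
    mask: np.ndarray
    spec: SectionSpec

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"section channels not congruent: {shapes}")
        if self.mask.shape != next(iter(shapes)):
            raise ValueError("mask shape must equal channel shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def copy(self) -> "SectionImage":
        return SectionImage(
            channels={k: v.copy_with(v.values.copy()) for k, v in self.channels.items()},
            mask=self.mask.copy(),
            spec=self.spec,
        )


def polygon_mask(shape: tuple[int, int], vertices: Sequence[tuple[float, float]],
                 ) -> np.ndarray:
    """Rasterise a polygon: even-odd rule tested at pixel centres,
    boundary pixels included.

    Vertices are (x, y) = (col, row).  Vectorised even-odd ray casting
    with an explicit on-segment test so that pixels whose centre lies
    exactly on an edge count as inside.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    x1 = verts
    x2 = np.roll(verts, -1, axis=0)
    # zero-area check via the shoelace formula
    area = 0.5 * abs(np.sum(x1[:, 0] * x2[:, 1] - x2[:, 0] * x1[:, 1]))
    if area == 0:
        raise ValueError("degenerate polygon: zero area")

    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    px = cc.ravel().astype(float)
    py = rr.ravel().astype(float)

    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    eps = 1e-12
    for (ax, ay), (bx, by) in zip(x1, x2):
        # even-odd crossing of the horizontal ray to +x
        cond = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (px < xint)
        # on-segment test
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        within = ((px >= min(ax, bx) - eps) & (px <= max(ax, bx) + eps)
                  & (py >= min(ay, by) - eps) & (py <= max(ay, by) + eps))
        on_edge |= (np.abs(cross) <= eps * max(1.0, abs(bx - ax) + abs(by - ay))) & within
    return (inside | on_edge).reshape(shape)


def split_sections(run: RawRun, specs: Sequence[SectionSpec]) -> list[SectionImage]:
    """Crop one :class:`SectionImage` per spec, all channels identically.

    Overlapping bounding boxes are allowed (nearby sections may overlap on
    the slide); each section carries its own copy.  The initial mask is
    all-true — masking happens in :func:`apply_mask`.
    """
    H, W = run.shape
    order = [s.order_index for s in specs]
    if sorted(order) != list(range(len(specs))):
        raise ValueError(f"order indices must be contiguous from 0, got {order}")
    out = []
    for spec in sorted(specs, key=lambda s: s.order_index):
        r0, c0, h, w = spec.bbox
        if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
            raise ValueError(f"bbox {spec.bbox} out of bounds for image {H}x{W}")
        channels = {
            iso: img.copy_with(img.values[r0:r0 + h, c0:c0 + w].copy())
            for iso, img in run.channels.items()
        }
        for img in channels.values():
            img.row_timestamps = None
        out.append(SectionImage(channels=channels,
                                mask=np.ones((h, w), dtype=bool), spec=spec))
    return out


def apply_mask(section: SectionImage,
               polygon: Sequence[tuple[float, float]]) -> SectionImage:
    """Zero out pixels outside the tissue polygon and clear their mask."""
    keep = polygon_mask(section.shape, polygon)
    channels = {}
    for iso, img in section.channels.items():
        vals = img.values.copy()
        vals[~keep] = 0.0
        channels[iso] = img.copy_with(vals)
    return SectionImage(
        channels=channels,
        mask=section.mask & keep,
        spec=replace(section.spec, mask_polygon=tuple(tuple(v) for v in polygon)),
    )


def pad_to_common_frame(sections: Sequence[SectionImage]) -> list[SectionImage]:
    """Centre every section in a frame of the maximal bbox dimensions.

    Padding is value 0 / mask false; with an odd size difference the extra
    pixel goes to the bottom/right.  Relative pixel geometry is preserved.
    """
    if not sections:
        raise ValueError("need at least one section")
    H = max(s.shape[0] for s in sections)
    W = max(s.shape[1] for s in sections)
    out = []
    for s in sections:
        h, w = s.shape
        if (h, w) == (H, W):
            out.append(s.copy())
            continue
        top = (H - h) // 2
        left = (W - w) // 2
        pad = ((top, H - h - top), (left, W - w - left))
        channels = {
            iso: img.copy_with(np.pad(img.values, pad, constant_values=0.0))
            for iso, img in s.channels.items()
        }
        out.append(SectionImage(channels=channels,
                                mask=np.pad(s.mask, pad, constant_values=False),
                                spec=s.spec))
    return out
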