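"""Voxel-volume assembly, multi-criteria selection, smoothing and export.

Aligned sections stack into an anisotropic multichannel voxel grid whose
spacing follows directly from the acquisition: dx = scan_speed x
acquisition period (along-scan), dy = line spacing (between ablation
lines), dz = section interval.  With an 80 um spot at 320 um/s and a
0.25 s acquisition period, all three give the canonical 80/80/90 um
brain-series geometry, and 23 sections at 90 um span ~2 mm of tissue.

Voxels are explored through per-channel histograms and selected by a
conjunction of closed (optionally open) per-channel intervals — a voxel
is visible iff it is in the tissue mask *and* inside every channel's
interval.  Volumes and selections export as VTK XML ImageData (.vti,
ASCII) for external 3D viewers, with a legacy STRUCTURED_POINTS writer
behind a flag; surface reconstruction is deliberately left to the viewer.

Axis order: arrays are (channel, z, y, x); files store x fastest and z
slowest, the VTK convention.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .rawio import RunManifest
from .sections import SectionImage

__all__ = [
    "VoxelGrid",
    "ChannelHistogram",
    "Interval",
    "CriteriaSet",
    "build_grid",
    "histogram",
    "select",
    "smooth",
    "export_vtk",
    "read_vti",
]


@dataclass
class VoxelGrid:
    """Multichannel 3D volume with anisotropic spacing.

    ``values`` is (channel, nz, ny, nx); ``spacing`` is (dx, dy, dz) in
    micrometres; ``mask`` marks tissue voxels.
    """

    values: np.ndarray
    channels: tuple[str, ...]
    units: tuple[str, ...]
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError("values must be (channel, nz, ny, nx)")
        if len(self.channels) != self.values.shape[0]:
            raise ValueError("one label per channel required")
        if len(self.units) != len(self.channels):
            raise ValueError("one unit per channel required")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask must be congruent with the volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx)."""
        return self.values.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) in micrometres."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        return (nx * dx, ny * dy, nz * dz)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"unknown channel {label!r}; have {self.channels}")


@dataclass
class ChannelHistogram:
    """Histogram of in-mask voxel values for one channel."""

    channel: str
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass(frozen=True)
class Interval:
    """A per-channel selection interval; bounds default closed, either
    side may be unbounded (None) or strict (open)."""

    lo: float | None = None
    hi: float | None = None
    lo_open: bool = False
    hi_open: bool = False

    def __post_init__(self) -> None:
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"interval lower bound {self.lo} > upper {self.hi}")

    def contains(self, values: np.ndarray) -> np.ndarray:
        ok = np.ones(np.shape(values), dtype=bool)
        if self.lo is not None:
            ok &= (values > self.lo) if self.lo_open else (values >= self.lo)
        if self.hi is not None:
            ok &= (values < self.hi) if self.hi_open else (values <= self.hi)
        return ok


@dataclass
class CriteriaSet:
    """Conjunction of per-channel intervals; absent channels are
    unconstrained."""

    intervals: Mapping[str, Interval] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping | Sequence]) -> "CriteriaSet":
        """Build from plain config, e.g. ``{"66Zn": {"lo": 4, "lo_open": True},
        "31P": [60000, 80000]}``."""
        intervals = {}
        for ch, v in spec.items():
            if isinstance(v, Mapping):
                intervals[ch] = Interval(**v)
            else:
                lo, hi = v
                intervals[ch] = Interval(lo=lo, hi=hi)
        return cls(intervals=intervals)


def build_grid(aligned_sections: Sequence[SectionImage],
               manifest: RunManifest) -> VoxelGrid:
    """Stack aligned sections (anterior to posterior) into a voxel grid."""
    if not aligned_sections:
        raise ValueError("need at least one section")
    shapes = {s.shape for s in aligned_sections}
    if len(shapes) != 1:
        raise ValueError(f"sections must share one frame, got shapes {shapes}")
    first = aligned_sections[0]
    channels = tuple(first.channels)
    for s in aligned_sections:
        if tuple(s.channels) != channels:
            raise ValueError("sections must share one channel set")
    values = np.stack([
        np.stack([s.channels[ch].values for s in aligned_sections])
        for ch in channels
    ])
    mask = np.stack([s.mask for s in aligned_sections])
    units = tuple(first.channels[ch].units for ch in channels)
    spacing = (manifest.pixel_size_x, manifest.pixel_size_y,
               manifest.section_interval)
    return VoxelGrid(values=values, channels=channels, units=units,
                     spacing=spacing, mask=mask)


def histogram(grid: VoxelGrid, channel: str,
              bins: int | Sequence[float] = 64) -> ChannelHistogram:
    """Histogram of one channel over in-mask voxels only."""
    vals = grid.channel(channel)[grid.mask]
    counts, edges = np.histogram(vals, bins=bins)
    return ChannelHistogram(channel=channel, edges=edges, counts=counts)


def select(grid: VoxelGrid, criteria: CriteriaSet) -> np.ndarray:
    """Boolean voxel selection: in the tissue mask AND inside every
    channel interval of the criteria (conjunction)."""
    unknown = set(criteria.intervals) - set(grid.channels)
    if unknown:
        raise KeyError(f"criteria name unknown channel(s) {sorted(unknown)}")
    sel = grid.mask.copy()
    for ch, interval in criteria.intervals.items():
        sel &= interval.contains(grid.channel(ch))
    return sel


def smooth(grid: VoxelGrid,
           sigma: float | tuple[float, float, float]) -> VoxelGrid:
    """Mask-aware Gaussian smoothing of every channel.

    ``sigma`` is (sx, sy, sz) in voxels (a scalar applies isotropically in
    voxel units).  The convolution is normalised by the smoothed mask so
    that the 0-valued exterior does not bleed inward; sigma 0 is the
    identity.
    """
    if np.isscalar(sigma):
        s = (float(sigma),) * 3
    else:
        s = tuple(float(v) for v in sigma)
    if any(v < 0 for v in s):
        raise ValueError("sigma must be non-negative")
    if all(v == 0 for v in s):
        return VoxelGrid(values=grid.values.copy(), channels=grid.channels,
                         units=grid.units, spacing=grid.spacing,
                         mask=grid.mask.copy())
    sigma_zyx = (s[2], s[1], s[0])  # arrays are (z, y, x)
    m = grid.mask.astype(float)
    den = ndimage.gaussian_filter(m, sigma_zyx, mode="constant")
    out = np.zeros_like(grid.values)
    for c in range(grid.values.shape[0]):
        num = ndimage.gaussian_filter(grid.values[c] * m, sigma_zyx,
                                      mode="constant")
        out[c] = np.where(grid.mask, num / np.maximum(den, 1e-12), 0.0)
    return VoxelGrid(values=out, channels=grid.channels, units=grid.units,
                     spacing=grid.spacing, mask=grid.mask.copy())


# ---------------------------------------------------------------------------
# VTK export (text formats written directly; x fastest, z slowest)

def _ascii(a: np.ndarray) -> str:
    return " ".join(np.char.mod("%.9g", a.ravel(order="C")))


def export_vtk(grid: VoxelGrid, path: str | Path,
               selection: np.ndarray | None = None,
               legacy: bool = False) -> Path:
    """Write the grid as VTK XML ImageData (.vti, ASCII) for 3D viewers.

    Spacing is converted from um to mm, origin is 0; every channel becomes
    a Float32 point array, the tissue mask (or a supplied selection) a
    UInt8 0/1 array.  With ``legacy`` set, a legacy ASCII
    STRUCTURED_POINTS file is written instead.
    """
    path = Path(path)
    nz, ny, nx = grid.shape
    dx, dy, dz = (v / 1000.0 for v in grid.spacing)  # um -> mm
    mask_arr = (selection if selection is not None else grid.mask)
    mask_arr = np.asarray(mask_arr).astype(np.uint8)
    if mask_arr.shape != grid.shape:
        raise ValueError("selection shape must equal grid shape")
    arrays: list[tuple[str, str, np.ndarray]] = [
        (ch, "Float32", grid.values[i].astype(np.float32))
        for i, ch in enumerate(grid.channels)
    ]
    arrays.append(("selection" if selection is not None else "mask",
                   "UInt8", mask_arr))

    if legacy:
        lines = [
            "# vtk DataFile Version 3.0",
            "voxelgram volume",
            "ASCII",
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx} {ny} {nz}",
            "ORIGIN 0 0 0",
            f"SPACING {dx:.9g} {dy:.9g} {dz:.9g}",
            f"POINT_DATA {nx * ny * nz}",
        ]
        for name, vtype, arr in arrays:
            stype = "float" if vtype == "Float32" else "unsigned_char"
            lines.append(f"SCALARS {name} {stype} 1")
            lines.append("LOOKUP_TABLE default")
            lines.append(_ascii(arr))
        path.write_text("\n".join(lines) + "\n")
        return path

    extent = f"0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"
    root = ET.Element("VTKFile", type="ImageData", version="0.1",
                      byte_order="LittleEndian")
    img = ET.SubElement(root, "ImageData", WholeExtent=extent,
                        Origin="0 0 0",
                        Spacing=f"{dx:.9g} {dy:.9g} {dz:.9g}")
    piece = ET.SubElement(img, "Piece", Extent=extent)
    pdata = ET.SubElement(piece, "PointData")
    for name, vtype, arr in arrays:
        da = ET.SubElement(pdata, "DataArray", type=vtype, Name=name,
                           format="ascii", NumberOfComponents="1")
        da.text = _ascii(arr)
    ET.SubElement(piece, "CellData")
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    return path


def read_vti(path: str | Path) -> tuple[dict[str, np.ndarray],
                                        tuple[float, float, float],
                                        tuple[int, int, int]]:
    """Read back an ASCII .vti written by :func:`export_vtk`.

    Returns (arrays keyed by name as (nz, ny, nx), spacing in mm,
    shape (nz, ny, nx)).
    """
    root = ET.parse(Path(path)).getroot()
    img = root.find("ImageData")
    spacing = tuple(float(v) for v in img.get("Spacing").split())
    x0, x1, y0, y1, z0, z1 = (int(v) for v in img.get("WholeExtent").split())
    shape = (z1 - z0 + 1, y1 - y0 + 1, x1 - x0 + 1)
    arrays: dict[str, np.ndarray] = {}
    for da in img.find("Piece").find("PointData").findall("DataArray"):
        vals = np.array(da.text.split(), dtype=float)
        dtype = np.float32 if da.get("type") == "Float32" else np.uint8
        arrays[da.get("Name")] = vals.astype(dtype).reshape(shape)
    return arrays, spacing, shape
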