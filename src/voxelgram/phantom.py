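"""Ground-truthed synthetic phantoms for end-to-end pipeline validation.

No public serial-section LA-ICP-MS dataset with known per-slice
misalignment exists, so validation rests on a synthetic "brain-like"
multichannel volume whose every corruption is recorded:

* geometry — an outer tissue ellipsoid with a strong P baseline, an inner
  high-Zn shell (hippocampus-like), two off-axis Fe + Au hotspot spheres
  (substantia-nigra-like, the Au standing in for an immunolabel), and a
  thin high-Cu streak (ventricle-like).  Ellipsoid radii vary smoothly
  with z so consecutive sections genuinely differ, as real serial
  sections do;
* mounting — every section after the first receives an independent rigid
  perturbation (rotation and shift, uniform within stated bounds);
* sensitivity drift — quantified channels decay/grow linearly over the
  acquisition, with bracketing standards synthesised from the true
  sensitivities;
* background — a smooth positive order-2 polynomial surface per channel;
* noise and spikes — additive Gaussian noise plus isolated single-pixel
  spikes at a stated rate, all positions recorded.

Region interiors sit exactly at their stated level before noise; region
edges carry a short decaying skirt *outside* the boundary so that images
are band-limited the way a finite laser spot renders real tissue edges
(a hard step would be indistinguishable from detector artefacts for any
local-neighbourhood despiking rule).  Within-tissue feature contrast is
kept below the 5x despiking factor for the same physical reason.

Named random substreams (transforms / noise / spikes) hang off the single
seed so that disabling one corruption does not shift the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial import ConvexHull

from .correct import StandardMeasurement
from .rawio import ChannelImage, RunManifest, save_manifest
from .register import (RegistrationResult, RigidTransform2D, warp_mask,
                       warp_values)
from .sections import SectionImage, SectionSpec

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_volume",
    "slice_and_corrupt",
    "write_fixtures",
    "recovery_score",
    "RecoveryScore",
    "dual_feature_stack",
]

#: Region label codes in the truth volume.
BACKGROUND, TISSUE, ZN_SHELL, FE_HOTSPOT, CU_STREAK, FIBER_TRACT = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic serial-section experiment.

    Channel levels are in source units: ug/g for channels with tissue
    standards (Fe, Cu, Zn), CPS for unquantified channels (P, Au).
    ``drift`` is the post/pre sensitivity ratio over the whole series;
    channels without standards carry no drift (there is nothing to correct
    it against).  Spike amplitude is ``spike_factor`` x the channel's CPS
    scale; ``spike_rate`` is expected spikes per 1000 pixels.
    """

    nz: int = 24
    ny: int = 128
    nx: int = 128
    spot_size: float = 80.0
    scan_speed: float = 320.0
    acquisition_period: float = 0.25
    line_spacing: float = 80.0
    section_interval: float = 90.0
    channels: tuple[str, ...] = ("31P", "56Fe", "63Cu", "66Zn", "197Au")
    # region intensity levels per channel:
    # (tissue, zn_shell, fe_hotspot, cu_streak, fiber_tract)
    levels: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "31P": (62_000.0, 78_000.0, 70_000.0, 48_000.0, 42_000.0),
            "56Fe": (8.0, 8.0, 30.0, 8.0, 12.0),
            "63Cu": (0.5, 0.5, 0.5, 2.0, 0.8),
            "66Zn": (2.5, 9.0, 2.5, 2.5, 3.2),
            "197Au": (80.0, 80.0, 300.0, 80.0, 80.0),
        })
    sensitivities: Mapping[str, float] = field(
        default_factory=lambda: {"56Fe": 350.0, "63Cu": 900.0, "66Zn": 500.0})
    drift: Mapping[str, float] = field(
        default_factory=lambda: {"56Fe": 0.85, "63Cu": 1.10, "66Zn": 0.92})
    standard_concentrations: Mapping[str, float] = field(
        default_factory=lambda: {"56Fe": 20.0, "63Cu": 10.0, "66Zn": 15.0})
    theta_max: float = 10.0       # degrees
    shift_max: float = 6.0        # pixels
    background_amplitude: float = 0.05   # fraction of channel CPS scale
    noise_sigma: float = 0.01            # fraction of channel CPS scale
    spike_rate: float = 0.5              # per kilopixel
    spike_factor: float = 10.0           # x channel CPS scale
    edge_softness: float = 2.0           # px, decaying skirt outside regions
    texture_amplitude: float = 0.08      # fraction of tissue level
    texture_scale: tuple[float, float, float] = (1.5, 2.5, 2.5)  # sigma (z, y, x)
    z_uniform: bool = False              # identical sections (closure testing)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_max < 0 or self.shift_max < 0:
            raise ValueError("perturbation bounds must be >= 0")
        for name in ("background_amplitude", "noise_sigma", "spike_rate",
                     "spike_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def manifest(self) -> RunManifest:
        return RunManifest(
            spot_size=self.spot_size, scan_speed=self.scan_speed,
            acquisition_period=self.acquisition_period,
            line_spacing=self.line_spacing,
            section_interval=self.section_interval,
            isotopes=self.channels,
            standard_concentrations=dict(self.standard_concentrations),
            concatenated=True)

    def cps_scale(self, iso: str) -> float:
        """Peak expected CPS for a channel (level x sensitivity)."""
        peak = max(self.levels[iso])
        return peak * self.sensitivities.get(iso, 1.0)


@dataclass
class PhantomTruth:
    """Complete corruption record of one synthetic experiment."""

    clean: np.ndarray                 # (C, nz, ny, nx), source units
    labels: np.ndarray                # (nz, ny, nx) region codes
    transforms: list[RigidTransform2D]  # aligning transform per slice
    sensitivities: dict[str, tuple[float, float]]  # iso -> (pre, post) of series
    spikes: list[tuple[str, int, int, int]]  # (isotope, z, row, col)
    spec: PhantomSpec


def _region_masks(spec: PhantomSpec) -> dict[int, np.ndarray]:
    nz, ny, nx = spec.nz, spec.ny, spec.nx
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                          indexing="ij")
    zc, yc, xc = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    # smooth z-dependent shrink so consecutive sections differ; total
    # radius variation ~2% over the stack, as for closely spaced sections
    if spec.z_uniform:
        g = np.ones_like(z, dtype=float)
    else:
        g = np.sqrt(1.0 - 0.04 * ((z - zc) / (nz / 2.0)) ** 2)
    ry, rx = 0.33 * ny * g, 0.41 * nx * g
    rho = ((y - yc) / ry) ** 2 + ((x - xc) / rx) ** 2
    tissue = rho <= 1.0

    shell_rho = (((y - (yc - 0.06 * ny)) / (0.62 * ry)) ** 2
                 + ((x - xc) / (0.66 * rx)) ** 2)
    zfrac = z / max(nz - 1, 1)
    shell = (shell_rho <= 1.0) & (shell_rho >= 0.45) & tissue
    if not spec.z_uniform:
        shell &= (zfrac >= 0.25) & (zfrac <= 0.85)

    hot = np.zeros_like(tissue)
    r_hot = 0.055 * min(ny, nx)
    for sx in (-1, 1):
        d2 = (((y - (yc + 0.16 * ny)) / r_hot) ** 2
              + ((x - (xc + sx * 0.16 * nx)) / r_hot) ** 2)
        if not spec.z_uniform:
            d2 = d2 + ((z - 0.68 * (nz - 1)) / (0.22 * nz)) ** 2
        hot |= d2 <= 1.0
    hot &= tissue

    streak = (np.abs(x - xc) <= 1.5) & (np.abs(y - yc) <= 0.28 * ny) & tissue

    # white-matter-like tracts running the full z-range at asymmetric
    # off-axis positions: every section has rotation-identifying anatomy
    r_fib = 0.05 * min(ny, nx)
    fiber = np.zeros_like(tissue)
    for fy, fx in ((-0.17, -0.24), (0.08, 0.27)):
        fiber |= (((y - (yc + fy * ny)) / r_fib) ** 2
                  + ((x - (xc + fx * nx)) / r_fib) ** 2) <= 1.0
    fiber &= tissue

    return {TISSUE: tissue, ZN_SHELL: shell, FE_HOTSPOT: hot,
            CU_STREAK: streak, FIBER_TRACT: fiber}


def _soften_edges(slice_vals: np.ndarray, inside: np.ndarray,
                  softness: float) -> np.ndarray:
    """Add a decaying skirt outside the tissue boundary of one 2D slice.

    Interior values are untouched; each outside pixel within ``softness``
    pixels of the boundary takes the nearest inside value scaled by a
    linear falloff.
    """
    if softness <= 0 or inside.all() or not inside.any():
        return slice_vals
    dist, (ir, ic) = ndimage.distance_transform_edt(~inside,
                                                    return_indices=True)
    falloff = np.clip(1.0 - dist / (softness + 1.0), 0.0, 1.0)
    out = slice_vals.copy()
    outside = ~inside
    out[outside] = slice_vals[ir[outside], ic[outside]] * falloff[outside]
    return out


def make_volume(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the clean multichannel volume and its region-label volume.

    Deterministic; region interiors sit exactly at their configured level.
    """
    masks = _region_masks(spec)
    if not masks[TISSUE].any():
        raise ValueError("tissue region is empty; check grid shape")
    labels = np.zeros((spec.nz, spec.ny, spec.nx), dtype=np.int8)
    for code in (TISSUE, ZN_SHELL, FE_HOTSPOT, CU_STREAK, FIBER_TRACT):
        labels[masks[code]] = code

    # smooth z-continuous "cell density" texture: real elemental images
    # carry fine structure everywhere, which is what anchors registration
    rng = np.random.default_rng(spec.seed)
    volume = np.zeros((len(spec.channels), spec.nz, spec.ny, spec.nx))
    regions = (TISSUE, ZN_SHELL, FE_HOTSPOT, CU_STREAK, FIBER_TRACT)
    for ci, iso in enumerate(spec.channels):
        lv = spec.levels[iso]
        chan = np.zeros(labels.shape)
        for code, level in zip(regions, lv):
            chan[labels == code] = level
        if spec.texture_amplitude > 0:
            if spec.z_uniform:
                plane = ndimage.gaussian_filter(
                    rng.standard_normal(labels.shape[1:]),
                    spec.texture_scale[1:])
                field = np.broadcast_to(plane, labels.shape).copy()
            else:
                field = ndimage.gaussian_filter(
                    rng.standard_normal(labels.shape), spec.texture_scale)
            field /= max(field.std(), 1e-12)
            amp = spec.texture_amplitude * lv[0]
            tex = amp * field
            # re-centre per region so region means stay exactly at level
            for code in regions:
                sel = labels == code
                if sel.any():
                    chan[sel] += tex[sel] - tex[sel].mean()
        for z in range(spec.nz):
            chan[z] = _soften_edges(chan[z], masks[TISSUE][z],
                                    spec.edge_softness)
        volume[ci] = chan
    return volume, labels


def _sensitivity(spec: PhantomSpec, iso: str, z: int, row: int) -> float:
    """True sensitivity at a given slice and scan line (global linear drift)."""
    s0 = spec.sensitivities.get(iso)
    if s0 is None:
        return 1.0
    d = spec.drift.get(iso, 1.0)
    t = (z * spec.ny + row) / max(spec.nz * spec.ny - 1, 1)
    return s0 * (1.0 + (d - 1.0) * t)


def _background_surface(spec: PhantomSpec, iso: str) -> np.ndarray:
    """Fixed positive order-2 polynomial background in CPS."""
    amp = spec.background_amplitude * spec.cps_scale(iso)
    y, x = np.meshgrid(np.linspace(-1, 1, spec.ny),
                       np.linspace(-1, 1, spec.nx), indexing="ij")
    return amp * (0.6 + 0.25 * x + 0.15 * y + 0.1 * x * x
                  - 0.08 * x * y + 0.05 * y * y)


def background_regions(spec: PhantomSpec) -> list[tuple[int, int, int, int]]:
    """Four tissue-free corner rectangles (row0, col0, height, width)."""
    s = max(8, min(spec.ny, spec.nx) // 8)
    return [(0, 0, s, s), (0, spec.nx - s, s, s),
            (spec.ny - s, 0, s, s), (spec.ny - s, spec.nx - s, s, s)]


def _mask_hull(mask: np.ndarray, margin: int = 2) -> list[tuple[float, float]]:
    """Convex hull polygon (x, y vertices) of a dilated tissue mask."""
    grown = ndimage.binary_dilation(mask, iterations=margin)
    pts = np.argwhere(grown)[:, ::-1].astype(float)  # (x, y)
    hull = ConvexHull(pts)
    return [tuple(pts[v]) for v in hull.vertices]


def slice_and_corrupt(volume: np.ndarray, labels: np.ndarray,
                      spec: PhantomSpec) -> tuple[list[dict], PhantomTruth]:
    """Turn the clean volume into corrupted per-section line-scan data.

    Returns one record per section — ``channels`` (isotope -> 2D CPS
    array), ``standards`` (bracketing :class:`StandardMeasurement` list)
    and ``mask_polygon`` (convex hull of the mounted tissue) — plus the
    complete :class:`PhantomTruth`.  Slice 0 keeps the identity mounting
    so the chained registration is anchored to the absolute frame.
    """
    seq = np.random.SeedSequence(spec.seed)
    rng_t, rng_n, rng_s = (np.random.default_rng(s) for s in seq.spawn(3))
    nz, ny, nx = labels.shape
    centre = ((nx - 1) / 2.0, (ny - 1) / 2.0)

    transforms: list[RigidTransform2D] = []
    spikes: list[tuple[str, int, int, int]] = []
    sections: list[dict] = []
    for z in range(nz):
        if z == 0 or (spec.theta_max == 0 and spec.shift_max == 0):
            t_align = RigidTransform2D(centre=centre)
        else:
            t_align = RigidTransform2D(
                theta=float(rng_t.uniform(-spec.theta_max, spec.theta_max)),
                tx=float(rng_t.uniform(-spec.shift_max, spec.shift_max)),
                ty=float(rng_t.uniform(-spec.shift_max, spec.shift_max)),
                centre=centre)
        transforms.append(t_align)
        mount = t_align.inverse()
        tissue = labels[z] > 0

        channels: dict[str, np.ndarray] = {}
        standards: list[StandardMeasurement] = []
        for ci, iso in enumerate(spec.channels):
            plane = volume[ci, z]
            mounted = np.maximum(warp_values(plane, mount, order=3), 0.0)
            s_rows = np.array([_sensitivity(spec, iso, z, r)
                               for r in range(ny)])
            cps = mounted * s_rows[:, None]
            cps = cps + _background_surface(spec, iso)
            if spec.noise_sigma > 0:
                cps = cps + rng_n.normal(
                    0.0, spec.noise_sigma * spec.cps_scale(iso), cps.shape)
                cps = np.maximum(cps, 0.0)
            if spec.spike_rate > 0:
                n_sp = rng_s.binomial(ny * nx, spec.spike_rate / 1000.0)
                placed: list[tuple[int, int]] = []
                attempts = 0
                while len(placed) < n_sp and attempts < 50 * max(n_sp, 1):
                    attempts += 1
                    r = int(rng_s.integers(0, ny))
                    c = int(rng_s.integers(0, nx))
                    if all(max(abs(r - pr), abs(c - pc)) > 4
                           for pr, pc in placed):
                        placed.append((r, c))
                for r, c in placed:
                    cps[r, c] += spec.spike_factor * spec.cps_scale(iso)
                    spikes.append((iso, z, r, c))
            channels[iso] = cps
            if iso in spec.sensitivities:
                conc = spec.standard_concentrations[iso]
                s_pre = _sensitivity(spec, iso, z, 0)
                s_post = _sensitivity(spec, iso, z, ny - 1)
                standards.append(StandardMeasurement(
                    isotope=iso, mean_cps=s_pre * conc, concentration=conc,
                    position="pre"))
                standards.append(StandardMeasurement(
                    isotope=iso, mean_cps=s_post * conc, concentration=conc,
                    position="post"))
        mounted_tissue = warp_mask(tissue, mount)
        sections.append({
            "channels": channels,
            "standards": standards,
            "mask_polygon": _mask_hull(mounted_tissue,
                                       margin=int(spec.edge_softness) + 1),
        })

    sens = {iso: (_sensitivity(spec, iso, 0, 0),
                  _sensitivity(spec, iso, nz - 1, ny - 1))
            for iso in spec.sensitivities}
    truth = PhantomTruth(clean=volume, labels=labels, transforms=transforms,
                         sensitivities=sens, spikes=spikes, spec=spec)
    return sections, truth


def write_fixtures(sections: list[dict], truth: PhantomTruth,
                   out_dir: str | Path) -> Path:
    """Write a fixture set in the concatenated line-scan CSV dialect.

    Produces ``section_##.csv`` files, a run ``manifest.yaml`` carrying
    background regions, per-section standards and mask polygons, and a
    ``truth.yaml`` with the recorded transforms, sensitivities and spike
    coordinates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = truth.spec
    files = []
    for k, sec in enumerate(sections):
        ny = next(iter(sec["channels"].values())).shape[0]
        frames = []
        for r in range(ny):
            df = pd.DataFrame({iso: sec["channels"][iso][r]
                               for iso in spec.channels})
            df.insert(0, "Line", r)
            frames.append(df)
        path = out / f"section_{k:02d}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        files.append(path.name)
    extra = {
        "section_files": files,
        "background_regions": [list(r) for r in background_regions(spec)],
        "sections": [
            {"order_index": k,
             "standards": [
                 {"isotope": s.isotope, "mean_cps": s.mean_cps,
                  "concentration": s.concentration, "position": s.position}
                 for s in sec["standards"]],
             "mask_polygon": [[float(a), float(b)]
                              for a, b in sec["mask_polygon"]]}
            for k, sec in enumerate(sections)],
    }
    save_manifest(spec.manifest(), out / "manifest.yaml", extra=extra)
    truth_doc = {
        "transforms": [{"theta_deg": t.theta, "tx_px": t.tx, "ty_px": t.ty,
                        "centre": list(t.centre)} for t in truth.transforms],
        "sensitivities": {k: list(v) for k, v in truth.sensitivities.items()},
        "spikes": [list(s) for s in truth.spikes],
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=False))
    return out


def sections_as_runs(sections: list[dict], spec: PhantomSpec,
                     ) -> list[SectionImage]:
    """Wrap in-memory corrupted sections as raw (unmasked) SectionImages."""
    out = []
    for k, sec in enumerate(sections):
        channels = {
            iso: ChannelImage(values=v, isotope=iso, units="CPS",
                              pixel_size_x=spec.scan_speed * spec.acquisition_period,
                              pixel_size_y=spec.line_spacing)
            for iso, v in sec["channels"].items()}
        shape = next(iter(channels.values())).shape
        spec_k = SectionSpec(order_index=k, bbox=(0, 0, *shape),
                             z_position=k * spec.section_interval)
        out.append(SectionImage(channels=channels,
                                mask=np.ones(shape, dtype=bool), spec=spec_k))
    return out


@dataclass
class RecoveryScore:
    """Per-slice registration error against recorded truth."""

    theta_errors: np.ndarray      # degrees, absolute
    translation_errors: np.ndarray  # pixels, Euclidean
    theta_tol: float = 0.5
    trans_tol: float = 1.0

    @property
    def mean_theta(self) -> float:
        return float(self.theta_errors.mean())

    @property
    def max_theta(self) -> float:
        return float(self.theta_errors.max())

    @property
    def mean_translation(self) -> float:
        return float(self.translation_errors.mean())

    @property
    def max_translation(self) -> float:
        return float(self.translation_errors.max())

    @property
    def fraction_recovered(self) -> float:
        ok = ((self.theta_errors <= self.theta_tol)
              & (self.translation_errors <= self.trans_tol))
        return float(ok.mean())


def recovery_score(truth: PhantomTruth | Sequence[RigidTransform2D],
                   results: Sequence[RegistrationResult | RigidTransform2D],
                   theta_tol: float = 0.5, trans_tol: float = 1.0,
                   ) -> RecoveryScore:
    """Compare recovered aligning transforms against recorded truth.

    ``results`` holds one entry per non-first slice (the first slice is
    the anchored identity); truth supplies one transform per slice.
    """
    true_ts = truth.transforms if isinstance(truth, PhantomTruth) else list(truth)
    rec_ts = [r.transform if isinstance(r, RegistrationResult) else r
              for r in results]
    if len(rec_ts) == len(true_ts):       # truth may include the anchor slice
        true_ts = true_ts
    elif len(rec_ts) == len(true_ts) - 1:
        true_ts = true_ts[1:]
    else:
        raise ValueError(
            f"{len(rec_ts)} results cannot be matched to {len(true_ts)} truths")
    th = np.array([abs(r.theta - t.theta) for r, t in zip(rec_ts, true_ts)])
    tr = np.array([np.hypot(r.tx - t.tx, r.ty - t.ty)
                   for r, t in zip(rec_ts, true_ts)])
    return RecoveryScore(theta_errors=th, translation_errors=tr,
                         theta_tol=theta_tol, trans_tol=trans_tol)


def dual_feature_stack(n_sections: int = 12, size: int = 96,
                       theta_max: float = 8.0, shift_max: float = 5.0,
                       seed: int = 0) -> tuple[list[SectionImage],
                                               list[RigidTransform2D]]:
    """A two-channel stack where channel A carries sharp features only in
    the first half of the slices and channel B only in the second half.

    Both channels share a smooth elliptical base (weak rotational
    information), so single-channel alignment degrades on its featureless
    half while the 50:50 composite has features throughout — the scenario
    in which a combined alignment channel beats either single channel.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    c = (size - 1) / 2.0
    base = np.exp(-(((yy - c) / (0.30 * size)) ** 2
                    + ((xx - c) / (0.36 * size)) ** 2)) * 120.0
    blob_at = lambda by, bx: 135.0 * np.exp(
        -(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * (0.035 * size) ** 2)))
    features = (blob_at(c - 0.22 * size, c - 0.16 * size)
                + blob_at(c + 0.18 * size, c + 0.20 * size)
                + blob_at(c - 0.05 * size, c + 0.24 * size))
    centre = (c, c)
    half = n_sections // 2
    sections, truths = [], []
    for k in range(n_sections):
        A = base + (features if k < half else 0.0)
        B = base + (features if k >= half else 0.0)
        if k == 0:
            t_align = RigidTransform2D(centre=centre)
        else:
            t_align = RigidTransform2D(
                theta=float(rng.uniform(-theta_max, theta_max)),
                tx=float(rng.uniform(-shift_max, shift_max)),
                ty=float(rng.uniform(-shift_max, shift_max)), centre=centre)
        mount = t_align.inverse()
        channels = {
            "A": ChannelImage(np.maximum(warp_values(A, mount, order=3), 0.0),
                              isotope="A"),
            "B": ChannelImage(np.maximum(warp_values(B, mount, order=3), 0.0),
                              isotope="B"),
        }
        spec_k = SectionSpec(order_index=k, bbox=(0, 0, size, size))
        sections.append(SectionImage(channels=channels,
                                     mask=np.ones((size, size), dtype=bool),
                                     spec=spec_k))
        truths.append(t_align)
    return sections, truths
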