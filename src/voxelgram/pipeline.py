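"""End-to-end orchestration: corrupted line scans in, voxel volume out.

The stages run in acquisition-physics order: despiking on raw counts
(spikes are detector artefacts in the raw stream), polynomial background
removal, per-line calibration against the bracketing standards, tissue
masking, chained pyramidal registration on a composite alignment channel,
and finally voxel-grid assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import correct, register, sections as sect, voxel
from .correct import BackgroundRegion, StandardMeasurement
from .phantom import PhantomTruth
from .rawio import RunManifest, load_manifest, read_line_files
from .register import PyramidConfig, RegistrationResult
from .sections import SectionImage
from .voxel import VoxelGrid

__all__ = ["PipelineOptions", "preprocess_sections", "reconstruct",
           "load_fixture_sections", "reconstruction_error"]


@dataclass
class PipelineOptions:
    """Stage settings for the end-to-end reduction.

    ``despike_floor`` None means automatic: 10% of the image's 99th
    percentile.  The spike rule fires when a pixel exceeds
    ``factor x local median + floor``; wherever the neighbourhood median
    is ~0 (outside tissue) a purely multiplicative rule would flag any
    positive pixel, so the floor restricts despiking to pixels that are
    also non-trivial on the image's own intensity scale.
    """

    despike: bool = True
    despike_window: int = 9
    despike_factor: float = 5.0
    despike_floor: float | None = None
    background_order: int = 2
    clamp_negative: bool = False
    alignment_channels: tuple[str, ...] = ("31P", "197Au")
    alignment_weights: tuple[float, ...] | None = None
    register: bool = True
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)


def preprocess_sections(raw_sections: Sequence[SectionImage],
                        bg_regions: Sequence[BackgroundRegion],
                        standards: Sequence[Sequence[StandardMeasurement]],
                        mask_polygons: Sequence[Sequence[tuple[float, float]]],
                        options: PipelineOptions | None = None,
                        ) -> list[SectionImage]:
    """Despike, background-subtract, calibrate and mask every section."""
    options = options or PipelineOptions()
    if len(standards) != len(raw_sections):
        raise ValueError("one standards list per section required")
    if len(mask_polygons) != len(raw_sections):
        raise ValueError("one mask polygon per section required")
    out = []
    for section, stds, poly in zip(raw_sections, standards, mask_polygons):
        channels = {}
        for iso, img in section.channels.items():
            if options.despike:
                floor = options.despike_floor
                if floor is None:
                    floor = 0.1 * float(np.percentile(img.values, 99))
                img, _ = correct.despike(
                    img, window=options.despike_window,
                    factor=options.despike_factor, floor=floor)
            model = correct.fit_background(img, bg_regions,
                                           order=options.background_order)
            channels[iso] = correct.subtract_background(
                img, model, clamp_negative=options.clamp_negative)
        channels, _ = correct.calibrate_run(channels, stds)
        cleaned = SectionImage(channels=channels, mask=section.mask.copy(),
                               spec=section.spec)
        out.append(sect.apply_mask(cleaned, poly))
    return sect.pad_to_common_frame(out)


def reconstruct(raw_sections: Sequence[SectionImage],
                manifest: RunManifest,
                bg_regions: Sequence[BackgroundRegion],
                standards: Sequence[Sequence[StandardMeasurement]],
                mask_polygons: Sequence[Sequence[tuple[float, float]]],
                options: PipelineOptions | None = None,
                ) -> tuple[VoxelGrid, list[RegistrationResult]]:
    """Run the full reduction chain and assemble the voxel grid."""
    options = options or PipelineOptions()
    prepped = preprocess_sections(raw_sections, bg_regions, standards,
                                  mask_polygons, options)
    if options.register and len(prepped) > 1:
        results = register.register_stack(
            prepped, options.alignment_channels,
            weights=options.alignment_weights, config=options.pyramid)
        aligned = register.apply_results(prepped, results)
    else:
        results = []
        aligned = [s.copy() for s in prepped]
    grid = voxel.build_grid(aligned, manifest)
    return grid, results


def load_fixture_sections(fixture_dir: str | Path,
                          ) -> tuple[list[SectionImage], RunManifest,
                                     list[BackgroundRegion],
                                     list[list[StandardMeasurement]],
                                     list[list[tuple[float, float]]]]:
    """Load a written fixture set (manifest + per-section CSVs) back into
    the in-memory structures :func:`reconstruct` consumes."""
    from .sections import SectionSpec

    fixture_dir = Path(fixture_dir)
    manifest, aux = load_manifest(fixture_dir / "manifest.yaml")
    bg_regions = [BackgroundRegion(rect=tuple(r))
                  for r in aux["background_regions"]]
    raw_sections, standards, polygons = [], [], []
    for rec in aux["sections"]:
        k = rec["order_index"]
        run = read_line_files([fixture_dir / aux["section_files"][k]], manifest)
        shape = run.shape
        spec_k = SectionSpec(order_index=k, bbox=(0, 0, *shape),
                             z_position=k * manifest.section_interval)
        raw_sections.append(SectionImage(
            channels=run.channels, mask=np.ones(shape, dtype=bool),
            spec=spec_k))
        standards.append([StandardMeasurement(**s) for s in rec["standards"]])
        polygons.append([tuple(v) for v in rec["mask_polygon"]])
    return raw_sections, manifest, bg_regions, standards, polygons


def reconstruction_error(grid: VoxelGrid, truth: PhantomTruth) -> dict[str, float]:
    """Relative RMS error of the reconstructed volume against phantom truth.

    Per channel: ||recon - clean|| / ||clean|| over true tissue voxels
    (quantified channels compare in ug/g, unquantified in CPS — both are
    the phantom's source units).  The ``overall`` entry pools channels.
    """
    mask = truth.labels > 0
    errors: dict[str, float] = {}
    num_tot = den_tot = 0.0
    for i, ch in enumerate(grid.channels):
        ci = truth.spec.channels.index(ch)
        diff = grid.values[i][mask] - truth.clean[ci][mask]
        ref = truth.clean[ci][mask]
        num, den = float(np.sum(diff ** 2)), float(np.sum(ref ** 2))
        errors[ch] = np.sqrt(num / den) if den > 0 else float("nan")
        scale = den / mask.sum()
        num_tot += num / scale
        den_tot += den / scale
    errors["overall"] = float(np.sqrt(num_tot / den_tot))
    return errors
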