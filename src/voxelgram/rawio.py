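"""Line-scan CSV ingestion and 2D image export for LA-ICP-MS runs.

A laser-ablation ICP-MS run rasters the sample line by line; the mass
spectrometer emits one delimited text file per ablation line (or a single
concatenated file with a line-index column), with one intensity column per
measured m/z channel.  Stacking the lines as rows yields one 2D image per
isotope.  Pixel geometry follows from the acquisition parameters:
``pixel_size_x = scan_speed * acquisition_period`` along the scan direction
and ``pixel_size_y = line_spacing`` between lines.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "RunManifest",
    "ChannelImage",
    "RawRun",
    "FormatError",
    "ChannelMissingError",
    "read_line_files",
    "read_concatenated_file",
    "export_channel",
    "import_channel",
    "load_manifest",
    "save_manifest",
]

#: Recognised intensity units.
UNITS = ("CPS", "ug/g", "dimensionless")


class FormatError(ValueError):
    """Raised when an input file does not parse as line-scan data."""


class ChannelMissingError(KeyError):
    """Raised when a manifest isotope has no matching column in the data."""


@dataclass(frozen=True)
class RunManifest:
    """Acquisition geometry and calibration bookkeeping for one run.

    Lengths are in micrometres, speeds in um/s, times in seconds.
    ``standard_concentrations`` maps isotope label to the reference-material
    concentration in ug/g; isotopes absent from the map are left
    unquantified downstream.
    """

    spot_size: float
    scan_speed: float
    acquisition_period: float
    line_spacing: float
    section_interval: float
    isotopes: tuple[str, ...]
    standard_concentrations: Mapping[str, float] = field(default_factory=dict)
    concatenated: bool = False
    line_column: str = "Line"

    def __post_init__(self) -> None:
        for name in ("spot_size", "scan_speed", "acquisition_period",
                     "line_spacing", "section_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if len(set(self.isotopes)) != len(self.isotopes):
            raise ValueError("isotope labels must be unique")
        if not self.isotopes:
            raise ValueError("manifest must name at least one isotope")

    @property
    def pixel_size_x(self) -> float:
        """Along-scan pixel size, um."""
        return self.scan_speed * self.acquisition_period

    @property
    def pixel_size_y(self) -> float:
        """Line-to-line pixel size, um."""
        return self.line_spacing


@dataclass
class ChannelImage:
    """One isotope's 2D intensity image.

    ``values`` is a rows x cols float array; row index is the ablation line
    (y), column index the along-scan position (x), both 0-based.
    """

    values: np.ndarray
    isotope: str
    units: str = "CPS"
    pixel_size_x: float = 1.0
    pixel_size_y: float = 1.0
    row_timestamps: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray, units: str | None = None,
                  **meta) -> "ChannelImage":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return ChannelImage(
            values=np.asarray(values, dtype=float),
            isotope=self.isotope,
            units=self.units if units is None else units,
            pixel_size_x=self.pixel_size_x,
            pixel_size_y=self.pixel_size_y,
            row_timestamps=self.row_timestamps,
            meta=new_meta,
        )


@dataclass
class RawRun:
    """All channel images of one run plus provenance.

    ``provenance`` records the source files and any pad/truncate events
    applied while reconciling ragged lines.
    """

    manifest: RunManifest
    channels: dict[str, ChannelImage]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.channels) != set(self.manifest.isotopes):
            raise ValueError("channel set must equal manifest isotopes")
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel grids are not congruent: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _read_table(path: Path, delimiter: str | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: file contains no data rows")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _check_header(df: pd.DataFrame, manifest: RunManifest, path: Path) -> None:
    missing = [iso for iso in manifest.isotopes if iso not in df.columns]
    if missing:
        raise ChannelMissingError(
            f"{path}: manifest isotope(s) {missing} not found in header "
            f"{list(df.columns)}")


def _reconcile(rows: list[np.ndarray], log: list[dict], isotope: str) -> np.ndarray:
    """Pad/truncate ragged lines to the modal length, logging every event."""
    lengths = [len(r) for r in rows]
    modal = Counter(lengths).most_common(1)[0][0]
    out = np.zeros((len(rows), modal), dtype=float)
    for i, r in enumerate(rows):
        if len(r) == modal:
            out[i] = r
        elif len(r) < modal:
            out[i, :len(r)] = r
            log.append({"isotope": isotope, "row": i, "action": "pad",
                        "n_pixels": modal - len(r)})
        else:
            out[i] = r[:modal]
            log.append({"isotope": isotope, "row": i, "action": "truncate",
                        "n_pixels": len(r) - modal})
    return out


def read_line_files(paths: Sequence[str | Path], manifest: RunManifest,
                    delimiter: str | None = None) -> RawRun:
    """Parse one-file-per-ablation-line CSV output into a :class:`RawRun`.

    Row *i* of every channel image comes from ``paths[i]``.  Ragged line
    lengths are reconciled to the modal length: shorter lines are padded
    with 0 (background) and longer ones truncated, each event logged in
    the run provenance.  With ``manifest.concatenated`` set, a single file
    holding all lines (distinguished by ``manifest.line_column``) is
    accepted instead.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise FormatError("at least one line file is required")
    if manifest.concatenated:
        if len(paths) != 1:
            raise FormatError("concatenated dialect expects exactly one file")
        return read_concatenated_file(paths[0], manifest, delimiter=delimiter)

    header: list[str] | None = None
    per_channel_rows: dict[str, list[np.ndarray]] = {iso: [] for iso in manifest.isotopes}
    times: list[float] = []
    for path in paths:
        df = _read_table(path, delimiter)
        _check_header(df, manifest, path)
        cols = list(df.columns)
        if header is None:
            header = cols
        elif cols != header:
            raise FormatError(
                f"{path}: header {cols} differs from first file's {header}")
        for iso in manifest.isotopes:
            per_channel_rows[iso].append(df[iso].to_numpy(dtype=float))
        time_cols = [c for c in cols if c.lower() in ("time", "time [s]", "t")]
        if time_cols:
            times.append(float(df[time_cols[0]].iloc[0]))

    log: list[dict] = []
    row_ts = np.asarray(times, dtype=float) if len(times) == len(paths) else None
    channels = {
        iso: ChannelImage(
            values=_reconcile(per_channel_rows[iso], log, iso),
            isotope=iso,
            units="CPS",
            pixel_size_x=manifest.pixel_size_x,
            pixel_size_y=manifest.pixel_size_y,
            row_timestamps=row_ts,
        )
        for iso in manifest.isotopes
    }
    provenance = {"source_files": [str(p) for p in paths], "reconcile_log": log}
    return RawRun(manifest=manifest, channels=channels, provenance=provenance)


def read_concatenated_file(path: str | Path, manifest: RunManifest,
                           delimiter: str | None = None) -> RawRun:
    """Parse a single concatenated line-scan file (line-index column)."""
    path = Path(path)
    df = _read_table(path, delimiter)
    _check_header(df, manifest, path)
    if manifest.line_column not in df.columns:
        raise FormatError(
            f"{path}: line-index column {manifest.line_column!r} not found")
    log: list[dict] = []
    groups = [g for _, g in df.groupby(manifest.line_column, sort=True)]
    channels = {}
    for iso in manifest.isotopes:
        rows = [g[iso].to_numpy(dtype=float) for g in groups]
        channels[iso] = ChannelImage(
            values=_reconcile(rows, log, iso),
            isotope=iso,
            units="CPS",
            pixel_size_x=manifest.pixel_size_x,
            pixel_size_y=manifest.pixel_size_y,
        )
    provenance = {"source_files": [str(path)], "reconcile_log": log}
    return RawRun(manifest=manifest, channels=channels, provenance=provenance)


# ---------------------------------------------------------------------------
# single-channel image export / import

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def export_channel(image: ChannelImage, path: str | Path,
                   format: str = "tiff") -> Path:
    """Write one channel image to float TIFF or plain CSV.

    A JSON sidecar (``<file>.meta.json``) carries units, pixel sizes and
    the isotope label so that :func:`import_channel` round-trips exactly.
    NaNs must be resolved (masked) before export.
    """
    path = Path(path)
    if not np.all(np.isfinite(image.values)):
        raise ValueError("image contains non-finite values; resolve masks first")
    fmt = format.lower()
    if fmt in ("tiff", "tif", "float-tiff"):
        tifffile.imwrite(path, image.values.astype(np.float32))
    elif fmt == "csv":
        np.savetxt(path, image.values, delimiter=",", fmt="%.17g")
    else:
        raise ValueError(f"unsupported format {format!r}; use 'tiff' or 'csv'")
    meta = {
        "isotope": image.isotope,
        "units": image.units,
        "pixel_size_x": image.pixel_size_x,
        "pixel_size_y": image.pixel_size_y,
        "format": fmt,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def import_channel(path: str | Path) -> ChannelImage:
    """Read back a channel image written by :func:`export_channel`."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if meta["format"] in ("tiff", "tif", "float-tiff"):
        values = tifffile.imread(path).astype(float)
    else:
        values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return ChannelImage(
        values=values,
        isotope=meta["isotope"],
        units=meta["units"],
        pixel_size_x=meta["pixel_size_x"],
        pixel_size_y=meta["pixel_size_y"],
    )


# ---------------------------------------------------------------------------
# manifest I/O (YAML)

def load_manifest(path: str | Path) -> tuple[RunManifest, dict]:
    """Load a YAML run manifest.

    Returns the :class:`RunManifest` plus a dict of auxiliary blocks the
    manifest file may carry (``standards``, ``background_regions``,
    ``sections`` ...), passed through untouched for the relevant modules.
    """
    raw = yaml.safe_load(Path(path).read_text())
    keys = ("spot_size", "scan_speed", "acquisition_period", "line_spacing",
            "section_interval")
    kwargs = {k: float(raw[k]) for k in keys}
    kwargs["isotopes"] = tuple(raw["isotopes"])
    kwargs["standard_concentrations"] = {
        str(k): float(v) for k, v in (raw.get("standard_concentrations") or {}).items()}
    kwargs["concatenated"] = bool(raw.get("concatenated", False))
    kwargs["line_column"] = str(raw.get("line_column", "Line"))
    manifest = RunManifest(**kwargs)
    aux = {k: v for k, v in raw.items()
           if k not in set(keys) | {"isotopes", "standard_concentrations",
                                    "concatenated", "line_column"}}
    return manifest, aux


def save_manifest(manifest: RunManifest, path: str | Path,
                  extra: Mapping | None = None) -> Path:
    path = Path(path)
    doc = {
        "spot_size": manifest.spot_size,
        "scan_speed": manifest.scan_speed,
        "acquisition_period": manifest.acquisition_period,
        "line_spacing": manifest.line_spacing,
        "section_interval": manifest.section_interval,
        "isotopes": list(manifest.isotopes),
        "standard_concentrations": dict(manifest.standard_concentrations),
        "concatenated": manifest.concatenated,
        "line_column": manifest.line_column,
    }
    if extra:
        doc.update(dict(extra))
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
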