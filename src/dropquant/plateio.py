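"""Reading and writing plate images and measurement tables.

On-disk conventions
-------------------
* one grayscale image per (well, field, channel), named
  ``<plate>_<well>_f<field>_<channel>.<ext>`` with ``ext`` in {tif, bmp};
* pixel coordinates are 0-based, row-major, origin top-left;
* stored intensities are kept raw (integer); normalization to [0, 1] by the
  bit-depth maximum is available as a derived view so that 8-bit and 16-bit
  stores of the same data compare equal, but all quantification (Tii Pi Pm
  in particular) runs on the raw stored values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import AcquisitionConfig

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

_EXTENSIONS = {"tiff": "tif", "bmp": "bmp"}


def validate_well_id(well_id: str) -> str:
    """Check a well id against the 96-well grammar A1–H12."""
    if not _WELL_RE.match(well_id):
        raise ValueError(f"invalid 96-well id {well_id!r} (expected A1–H12)")
    return well_id


def field_filename(plate_id: str, well_id: str, field_id: int, channel: str,
                   image_format: str = "tiff") -> str:
    ext = _EXTENSIONS[image_format]
    return f"{plate_id}_{well_id}_f{field_id}_{channel}.{ext}"


def parse_field_filename(name: str) -> tuple[str, str, int, str]:
    """Inverse of :func:`field_filename`: (plate, well, field, channel)."""
    m = re.match(r"^(.+)_([A-H](?:[1-9]|1[0-2]))_f(\d+)_([^_.]+)\.(tif|bmp)$", name)
    if m is None:
        raise ValueError(f"filename {name!r} does not follow <plate>_<well>_f<field>_<channel>.<ext>")
    return m.group(1), m.group(2), int(m.group(3)), m.group(4)


@dataclass
class FieldImageSet:
    """Co-registered multi-channel intensity grids for one field of view."""

    channels: dict[str, np.ndarray]
    well_id: str
    field_id: int
    acq: AcquisitionConfig

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel grids disagree in shape: {sorted(shapes)}")
        for name, grid in self.channels.items():
            if grid.max(initial=0) > self.acq.max_intensity:
                raise ValueError(
                    f"channel {name!r} exceeds the {self.acq.bit_depth}-bit range")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def normalized(self, channel: str) -> np.ndarray:
        """Intensities scaled to [0, 1] by the bit-depth maximum (display scale).

        Metadata-level convenience only — quantification uses raw values.
        """
        return self.channels[channel].astype(np.float64) / self.acq.max_intensity


@dataclass
class PlateLayout:
    """Map from well id to (condition_id, time_min, replicate index)."""

    rows: dict[str, tuple[str, float, int]]
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for well in self.rows:
            validate_well_id(well)
            if well in seen:
                raise ValueError(f"duplicate well id {well!r} in layout")
            seen.add(well)

    def condition_of(self, well_id: str) -> str:
        return self.rows[well_id][0]

    def wells_for(self, condition_id: str, time_min: float | None = None) -> list[str]:
        return [w for w, (c, t, _r) in self.rows.items()
                if c == condition_id and (time_min is None or t == time_min)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w, c, t, r) for w, (c, t, r) in self.rows.items()],
            columns=["well_id", "condition_id", "time_min", "replicate"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, plate_id: str = "plate1") -> "PlateLayout":
        df = pd.read_csv(path)
        rows = {
            str(rec.well_id): (str(rec.condition_id), float(rec.time_min), int(rec.replicate))
            for rec in df.itertuples()
        }
        return cls(rows=rows, plate_id=plate_id)


def write_field(fis: FieldImageSet, directory: str | Path, plate_id: str = "plate1",
                image_format: str = "tiff") -> list[Path]:
    """Write one file per channel; 16-bit data goes to TIFF, 8-bit to TIFF or BMP."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if image_format == "bmp" and fis.acq.bit_depth != 8:
        raise ValueError("BMP storage requires 8-bit data")
    dtype = np.uint8 if fis.acq.bit_depth == 8 else np.uint16
    paths = []
    for channel, grid in fis.channels.items():
        path = directory / field_filename(plate_id, fis.well_id, fis.field_id,
                                          channel, image_format)
        data = np.ascontiguousarray(grid.astype(dtype))
        if image_format == "tiff":
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)
        paths.append(path)
    return paths


def read_field(directory: str | Path, well_id: str, field_id: int,
               acq: AcquisitionConfig, plate_id: str = "plate1",
               image_format: str = "tiff") -> FieldImageSet:
    """Read the 4 channel images of one field.

    Raises FileNotFoundError naming (well, field, channel) if any channel
    file is absent, and ValueError if channel shapes disagree.
    """
    directory = Path(directory)
    channels: dict[str, np.ndarray] = {}
    for channel in acq.channel_names:
        path = directory / field_filename(plate_id, well_id, field_id, channel, image_format)
        if not path.exists():
            raise FileNotFoundError(
                f"missing channel image for well {well_id}, field {field_id}, "
                f"channel {channel!r}: {path}")
        grid = np.asarray(iio.imread(path)) if image_format == "bmp" else tifffile.imread(path)
        channels[channel] = grid
    return FieldImageSet(channels=channels, well_id=well_id, field_id=field_id, acq=acq)


def write_measurements(records, path: str | Path, allow_empty: bool = False,
                       columns: list[str] | None = None) -> Path:
    """Write per-cell or per-well records to CSV with a stable column order.

    ``records`` may be a list of dataclass records (CellMeasurements,
    WellSummary) or a DataFrame. Floats are written with full (repr)
    precision so a read round-trips exactly.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records and not allow_empty:
            raise ValueError("refusing to write an empty table (pass allow_empty=True)")
        if records:
            df = pd.DataFrame([r.__dict__ for r in records])
        else:
            df = pd.DataFrame(columns=columns or [])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
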