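"""Image and table readers/writers plus the run configuration file.

The config file is a flat, human-editable INI with ``[features]``,
``[detector]`` and ``[synthetic]`` sections whose keys mirror the
corresponding dataclass fields; omitted keys fall back to the package
defaults, so an empty file is a valid configuration.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageOps

from .detector import DetectorConfig
from .evaluate import CountTable
from .exceptions import FormatError, InvalidInputError
from .fourierhog import FeatureConfig
from .synthetic import SceneConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_counts",
    "write_counts",
]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a run needs: feature, detector and scene parameters."""

    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    detector: DetectorConfig = dataclasses.field(default_factory=DetectorConfig)
    scene: SceneConfig = dataclasses.field(default_factory=SceneConfig)
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        parser = configparser.ConfigParser()
        read = parser.read(Path(path))
        if not read:
            raise FormatError(f"config file {path} not found or unreadable")

        def build(section: str, dc_type):
            fields = {f.name: f.type for f in dataclasses.fields(dc_type)}
            kwargs = {}
            if parser.has_section(section):
                for key, raw in parser.items(section):
                    if key not in fields:
                        raise FormatError(
                            f"unknown key {key!r} in [{section}] of {path}"
                        )
                    default = getattr(dc_type(), key)
                    if raw.strip().lower() in ("none", ""):
                        kwargs[key] = None
                    elif isinstance(default, bool):
                        kwargs[key] = raw.strip().lower() in ("1", "true", "yes")
                    elif isinstance(default, int):
                        kwargs[key] = int(raw)
                    elif isinstance(default, float):
                        kwargs[key] = float(raw)
                    elif default is None:  # optional integer field
                        kwargs[key] = int(raw)
                    else:
                        kwargs[key] = raw
            return dc_type(**kwargs)

        seed = 0
        if parser.has_section("run") and parser.has_option("run", "seed"):
            seed = parser.getint("run", "seed")
        return cls(
            features=build("features", FeatureConfig),
            detector=build("detector", DetectorConfig),
            scene=build("synthetic", SceneConfig),
            seed=seed,
        )

    def save(self, path: str | Path) -> Path:
        parser = configparser.ConfigParser()
        parser["run"] = {"seed": str(self.seed)}
        for section, dc in (
            ("features", self.features),
            ("detector", self.detector),
            ("synthetic", self.scene),
        ):
            parser[section] = {
                f.name: str(getattr(dc, f.name)) for f in dataclasses.fields(dc)
            }
        path = Path(path)
        with open(path, "w") as fh:
            parser.write(fh)
        return path


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG as a float array with intensities in [0, 1].

    EXIF orientation is honoured; 8- and 16-bit images are normalized by
    their full dtype range.  Returns ``(H, W)`` for single-channel files
    and ``(H, W, 3)`` for colour.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img = ImageOps.exif_transpose(img)
            arr = np.asarray(img)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    elif arr.dtype == np.int32:  # PIL mode "I" (16-bit grayscale PNG)
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def write_image(path: str | Path, image: np.ndarray, bitdepth: int = 8) -> Path:
    """Write a float [0, 1] image as an 8- or 16-bit PNG/TIFF."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bitdepth == 8:
        data = np.round(image * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        data = np.round(image * 65535.0).astype(np.uint16)
        if data.ndim != 2:
            raise InvalidInputError("16-bit output supported for grayscale only")
    else:
        raise InvalidInputError("bitdepth must be 8 or 16")
    Image.fromarray(data).save(path)
    return path


# ---------------------------------------------------------------------------
# count tables


REQUIRED_COUNT_COLUMNS = ("image_id", "final_manual")


def read_counts(path: str | Path) -> CountTable:
    """Read a per-image count CSV into a validated :class:`CountTable`.

    Requires ``image_id`` and ``final_manual`` columns; any of
    ``first_manual``, ``second_manual``, ``automated`` and
    ``automated_<n>`` are carried through.  Rows with negative or
    non-numeric counts are rejected with their line numbers.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"count table {path} missing columns {missing}")
    count_cols = [c for c in frame.columns if c != "image_id"]
    bad_lines: list[int] = []
    for col in count_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        bad |= numeric < 0
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            bad_lines.extend((frame.index[bad] + 2).tolist())
        frame[col] = numeric
    if bad_lines:
        raise FormatError(
            f"count table {path} has invalid counts on lines "
            f"{sorted(set(bad_lines))}"
        )
    return CountTable(frame=frame)


def write_counts(table: CountTable | pd.DataFrame, path: str | Path) -> Path:
    frame = table.frame if isinstance(table, CountTable) else table
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
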