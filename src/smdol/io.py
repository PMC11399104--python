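"""Images, localization tables, configuration.

All localization coordinates are carried in nanometres throughout the
package; conversion from pixels happens exactly once, at fit time.  This
avoids the px/nm ambiguity that otherwise creeps in between detection,
registration and colocalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Image2D",
    "LocalizationSet",
    "AnalysisConfig",
    "FormatError",
    "read_image",
    "write_image",
    "read_localizations",
    "write_localizations",
    "read_mask",
    "write_mask",
]

LOC_COLUMNS = ["id", "x_nm", "y_nm", "sigma_nm", "intensity_photons", "background"]

#: ThunderSTORM-style CSV headers mapped onto the native column names.
_THUNDERSTORM_ALIASES = {
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "intensity [photon]": "intensity_photons",
    "offset [photon]": "background",
    "bkgstd [photon]": None,  # recognised, dropped
    "frame": None,
    "uncertainty [nm]": None,
    "chi2": None,
}


class FormatError(ValueError):
    """Raised when a file does not match an expected on-disk format."""


@dataclass
class Image2D:
    """A single-channel raster with a physical pixel pitch.

    The pixel grid convention shared by every module: pixel ``(r, c)``
    covers ``[c*px, (c+1)*px) x [r*px, (r+1)*px)`` in nm with the origin at
    the top-left image corner; the pixel centre sits at ``(+0.5)*px``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_name: str = ""
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(f"Image2D requires a 2D raster, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 16:
            raise FormatError(f"image too small: {self.pixels.shape} (min dimension 16 px)")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def frame_size_nm(self) -> tuple[float, float]:
        """Physical (width_x, height_y) of the frame in nm."""
        rows, cols = self.pixels.shape
        return cols * self.pixel_size_nm, rows * self.pixel_size_nm


@dataclass
class LocalizationSet:
    """Sub-pixel emitter localizations for one channel of one image.

    Backed by a DataFrame with columns ``id, x_nm, y_nm, sigma_nm,
    intensity_photons, background``.  Ids are unique within a set.
    """

    table: pd.DataFrame
    channel_name: str = ""
    image_id: str = ""
    pixel_size_nm: float = float("nan")

    def __post_init__(self) -> None:
        missing = [c for c in LOC_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"localization table missing columns: {missing}")
        self.table = self.table.loc[:, LOC_COLUMNS].reset_index(drop=True)
        if self.table["id"].duplicated().any():
            raise ValueError("localization ids must be unique within a set")

    @classmethod
    def from_arrays(
        cls,
        x_nm,
        y_nm,
        sigma_nm=None,
        intensity_photons=None,
        background=None,
        ids=None,
        **meta,
    ) -> "LocalizationSet":
        x = np.atleast_1d(np.asarray(x_nm, dtype=float))
        n = x.size
        def _col(v, default):
            if v is None:
                return np.full(n, default, dtype=float)
            return np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
        table = pd.DataFrame(
            {
                "id": np.arange(n) if ids is None else np.asarray(ids),
                "x_nm": x,
                "y_nm": _col(y_nm, np.nan),
                "sigma_nm": _col(sigma_nm, np.nan),
                "intensity_photons": _col(intensity_photons, np.nan),
                "background": _col(background, 0.0),
            }
        )
        return cls(table, **meta)

    @classmethod
    def empty(cls, **meta) -> "LocalizationSet":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS}), **meta)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (x_nm, y_nm)."""
        return self.table[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def x_nm(self) -> np.ndarray:
        return self.table["x_nm"].to_numpy(dtype=float)

    @property
    def y_nm(self) -> np.ndarray:
        return self.table["y_nm"].to_numpy(dtype=float)

    @property
    def sigma_nm(self) -> np.ndarray:
        return self.table["sigma_nm"].to_numpy(dtype=float)

    def select(self, mask) -> "LocalizationSet":
        """Subset by a boolean mask over rows, preserving ids and metadata."""
        sub = self.table.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return LocalizationSet(
            sub,
            channel_name=self.channel_name,
            image_id=self.image_id,
            pixel_size_nm=self.pixel_size_nm,
        )

    def with_xy(self, x_nm, y_nm) -> "LocalizationSet":
        """Copy with replaced coordinates (all other fields preserved)."""
        table = self.table.copy()
        table["x_nm"] = np.asarray(x_nm, dtype=float)
        table["y_nm"] = np.asarray(y_nm, dtype=float)
        return LocalizationSet(
            table,
            channel_name=self.channel_name,
            image_id=self.image_id,
            pixel_size_nm=self.pixel_size_nm,
        )


def read_image(path, pixel_size_nm: float, channel_name: str = "") -> Image2D:
    """Read a TIFF; multi-page stacks are averaged over pages.

    Averaging mirrors the acquisition scheme in which ten to twenty frames
    are recorded and averaged per measurement.
    """
    path = Path(path)
    data = tifffile.imread(path)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        pages = 1
    elif arr.ndim == 3:
        pages = arr.shape[0]
        arr = arr.mean(axis=0)
    else:
        raise FormatError(f"{path}: expected a 2D image or a page stack, got shape {data.shape}")
    return Image2D(arr, pixel_size_nm=pixel_size_nm, channel_name=channel_name, n_frames_averaged=pages)


def write_image(image: Image2D, path) -> None:
    tifffile.imwrite(Path(path), image.pixels.astype(np.float32))


def read_mask(path) -> np.ndarray:
    """Read an 8-bit mask TIFF (0/255) as a boolean raster."""
    arr = tifffile.imread(Path(path))
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_localizations(path, **meta) -> LocalizationSet:
    """Read a localization CSV in the native or ThunderSTORM dialect."""
    path = Path(path)
    raw = pd.read_csv(path)
    raw.columns = [str(c).strip().strip('"') for c in raw.columns]
    cols = {}
    for c in raw.columns:
        if c in LOC_COLUMNS:
            cols[c] = c
        elif c in _THUNDERSTORM_ALIASES:
            target = _THUNDERSTORM_ALIASES[c]
            if target is not None:
                cols[c] = target
    table = raw[list(cols)].rename(columns=cols)
    for col in ("x_nm", "y_nm"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing positional column '{col}' (or its ThunderSTORM alias)")
    if "id" not in table.columns:
        table.insert(0, "id", np.arange(len(table)))
    for col in LOC_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan if col != "background" else 0.0
    return LocalizationSet(table, **meta)


def write_localizations(locs: LocalizationSet, path) -> None:
    """Write the native CSV dialect with fixed float formatting.

    The 6-decimal format keeps the write -> read round trip lossless to
    1e-3 nm while producing byte-identical files for identical inputs.
    """
    table = locs.table.copy()
    table["id"] = table["id"].astype(int)
    table.to_csv(Path(path), index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SegmentationSettings:
    """Cell segmentation tunables.

    The band-pass must include the cell-body scale: the automatic
    threshold keys on the diffuse cellular fluorescence, with single
    molecules riding on top, so ``high_sigma_px`` sits well above the PSF
    scale while ``low_sigma_px`` suppresses pixel noise.
    """

    low_sigma_px: float = 4.0
    high_sigma_px: float = 64.0
    min_object_area_um2: float = 20.0
    close_radius_px: float = 8.0
    min_separation_sd: float = 4.0


@dataclass
class DetectionSettings:
    """Spot detection / fitting tunables.

    threshold = ``peak_threshold_k`` times the robust noise SD (1.4826*MAD)
    of the band-pass filtered image.  ``fit_window_px`` must be odd.
    """

    dog_low_px: float = 1.0
    dog_high_px: float = 2.0
    peak_threshold_k: float = 4.0
    fit_window_px: int = 9
    max_emitters_per_fit: int = 3
    sigma_window_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fit_window_px % 2 == 0 or self.fit_window_px < 5:
            raise ValueError("fit_window_px must be odd and >= 5")
        if self.max_emitters_per_fit not in (1, 2, 3):
            raise ValueError("max_emitters_per_fit must be 1, 2 or 3")


@dataclass
class RegistrationSettings:
    match_radius_nm: float = 500.0
    n_iterations: int = 5
    min_emitters: int = 50
    max_shift_px: float = 3.0
    max_rotation_deg: float = 5.0
    max_scale_dev: float = 0.05


@dataclass
class ColocSettings:
    t_min_nm: float = 0.0
    t_max_nm: float = 500.0
    t_step_nm: float = 10.0
    # Normalization of F_c/F_r: "reference" divides matched-pair counts by
    # the number of reference localizations; "pairs_at_tmax" divides by the
    # pair count at the largest tolerance.
    normalization: str = "reference"
    # "per_experiment" pools pair counts across images for one cutoff T;
    # "per_image" computes T per image.
    cutoff_scope: str = "per_experiment"

    @property
    def t_grid_nm(self) -> np.ndarray:
        return np.arange(self.t_min_nm, self.t_max_nm + 0.5 * self.t_step_nm, self.t_step_nm)


@dataclass
class ReportSettings:
    min_reference_locs: int = 20
    unspec_mode: str = "residual"  # or "control"


@dataclass
class AnalysisConfig:
    """All tunables of the analysis pipeline, schema-validated.

    Unknown keys in a config file are rejected rather than ignored so that
    a typo cannot silently fall back to a default.
    """

    pixel_size_nm: float = 160.0
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    coloc: ColocSettings = field(default_factory=ColocSettings)
    report: ReportSettings = field(default_factory=ReportSettings)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        return _build_dataclass(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise FormatError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get(name)
        if target is not None:
            kwargs[name] = _build_dataclass(target, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "segmentation": SegmentationSettings,
    "detection": DetectionSettings,
    "registration": RegistrationSettings,
    "coloc": ColocSettings,
    "report": ReportSettings,
}
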