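"""Core data types and file I/O.

Two-channel time-lapse stacks (vessel dye + Ca2+ indicator) are stored as
multi-page TIFF; vessel centerlines as CSV polylines; stimulus events and
analysis settings as YAML key-value files.  All distances are micrometers,
converted through the (isotropic, in-plane) pixel size; pixel coordinates
are 0-based, row-major.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("sheathquant")

VESSEL_LAYERS = ("SVP", "IVP", "DVP")
PUFF_SITES = ("surface", "direct")


class SheathQuantError(ValueError):
    """Raised on contract violations (bad files, out-of-range settings)."""


# ---------------------------------------------------------------------------
# image stack
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Two-channel fluorescence movie.

    Attributes
    ----------
    vessel, calcium : ndarray, shape (T, Y, X)
        Vessel-lumen dye channel and Ca2+ indicator channel.
    pixel_size_um : float
        Micrometers per pixel, isotropic in-plane.
    frame_interval_s : float
        Seconds between consecutive frames.
    """

    vessel: np.ndarray
    calcium: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.vessel = np.asarray(self.vessel)
        self.calcium = np.asarray(self.calcium)
        if self.vessel.ndim != 3 or self.calcium.ndim != 3:
            raise SheathQuantError("channel arrays must be 3D (T, Y, X)")
        if self.vessel.shape != self.calcium.shape:
            raise SheathQuantError(
                f"channel shapes differ: {self.vessel.shape} vs {self.calcium.shape}"
            )
        if self.n_frames == 0 or self.shape[1] == 0 or self.shape[2] == 0:
            raise SheathQuantError("empty stack (zero-sized axis)")
        if not (self.pixel_size_um > 0):
            raise SheathQuantError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_interval_s > 0):
            raise SheathQuantError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        for name, arr in (("vessel", self.vessel), ("calcium", self.calcium)):
            if not np.all(np.isfinite(arr)):
                raise SheathQuantError(f"{name} channel contains non-finite values")
            if np.any(arr < 0):
                raise SheathQuantError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple:
        return self.vessel.shape

    @property
    def n_frames(self) -> int:
        return self.vessel.shape[0]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def read_stack(
    path: str,
    pixel_size_um: float,
    frame_interval_s: float,
    dialect: str = "interleaved",
    channel_order: str = "vc",
) -> ImageStack:
    """Read a two-channel multi-page TIFF.

    ``dialect='interleaved'`` expects 2T pages alternating channels;
    ``dialect='stacked'`` expects an array of shape (2, T, Y, X).
    ``channel_order`` gives the on-disk order: ``'vc'`` (vessel first)
    or ``'cv'`` (calcium first).
    """
    if not os.path.exists(path):
        raise SheathQuantError(f"no such file: {path}")
    data = tifffile.imread(path)
    if dialect == "interleaved":
        if data.ndim != 3:
            raise SheathQuantError(
                f"interleaved stack must have 3 axes (pages, Y, X); got shape {data.shape}"
            )
        if data.shape[0] % 2 != 0:
            raise SheathQuantError(
                f"expected 2 channels (even page count); got {data.shape[0]} pages"
            )
        a, b = data[0::2], data[1::2]
    elif dialect == "stacked":
        if data.ndim != 4 or data.shape[0] != 2:
            raise SheathQuantError(
                f"expected 2 channels as leading axis; got shape {data.shape}"
            )
        a, b = data[0], data[1]
    else:
        raise SheathQuantError(f"unknown TIFF dialect: {dialect!r}")
    if channel_order == "vc":
        vessel, calcium = a, b
    elif channel_order == "cv":
        vessel, calcium = b, a
    else:
        raise SheathQuantError(f"unknown channel_order: {channel_order!r}")
    return ImageStack(vessel, calcium, pixel_size_um, frame_interval_s)


def write_stack(stack: ImageStack, path: str, dialect: str = "interleaved") -> str:
    """Write an :class:`ImageStack` to multi-page TIFF.

    Integer data round-trips bit-exactly; floating point data is stored as
    float32.  Returns the path written.
    """
    v, c = stack.vessel, stack.calcium
    if np.issubdtype(v.dtype, np.floating) or np.issubdtype(c.dtype, np.floating):
        v = v.astype(np.float32)
        c = c.astype(np.float32)
    if dialect == "interleaved":
        pages = np.empty((2 * stack.n_frames,) + v.shape[1:], dtype=v.dtype)
        pages[0::2] = v
        pages[1::2] = c
    elif dialect == "stacked":
        pages = np.stack([v, c])
    else:
        raise SheathQuantError(f"unknown TIFF dialect: {dialect!r}")
    tifffile.imwrite(path, pages)
    return path


# ---------------------------------------------------------------------------
# stimulus event
# ---------------------------------------------------------------------------

@dataclass
class PuffEvent:
    """Agonist puff: onset frame, duration and delivery site.

    ``agonist_mM`` and ``pressure_psi`` are metadata only (5 mM ATP at
    5 psi in the emulated protocol).
    """

    onset_frame: int
    duration_s: float = 0.2
    site: str = "surface"
    agonist_mM: float = 5.0
    pressure_psi: float = 5.0

    def __post_init__(self) -> None:
        if self.onset_frame < 0:
            raise SheathQuantError(f"onset_frame must be >= 0, got {self.onset_frame}")
        if not (self.duration_s > 0):
            raise SheathQuantError(f"duration_s must be > 0, got {self.duration_s}")
        if self.site not in PUFF_SITES:
            raise SheathQuantError(f"site must be one of {PUFF_SITES}, got {self.site!r}")

    def validate_against(self, stack: ImageStack) -> None:
        if self.onset_frame >= stack.n_frames:
            raise SheathQuantError(
                f"onset_frame {self.onset_frame} outside stack of {stack.n_frames} frames"
            )


def load_event(path: str) -> PuffEvent:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SheathQuantError(f"event file {path} must be a key-value mapping")
    return PuffEvent(**raw)


def save_event(event: PuffEvent, path: str) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(event), fh)
    return path


# ---------------------------------------------------------------------------
# vessel centerline
# ---------------------------------------------------------------------------

@dataclass
class VesselTrace:
    """Capillary centerline polyline (pixel coordinates) plus diameter.

    The polyline defines the axis of the vessel-centric coordinate frame:
    signed perpendicular distance from the centerline is the radial axis
    of sheath profiles.
    """

    centerline: np.ndarray  # (N, 2) float, (row, col)
    diameter_um: float
    layer: str = "IVP"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise SheathQuantError("centerline must be an (N, 2) array of (row, col)")
        if len(np.unique(self.centerline, axis=0)) < 2:
            raise SheathQuantError("centerline needs >= 2 distinct points")
        steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(steps >= 5.0):
            raise SheathQuantError(
                "consecutive centerline points must be closer than 5 px"
            )
        if np.any(steps == 0):
            # repeated points carry no direction; drop them
            keep = np.concatenate([[True], steps > 0])
            self.centerline = self.centerline[keep]
        if not (self.diameter_um > 0):
            raise SheathQuantError(f"diameter_um must be > 0, got {self.diameter_um}")
        if self.layer not in VESSEL_LAYERS:
            raise SheathQuantError(
                f"layer must be one of {VESSEL_LAYERS}, got {self.layer!r}"
            )

    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    def arclength_px(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1))
        )

    def validate_bounds(self, image_shape: Sequence[int]) -> None:
        ny, nx = image_shape[-2], image_shape[-1]
        r, c = self.centerline[:, 0], self.centerline[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() > ny - 1 or c.max() > nx - 1:
            raise SheathQuantError("centerline lies outside image bounds")


def load_vessel(path: str) -> VesselTrace:
    """Read a vessel CSV: ``# key: value`` comment header, then row,col points."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("# ").split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    if not {"row", "col"} <= set(df.columns):
        raise SheathQuantError(f"vessel file {path} needs 'row' and 'col' columns")
    if "diameter_um" not in meta:
        raise SheathQuantError(f"vessel file {path} missing '# diameter_um:' header")
    return VesselTrace(
        df[["row", "col"]].to_numpy(float),
        float(meta["diameter_um"]),
        meta.get("layer", "IVP"),
    )


def save_vessel(vessel: VesselTrace, path: str) -> str:
    with open(path, "w") as fh:
        fh.write(f"# diameter_um: {vessel.diameter_um}\n")
        fh.write(f"# layer: {vessel.layer}\n")
        fh.write("row,col\n")
        for r, c in vessel.centerline:
            fh.write(f"{r},{c}\n")
    return path


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

ROI_MODES = ("diameters", "fixed_um")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the quantification.

    Defaults follow the protocol: 8-10 frames averaged for baseline and
    peak (default 9), stalk mask = top 2-4% of the averaged peak image
    (default 3) dilated 2-3 times (default 2), profiles extend at least
    20 um on either side of the vessel, and the vessel channel is
    normalized to z = 5 for display.
    """

    baseline_frames: int = 9
    peak_frames: int = 9
    stalk_percentile: float = 3.0
    dilation_iters: int = 2
    profile_halfwidth_um: float = 20.0
    background_min_um: float = 15.0
    sheath_search_um: float = 10.0
    vessel_display_z: float = 5.0
    roi_mode: str = "diameters"
    roi_extent: float = 3.0
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        numeric = {
            "baseline_frames": self.baseline_frames,
            "peak_frames": self.peak_frames,
            "stalk_percentile": self.stalk_percentile,
            "dilation_iters": self.dilation_iters,
            "profile_halfwidth_um": self.profile_halfwidth_um,
            "background_min_um": self.background_min_um,
            "sheath_search_um": self.sheath_search_um,
            "vessel_display_z": self.vessel_display_z,
            "roi_extent": self.roi_extent,
        }
        for key, val in numeric.items():
            if not (val > 0):
                raise SheathQuantError(f"{key} must be positive, got {val}")
        if not (0 < self.stalk_percentile < 100):
            raise SheathQuantError(
                f"stalk_percentile must be in (0, 100), got {self.stalk_percentile}"
            )
        if self.roi_mode not in ROI_MODES:
            raise SheathQuantError(
                f"roi_mode must be one of {ROI_MODES}, got {self.roi_mode!r}"
            )
        if self.background_min_um >= self.profile_halfwidth_um:
            raise SheathQuantError(
                "background_min_um must be smaller than profile_halfwidth_um "
                f"({self.background_min_um} >= {self.profile_halfwidth_um})"
            )
        if not self.allow_out_of_range:
            protocol = {
                "baseline_frames": (self.baseline_frames, 8, 10),
                "peak_frames": (self.peak_frames, 8, 10),
                "stalk_percentile": (self.stalk_percentile, 2, 4),
                "dilation_iters": (self.dilation_iters, 2, 3),
            }
            for key, (val, lo, hi) in protocol.items():
                if not (lo <= val <= hi):
                    raise SheathQuantError(
                        f"{key}={val} outside the protocol range [{lo}, {hi}] "
                        "(set allow_out_of_range to override)"
                    )
            if self.profile_halfwidth_um < 20:
                raise SheathQuantError(
                    f"profile_halfwidth_um={self.profile_halfwidth_um} below the "
                    "20 um minimum (set allow_out_of_range to override)"
                )


def load_config(path: Optional[str]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    Absent keys take their defaults; unknown keys are an error (they are
    usually typos of a real setting).
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SheathQuantError(f"config file {path} must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SheathQuantError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(cfg: AnalysisConfig, path: str) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)
    return path


def configure_logging(verbose: bool = False) -> None:
    """Log to stderr; -v raises the level to DEBUG."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
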