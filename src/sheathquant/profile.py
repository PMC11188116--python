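"""Vessel-centric 2D analysis: the sheath z-score statistic.

The chain: average 8-10 frames at baseline and at the response peak;
subtract to isolate the evoked ΔF; mask out bright Müller stalks
(top-percentile threshold of the averaged peak image, dilated, converted
to NaN); resample the field into vessel-centric coordinates by sampling
along centerline normals (straightening); collapse along the vessel axis
into a radial profile; convert to z-scores against the far-from-vessel
background; and take the mean of the two per-side peak z values just
outside the vessel wall — the sheath statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .io import AnalysisConfig, ImageStack, SheathQuantError, VesselTrace

logger = logging.getLogger("sheathquant.profile")


# ---------------------------------------------------------------------------
# frame averaging and subtraction
# ---------------------------------------------------------------------------

def average_frames(
    frames: np.ndarray,
    window: Tuple[int, int],
    cfg: Optional[AnalysisConfig] = None,
) -> np.ndarray:
    """Pixelwise mean of ``frames[start:stop]``.

    With a config, the window length is held to the 8-10 frame protocol
    range unless ``allow_out_of_range`` is set.
    """
    frames = np.asarray(frames, dtype=float)
    start, stop = window
    if start < 0 or stop > frames.shape[0] or stop <= start:
        raise SheathQuantError(
            f"window [{start}, {stop}) outside stack of {frames.shape[0]} frames"
        )
    n = stop - start
    if cfg is not None and not cfg.allow_out_of_range and not (8 <= n <= 10):
        raise SheathQuantError(
            f"averaging window of {n} frames outside the 8-10 protocol range"
        )
    return frames[start:stop].mean(axis=0)


def baseline_subtract(peak_avg: np.ndarray, base_avg: np.ndarray) -> np.ndarray:
    """Evoked ΔF field: averaged peak image minus averaged baseline image.

    Negative values are retained (no clipping).
    """
    peak_avg = np.asarray(peak_avg, dtype=float)
    base_avg = np.asarray(base_avg, dtype=float)
    if peak_avg.shape != base_avg.shape:
        raise SheathQuantError(
            f"shape mismatch: {peak_avg.shape} vs {base_avg.shape}"
        )
    return peak_avg - base_avg


# ---------------------------------------------------------------------------
# stalk mask
# ---------------------------------------------------------------------------

@dataclass
class StalkMask:
    """Exclusion mask for bright Müller stalk cross-sections."""

    mask: np.ndarray            # (Y, X) bool; True = excluded
    percentile: float
    dilation_iters: int
    threshold: float

    def fraction(self) -> float:
        return float(self.mask.mean())


def build_stalk_mask(
    peak_avg: np.ndarray,
    cfg: AnalysisConfig,
    exclude: Optional[np.ndarray] = None,
) -> StalkMask:
    """Threshold the top ``stalk_percentile`` percent of the averaged peak
    image (not baseline-subtracted), binarize, and dilate with a 3x3 cross.

    Pixels in ``exclude`` (typically the vessel lumen, from the dye
    channel) do not enter the percentile computation, so the bright vessel
    itself cannot drag the threshold up; they can still end up masked if
    they exceed it.  A constant field yields an empty mask (strict
    inequality) with a warning.
    """
    peak_avg = np.asarray(peak_avg, dtype=float)
    if peak_avg.size == 0:
        raise SheathQuantError("empty field")
    vals = peak_avg[~exclude] if exclude is not None else peak_avg.ravel()
    if vals.size == 0:
        raise SheathQuantError("exclusion leaves no pixels for the percentile")
    threshold = float(np.percentile(vals, 100.0 - cfg.stalk_percentile))
    binary = peak_avg > threshold
    if not binary.any():
        logger.warning(
            "stalk mask is empty (constant or near-constant field)"
        )
        return StalkMask(binary, cfg.stalk_percentile, cfg.dilation_iters, threshold)
    cross = ndimage.generate_binary_structure(2, 1)
    mask = ndimage.binary_dilation(binary, structure=cross, iterations=cfg.dilation_iters)
    frac = float(mask.mean())
    if frac >= 0.5:
        logger.warning("stalk mask covers %.0f%% of the field", 100 * frac)
    return StalkMask(mask, cfg.stalk_percentile, cfg.dilation_iters, threshold)


def apply_mask(field_2d: np.ndarray, mask: StalkMask) -> np.ndarray:
    """Set masked pixels to NaN (idempotent); others unchanged."""
    field_2d = np.asarray(field_2d, dtype=float)
    if field_2d.shape != mask.mask.shape:
        raise SheathQuantError(
            f"shape mismatch: field {field_2d.shape} vs mask {mask.mask.shape}"
        )
    out = field_2d.copy()
    out[mask.mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# straightening
# ---------------------------------------------------------------------------

@dataclass
class StraightenedImage:
    """Field resampled into vessel-centric coordinates.

    Rows index arclength along the vessel; columns index signed
    perpendicular distance from the vessel center.  NaN marks samples whose
    bilinear stencil touched a masked or out-of-bounds source pixel.
    """

    data: np.ndarray          # (S, D)
    distances_um: np.ndarray  # (D,) signed, symmetric about 0
    step_um: float


def _resample_centerline(vessel: VesselTrace, step_px: float):
    pts = vessel.centerline
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 2 * step_px:
        raise SheathQuantError("centerline shorter than two sampling steps")
    n = int(np.floor(total / step_px)) + 1
    su = np.arange(n) * step_px
    rows = np.interp(su, s, pts[:, 0])
    cols = np.interp(su, s, pts[:, 1])
    p = np.column_stack([rows, cols])
    # tangents by central differences, one-sided at the ends
    t = np.empty_like(p)
    t[1:-1] = p[2:] - p[:-2]
    t[0] = p[1] - p[0]
    t[-1] = p[-1] - p[-2]
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    normal = np.column_stack([-t[:, 1], t[:, 0]])
    return p, normal


def _bilinear_nan(field: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation where any stencil pixel with nonzero weight
    that is NaN or out of bounds contaminates the sample."""
    ny, nx = field.shape
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros(rows.shape, dtype=float)
    bad = np.zeros(rows.shape, dtype=bool)
    for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        w = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
        active = w > 0
        rr = r0 + dr
        cc = c0 + dc
        inside = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        vals = np.where(inside, field[np.clip(rr, 0, ny - 1), np.clip(cc, 0, nx - 1)], np.nan)
        bad |= active & ~np.isfinite(vals)
        out += np.where(active, w * np.where(np.isfinite(vals), vals, 0.0), 0.0)
    out[bad] = np.nan
    return out


def straighten_vessel(
    field_2d: np.ndarray,
    vessel: VesselTrace,
    cfg: AnalysisConfig,
    pixel_size_um: float,
) -> StraightenedImage:
    """Resample ``field_2d`` along centerline normals.

    One row per arclength step (= one pixel), one column per signed
    perpendicular offset out to ±(profile_halfwidth_um + vessel radius),
    by bilinear interpolation; interpolation touching NaN or leaving the
    image yields NaN.  For a straight axis-aligned vessel this is the
    identity restricted to the band.
    """
    field_2d = np.asarray(field_2d, dtype=float)
    p, normal = _resample_centerline(vessel, step_px=1.0)
    half_um = cfg.profile_halfwidth_um + vessel.radius_um()
    w = int(np.ceil(half_um / pixel_size_um))
    offsets = np.arange(-w, w + 1, dtype=float)  # px
    rows = p[:, 0:1] + offsets[None, :] * normal[:, 0:1]
    cols = p[:, 1:2] + offsets[None, :] * normal[:, 1:2]
    data = _bilinear_nan(field_2d, rows, cols)
    return StraightenedImage(
        data=data,
        distances_um=offsets * pixel_size_um,
        step_um=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# collapse and z-score
# ---------------------------------------------------------------------------

@dataclass
class SheathProfile:
    """Fluorescence vs signed distance from the vessel center."""

    d_um: np.ndarray
    raw: np.ndarray
    n_valid: np.ndarray
    z: Optional[np.ndarray] = None
    bg_mean: Optional[float] = None
    bg_sd: Optional[float] = None


def collapse_to_profile(simg: StraightenedImage, cfg: AnalysisConfig) -> SheathProfile:
    """NaN-ignoring mean along the vessel axis per signed-distance bin."""
    n_valid = np.sum(np.isfinite(simg.data), axis=0)
    if np.all(n_valid == 0):
        raise SheathQuantError("straightened image is entirely NaN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        raw = np.nanmean(simg.data, axis=0)
    if np.any(n_valid == 0):
        logger.warning("%d distance bins have no valid samples", int(np.sum(n_valid == 0)))
    return SheathProfile(d_um=simg.distances_um.copy(), raw=raw, n_valid=n_valid)


def zscore_profile(profile: SheathProfile, cfg: AnalysisConfig) -> SheathProfile:
    """Convert the collapsed profile to z-scores.

    The reference is the background window |d| >= ``background_min_um``,
    pooled over both sides: z(d) = (raw(d) - mu_bg) / sd_bg (SD with one
    delta degree of freedom).
    """
    bg = (np.abs(profile.d_um) >= cfg.background_min_um) & np.isfinite(profile.raw)
    if bg.sum() < 10:
        raise SheathQuantError(
            f"background window has only {int(bg.sum())} valid bins (need >= 10)"
        )
    mu = float(np.mean(profile.raw[bg]))
    sd = float(np.std(profile.raw[bg], ddof=1))
    if sd == 0:
        raise SheathQuantError("background SD is zero; z-scores undefined")
    return SheathProfile(
        d_um=profile.d_um,
        raw=profile.raw,
        n_valid=profile.n_valid,
        z=(profile.raw - mu) / sd,
        bg_mean=mu,
        bg_sd=sd,
    )


# ---------------------------------------------------------------------------
# sheath peak statistic
# ---------------------------------------------------------------------------

@dataclass
class SheathStatistic:
    """Per-side peak z just outside the vessel wall, and their mean."""

    peak_z_left: float
    peak_z_right: float
    peak_z_mean: float
    pos_left_um: float
    pos_right_um: float
    vessel_radius_um: float
    one_sided: bool = False


def sheath_peak(
    zprof: SheathProfile, vessel: VesselTrace, cfg: AnalysisConfig
) -> SheathStatistic:
    """Maximum z per side within (radius, radius + sheath_search_um],
    averaged over the two sides."""
    if zprof.z is None:
        raise SheathQuantError("profile has no z-scores; run zscore_profile first")
    r = vessel.radius_um()
    hi = r + cfg.sheath_search_um
    out = {}
    for side, sign in (("left", -1), ("right", 1)):
        sel = (
            (np.sign(zprof.d_um) == sign)
            & (np.abs(zprof.d_um) > r)
            & (np.abs(zprof.d_um) <= hi)
            & np.isfinite(zprof.z)
        )
        if not sel.any():
            out[side] = None
            continue
        idx = np.nonzero(sel)[0]
        best = idx[np.argmax(zprof.z[idx])]
        out[side] = (float(zprof.z[best]), float(zprof.d_um[best]))
    if out["left"] is None and out["right"] is None:
        raise SheathQuantError("both sheath search windows are entirely NaN")
    one_sided = out["left"] is None or out["right"] is None
    if one_sided:
        logger.warning("one sheath search window entirely NaN; statistic is one-sided")
        valid = out["left"] or out["right"]
        zl, pl = valid if out["left"] else (np.nan, np.nan)
        zr, pr = valid if out["right"] else (np.nan, np.nan)
        mean = valid[0]
    else:
        (zl, pl), (zr, pr) = out["left"], out["right"]
        mean = (zl + zr) / 2.0
    return SheathStatistic(
        peak_z_left=zl,
        peak_z_right=zr,
        peak_z_mean=mean,
        pos_left_um=pl,
        pos_right_um=pr,
        vessel_radius_um=r,
        one_sided=one_sided,
    )


def normalize_vessel_display(
    vessel_profile: np.ndarray, cfg: AnalysisConfig
) -> np.ndarray:
    """Rescale the vessel-channel profile so its maximum equals
    ``vessel_display_z`` (default 5).  Display only; never feeds the
    sheath statistic.  Scale-invariant: doubling the input changes nothing.
    """
    vessel_profile = np.asarray(vessel_profile, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        peak = np.nanmax(vessel_profile)
    if not (peak > 0):
        raise SheathQuantError(f"vessel profile peak must be positive, got {peak}")
    # divide by the peak first so the maximum is exactly vessel_display_z
    return vessel_profile / peak * cfg.vessel_display_z
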