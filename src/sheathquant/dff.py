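"""Gross ΔF/F of an ROI around a capillary.

The first of the two measurements: the indicator signal averaged over a
band around the vessel (three vessel diameters per side by default, or a
fixed 10 um), expressed as (F - F0)/F0 against the mean of the baseline
frames immediately preceding the puff.  No background subtraction or
bleach correction is applied, so ΔF/F is invariant to multiplicative gain
but not to additive offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .io import AnalysisConfig, ImageStack, PuffEvent, SheathQuantError, VesselTrace


@dataclass
class DffTrace:
    """Per-frame ROI ΔF/F with its baseline."""

    t: np.ndarray                 # frame times, s
    dff: np.ndarray               # dimensionless
    f0: float                     # baseline mean intensity
    baseline_window: Tuple[int, int]  # [start, stop) frame indices


def roi_halfwidth_um(vessel: VesselTrace, cfg: AnalysisConfig) -> float:
    if cfg.roi_mode == "diameters":
        return cfg.roi_extent * vessel.diameter_um
    return cfg.roi_extent if cfg.roi_mode == "fixed_um" else 10.0


def make_roi(
    vessel: VesselTrace, cfg: AnalysisConfig, image_shape, pixel_size_um: float
) -> np.ndarray:
    """Boolean (Y, X) mask of pixels within the ROI band around the centerline.

    The band extends ``roi_extent`` vessel diameters (or a fixed number of
    micrometers) perpendicular from the centerline on each side and is
    clipped to the image bounds.
    """
    ny, nx = image_shape[-2], image_shape[-1]
    vessel.validate_bounds((ny, nx))
    half_um = roi_halfwidth_um(vessel, cfg)
    # densify the polyline so distance-to-polyline is accurate
    pts = _densify(vessel.centerline, step_px=0.5)
    tree = cKDTree(pts)
    yy, xx = np.mgrid[0:ny, 0:nx]
    d_px, _ = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    roi = (d_px * pixel_size_um <= half_um).reshape(ny, nx)
    if not roi.any():
        raise SheathQuantError("ROI is empty after clipping to image bounds")
    return roi


def _densify(centerline: np.ndarray, step_px: float = 0.5) -> np.ndarray:
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / step_px)) + 1, 2)
    su = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(su, s, centerline[:, 0]), np.interp(su, s, centerline[:, 1])]
    )


def compute_dff(
    stack: ImageStack,
    roi: np.ndarray,
    event: PuffEvent,
    cfg: AnalysisConfig,
) -> DffTrace:
    """ROI-mean ΔF/F per frame against the pre-puff baseline.

    F0 is the mean ROI intensity over the ``cfg.baseline_frames`` frames
    ending at ``event.onset_frame - 1``.  NaN pixels (from an upstream
    mask) are excluded from the ROI mean.
    """
    event.validate_against(stack)
    nb = cfg.baseline_frames
    start = event.onset_frame - nb
    if start < 0:
        raise SheathQuantError(
            f"onset frame {event.onset_frame} too early for a {nb}-frame baseline"
        )
    if roi.shape != stack.shape[1:]:
        raise SheathQuantError("ROI shape does not match image shape")
    frames = np.asarray(stack.calcium, dtype=float)[:, roi]
    f_t = np.nanmean(frames, axis=1)
    f0 = float(np.mean(f_t[start : event.onset_frame]))
    if not (f0 > 0):
        raise SheathQuantError(f"baseline F0 must be positive, got {f0}")
    dff = (f_t - f0) / f0
    return DffTrace(
        t=stack.frame_times_s, dff=dff, f0=f0, baseline_window=(start, event.onset_frame)
    )


def peak_dff(trace: DffTrace, event: PuffEvent) -> Tuple[float, int]:
    """Maximum ΔF/F over frames at or after puff onset.

    Ties break to the earliest frame.  Returns (value, frame index).
    """
    if event.onset_frame >= len(trace.dff):
        raise SheathQuantError("no post-onset frames in trace")
    post = trace.dff[event.onset_frame :]
    idx = int(np.argmax(post))  # argmax returns the first maximum
    return float(post[idx]), event.onset_frame + idx
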