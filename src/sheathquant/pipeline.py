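"""End-to-end analysis of one capillary: ROI ΔF/F plus the sheath profile."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu

from .dff import DffTrace, compute_dff, make_roi, peak_dff
from .io import AnalysisConfig, ImageStack, PuffEvent, SheathQuantError, VesselTrace
from .profile import (
    SheathProfile,
    SheathStatistic,
    StalkMask,
    apply_mask,
    average_frames,
    baseline_subtract,
    build_stalk_mask,
    collapse_to_profile,
    normalize_vessel_display,
    sheath_peak,
    straighten_vessel,
    zscore_profile,
)

logger = logging.getLogger("sheathquant.pipeline")


@dataclass
class VesselAnalysis:
    """Everything the pipeline measures for one vessel."""

    dff_trace: DffTrace
    peak_dff: float
    peak_frame: int
    baseline_window: Tuple[int, int]
    peak_window: Tuple[int, int]
    stalk_mask: StalkMask
    zprofile: SheathProfile
    statistic: SheathStatistic
    vessel_display: np.ndarray  # vessel-channel profile scaled to display z


def centered_window(center: int, length: int, n_frames: int) -> Tuple[int, int]:
    """Frame window of ``length`` centered on ``center``, shifted (with a
    warning) to fit inside the stack."""
    start = center - (length - 1) // 2
    if start < 0 or start + length > n_frames:
        shifted = min(max(start, 0), n_frames - length)
        if shifted < 0:
            raise SheathQuantError(
                f"stack of {n_frames} frames cannot hold a {length}-frame window"
            )
        logger.warning(
            "peak window [%d, %d) shifted to [%d, %d) to fit the stack",
            start, start + length, shifted, shifted + length,
        )
        start = shifted
    return start, start + length


def lumen_mask_from_vessel_channel(vessel_avg: np.ndarray) -> np.ndarray:
    """Vessel-lumen pixels via Otsu's threshold on the averaged dye channel."""
    thr = threshold_otsu(np.asarray(vessel_avg, dtype=float))
    return vessel_avg > thr


def analyze_vessel(
    stack: ImageStack,
    vessel: VesselTrace,
    event: PuffEvent,
    cfg: Optional[AnalysisConfig] = None,
    peak_frame: Optional[int] = None,
) -> VesselAnalysis:
    """Run both measurements on one capillary.

    ``peak_frame`` overrides the automatic (max post-onset ROI ΔF/F) peak
    detection, mirroring manual peak selection.
    """
    cfg = cfg or AnalysisConfig()
    vessel.validate_bounds(stack.shape)
    event.validate_against(stack)

    roi = make_roi(vessel, cfg, stack.shape, stack.pixel_size_um)
    trace = compute_dff(stack, roi, event, cfg)
    auto_peak, auto_frame = peak_dff(trace, event)
    pk_frame = auto_frame if peak_frame is None else int(peak_frame)
    pk_value = float(trace.dff[pk_frame]) if peak_frame is not None else auto_peak

    base_window = trace.baseline_window
    peak_window = centered_window(pk_frame, cfg.peak_frames, stack.n_frames)

    base_avg = average_frames(stack.calcium, base_window, cfg)
    peak_avg = average_frames(stack.calcium, peak_window, cfg)
    vessel_avg = average_frames(stack.vessel, peak_window, cfg)

    lumen = lumen_mask_from_vessel_channel(vessel_avg)
    mask = build_stalk_mask(peak_avg, cfg, exclude=lumen)
    dfield = apply_mask(baseline_subtract(peak_avg, base_avg), mask)

    simg = straighten_vessel(dfield, vessel, cfg, stack.pixel_size_um)
    zprof = zscore_profile(collapse_to_profile(simg, cfg), cfg)
    stat = sheath_peak(zprof, vessel, cfg)

    v_simg = straighten_vessel(vessel_avg, vessel, cfg, stack.pixel_size_um)
    v_prof = collapse_to_profile(v_simg, cfg)
    v_display = normalize_vessel_display(v_prof.raw, cfg)

    return VesselAnalysis(
        dff_trace=trace,
        peak_dff=pk_value,
        peak_frame=pk_frame,
        baseline_window=base_window,
        peak_window=peak_window,
        stalk_mask=mask,
        zprofile=zprof,
        statistic=stat,
        vessel_display=v_display,
    )
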