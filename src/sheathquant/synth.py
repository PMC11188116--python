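"""Synthetic two-channel perivascular Ca2+ imaging simulator.

Generates time-lapse stacks that emulate the study conditions of a
capillary-sheath recording: a bright static tube in the vessel-dye channel,
and an indicator channel consisting of a uniform baseline, bright static
Müller stalk cross-sections, a thin sheath ring hugging the vessel wall,
and a puff-evoked activity wave expanding radially from the puff origin.
Every component has a closed form so downstream analysis stages can be
verified against the generator's ground truth.

Model of the indicator channel (noiseless):

    F(t, y, x) = F0(y, x) + stalk(y, x)
                 + sigma_ref * max(A_sheath * ring(y, x),
                                   A_wave * wave(y, x)) * act(t, y, x)

where ``ring`` is a Gaussian annulus centered ``offset_um`` beyond the
vessel edge, ``wave`` decays exponentially with distance from the puff
origin, and ``act`` is a smoothstep front arriving at each pixel at
``onset + distance/speed``.  Amplitudes are expressed as multiples of the
reference noise SD ``sigma_ref = sqrt(shot_scale * baseline_F0 + read_sd^2)``
so that "amplitude" means "peak ΔF in units of background noise".  Noise,
when enabled, is Gaussian with variance ``shot_scale * mean + read_sd^2``
(the usual confocal shot + read model).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .io import ImageStack, PuffEvent, SheathQuantError, VesselTrace

CONDITIONS = ("control", "apb", "apb_suramin", "rd10_dvp")

# Emulation multipliers for the pharmacology / degeneration presets.  They
# parameterize the simulator to mirror the direction and rough size of the
# reported effects; they are inputs, not reproduced results.
APB_SURFACE_SCALE = 0.06      # surface-puff response in IP3R blockade
SURAMIN_SCALE = 0.26          # residual response after purinergic blockade
RD10_WIDTH_SCALE = 3.0        # diffuse, irregular deep-layer sheaths
RD10_AMPLITUDE_SCALE = 0.45
RD10_JITTER_UM = 2.0


@dataclass
class VesselSpec:
    """Centerline geometry: straight horizontal or in-plane sinusoid."""

    kind: str = "straight"          # 'straight' | 'sinusoid'
    diameter_um: float = 4.0
    intensity: float = 300.0        # peak dye intensity above floor
    floor: float = 10.0             # dye-channel background
    amplitude_um: float = 8.0       # sinusoid only
    period_um: float = 96.0         # sinusoid only

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "sinusoid"):
            raise SheathQuantError(f"unknown vessel kind: {self.kind!r}")
        if not (self.diameter_um > 0):
            raise SheathQuantError("vessel diameter_um must be > 0")


@dataclass
class SheathSpec:
    amplitude: float = 2.0      # peak ΔF as multiple of sigma_ref
    width_um: float = 1.5       # Gaussian SD of the ring
    offset_um: float = 1.0      # ring center beyond the vessel edge
    jitter_um: float = 0.0      # along-vessel wobble of the ring center

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise SheathQuantError("sheath amplitude must be >= 0")
        if not (self.width_um > 0):
            raise SheathQuantError("sheath width_um must be > 0")


@dataclass
class StalkSpec:
    """Bright static Müller stalk cross-sections (uniform disks).

    The default count x area covers ~3% of the field so the top-percentile
    masking rule has the same meaning it has in real recordings, where
    stalks are the top-intensity pixels.
    """

    count: int = 36
    radius_um: float = 3.0
    amplitude: float = 20.0     # static brightness as multiple of sigma_ref


@dataclass
class WaveSpec:
    onset_frame: int = 10
    speed_um_s: float = 25.0
    origin: Optional[Tuple[float, float]] = None  # (row, col); default: site-dependent
    amplitude: float = 0.5      # diffuse parenchymal ΔF, multiples of sigma_ref
    decay_um: float = 40.0      # spatial e-fold of the wave from the origin
    rise_s: float = 1.0         # smoothstep rise time of the front
    site: str = "surface"       # 'surface' | 'direct'
    duration_s: float = 0.2     # puff metadata


@dataclass
class NoiseSpec:
    shot_scale: float = 1.0
    read_sd: float = 2.0
    enabled: bool = True


@dataclass
class SynthConfig:
    """Generative parameters of one synthetic recording."""

    shape: Tuple[int, int, int] = (40, 192, 192)   # (T, Y, X)
    pixel_size_um: float = 1.0
    frame_interval_s: float = 0.5
    baseline_F0: float = 100.0
    lumen_dimming: float = 0.3  # indicator baseline inside the lumen, x F0
    vessel: VesselSpec = field(default_factory=VesselSpec)
    sheath: SheathSpec = field(default_factory=SheathSpec)
    stalks: StalkSpec = field(default_factory=StalkSpec)
    wave: WaveSpec = field(default_factory=WaveSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    condition: str = "control"
    seed: int = 0

    def sigma_ref(self) -> float:
        """Reference background noise SD implied by the noise parameters.

        Computed from the configured shot/read levels whether or not noise
        is actually applied, so amplitudes keep their meaning in noiseless
        runs.
        """
        s = math.sqrt(self.noise.shot_scale * self.baseline_F0 + self.noise.read_sd**2)
        if s == 0:
            raise SheathQuantError(
                "noise parameters imply sigma_ref = 0; amplitudes are undefined"
            )
        return s


@dataclass
class GroundTruth:
    """Hidden truth of a generated dataset, for recovery tests."""

    stalk_pixel_set: np.ndarray        # (K, 2) int rows/cols of stalk pixels
    vessel_mask: np.ndarray            # (Y, X) bool, lumen pixels
    sheath_amplitude: float
    sheath_width_um: float
    true_peak_dff: float               # amplitude * sigma_ref / baseline_F0
    sigma_ref: float
    f0_map: np.ndarray                 # static indicator baseline (Y, X)
    stalk_map: np.ndarray              # static stalk brightness (Y, X)
    activity_peak_map: np.ndarray      # asymptotic ΔF field (act == 1), (Y, X)
    dist_to_centerline_um: np.ndarray  # (Y, X) unsigned distance


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _centerline_points(cfg: SynthConfig) -> np.ndarray:
    T, ny, nx = cfg.shape
    px = cfg.pixel_size_um
    cols = np.arange(nx, dtype=float)
    # center row on the pixel grid so radial distances land on exact
    # multiples of the pixel size for a straight vessel
    cy = float((ny - 1) // 2)
    if cfg.vessel.kind == "straight":
        rows = np.full(nx, cy)
    else:
        amp = cfg.vessel.amplitude_um / px
        per = cfg.vessel.period_um / px
        rows = cy + amp * np.sin(2 * np.pi * cols / per)
    pts = np.column_stack([rows, cols])
    margin = cfg.sheath.offset_um + 3 * cfg.sheath.width_um
    halfspan = (cfg.vessel.diameter_um / 2 + margin) / px
    if rows.min() - halfspan < 0 or rows.max() + halfspan > ny - 1:
        raise SheathQuantError("vessel geometry exceeds image bounds")
    return pts


def _distance_fields(cfg: SynthConfig, pts: np.ndarray):
    """Unsigned distance (um) to the centerline and the index of the
    nearest centerline sample, for every pixel."""
    T, ny, nx = cfg.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    tree = cKDTree(pts)
    d_px, idx = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    dist_um = (d_px * cfg.pixel_size_um).reshape(ny, nx)
    return dist_um, idx.reshape(ny, nx)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: SynthConfig,
) -> Tuple[ImageStack, VesselTrace, PuffEvent, GroundTruth]:
    """Generate one synthetic recording with its ground truth.

    Deterministic under a fixed ``cfg.seed``.
    """
    T, ny, nx = cfg.shape
    if T < 1:
        raise SheathQuantError("need at least one frame")
    px = cfg.pixel_size_um
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.sigma_ref()

    pts = _centerline_points(cfg)
    dist_um, nearest_idx = _distance_fields(cfg, pts)
    r_um = cfg.vessel.diameter_um / 2.0

    # --- vessel channel: static soft-edged tube -------------------------
    edge_softness = 0.5  # um
    tube = 1.0 / (1.0 + np.exp((dist_um - r_um) / edge_softness))
    vessel_frame = cfg.vessel.floor + cfg.vessel.intensity * tube

    # --- indicator statics ----------------------------------------------
    lumen = dist_um < r_um
    f0_map = np.where(lumen, cfg.lumen_dimming * cfg.baseline_F0, cfg.baseline_F0)

    stalk_map = np.zeros((ny, nx))
    stalk_pixels = []
    stalk_r_px = cfg.stalks.radius_um / px
    yy, xx = np.mgrid[0:ny, 0:nx]
    placed = 0
    attempts = 0
    while placed < cfg.stalks.count and attempts < 1000:
        attempts += 1
        cy = rng.uniform(stalk_r_px, ny - 1 - stalk_r_px)
        cx = rng.uniform(stalk_r_px, nx - 1 - stalk_r_px)
        # keep stalks clear of the lumen and the sheath ring
        d_center = (
            np.min(np.linalg.norm(pts - np.array([cy, cx]), axis=1)) * px
        )
        if d_center < r_um + cfg.sheath.offset_um + 3 * cfg.sheath.width_um + cfg.stalks.radius_um:
            continue
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= stalk_r_px**2
        stalk_map[disk] = cfg.stalks.amplitude * sigma
        stalk_pixels.append(np.column_stack(np.nonzero(disk)))
        placed += 1
    if placed < cfg.stalks.count:
        raise SheathQuantError("could not place all stalks inside image bounds")
    stalk_pixel_set = (
        np.unique(np.concatenate(stalk_pixels), axis=0)
        if stalk_pixels
        else np.empty((0, 2), int)
    )

    # --- activity: sheath ring + diffuse wave ---------------------------
    ring_center_um = r_um + cfg.sheath.offset_um
    if cfg.sheath.jitter_um > 0:
        # smooth along-vessel wobble of the ring center (diffuse/irregular
        # sheath emulation); a low-order random Fourier series over arclength
        s = np.arange(len(pts)) * px
        L = max(s[-1], 1.0)
        wobble = np.zeros(len(pts))
        for k in (1, 2, 3):
            wobble += rng.normal() * np.sin(2 * np.pi * k * s / L + rng.uniform(0, 2 * np.pi))
        wobble *= cfg.sheath.jitter_um / max(np.abs(wobble).max(), 1e-12)
        center_map = ring_center_um + wobble[nearest_idx]
    else:
        center_map = np.full((ny, nx), ring_center_um)
    ring = np.exp(-((dist_um - center_map) ** 2) / (2 * cfg.sheath.width_um**2))
    ring[lumen] = 0.0  # no Müller signal inside the lumen

    if cfg.wave.origin is None:
        if cfg.wave.site == "surface":
            origin = (0.0, (nx - 1) / 2.0)
        else:  # direct puff onto the vessel
            origin = (float(pts[len(pts) // 2, 0]), float(pts[len(pts) // 2, 1]))
    else:
        origin = cfg.wave.origin
    d_origin_um = np.hypot(yy - origin[0], xx - origin[1]) * px
    wave = np.exp(-d_origin_um / cfg.wave.decay_um)
    wave[lumen] = 0.0

    amp_map = sigma * np.maximum(cfg.sheath.amplitude * ring, cfg.wave.amplitude * wave)

    onset_s = cfg.wave.onset_frame * cfg.frame_interval_s
    arrival_s = onset_s + d_origin_um / cfg.wave.speed_um_s
    t_s = np.arange(T) * cfg.frame_interval_s

    # smoothstep front: 0 before arrival, 1 after arrival + rise_s
    u = (t_s[:, None, None] - arrival_s[None, :, :]) / cfg.wave.rise_s
    u = np.clip(u, 0.0, 1.0)
    act = u * u * (3.0 - 2.0 * u)

    calcium = f0_map[None] + stalk_map[None] + amp_map[None] * act
    vessel_stack = np.broadcast_to(vessel_frame, (T, ny, nx)).copy()

    if cfg.noise.enabled:
        calcium = calcium + rng.normal(size=calcium.shape) * np.sqrt(
            cfg.noise.shot_scale * calcium + cfg.noise.read_sd**2
        )
        vessel_stack = vessel_stack + rng.normal(size=vessel_stack.shape) * np.sqrt(
            cfg.noise.shot_scale * vessel_stack + cfg.noise.read_sd**2
        )
        calcium = np.clip(calcium, 0, None)
        vessel_stack = np.clip(vessel_stack, 0, None)

    stack = ImageStack(vessel_stack, calcium, px, cfg.frame_interval_s)
    # subsample the dense per-column centerline to keep the trace compact
    step = max(1, int(round(2.0 / px)))
    cl = pts[::step]
    if not np.array_equal(cl[-1], pts[-1]):
        cl = np.vstack([cl, pts[-1]])
    vessel_trace = VesselTrace(cl, cfg.vessel.diameter_um,
                               "DVP" if cfg.condition == "rd10_dvp" else "IVP")
    event = PuffEvent(
        onset_frame=cfg.wave.onset_frame,
        duration_s=cfg.wave.duration_s,
        site=cfg.wave.site,
    )
    truth = GroundTruth(
        stalk_pixel_set=stalk_pixel_set,
        vessel_mask=lumen,
        sheath_amplitude=cfg.sheath.amplitude,
        sheath_width_um=cfg.sheath.width_um,
        true_peak_dff=cfg.sheath.amplitude * sigma / cfg.baseline_F0,
        sigma_ref=sigma,
        f0_map=f0_map,
        stalk_map=stalk_map,
        activity_peak_map=amp_map,
        dist_to_centerline_um=dist_um,
    )
    return stack, vessel_trace, event, truth


def preset_condition(name: str, base: SynthConfig) -> SynthConfig:
    """Derive a condition preset from a base configuration.

    ``control`` returns an unchanged copy.  ``apb`` (IP3R blockade) scales
    the surface-puff response to ~6% of control while leaving direct-puff
    responses intact; ``apb_suramin`` additionally scales responses to ~26%
    (purinergic blockade); ``rd10_dvp`` widens the sheath 3x, lowers its
    amplitude to 45%, and adds along-vessel jitter of the ring center
    (diffuse, irregular deep-layer sheaths).  The multipliers are emulation
    targets taken from reported effect sizes, not reproduced results.
    """
    if name not in CONDITIONS:
        raise SheathQuantError(f"unknown condition: {name!r} (choose from {CONDITIONS})")
    cfg = copy.deepcopy(base)
    cfg.condition = name
    if name == "control":
        return cfg
    if name in ("apb", "apb_suramin"):
        scale = 1.0
        if cfg.wave.site == "surface":
            scale *= APB_SURFACE_SCALE
        if name == "apb_suramin":
            scale *= SURAMIN_SCALE
        cfg.sheath.amplitude *= scale
        cfg.wave.amplitude *= scale
        return cfg
    # rd10_dvp
    cfg.sheath.width_um *= RD10_WIDTH_SCALE
    cfg.sheath.amplitude *= RD10_AMPLITUDE_SCALE
    cfg.sheath.jitter_um = RD10_JITTER_UM
    return cfg
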