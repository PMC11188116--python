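import numpy as np
import pytest

from sheathquant import (
    AnalysisConfig,
    SheathProfile,
    SheathQuantError,
    VesselTrace,
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
from sheathquant.profile import StalkMask, StraightenedImage

from reference import (
    naive_average_frames,
    naive_collapse,
    naive_straighten,
)


def horizontal_vessel(row=32.0, ncol=64, diameter_um=4.0):
    pts = np.column_stack([np.full(ncol // 4, row), np.arange(0, ncol, 4, dtype=float)])
    return VesselTrace(pts, diameter_um)


# ---------------------------------------------------------------------------
# averaging / subtraction
# ---------------------------------------------------------------------------

def test_average_frames_constant_and_ramp():
    const = np.full((12, 8, 8), 7.0)
    assert np.array_equal(average_frames(const, (0, 9)), np.full((8, 8), 7.0))
    ramp = np.arange(12, dtype=float)[:, None, None] * np.ones((8, 8))
    assert np.array_equal(average_frames(ramp, (0, 9)), np.full((8, 8), 4.0))


def test_average_frames_window_validation():
    frames = np.zeros((12, 4, 4))
    cfg = AnalysisConfig()
    with pytest.raises(SheathQuantError, match="outside"):
        average_frames(frames, (5, 15), cfg)
    with pytest.raises(SheathQuantError, match="8-10"):
        average_frames(frames, (0, 5), cfg)
    loose = AnalysisConfig(allow_out_of_range=True)
    assert average_frames(frames, (0, 5), loose).shape == (4, 4)


def test_average_frames_matches_naive_loop():
    rng = np.random.default_rng(1)
    frames = rng.uniform(0, 500, size=(14, 10, 11))
    got = average_frames(frames, (2, 11))
    assert np.allclose(got, naive_average_frames(frames, (2, 11)), atol=1e-10)


def test_baseline_subtract():
    base = np.full((6, 6), 100.0)
    peak = np.full((6, 6), 150.0)
    assert np.array_equal(baseline_subtract(peak, base), np.full((6, 6), 50.0))
    assert np.array_equal(baseline_subtract(base, base), np.zeros((6, 6)))
    # negative responses are kept, not clipped
    assert baseline_subtract(base, peak).min() == -50.0
    with pytest.raises(SheathQuantError, match="mismatch"):
        baseline_subtract(peak, np.zeros((5, 6)))


# ---------------------------------------------------------------------------
# stalk mask
# ---------------------------------------------------------------------------

def test_constant_field_yields_empty_mask():
    mask = build_stalk_mask(np.full((50, 50), 3.0), AnalysisConfig())
    assert not mask.mask.any()


def test_top_percentile_covers_planted_bright_pixels():
    """300 brightest pixels of a 100x100 field are exactly the top 3%."""
    rng = np.random.default_rng(0)
    field = rng.uniform(0, 1, size=(100, 100))
    flat = rng.choice(10000, size=300, replace=False)
    field.ravel()[flat] += 10.0
    mask = build_stalk_mask(field, AnalysisConfig())
    pre_dilation = field > mask.threshold
    planted = np.zeros((100, 100), dtype=bool)
    planted.ravel()[flat] = True
    assert pre_dilation.sum() == 300
    assert (pre_dilation & planted).sum() == 300
    assert (mask.mask & planted).sum() == 300  # dilation only adds pixels


def test_excluded_pixels_do_not_set_the_threshold():
    field = np.ones((40, 40))
    field[:, :4] = 1000.0  # a bright column, e.g. the vessel
    exclude = np.zeros((40, 40), dtype=bool)
    exclude[:, :4] = True
    mask = build_stalk_mask(field, AnalysisConfig(), exclude=exclude)
    # percentile over the remaining constant field -> only the bright
    # column exceeds it
    assert mask.threshold == 1.0
    assert mask.mask[:, :4].all()
    assert not mask.mask[:, 7:].any()


def test_apply_mask_semantics_and_idempotence():
    field = np.arange(36, dtype=float).reshape(6, 6)
    empty = StalkMask(np.zeros((6, 6), bool), 3.0, 2, 0.0)
    assert np.array_equal(apply_mask(field, empty), field)
    row = StalkMask(np.zeros((6, 6), bool), 3.0, 2, 0.0)
    row.mask[2] = True
    once = apply_mask(field, row)
    assert np.isnan(once[2]).all() and np.isfinite(once[3]).all()
    twice = apply_mask(once, row)
    assert np.array_equal(np.isnan(twice), np.isnan(once))
    with pytest.raises(SheathQuantError, match="mismatch"):
        apply_mask(np.zeros((5, 6)), row)


# ---------------------------------------------------------------------------
# straightening
# ---------------------------------------------------------------------------

def test_straighten_straight_vessel_is_identity():
    rng = np.random.default_rng(2)
    field = rng.uniform(0, 100, size=(64, 64))
    vessel = horizontal_vessel(row=32.0)
    cfg = AnalysisConfig()
    simg = straighten_vessel(field, vessel, cfg, pixel_size_um=1.0)
    w = 22  # profile halfwidth 20 + radius 2
    offsets = np.arange(-w, w + 1)
    # normal points toward decreasing row: sample (32 - d, s)
    expected = np.stack([field[32 - d, : simg.data.shape[0]] for d in offsets], axis=1)
    assert simg.data.shape[1] == 45
    assert np.allclose(simg.data, expected, atol=1e-9)
    assert np.array_equal(simg.distances_um, offsets.astype(float))


def test_straighten_quarter_circle_on_radial_field_gives_identical_rows():
    """A centerline along a circular arc over a radially symmetric field
    must produce the same radial profile at every arclength position."""
    ny = nx = 128
    cy, cx = 64.0, 64.0
    R = 40.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)
    field = np.exp(-((r - R) ** 2) / 200.0)
    theta = np.linspace(0, np.pi / 2, 40)
    pts = np.column_stack([cy + R * np.sin(theta), cx + R * np.cos(theta)])
    vessel = VesselTrace(pts, 4.0)
    simg = straighten_vessel(field, vessel, AnalysisConfig(), pixel_size_um=1.0)
    ref = np.nanmedian(simg.data, axis=0)
    dev = np.nanmax(np.abs(simg.data - ref[None, :]))
    assert dev < 5e-3


def test_straighten_nan_contamination_follows_the_stencil():
    field = np.ones((64, 64))
    field[20, 10] = np.nan
    cfg = AnalysisConfig()
    # integer coordinates: only the sample that lands on the NaN is hit
    simg = straighten_vessel(field, horizontal_vessel(row=32.0), cfg, 1.0)
    nan_cells = np.argwhere(np.isnan(simg.data))
    assert nan_cells.tolist() == [[10, list(simg.distances_um).index(12.0)]]
    # half-pixel offset: the stencil spans rows 19-20 and 20-21
    simg2 = straighten_vessel(field, horizontal_vessel(row=32.5), cfg, 1.0)
    nan_d = simg2.distances_um[np.isnan(simg2.data[10])]
    assert set(nan_d.tolist()) == {12.0, 13.0}


def test_straighten_matches_naive_loops():
    rng = np.random.default_rng(4)
    field = rng.uniform(0, 10, size=(64, 64))
    field[25, 30] = np.nan
    vessel = VesselTrace(
        np.column_stack([32.0 + 0.3 * np.arange(16), np.arange(0, 64, 4, dtype=float)]),
        4.0,
    )
    cfg = AnalysisConfig()
    simg = straighten_vessel(field, vessel, cfg, 1.0)
    ref, d_ref = naive_straighten(field, vessel.centerline, 2.0, 20.0, 1.0)
    assert np.array_equal(np.isnan(simg.data), np.isnan(ref))
    both = np.isfinite(ref)
    assert np.allclose(simg.data[both], ref[both], atol=1e-10)
    assert np.allclose(simg.distances_um, d_ref)


def test_straighten_degenerate_centerline():
    with pytest.raises(SheathQuantError, match="distinct"):
        VesselTrace(np.array([[2.0, 2.0], [2.0, 2.0]]), 4.0)


# ---------------------------------------------------------------------------
# collapse and z-score
# ---------------------------------------------------------------------------

def test_collapse_constant_and_nan_mean():
    simg = StraightenedImage(np.full((20, 9), 3.5), np.arange(-4.0, 5.0), 1.0)
    prof = collapse_to_profile(simg, AnalysisConfig())
    assert np.allclose(prof.raw, 3.5)
    assert (prof.n_valid == 20).all()

    data = np.full((10, 5), 2.0)
    data[:5, 2] = np.nan
    data[5:, 2] = 8.0
    prof = collapse_to_profile(
        StraightenedImage(data, np.arange(-2.0, 3.0), 1.0), AnalysisConfig()
    )
    assert prof.raw[2] == pytest.approx(8.0)
    assert prof.n_valid[2] == 5


def test_collapse_matches_naive_loops():
    rng = np.random.default_rng(5)
    data = rng.uniform(-3, 3, size=(30, 11))
    data[rng.uniform(size=data.shape) < 0.2] = np.nan
    simg = StraightenedImage(data, np.arange(-5.0, 6.0), 1.0)
    raw, n_valid = naive_collapse(data)
    prof = collapse_to_profile(simg, AnalysisConfig())
    assert np.allclose(prof.raw, raw, atol=1e-12, equal_nan=True)
    assert np.array_equal(prof.n_valid, n_valid)


def _profile(d, raw):
    return SheathProfile(d_um=np.asarray(d, float), raw=np.asarray(raw, float),
                         n_valid=np.ones(len(d), int))


def test_zscore_background_has_mean_zero_sd_one():
    rng = np.random.default_rng(6)
    d = np.arange(-22.0, 23.0)
    raw = rng.normal(5.0, 2.0, size=d.size)
    cfg = AnalysisConfig()
    zp = zscore_profile(_profile(d, raw), cfg)
    bg = np.abs(d) >= cfg.background_min_um
    assert abs(zp.z[bg].mean()) < 1e-12
    assert abs(zp.z[bg].std(ddof=1) - 1.0) < 1e-12


def test_zscore_recovers_constructed_bump_height():
    """Background noise of SD 1 with a 3-sigma bump: peak z ~ 3."""
    rng = np.random.default_rng(7)
    d = np.arange(-25.0, 26.0)
    raw = rng.normal(0.0, 1.0, size=d.size)
    bg = np.abs(d) >= 15.0
    mu, sd = raw[bg].mean(), raw[bg].std(ddof=1)
    bump_idx = np.where(d == 3.0)[0][0]
    raw[bump_idx] = mu + 3.0 * sd
    zp = zscore_profile(_profile(d, raw), AnalysisConfig())
    assert zp.z[bump_idx] == pytest.approx(3.0, abs=1e-9)
    assert zp.bg_mean == pytest.approx(mu) and zp.bg_sd == pytest.approx(sd)


def test_zscore_inner_bins_at_background_mean_are_zero():
    d = np.arange(-22.0, 23.0)
    raw = np.zeros(d.size)
    bg = np.abs(d) >= 15.0
    raw[bg] = np.tile([4.0, 6.0], bg.sum() // 2)  # mean exactly 5
    raw[~bg] = 5.0
    zp = zscore_profile(_profile(d, raw), AnalysisConfig())
    assert np.allclose(zp.z[~bg], 0.0)


def test_zscore_error_conditions():
    d = np.arange(-22.0, 23.0)
    with pytest.raises(SheathQuantError, match="zero"):
        zscore_profile(_profile(d, np.ones(d.size)), AnalysisConfig())
    raw = np.ones(d.size)
    raw[np.abs(d) >= 14.0] = np.nan  # too few valid background bins
    with pytest.raises(SheathQuantError, match="background window"):
        zscore_profile(_profile(d, raw), AnalysisConfig())


# ---------------------------------------------------------------------------
# sheath peak statistic
# ---------------------------------------------------------------------------

def vessel_stub(diameter_um=4.0):
    return VesselTrace(np.array([[10.0, 0.0], [10.0, 4.0]]), diameter_um)


def _zprofile(d, z):
    p = _profile(d, z)
    p.z = np.asarray(z, float)
    p.bg_mean, p.bg_sd = 0.0, 1.0
    return p


def test_symmetric_bumps_average_to_their_height():
    d = np.arange(-22.0, 23.0)
    z = np.zeros(d.size)
    z[d == 3.0] = 4.0
    z[d == -3.0] = 4.0
    st = sheath_peak(_zprofile(d, z), vessel_stub(), AnalysisConfig())
    assert st.peak_z_mean == 4.0
    assert (st.pos_left_um, st.pos_right_um) == (-3.0, 3.0)


def test_asymmetric_bumps_average():
    d = np.arange(-22.0, 23.0)
    z = np.zeros(d.size)
    z[d == -4.0] = 2.0
    z[d == 5.0] = 4.0
    st = sheath_peak(_zprofile(d, z), vessel_stub(), AnalysisConfig())
    assert st.peak_z_mean == 3.0 and st.peak_z_left == 2.0 and st.peak_z_right == 4.0


def test_search_window_excludes_lumen_and_far_field():
    d = np.arange(-22.0, 23.0)
    z = np.zeros(d.size)
    z[d == 1.0] = 50.0   # inside the vessel: ignored
    z[d == 13.0] = 50.0  # beyond radius + 10 um: ignored
    z[d == 3.0] = 1.5
    z[d == -3.0] = 1.5
    st = sheath_peak(_zprofile(d, z), vessel_stub(), AnalysisConfig())
    assert st.peak_z_mean == 1.5


def test_one_sided_statistic_when_a_side_is_nan():
    d = np.arange(-22.0, 23.0)
    z = np.zeros(d.size)
    z[(d < 0)] = np.nan
    z[d == 3.0] = 2.5
    st = sheath_peak(_zprofile(d, z), vessel_stub(), AnalysisConfig())
    assert st.one_sided
    assert st.peak_z_mean == 2.5
    assert np.isnan(st.peak_z_left)
    d2 = d.copy()
    z2 = np.full(d.size, np.nan)
    with pytest.raises(SheathQuantError, match="entirely NaN"):
        sheath_peak(_zprofile(d2, z2), vessel_stub(), AnalysisConfig())


# ---------------------------------------------------------------------------
# vessel display normalization
# ---------------------------------------------------------------------------

def test_vessel_display_normalization():
    cfg = AnalysisConfig()
    prof = np.array([0.0, 1.0, 37.0, 2.0])
    out = normalize_vessel_display(prof, cfg)
    assert out.max() == 5.0
    already = np.array([0.0, 5.0, 1.0])
    assert np.array_equal(normalize_vessel_display(already, cfg), already)
    # scale invariance: doubling the input changes nothing
    assert np.allclose(normalize_vessel_display(2 * prof, cfg), out)
    with pytest.raises(SheathQuantError, match="positive"):
        normalize_vessel_display(np.array([-1.0, 0.0]), cfg)
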