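"""Drift correction, turn-on counting, radial profiles and rate series."""

import numpy as np
import pytest
from scipy import ndimage

import tgtquant as tq
from tgtquant.calibration import CalibrationResult
from tgtquant.rupture import MAX_TOTAL_RUPTURES, MarkerLostError
from tgtquant.synth import _render_spot


def _fiducial_stack(n_frames, drift, jitter_per_marker=0.0, seed=0,
                    markers=((15.0, 15.0), (15.0, 49.0), (49.0, 32.0))):
    """Stack with bright fiducials only, drifting by `drift` px/frame."""
    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, 64, 64))
    for t in range(n_frames):
        frame = np.full((64, 64), 200.0)
        for r, c in markers:
            jr = jitter_per_marker * rng.standard_normal()
            jc = jitter_per_marker * rng.standard_normal()
            _render_spot(frame, r + drift[0] * t + jr, c + drift[1] * t + jc,
                         1.1, 30000.0)
        stack[t] = frame + rng.normal(0, 5.0, (64, 64))
    return stack


# ---------------------------------------------------------------------------
# Fiducial tracking and registration
# ---------------------------------------------------------------------------


def test_zero_drift_offsets_near_zero():
    stack = _fiducial_stack(20, (0.0, 0.0))
    track = tq.track_fiducials(stack)
    assert np.abs(track.offsets).max() < 0.05
    assert track.offsets[0] == pytest.approx((0.0, 0.0))


def test_linear_drift_slope_recovered():
    stack = _fiducial_stack(30, (0.1, 0.05))
    track = tq.track_fiducials(stack)
    t = np.arange(30)
    slope_r = np.polyfit(t, track.offsets[:, 0], 1)[0]
    slope_c = np.polyfit(t, track.offsets[:, 1], 1)[0]
    assert slope_r == pytest.approx(0.1, rel=0.05)
    assert slope_c == pytest.approx(0.05, rel=0.05)


def test_marker_averaging_beats_single_marker():
    """Averaging 3 independently jittering markers reduces the drift error."""
    drift = (0.08, 0.0)
    stack = _fiducial_stack(40, drift, jitter_per_marker=0.3, seed=5)
    true = np.outer(np.arange(40), drift)

    err_avg = np.sqrt(np.mean((tq.track_fiducials(stack).offsets - true) ** 2))
    single = tq.track_fiducials(stack, candidate_positions=[(15.0, 15.0)])
    err_one = np.sqrt(np.mean((single.offsets - true) ** 2))
    assert err_avg < err_one


def test_lost_marker_raises_with_frame_number():
    stack = _fiducial_stack(10, (0.0, 0.0), markers=((20.0, 20.0),))
    stack[6:] = 200.0    # marker vanishes at frame 6
    with pytest.raises(MarkerLostError, match="frame 6"):
        tq.track_fiducials(stack, candidate_positions=[(20.0, 20.0)])


def test_identity_registration_is_a_no_op():
    stack = _fiducial_stack(5, (0.0, 0.0))
    drift = tq.DriftTrack(offsets=np.zeros((5, 2)))
    out = tq.register_stack(stack, drift)
    np.testing.assert_array_equal(out, stack)


def test_registration_residual_below_fifth_of_a_pixel():
    """Fiducials are stationary to < 0.2 px RMS after registration."""
    stack = _fiducial_stack(40, (0.1, 0.07), seed=2)
    drift = tq.track_fiducials(stack)
    registered = tq.register_stack(stack, drift)
    resid = tq.track_fiducials(registered)
    rms = float(np.sqrt(np.mean(resid.offsets ** 2)))
    assert rms < 0.2


def test_drift_then_correction_matches_no_drift_counting(calib800):
    """Counting after drift correction is within 3% of drift-free counting."""
    def run(drift_v, jitter):
        params = tq.AcquisitionParams(seed=31)
        scenario = tq.SpreadingScenario(n_events=300)
        stack, _ = tq.simulate_rupture_stack(params, scenario,
                                             drift_velocity=drift_v,
                                             drift_jitter_sd=jitter)
        if drift_v != (0.0, 0.0):
            stack = tq.register_stack(stack, tq.track_fiducials(stack))
        return tq.cumulative_rupture_map(stack, calib800).total_count

    still = run((0.0, 0.0), 0.0)
    moved = run((0.1, 0.1), 0.03)
    assert moved == pytest.approx(still, rel=0.03)


# ---------------------------------------------------------------------------
# Frame differencing
# ---------------------------------------------------------------------------


def test_constant_stack_has_zero_increments():
    stack = np.full((8, 32, 32), 100.0)
    inc = tq.frame_difference_map(stack)
    np.testing.assert_array_equal(inc, 0.0)


def test_even_median_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        tq.frame_difference_map(np.zeros((8, 16, 16)), median_window=2)


def test_single_frame_defocus_spike_removed_by_median_filter():
    """A one-frame intensity transient survives N=1 but not N=3."""
    stack = np.full((9, 32, 32), 100.0)
    stack[4] += 50.0   # defocus-like global transient
    inc_raw = tq.frame_difference_map(stack, median_window=1)
    inc_filt = tq.frame_difference_map(stack, median_window=3)
    assert inc_raw.max() == pytest.approx(50.0)
    np.testing.assert_array_equal(inc_filt, 0.0)


def test_turn_on_increment_localized_to_event_frame():
    stack = np.full((12, 32, 32), 100.0)
    for t in range(6, 12):
        _render_spot(stack[t], 16.0, 16.0, 1.1, 800.0)
    inc = tq.frame_difference_map(stack, median_window=3)
    per_frame = inc.sum(axis=(1, 2))
    assert per_frame.argmax() in (4, 5, 6)
    assert per_frame.max() == pytest.approx(800.0, rel=1e-6)


# ---------------------------------------------------------------------------
# Cumulative counting
# ---------------------------------------------------------------------------


def test_noise_free_count_is_exact(clean_sim, calib800):
    """Noise and drift off: the pipeline returns the event count exactly."""
    _, _, stack, truth = clean_sim
    rmap = tq.cumulative_rupture_map(stack, calib800, median_window=1,
                                     background_window=1, late_window=1)
    assert rmap.total_count == pytest.approx(len(truth.rupture_events), abs=1e-6)


def test_default_noise_count_recovery(default_sim, calib800):
    params, scenario, stack, truth = default_sim
    registered = tq.register_stack(stack, tq.track_fiducials(stack))
    roi = ndimage.binary_dilation(truth.footprint_mask_series[-1], iterations=2)
    rmap = tq.cumulative_rupture_map(registered, calib800, roi)
    assert rmap.total_count == pytest.approx(len(truth.rupture_events), rel=0.10)


def test_total_count_consistent_with_map(default_sim, calib800):
    _, _, stack, truth = default_sim
    registered = tq.register_stack(stack, tq.track_fiducials(stack))
    roi = ndimage.binary_dilation(truth.footprint_mask_series[-1], iterations=2)
    rmap = tq.cumulative_rupture_map(registered, calib800, roi)
    assert (rmap.counts >= 0).all()
    assert rmap.total_count <= rmap.counts.sum() + 1e-9


def test_empty_roi_counts_near_zero(default_sim, calib800):
    """An ROI far from every spot yields |count| < 5 molecules."""
    _, _, stack, _ = default_sim
    registered = tq.register_stack(stack, tq.track_fiducials(stack))
    roi = np.zeros(registered.frame_shape, bool)
    roi[2:12, 100:160] = True   # corner strip, away from cell and fiducials
    rmap = tq.cumulative_rupture_map(registered, calib800, roi)
    assert abs(rmap.total_count) < 5.0


def test_missing_calibration_rejected(clean_sim):
    _, _, stack, _ = clean_sim
    with pytest.raises(ValueError, match="[Cc]alibration"):
        tq.cumulative_rupture_map(stack, None)


def test_conservation_increments_vs_cumulative(default_sim, clean_sim, calib800):
    """Summed rate increments match the cumulative count (2% clean, 10% noisy)."""
    _, _, clean_stack, clean_truth = clean_sim
    rates = tq.rupture_rate_timeseries(clean_stack, calib800,
                                       [np.ones(clean_stack.frame_shape, bool)],
                                       median_window=1, late_window=1,
                                       background_window=1)
    cum = tq.cumulative_rupture_map(clean_stack, calib800, median_window=1,
                                    background_window=1, late_window=1)
    inc_sum = rates.per_cell[0].sum() * clean_stack.frame_interval / 60.0
    assert inc_sum == pytest.approx(cum.total_count, rel=0.02)

    _, _, stack, truth = default_sim
    registered = tq.register_stack(stack, tq.track_fiducials(stack))
    roi = ndimage.binary_dilation(truth.footprint_mask_series[-1], iterations=2)
    cum_n = tq.cumulative_rupture_map(registered, calib800, roi)
    rates_n = tq.rupture_rate_timeseries(registered, calib800, [roi])
    inc_sum_n = rates_n.per_cell[0].sum() * registered.frame_interval / 60.0
    assert inc_sum_n == pytest.approx(cum_n.total_count, rel=0.10)


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------


def _disk_roi(shape, center, radius, pixel_size=0.16):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    rois = tq.segment_ricm(
        tq.simulate_ricm(mask, tq.AcquisitionParams(seed=8, image_shape=shape)),
        pixel_size)
    assert len(rois) == 1
    return rois[0]


def _map_from_counts(counts, calib, pixel_size=0.16):
    return tq.RuptureMap(counts=counts, total_count=float(counts.sum()),
                         calibration=calib, pixel_size=pixel_size)


def test_uniform_density_gives_flat_profile(calib800):
    roi = _disk_roi((256, 256), (128, 128), 90)
    counts = np.where(roi.mask, 1.0, 0.0)
    prof = tq.radial_profile(_map_from_counts(counts, calib800), roi, n_bins=10)
    assert prof.normalized.min() > 0.9


def test_edge_ring_peaks_in_outer_bin(calib800):
    roi = _disk_roi((256, 256), (128, 128), 90)
    rr, cc = np.ogrid[:256, :256]
    rnorm = np.sqrt((rr - 128) ** 2 + (cc - 128) ** 2) / 90.0
    counts = np.where((rnorm >= 0.9) & (rnorm <= 1.0), 1.0, 0.0)
    prof = tq.radial_profile(_map_from_counts(counts, calib800), roi, n_bins=10)
    assert prof.bin_centers[prof.normalized.argmax()] >= 0.9
    assert prof.normalized.max() == 1.0


def test_elongated_roi_ring_peaks_at_same_radius(calib800):
    """Ray-wise normalization puts an edge ring at the same peak location
    for elongated and circular cells."""
    shape = (256, 512)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    b, a = 55.0, 165.0
    enorm = np.sqrt(((rr - 128) / b) ** 2 + ((cc - 256) / a) ** 2)
    mask = enorm <= 1.0
    rois = tq.segment_ricm(
        tq.simulate_ricm(mask, tq.AcquisitionParams(seed=8, image_shape=shape)),
        0.16)
    counts = np.where((enorm >= 0.9) & (enorm <= 1.0), 1.0, 0.0)
    prof = tq.radial_profile(_map_from_counts(counts, calib800), rois[0], n_bins=10)
    assert prof.bin_centers[prof.normalized.argmax()] >= 0.9


def test_degenerate_roi_rejected(calib800):
    roi = tq.CellROI(mask=np.zeros((32, 32), bool), contour=np.empty((0, 2)),
                     centroid=(16.0, 16.0), area=0.0, aspect_ratio=1.0)
    roi.mask[16, 16] = True
    with pytest.raises(ValueError, match="degenerate"):
        tq.radial_profile(_map_from_counts(np.zeros((32, 32)), calib800), roi)


# ---------------------------------------------------------------------------
# Rate time series
# ---------------------------------------------------------------------------


def test_constant_hazard_rate_recovered(calib800):
    """A 100 events/min scenario reads back at 100 +/- 10 per minute."""
    params = tq.AcquisitionParams(seed=17, n_frames=40)
    scenario = tq.SpreadingScenario(rate=100.0, spreading_timescale=8)
    stack, truth = tq.simulate_rupture_stack(params, scenario)
    registered = tq.register_stack(stack, tq.track_fiducials(stack))
    roi = ndimage.binary_dilation(truth.footprint_mask_series[-1], iterations=2)
    rates = tq.rupture_rate_timeseries(registered, calib800, [roi])
    # steady-state portion: footprint grown, hazard constant
    steady = rates.per_cell[0, 20:36]
    assert steady.mean() == pytest.approx(100.0, abs=10.0)


def test_zero_rate_series_near_zero(calib800):
    params = tq.AcquisitionParams(seed=18, n_frames=20)
    scenario = tq.SpreadingScenario(rate=0.0)
    stack, _ = tq.simulate_rupture_stack(params, scenario)
    registered = tq.register_stack(stack, tq.track_fiducials(stack))
    rates = tq.rupture_rate_timeseries(
        registered, calib800, [np.ones(stack.frame_shape, bool)])
    assert np.abs(rates.per_cell).max() < 5.0


def test_hazard_peak_ordering_recovered(calib800):
    """Early- vs late-peaked hazards keep their order in the rate series."""
    def center_of_mass(profile_name, seed):
        params = tq.AcquisitionParams(seed=seed)
        scenario = tq.SpreadingScenario(n_events=400, rate_profile=profile_name,
                                        spreading_timescale=10)
        stack, truth = tq.simulate_rupture_stack(params, scenario)
        registered = tq.register_stack(stack, tq.track_fiducials(stack))
        roi = ndimage.binary_dilation(truth.footprint_mask_series[-1], iterations=2)
        rates = tq.rupture_rate_timeseries(registered, calib800, [roi])
        w = np.clip(rates.per_cell[0], 0, None)
        com = float((rates.times_min * w).sum() / w.sum())
        truth_com = float(np.mean([f for f, _, _ in truth.rupture_events]))
        return com, truth_com

    com_early, truth_early = center_of_mass("early_peak", 41)
    com_late, truth_late = center_of_mass("late_peak", 42)
    assert truth_early < truth_late          # generator sanity
    assert com_early < com_late


def test_max_total_filter_excludes_cells_exactly(calib800):
    """Cells at or above the molecule cap are excluded from the summary."""
    stack = np.full((10, 48, 48), 100.0)
    # cell A: modest signal; cell B: enormous signal
    for t in range(4, 10):
        _render_spot(stack[t], 12.0, 12.0, 1.1, 800.0 * 5)
        _render_spot(stack[t], 36.0, 36.0, 1.1, 800.0 * MAX_TOTAL_RUPTURES * 2)
    mask_a = np.zeros((48, 48), bool); mask_a[:24, :24] = True
    mask_b = np.zeros((48, 48), bool); mask_b[24:, 24:] = True
    rates = tq.rupture_rate_timeseries(stack, calib800, [mask_a, mask_b],
                                       median_window=1, late_window=1,
                                       background_window=1, frame_interval=60.0)
    assert rates.included.tolist() == [True, False]
    assert rates.per_cell.shape[0] == 1


def test_no_passing_cells_flagged_empty(calib800):
    stack = np.full((10, 32, 32), 100.0)
    for t in range(4, 10):
        _render_spot(stack[t], 16.0, 16.0, 1.1, 800.0 * MAX_TOTAL_RUPTURES * 2)
    rates = tq.rupture_rate_timeseries(stack, calib800,
                                       [np.ones((32, 32), bool)],
                                       median_window=1, late_window=1,
                                       background_window=1, frame_interval=60.0)
    assert rates.empty
    assert rates.per_cell.shape[0] == 0


# ---------------------------------------------------------------------------
# Time-colored rendering
# ---------------------------------------------------------------------------


def test_render_single_event_colors_one_cluster():
    inc = np.zeros((10, 32, 32))
    inc[3, 10:13, 10:13] = 5.0
    rgb = tq.render_time_colored_map(inc)
    lit = (rgb.sum(axis=2) > 0)
    assert lit.sum() == 9
    assert lit[11, 11]


def test_render_two_epochs_two_hues():
    inc = np.zeros((10, 32, 32))
    inc[1, 5, 5] = 5.0
    inc[8, 20, 20] = 5.0
    rgb = tq.render_time_colored_map(inc)
    assert not np.allclose(rgb[5, 5], rgb[20, 20])


def test_render_round_trips_event_time_within_one_bin():
    import matplotlib
    n_t = 24
    inc = np.zeros((n_t, 16, 16))
    events = {(4, 4): 2, (8, 8): 11, (12, 12): 21}
    for (r, c), t in events.items():
        inc[t, r, c] = 5.0
    rgb = tq.render_time_colored_map(inc)
    table = np.asarray([matplotlib.colormaps["viridis"](i / (n_t - 1))[:3]
                        for i in range(n_t)])
    for (r, c), t_true in events.items():
        decoded = int(np.argmin(np.linalg.norm(table - rgb[r, c], axis=1)))
        assert abs(decoded - t_true) <= 1
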