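"""Cluster classification, rejection curves, threshold selection, pipeline."""

import dataclasses

import numpy as np
import pytest

from paintdenoise import (
    PaintDenoiser,
    RejectionCurve,
    ValidationError,
    classify_cluster,
    denoise_table,
    link_events,
    rejection_curve,
    select_threshold,
    simulate_scene,
    smooth,
)


def _train_from_darks(dark_frames, frame_duration_s=1.0):
    """Single-frame events separated by the given dark-frame gaps."""
    frames = np.concatenate([[0], 1 + np.cumsum(np.asarray(dark_frames) + 1)])
    return link_events(frames, 0, frame_duration_s=frame_duration_s)


def test_classify_below_min_events():
    train = _train_from_darks([10, 10, 10, 10])  # 5 events
    assert classify_cluster(train, min_events=8) == "below_min_events"


def test_classify_exponential_vs_constant(rng):
    kept = 0
    for i in range(60):
        darks = np.maximum(rng.exponential(100.0, 49).astype(int), 1)
        train = _train_from_darks(darks)
        kept += classify_cluster(train, min_events=8, seed=5) == "specific"
    assert kept >= 57  # ~ 1 - alpha of replicates

    const = _train_from_darks(np.full(49, 50))
    assert classify_cluster(const, min_events=8, seed=5) == "noise"


def test_rejection_curve_all_small():
    trains = [_train_from_darks([5, 5]) for _ in range(10)]  # 3 events each
    curve = rejection_curve(trains, thresholds=range(2, 7))
    assert (curve.fraction_rejected[curve.thresholds >= 4] == 1.0).all()
    assert (np.diff(curve.fraction_rejected) >= 0).all()


def test_rejection_curve_type_i_level(rng):
    trains = []
    for _ in range(400):
        darks = np.maximum(rng.exponential(100.0, 59).astype(int), 1)
        trains.append(_train_from_darks(darks))
    curve = rejection_curve(trains, thresholds=[4, 8, 12], alpha=0.01, seed=2)
    se = np.sqrt(0.01 * 0.99 / 400)
    assert (curve.fraction_rejected <= 0.01 + 3 * se).all()


def test_rejection_curve_empty_errors():
    with pytest.raises(ValidationError):
        rejection_curve([], thresholds=[4])


@pytest.mark.parametrize("kind", ["median5", "mean3"])
def test_smooth_constant_unchanged(kind):
    x = np.full(9, 2.5)
    np.testing.assert_array_equal(smooth(x, kind), x)


def test_smooth_median_removes_spike():
    x = np.array([0.0, 0, 1, 0, 0])
    assert smooth(x, "median5")[2] == 0.0


def test_smooth_matches_windowed_oracle(rng):
    x = rng.normal(size=25)
    got5 = smooth(x, "median5")
    got3 = smooth(x, "mean3")
    for i in range(25):
        lo5, hi5 = max(0, i - 2), min(25, i + 3)
        lo3, hi3 = max(0, i - 1), min(25, i + 2)
        assert got5[i] == pytest.approx(np.median(x[lo5:hi5]))
        assert got3[i] == pytest.approx(np.mean(x[lo3:hi3]))


def _curve(thresholds, rate, region=""):
    frac = np.cumsum(rate)
    return RejectionCurve(np.asarray(thresholds), frac, np.asarray(rate, float), region)


def test_select_threshold_equal_rates_no_crossing():
    T = np.arange(2, 12)
    r = np.linspace(0.2, 0.0, T.size)
    res = select_threshold(_curve(T, r), _curve(T, r))
    assert res.status == "no-crossing" and res.selected_threshold is None
    np.testing.assert_allclose(res.values[~np.isnan(res.values)], 0.0, atol=1e-12)


def test_select_threshold_background_vanishes():
    T = np.arange(2, 12)
    r_b = np.array([0.3, 0.25, 0.2, 0.1, 0.05, 0.04, 0.03, 0.02, 0.02, 0.01])
    r_s = np.array([0.3, 0.25, 0.2, 0.1, 0.05, 0.1, 0.12, 0.15, 0.15, 0.2])
    res = select_threshold(_curve(T, r_s), _curve(T, r_b))
    assert res.status == "ok"
    assert res.selected_threshold is not None
    # crossing happens where signal rate pulls clear of background
    assert res.selected_threshold >= 7


def test_select_threshold_grid_mismatch():
    with pytest.raises(ValidationError):
        select_threshold(_curve([2, 3], [0.1, 0.1]), _curve([3, 4], [0.1, 0.1]))


def test_select_threshold_on_simulated_scene():
    """Region-based threshold selection on a mixed scene matches a
    brute-force re-evaluation of the smoothed normalized-rate definition."""
    from paintdenoise import trains_from_clusters, two_step_cluster

    table, truth, signal_mask, background_mask = simulate_scene(
        n_specific=120, n_noise=2500, seed=11
    )
    clusters = two_step_cluster(table)
    trains = trains_from_clusters(table, clusters)
    in_signal = np.array([
        signal_mask.label_at(*c.centroid_nm) == "signal" for c in clusters
    ])
    T = np.arange(5, 31)
    curve_s = rejection_curve([t for t, m in zip(trains, in_signal) if m], T, seed=3)
    curve_b = rejection_curve([t for t, m in zip(trains, in_signal) if not m], T, seed=3)
    res = select_threshold(curve_s, curve_b)
    assert res.status == "ok"

    # independent sliding-window re-evaluation of the same definition
    def med5(x):
        return np.array([np.median(x[max(0, i - 2): i + 3]) for i in range(len(x))])

    r_s, r_b = med5(curve_s.rate), med5(curve_b.rate)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(r_b > 0, (r_s - r_b) / r_b, np.nan)
    raw[(r_b == 0) & (r_s > 0)] = np.inf
    sm = np.array([
        np.nan if np.all(np.isnan(raw[max(0, i - 1): i + 2]))
        else np.nanmean(raw[max(0, i - 1): i + 2])
        for i in range(len(raw))
    ])
    above = np.flatnonzero(np.nan_to_num(sm, nan=-np.inf) > 1.0)
    assert above.size > 0
    assert res.selected_threshold == T[above[0]]
    # the pick is past the bulk of the noise event-count distribution
    assert res.selected_threshold >= 8


def test_denoise_table_scene_confusion():
    """Most noise clusters removed, nearly all specific clusters kept."""
    table, truth, _, _ = simulate_scene(n_specific=150, n_noise=600, seed=21)
    filtered, summaries = denoise_table(table, seed=21)
    assert len(filtered) <= len(table)
    # localizations in the output are a subset of the input
    assert set(np.round(filtered.x_nm, 6)) <= set(np.round(table.x_nm, 6))

    kept_ids = set()
    from paintdenoise import two_step_cluster

    clusters = two_step_cluster(table)
    for c, s in zip(clusters, summaries):
        if s.decision == "specific":
            kept_ids.add(int(np.bincount(truth.loc_cluster_id[c.member_indices]).argmax()))
    n_spec = sum(1 for v in truth.cluster_class.values() if v == "specific")
    n_noise = sum(1 for v in truth.cluster_class.values() if v == "noise")
    spec_kept = sum(1 for k in kept_ids if truth.cluster_class[k] == "specific")
    noise_kept = sum(1 for k in kept_ids if truth.cluster_class[k] == "noise")
    assert spec_kept / n_spec >= 0.98
    assert 1 - noise_kept / n_noise >= 0.90


def test_denoise_table_all_below_threshold():
    # every cluster too small for the event threshold: nothing survives
    rng = np.random.default_rng(3)
    xs, ys, fr = [], [], []
    for i in range(5):
        xs.append(rng.normal(i * 500, 5, 6))
        ys.append(rng.normal(0, 5, 6))
        fr.append(np.arange(6) * 50)
    from conftest import make_table

    t = make_table(np.concatenate(xs), np.concatenate(ys),
                   frame=np.concatenate(fr), n_frames=300)
    filtered, summaries = denoise_table(t, min_events=8)
    assert len(filtered) == 0
    assert all(s.decision == "below_min_events" for s in summaries)


def test_denoise_table_deterministic():
    table, _, _, _ = simulate_scene(n_specific=30, n_noise=100, seed=33)
    out1 = denoise_table(table, seed=9)
    out2 = denoise_table(table, seed=9)
    assert [dataclasses.astuple(s) for s in out1[1]] == [
        dataclasses.astuple(s) for s in out2[1]
    ]
    np.testing.assert_array_equal(out1[0].x_nm, out2[0].x_nm)


def test_alpha_zero_rejects_nothing_by_test():
    rng = np.random.default_rng(5)
    trains = [_train_from_darks(np.full(20, int(50)))]  # constant = worst case
    assert classify_cluster(trains[0], min_events=1, alpha=0.0) != "noise"


def test_paintdenoiser_estimator_api():
    from sklearn.base import clone

    table, _, _, _ = simulate_scene(n_specific=20, n_noise=60, seed=44)
    est = clone(PaintDenoiser(min_events=8, random_state=1))
    out = est.fit(table).transform(table)
    assert est.n_specific_ == sum(d == "specific" for d in est.decisions_)
    assert len(out) <= len(table)
    assert est.get_params()["min_events"] == 8
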