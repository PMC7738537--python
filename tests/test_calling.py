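"""The ring-window z-score statistic, its filters and site collapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txends as tx
from txends.calling import LocalStats, build_profile

from _oracle import assert_stats_equal, brute_force_local_stats
from conftest import make_spiky_track


# ---------------------------------------------------------------------------
# ring window


def test_ring_window_full_interior(params):
    w = tx.ring_window(100, 10_000, params)
    assert w.size == 96
    assert w.min() == 50 and w.max() == 150
    assert set(w) == set(range(50, 98)) | set(range(103, 151))


def test_ring_window_truncates_at_linear_start(params):
    w = tx.ring_window(1, 10_000, params)
    assert np.array_equal(w, np.arange(4, 52))


def test_ring_window_can_be_empty_on_tiny_replicon(params):
    # L=5: no y satisfies 2 < |3-y| <= 50 within 1..5
    assert tx.ring_window(3, 5, params).size == 0


def test_ring_window_wraps_on_circular_replicon(params):
    w = tx.ring_window(1, 10_000, params, topology="circular")
    assert w.size == 96
    assert 9_951 in w and 4 in w and 2 not in w and 9_999 not in w


# ---------------------------------------------------------------------------
# local z-score


def test_worked_instance_alternating_background_with_spike(params):
    # 0/2 alternating counts, spike 25 at position 100: the ring window
    # holds 48 zeros and 48 twos, so m=1, population sigma=1, z=24.
    track = make_spiky_track(200, [100], 25)
    stats = tx.local_zscore(track, params)
    assert stats.local_mean[99] == pytest.approx(1.0)
    assert stats.local_sd[99] == pytest.approx(1.0)
    assert stats.z_raw[99] == pytest.approx(24.0)
    assert_stats_equal(stats, brute_force_local_stats(track.counts, params))


def test_constant_counts_leave_z_undefined(params):
    stats = tx.local_zscore(np.ones(300, dtype=int), params)
    assert np.isnan(stats.z_raw).all()
    assert np.allclose(stats.local_sd, 0.0)


def test_sd_floor_recovers_flat_background():
    p = tx.CallingParams(sd_floor=0.5)
    counts = np.ones(300, dtype=int)
    counts[149] = 10
    stats = tx.local_zscore(counts, p)
    # window around the spike holds only ones: m=1, sd=0 -> floored to 0.5
    assert stats.z_raw[149] == pytest.approx((10 - 1) / 0.5)


def test_all_zero_counts_are_masked_by_background_floor(params):
    stats = tx.local_zscore(np.zeros(300, dtype=int), params)
    masked = tx.mask_low_background([stats], params)
    assert masked.all()


@pytest.mark.parametrize("lam", [0.5, 2, 10])
@pytest.mark.parametrize("sd_mode", ["population", "sample"])
def test_vectorized_zscore_matches_bruteforce(lam, sd_mode):
    rng = np.random.default_rng(int(lam * 10) + (sd_mode == "sample"))
    counts = rng.poisson(lam, 300)
    p = tx.CallingParams(sd_mode=sd_mode)
    assert_stats_equal(tx.local_zscore(counts, p), brute_force_local_stats(counts, p))


def test_circular_zscore_matches_bruteforce():
    rng = np.random.default_rng(7)
    counts = rng.poisson(2.0, 250)
    p = tx.CallingParams()
    stats = tx.local_zscore(counts, p, topology="circular")
    assert_stats_equal(stats, brute_force_local_stats(counts, p, topology="circular"))


# ---------------------------------------------------------------------------
# masking and averaging


def _stats_with_mean(mean_value, n=5):
    arr = np.full(n, mean_value, dtype=float)
    return LocalStats(z_raw=np.zeros(n), local_mean=arr, local_sd=np.ones(n))


def test_mask_triggers_if_any_replicate_is_low(params):
    masked = tx.mask_low_background([_stats_with_mean(0.3), _stats_with_mean(0.2)], params)
    assert masked.all()


def test_mask_boundary_is_inclusive(params):
    assert tx.mask_low_background([_stats_with_mean(0.25)], params).all()
    assert not tx.mask_low_background([_stats_with_mean(0.26)], params).any()


def test_average_replicates():
    assert tx.average_replicates([np.array([10.0]), np.array([14.0])])[0] == 12.0
    single = np.array([3.0, 4.0])
    assert np.array_equal(tx.average_replicates([single]), single)


# ---------------------------------------------------------------------------
# TAP(+)/TAP(-) precondition


def _norm(values, strand="+"):
    return tx.NormalizedTrack("chr1", strand, tx.FIVE_PRIME, np.asarray(values, float))


def test_tap_precondition_strict_two_fold(params):
    eligible = tx.tap_precondition([_norm([10.0, 2.0, 0.0, 1.0])],
                                   [_norm([4.0, 1.0, 0.0, 0.0])], params)
    # 10>8 passes; 2 is exactly two-fold of 1, not "more than"; 0 vs 0
    # fails; 1 vs 0 passes with no pseudocount.
    assert eligible.tolist() == [True, False, False, True]


def test_tap_precondition_requires_all_replicate_pairs(params):
    eligible = tx.tap_precondition(
        [_norm([10.0]), _norm([3.0])], [_norm([1.0]), _norm([2.0])], params
    )
    assert not eligible[0]  # replicate 2 fails 3 > 2*2


def test_tap_precondition_pooled_mode():
    p = tx.CallingParams(tap_mode="pooled")
    eligible = tx.tap_precondition(
        [_norm([10.0]), _norm([3.0])], [_norm([1.0]), _norm([2.0])], p
    )
    assert eligible[0]  # mean 6.5 > 2 * mean 1.5


def test_tap_precondition_replicate_mismatch_is_fatal(params):
    with pytest.raises(ValueError, match="replicate"):
        tx.tap_precondition([_norm([1.0])], [], params)


# ---------------------------------------------------------------------------
# thresholding and collapse


def _profile(position_z: dict[int, float], length=200, masked=None):
    z = np.full(length, np.nan)
    for pos, val in position_z.items():
        z[pos - 1] = val
    m = np.zeros(length, dtype=bool) if masked is None else masked
    m |= ~np.isfinite(z)
    return tx.ZScoreProfile("chr1", "+", z, m)


def test_collapse_keeps_only_strongest_within_three_nt(params):
    sites = tx.call_sites(_profile({10: 15.0, 12: 20.0, 14: 13.0}), params, tx.SITE_TSS)
    assert [s.position for s in sites] == [12]
    assert sites[0].z == 20.0


def test_z_threshold_is_strict(params):
    assert tx.call_sites(_profile({50: 12.0}), params, tx.SITE_TSS) == []
    assert len(tx.call_sites(_profile({50: 12.0001}), params, tx.SITE_TSS)) == 1


def test_sites_beyond_collapse_distance_both_survive(params):
    sites = tx.call_sites(_profile({100: 14.0, 104: 13.0}), params, tx.SITE_TSS)
    assert [s.position for s in sites] == [100, 104]


def test_collapse_tie_breaks_to_smaller_coordinate(params):
    sites = tx.call_sites(_profile({30: 15.0, 32: 15.0}), params, tx.SITE_TSS)
    assert [s.position for s in sites] == [30]


@given(
    st.dictionaries(st.integers(1, 300), st.floats(12.5, 100.0), min_size=0, max_size=40)
)
@settings(max_examples=300, deadline=None)
def test_collapsed_sites_are_pairwise_separated(position_z):
    params = tx.CallingParams()
    sites = tx.call_sites(_profile(position_z, length=300), params, tx.SITE_TTS)
    positions = [s.position for s in sites]
    assert positions == sorted(positions)
    for a, b in zip(positions, positions[1:]):
        assert b - a > params.collapse_distance
    # every candidate is either output or within collapse distance of a
    # stronger output site
    for pos, zval in position_z.items():
        if pos not in positions:
            assert any(abs(pos - q) <= params.collapse_distance for q in positions)


@given(
    st.lists(st.floats(12.5, 100.0), min_size=1, max_size=20),
    st.floats(12.0, 90.0),
)
@settings(max_examples=200, deadline=None)
def test_raising_threshold_shrinks_collapse_free_output(zs, higher):
    # collapse-free instance: candidates spaced 10 nt apart
    position_z = {10 * (i + 1): z for i, z in enumerate(zs)}
    low = tx.CallingParams()
    high = tx.CallingParams(z_threshold=max(higher, low.z_threshold))
    out_low = {s.position for s in tx.call_sites(_profile(position_z, 500), low, tx.SITE_TSS)}
    out_high = {s.position for s in tx.call_sites(_profile(position_z, 500), high, tx.SITE_TSS)}
    assert out_high <= out_low


# ---------------------------------------------------------------------------
# composed dRNA-Seq / Term-Seq pipelines


def _tap_pair(spike_pos, plus_height, minus_height, length=400):
    plus = [make_spiky_track(length, [spike_pos], plus_height, label=f"p{i}")
            for i in range(2)]
    minus = [make_spiky_track(length, [spike_pos], minus_height, label=f"m{i}")
             for i in range(2)]
    return plus, minus


def test_drnaseq_recovers_tap_specific_spike(params):
    plus, minus = _tap_pair(200, plus_height=30, minus_height=2)
    sites = tx.run_drnaseq_calling(plus, minus, params)
    assert [s.position for s in sites] == [200]
    assert sites[0].site_type == tx.SITE_TSS
    assert sites[0].z == pytest.approx(29.0)  # (30 - 1) / 1


def test_drnaseq_rejects_processed_end_with_equal_tap_signal(params):
    plus, minus = _tap_pair(200, plus_height=30, minus_height=30)
    assert tx.run_drnaseq_calling(plus, minus, params) == []


def test_drnaseq_on_zero_tracks_is_empty(params):
    zero = [make_spiky_track(400, [], 0, background="flat0") for _ in range(2)]
    zero_minus = [make_spiky_track(400, [], 0, background="flat0") for _ in range(2)]
    assert tx.run_drnaseq_calling(zero, zero_minus, params) == []


def test_termseq_recovers_spike_without_tap_filter(params):
    tracks = [make_spiky_track(400, [200], 30, end_type=tx.THREE_PRIME) for _ in range(2)]
    sites = tx.run_termseq_calling(tracks, params)
    assert [s.position for s in sites] == [200]
    assert sites[0].site_type == tx.SITE_TTS


def test_flat_zero_replicate_masks_everything(params):
    good = make_spiky_track(400, [200], 30, end_type=tx.THREE_PRIME)
    dead = make_spiky_track(400, [], 0, end_type=tx.THREE_PRIME, background="flat0")
    assert tx.run_termseq_calling([good, dead], params) == []


def test_calling_is_deterministic(default_dataset):
    a = tx.run_drnaseq_calling(default_dataset.tap_plus, default_dataset.tap_minus)
    b = tx.run_drnaseq_calling(default_dataset.tap_plus, default_dataset.tap_minus)
    assert a == b


def test_no_output_site_is_masked_or_weak(default_dataset, params):
    sites = tx.run_termseq_calling(default_dataset.term, params)
    assert sites
    for site in sites:
        assert site.z > params.z_threshold
    for key in default_dataset.term[0]:
        strand_sites = [s.position for s in sites
                        if (s.replicon_id, s.strand) == key]
        profile, _ = build_profile([lib[key] for lib in default_dataset.term], params)
        for pos in strand_sites:
            assert not profile.masked[pos - 1]
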