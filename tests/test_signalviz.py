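"""Move-table segmentation, six-point subsampling, and signal tracks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trnamod as tm
from trnamod.signalviz import (
    build_signal_tracks,
    read_signal_npz,
    segment_signal,
    subsample_six,
    vertical_shift,
    write_signal_npz,
)
from trnamod.simulate import simulate_signals


def test_segment_lengths_follow_moves():
    moves = np.array([1, 1, 0, 1])  # bases with 1, 2, 1 stride-blocks
    signal = np.arange(24.0)
    seg = segment_signal(moves, signal)
    assert [(e - s) for s, e in seg.segments] == [6, 12, 6]
    assert seg.segments == [(0, 6), (6, 18), (18, 24)]


def test_segment_requires_stride_consistent_signal():
    with pytest.raises(ValueError, match="signal length"):
        segment_signal(np.array([1]), np.arange(7.0))  # 7 is not a multiple of 6


def test_segment_rejects_bad_move_vectors():
    with pytest.raises(ValueError):
        segment_signal(np.array([0, 1]), np.arange(12.0))  # must start with 1
    with pytest.raises(ValueError):
        segment_signal(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        segment_signal(np.array([1, 2]), np.arange(12.0))


def test_segmentation_round_trip_with_simulator(small_refs):
    reads, truth = tm.simulate_reads(small_refs, per_ref_depth=3, seed=61)
    signals, moves = simulate_signals(truth, seed=62)
    for read_id, seq in reads.items():
        seg = segment_signal(moves[read_id], signals[read_id], read_id=read_id)
        assert len(seg) == len(seq)  # one segment per basecalled position
        assert seg.segments[0][0] == 0
        assert seg.segments[-1][1] == signals[read_id].size
        for (s1, e1), (s2, e2) in zip(seg.segments, seg.segments[1:]):
            assert e1 == s2  # contiguous, non-overlapping
            assert (e1 - s1) % 6 == 0 and e1 > s1


def test_subsample_identity_on_length_six():
    seg = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
    np.testing.assert_array_equal(subsample_six(seg), seg)
    np.testing.assert_array_equal(subsample_six(subsample_six(seg)), seg)


def test_subsample_indices_for_length_twelve():
    seg = np.arange(12.0)
    np.testing.assert_array_equal(subsample_six(seg), [0, 2, 4, 6, 8, 10])


def test_subsample_constant_segment():
    assert (subsample_six(np.full(18, 7.0)) == 7.0).all()


def test_subsample_rejects_bad_lengths():
    with pytest.raises(ValueError):
        subsample_six(np.arange(7.0))
    with pytest.raises(ValueError):
        subsample_six(np.array([]))


@given(st.integers(min_value=1, max_value=20))
def test_subsample_always_six_values(m):
    assert subsample_six(np.arange(6.0 * m)).size == 6


def _tracks_for(refs, seed, level_shift=None, depth=20):
    reads, truth = tm.simulate_reads(
        refs, per_ref_depth=depth, sub_rate=0.02, ins_rate=0.01, del_rate=0.01,
        truncation_prob=0.0, seed=seed,
    )
    signals, moves = simulate_signals(truth, level_shift=level_shift, seed=seed + 1)
    alns = tm.filter_alignments(tm.align_all(reads, refs))
    segs = {r: segment_signal(moves[r], signals[r], read_id=r) for r in moves}
    return build_signal_tracks(alns, segs, signals, refs), truth


def test_track_values_only_at_aligned_reference_positions(small_refs):
    one = tm.ReferenceSet([small_refs.entries[0]])
    tracks, truth = _tracks_for(one, seed=71)
    track = tracks[one.entries[0].ref_id]
    ref = one.entries[0]
    assert set(track.positions()) <= set(range(1, ref.body_len + 1))
    for arrs in track.values.values():
        assert all(a.size == 6 for a in arrs)


def test_deleted_positions_get_no_values_from_that_read(tiny_refs):
    ref = tiny_refs["tRNA-toy"]
    reads = {"r1": ref.sequence, "r2": ref.sequence[: ref.body_to_full(40)] + ref.sequence[ref.body_to_full(40) + 1 :]}
    alns = tm.filter_alignments(tm.align_all(reads, tiny_refs))
    rng = np.random.default_rng(0)
    signals = {rid: rng.normal(100, 3, size=len(seq) * 6) for rid, seq in reads.items()}
    moves = {rid: np.ones(len(seq), dtype=int) for rid, seq in reads.items()}
    segs = {rid: segment_signal(moves[rid], signals[rid], read_id=rid) for rid in reads}
    track = build_signal_tracks(alns, segs, signals, tiny_refs)["tRNA-toy"]
    assert len(track.values[40]) == 1  # only the read without the deletion
    assert len(track.values[39]) == 2


def test_track_medians_near_simulator_level_table(small_refs):
    one = tm.ReferenceSet([small_refs.entries[0]])
    tracks, truth = _tracks_for(one, seed=81, depth=30)
    ref = one.entries[0]
    track = tracks[ref.ref_id]
    diffs = [
        track.median(p) - truth.level_table[(ref.ref_id, ref.body_to_full(p))]
        for p in track.positions()
    ]
    assert np.median(np.abs(diffs)) < 2.0  # noise_sd=3 around the level


def test_vertical_shift_identity_and_hand_median():
    t1 = tm.SignalTrack("t", {1: [np.full(6, 10.0)], 2: [np.full(6, 20.0)]})
    assert vertical_shift(t1, t1) == 0.0
    t2 = tm.SignalTrack("t", {1: [np.full(6, 8.0)], 2: [np.full(6, 17.0)]})
    assert vertical_shift(t1, t2) == pytest.approx(2.5)  # median of {2, 3}


def test_vertical_shift_equivariance():
    rng = np.random.default_rng(4)
    t1 = tm.SignalTrack("t", {p: [rng.normal(100, 3, 6)] for p in range(1, 20)})
    t2 = tm.SignalTrack("t", {p: [v[0] + rng.normal(0, 0.5, 6)] for p, v in t1.values.items()})
    base = vertical_shift(t1, t2)
    t2c = tm.SignalTrack("t", {p: [a + 5.0 for a in arrs] for p, arrs in t2.values.items()})
    assert vertical_shift(t1, t2c) == pytest.approx(base - 5.0)


def test_vertical_shift_self_consistency(small_refs):
    one = tm.ReferenceSet([small_refs.entries[0]])
    shift_map = {(one.entries[0].ref_id, p): 4.0 for p in range(1, one.entries[0].body_len + 1)}
    tracks_a, _ = _tracks_for(one, seed=91)
    tracks_b, _ = _tracks_for(one, seed=93, level_shift=shift_map)
    ta = tracks_a[one.entries[0].ref_id]
    tb = tracks_b[one.entries[0].ref_id]
    shift = vertical_shift(ta, tb)
    # after applying the shift to sample b, the median difference is zero
    shifted = tm.SignalTrack("t", {p: [a + shift for a in arrs] for p, arrs in tb.values.items()})
    common = sorted(set(ta.positions()) & set(shifted.positions()))
    assert np.median([ta.median(p) - shifted.median(p) for p in common]) == pytest.approx(0.0, abs=1e-9)


def test_no_common_positions_errors():
    t1 = tm.SignalTrack("t", {1: [np.full(6, 1.0)]})
    t2 = tm.SignalTrack("t", {2: [np.full(6, 1.0)]})
    with pytest.raises(ValueError):
        vertical_shift(t1, t2)


def test_npz_sidecar_round_trip(tmp_path, small_refs):
    reads, truth = tm.simulate_reads(small_refs, per_ref_depth=2, seed=95)
    signals, moves = simulate_signals(truth, seed=96)
    p = tmp_path / "sig.npz"
    write_signal_npz(p, signals, moves)
    s2, m2 = read_signal_npz(p)
    assert set(s2) == set(signals) and set(m2) == set(moves)
    for rid in signals:
        np.testing.assert_array_equal(signals[rid], s2[rid])
        np.testing.assert_array_equal(moves[rid], m2[rid])
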