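"""Determinism and statistical fidelity of the synthetic-data generator."""

import numpy as np
import pytest

import trnamod as tm
from trnamod.simulate import (
    ABNORMAL_DIST,
    PSI_MODIFIED_DIST,
    UNMODIFIED_DIST,
    PointScoreDist,
    simulate_signals,
)


def test_references_unique_and_reproducible():
    refs1 = tm.simulate_references(5, seed=1)
    refs2 = tm.simulate_references(5, seed=1)
    assert len(set(refs1.ids())) == 5
    assert [r.sequence for r in refs1] == [r.sequence for r in refs2]
    refs3 = tm.simulate_references(5, seed=2)
    assert [r.sequence for r in refs1] != [r.sequence for r in refs3]


def test_reads_without_errors_equal_references(small_refs):
    reads, truth = tm.simulate_reads(
        small_refs, per_ref_depth=2, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        truncation_prob=0.0, seed=2,
    )
    for read_id, seq in reads.items():
        assert seq == small_refs[truth.reads[read_id].source_ref].sequence


def test_full_truncation_defeats_full_length_filter(small_refs):
    reads, truth = tm.simulate_reads(
        small_refs, per_ref_depth=5, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        truncation_prob=1.0, seed=3,
    )
    assert all(r.truncated for r in truth.reads.values())
    kept = tm.filter_alignments(tm.align_all(reads, small_refs), min_as=50)
    assert kept == []


def test_empirical_substitution_rate(small_refs):
    sub = 0.02
    reads, truth = tm.simulate_reads(
        small_refs, per_ref_depth=70, sub_rate=sub, ins_rate=0.0, del_rate=0.0,
        truncation_prob=0.0, seed=4,
    )
    n_mm = sum(1 for r in truth.reads.values() for p in r.pairs if p[2] == "X")
    n_tot = sum(len(r.pairs) for r in truth.reads.values())
    se = np.sqrt(sub * (1 - sub) / n_tot)
    assert abs(n_mm / n_tot - sub) <= 3 * se


def test_scores_reproducible_and_thresholded(small_refs):
    _, truth1 = tm.simulate_reads(small_refs, per_ref_depth=5, seed=5)
    tracks1 = tm.simulate_scores(truth1, {}, seed=6)
    _, truth2 = tm.simulate_reads(small_refs, per_ref_depth=5, seed=5)
    tracks2 = tm.simulate_scores(truth2, {}, seed=6)
    assert {r: t.scores for r, t in tracks1.items()} == {r: t.scores for r, t in tracks2.items()}
    for track in tracks1.values():
        assert all(s >= 12 for s in track.scores.values())


def test_emission_threshold_256_empties_tracks(small_refs):
    _, truth = tm.simulate_reads(small_refs, per_ref_depth=3, seed=7)
    tracks = tm.simulate_scores(truth, {}, emission_threshold=256, seed=8)
    assert all(not t.scores for t in tracks.values())


def test_point_mass_full_stoichiometry_gives_fraction_one(small_refs):
    ref = small_refs.entries[0]
    u = [p for p in range(1, ref.body_len + 1) if ref.body_base(p) == "T"]
    models = {(ref.ref_id, u[0]): tm.SiteModel(u[0], 1.0, modified_dist=PointScoreDist(255))}
    table = tm.simulate_site_table(small_refs, models, n_reads=100, seed=9)
    rec = tm.site_fraction(ref.ref_id, u[0], table.sites[(ref.ref_id, u[0])])
    assert rec.fraction == 1.0


def test_zero_stoichiometry_fractions_near_false_positive_rate(small_refs):
    from scipy.stats import beta

    table = tm.simulate_site_table(small_refs, {}, n_reads=400, seed=10)
    fracs = [r.fraction for r in tm.site_fractions(table)]
    fp = beta.sf(205 / 256, 1, 20)  # unmodified Beta(1,20) above the 204 cut
    assert np.mean(fracs) == pytest.approx(fp, abs=3 * np.sqrt(fp / 400) + 1e-3)


def test_score_distribution_shapes():
    rng = np.random.default_rng(0)
    unmod = UNMODIFIED_DIST.sample(rng, 5000)
    mod = PSI_MODIFIED_DIST.sample(rng, 5000)
    abn = ABNORMAL_DIST.sample(rng, 5000)
    assert np.median(unmod) < 40
    assert np.median(mod) > 220
    assert 80 < np.median(abn) < 220  # intermediate, distinct from both


def test_neighbor_interference_perturbs_adjacent_sites_only(tiny_refs):
    ref = tiny_refs["tRNA-toy"]
    u = [p for p in range(1, ref.body_len + 1) if ref.body_base(p) == "T"]
    # pick a U with U neighbors at distance 1 (positions 6,7,8 region of the toy body)
    target = next(p for p in u if p + 1 in u and p - 1 in u)
    models = {
        (ref.ref_id, target): tm.SiteModel(
            target, 1.0,
            neighbor_interference=tm.NeighborInterference(1, ABNORMAL_DIST),
        )
    }
    reads, truth = tm.simulate_reads(tiny_refs, per_ref_depth=300, sub_rate=0.0,
                                     ins_rate=0.0, del_rate=0.0, truncation_prob=0.0, seed=11)
    tm.simulate_scores(truth, models, seed=12)
    by_pos: dict[int, list[int]] = {}
    for sim_read in truth.reads.values():
        matched = {rp: fp for rp, fp, op in sim_read.pairs if op == "="}
        for rp, score in sim_read.true_scores.items():
            fp = matched.get(rp)
            if fp is None:
                continue
            body = ref.full_to_body(fp)
            if body is not None:
                by_pos.setdefault(body, []).append(score)
    neighbor_medians = [np.median(by_pos[target - 1]), np.median(by_pos[target + 1])]
    distant = [np.median(by_pos[p]) for p in u if abs(p - target) >= 2]
    assert min(neighbor_medians) > max(distant)


def test_signals_deterministic_and_stride_consistent(small_refs):
    reads, truth = tm.simulate_reads(small_refs, per_ref_depth=2, seed=13)
    s1, m1 = simulate_signals(truth, seed=14)
    truth.level_table.clear()
    s2, m2 = simulate_signals(truth, seed=14)
    for rid in s1:
        np.testing.assert_array_equal(s1[rid], s2[rid])
        assert s1[rid].size == m1[rid].size * 6
        assert m1[rid][0] == 1


def test_noise_free_signals_equal_levels(small_refs):
    one = tm.ReferenceSet([small_refs.entries[0]])
    reads, truth = tm.simulate_reads(one, per_ref_depth=1, sub_rate=0.0, ins_rate=0.0,
                                     del_rate=0.0, truncation_prob=0.0, seed=15)
    signals, moves = simulate_signals(truth, noise_sd=0.0, seed=16)
    rid = next(iter(signals))
    seg = tm.segment_signal(moves[rid], signals[rid], read_id=rid)
    ref = one.entries[0]
    for read_pos, (s, e) in enumerate(seg.segments):
        level = truth.level_table[(ref.ref_id, read_pos)]
        assert (signals[rid][s:e] == level).all()


def test_manifest_summarizes_truth(tmp_path, small_refs):
    reads, truth = tm.simulate_reads(small_refs, per_ref_depth=4, seed=17)
    ref_id = small_refs.ids()[0]
    tm.simulate_scores(truth, {(ref_id, 2): tm.SiteModel(2, 0.5)}, seed=18)
    from trnamod.simulate import truth_manifest, write_manifest
    import json

    m = truth_manifest(truth)
    assert m["n_reads"] == len(truth.reads)
    assert f"{ref_id}:2" in m["site_models"]
    p = tmp_path / "truth.json"
    write_manifest(truth, p)
    assert json.loads(p.read_text()) == m
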