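"""Histogram smoothing, KL divergence, sample comparison, map integration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trnamod as tm
from trnamod.klcompare import (
    KLRecord,
    compare_samples,
    integrate_models,
    kl_divergence,
    min_max_normalize,
    smooth_histogram,
    symmetric_kl,
)

simplex = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=10
).map(lambda xs: [x / sum(xs) for x in xs])


def test_histogram_single_bin_smoothing():
    n = 50
    h = smooth_histogram([12] * n)
    assert h.counts[0] == n and h.counts[1:].sum() == 0
    np.testing.assert_allclose(h.probs, np.array([n + 1] + [1] * 9) / (n + 10))
    assert h.probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_histogram_edge_arithmetic():
    # bin width (256-11)/10 = 24.5: [11, 35.5) then [35.5, 60) ...
    assert smooth_histogram([35]).counts[0] == 1
    assert smooth_histogram([36]).counts[1] == 1
    assert smooth_histogram([255]).counts[9] == 1


def test_histogram_near_uniform_on_all_integer_scores():
    scores = list(range(12, 256))
    h = smooth_histogram(scores)
    assert h.counts.sum() == len(scores)
    assert h.counts.max() / h.counts.min() <= 25 / 24 + 1e-12


def test_histogram_rejects_empty_and_out_of_range():
    with pytest.raises(ValueError):
        smooth_histogram([])
    with pytest.raises(ValueError):
        smooth_histogram([5])
    with pytest.raises(ValueError):
        smooth_histogram([256])


def test_kl_direct_summation_example():
    p, q = [0.5, 0.5], [0.25, 0.75]
    assert kl_divergence(p, p) == 0.0
    assert kl_divergence(p, q) == pytest.approx(0.14384, abs=1e-5)
    assert symmetric_kl(p, q) == pytest.approx(0.27465, abs=1e-5)


def test_kl_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        kl_divergence([1.0, 0.0], [0.5, 0.5])
    with pytest.raises(ValueError):
        kl_divergence([0.5, 0.5], [0.5, 0.25, 0.25])


@given(simplex, st.data())
def test_gibbs_inequality_and_symmetry(p, data):
    q = data.draw(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=len(p), max_size=len(p)))
    q = [x / sum(q) for x in q]
    assert kl_divergence(p, q) >= 0.0
    assert symmetric_kl(p, q) == pytest.approx(symmetric_kl(q, p))


def test_sym_kl_zero_iff_identical_histograms():
    h1 = smooth_histogram([100, 150, 200])
    h2 = smooth_histogram([101, 150, 200])  # same bins
    h3 = smooth_histogram([40, 150, 200])
    assert symmetric_kl(h1.probs, h2.probs) == 0.0
    assert symmetric_kl(h1.probs, h3.probs) > 0.0


def test_identical_tables_give_zero_divergence(small_refs):
    t = tm.simulate_site_table(small_refs, {}, n_reads=120, seed=9)
    recs = compare_samples(t, t)
    assert all(r.sym_kl == 0.0 for r in recs if r.passed_coverage)
    assert any(r.passed_coverage for r in recs)


def test_coverage_gate_is_per_trna(small_refs):
    t_a = tm.simulate_site_table(small_refs, {}, n_reads=120, seed=9)
    t_b = tm.simulate_site_table(small_refs, {}, n_reads=99, seed=10)
    recs = compare_samples(t_a, t_b, min_coverage=100)
    assert recs and all(not r.passed_coverage for r in recs)
    assert all(r.sym_kl is None for r in recs)


def test_sample_swap_symmetry(small_refs):
    ref_id = small_refs.ids()[0]
    u = [p for p in range(1, small_refs[ref_id].body_len + 1) if small_refs[ref_id].body_base(p) == "T"]
    models = {(ref_id, u[0]): tm.SiteModel(u[0], 0.8)}
    t_a = tm.simulate_site_table(small_refs, models, n_reads=200, seed=11)
    t_b = tm.simulate_site_table(small_refs, {}, n_reads=200, seed=12)
    ab = {(r.ref_id, r.body_position): r.sym_kl for r in compare_samples(t_a, t_b)}
    ba = {(r.ref_id, r.body_position): r.sym_kl for r in compare_samples(t_b, t_a)}
    for key in ab:
        if ab[key] is None:
            assert ba[key] is None
        else:
            assert ab[key] == pytest.approx(ba[key])


def test_modified_site_stands_out_in_wt_vs_knockout(small_refs):
    ref_id = small_refs.ids()[0]
    ref = small_refs[ref_id]
    u = [p for p in range(1, ref.body_len + 1) if ref.body_base(p) == "T"]
    target = u[len(u) // 2]
    models = {(ref_id, target): tm.SiteModel(target, 0.8)}
    wt = tm.simulate_site_table(small_refs, models, n_reads=500, seed=13)
    ko = tm.simulate_site_table(small_refs, {}, n_reads=500, seed=14)
    recs = [r for r in compare_samples(wt, ko) if r.passed_coverage and r.ref_id == ref_id]
    by_pos = {r.body_position: r.sym_kl for r in recs}
    others = [v for p, v in by_pos.items() if p != target]
    assert by_pos[target] > np.quantile(others, 0.95)


def test_pseudocount_consistency(small_refs):
    """sym_kl converges to the unsmoothed value as the pseudocount shrinks."""
    rng = np.random.default_rng(5)
    a = rng.integers(12, 256, size=400)
    b = np.concatenate([rng.integers(12, 256, size=300), rng.integers(12, 120, size=100)])
    ha_raw = np.histogram(a, bins=np.linspace(11, 256, 11))[0] / 400
    hb_raw = np.histogram(b, bins=np.linspace(11, 256, 11))[0] / 400
    assert (ha_raw > 0).all() and (hb_raw > 0).all()
    exact = float(np.sum(ha_raw * np.log(ha_raw / hb_raw)) + np.sum(hb_raw * np.log(hb_raw / ha_raw)))
    errors = []
    for pc in (1.0, 0.1, 0.01):
        ha = smooth_histogram(a, pseudocount=pc)
        hb = smooth_histogram(b, pseudocount=pc)
        errors.append(abs(symmetric_kl(ha.probs, hb.probs) - exact))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 1e-3


def test_min_max_normalize_examples():
    assert min_max_normalize([2, 4, 6]) == pytest.approx([0.0, 0.5, 1.0])
    out = min_max_normalize({"a": 5.0})
    assert out == {"a": 0.0}


def test_min_max_preserves_ranking(rng):
    vals = rng.random(20).tolist()
    normed = min_max_normalize(vals)
    assert np.argsort(vals).tolist() == np.argsort(normed).tolist()


def test_min_max_grouping():
    values = {"a": 1.0, "b": 3.0, "c": 10.0, "d": 20.0}
    groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
    out = min_max_normalize(values, groups)
    assert out["a"] == 0.0 and out["b"] == 1.0 and out["c"] == 0.0 and out["d"] == 1.0


def _kl_rec(ref_id, pos, mod_code, kl):
    return KLRecord(ref_id, pos, mod_code, 200, 200, True, kl / 2, kl / 2)


def test_integrate_models_base_mapping(small_refs):
    ref = small_refs.entries[0]
    records = {"psi": [], "m6A": [], "m5C": []}
    for pos in range(1, ref.body_len + 1):
        base = ref.body_base(pos)
        model = {"T": "psi", "A": "m6A", "C": "m5C"}.get(base)
        if model:
            records[model].append(_kl_rec(ref.ref_id, pos, model, float(pos)))
    mod_map = integrate_models(records, small_refs)
    for pos in range(1, ref.body_len + 1):
        cell = mod_map.cells[(ref.ref_id, pos)]
        if cell.canonical_base == "G":
            assert cell.sym_kl is None and cell.mod_code is None
        else:
            assert cell.sym_kl == pytest.approx(float(pos))
            assert cell.mod_code == {"T": "psi", "A": "m6A", "C": "m5C"}[cell.canonical_base]
    normed = [c.sym_kl_norm for c in mod_map.cells.values() if c.sym_kl_norm is not None]
    assert normed and all(0.0 <= v <= 1.0 for v in normed)


def test_integrate_rejects_conflicting_duplicates(small_refs):
    ref = small_refs.entries[0]
    pos = next(p for p in range(1, ref.body_len + 1) if ref.body_base(p) == "T")
    recs = [_kl_rec(ref.ref_id, pos, "psi", 1.0), _kl_rec(ref.ref_id, pos, "psi", 2.0)]
    with pytest.raises(ValueError, match="duplicate"):
        integrate_models({"psi": recs}, small_refs)


def test_map_cells_nonempty_exactly_at_covered_non_g_positions(small_refs):
    models = {}
    wt = tm.simulate_site_table(small_refs, models, n_reads=150, seed=15)
    ko = tm.simulate_site_table(small_refs, models, n_reads=150, seed=16)
    recs = compare_samples(wt, ko)
    mod_map = integrate_models({"psi": recs}, small_refs)
    covered = {(r.ref_id, r.body_position) for r in recs if r.passed_coverage}
    for key, cell in mod_map.cells.items():
        if cell.canonical_base == "T":
            assert (cell.sym_kl is not None) == (key in covered)
        elif cell.canonical_base == "G":
            assert cell.sym_kl is None
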