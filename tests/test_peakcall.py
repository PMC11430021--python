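import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rloopkit.io import Condition, FragmentSet, GenomeModel
from rloopkit.peakcall import (CallerParams, Peak, bh_qvalues, call_peaks,
                               link_intervals, local_lambda, poisson_sf,
                               pool_fragments)
from rloopkit.simulate import SimConfig, make_genome, simulate_fragments


from oracles import bh_oracle, poisson_sf_oracle


class TestPoissonSF:
    def test_t_zero_is_one(self):
        assert poisson_sf(0, 2.3) == 1.0

    def test_worked_examples(self):
        assert poisson_sf(5, 1.0) == pytest.approx(3.6598e-3, rel=1e-3)
        assert poisson_sf(10, 10.0) == pytest.approx(0.54207, rel=1e-4)

    def test_matches_oracle_grid(self):
        for lam in (0.1, 1.0, 5.0, 17.3, 50.0):
            for t in (0, 1, 2, 5, 20, 80):
                assert poisson_sf(t, lam) == pytest.approx(
                    poisson_sf_oracle(t, lam), rel=1e-10, abs=1e-300)

    def test_monotone_in_t(self):
        vals = [poisson_sf(t, 7.0) for t in range(30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_monotone_in_lambda(self):
        vals = [poisson_sf(8, lam) for lam in np.linspace(0.1, 30, 50)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_negative_lambda_errors(self):
        with pytest.raises(ValueError):
            poisson_sf(1, -0.5)

    def test_non_integer_t_errors(self):
        with pytest.raises(ValueError):
            poisson_sf(1.5, 1.0)

    def test_large_t_stable(self):
        p = poisson_sf(200, 50.0)
        assert 0.0 < p < 1e-50


class TestLocalLambda:
    def test_uniform_control(self):
        # all nested windows at the same per-bp rate v = 0.01 frag/bp
        bases = {L: 0.01 * L * 250 for L in (1000, 5000, 10000)}
        lam = local_lambda(200, bases, genome_rate=0.01, depth_ratio=1.0,
                           mean_frag_len=250, pseudocount=0.5)
        assert lam == pytest.approx(0.01 * 200 * 1.0 + 0.5)

    def test_max_rule_arithmetic(self):
        # choose bases so the candidates are exactly 2.0, 0.8, 0.6; bg 0.4
        bases = {1000: 2.0 * 250 * (1000 / 200),
                 5000: 0.8 * 250 * (5000 / 200),
                 10000: 0.6 * 250 * (10000 / 200)}
        lam = local_lambda(200, bases, genome_rate=0.4 / 200, depth_ratio=1.0,
                           mean_frag_len=250, pseudocount=0.0)
        assert lam == pytest.approx(2.0)

    def test_empty_control_pseudocount(self):
        lam = local_lambda(200, {1000: 0.0}, genome_rate=0.0, depth_ratio=1.0,
                           mean_frag_len=250, pseudocount=0.5)
        assert lam == 0.5

    def test_empty_control_zero_pseudocount_errors(self):
        with pytest.raises(ValueError):
            local_lambda(200, {1000: 0.0}, genome_rate=0.0, depth_ratio=1.0,
                         mean_frag_len=250, pseudocount=0.0)


class TestBH:
    def test_single(self):
        assert bh_qvalues([0.05]).tolist() == [0.05]

    def test_worked_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_qvalues([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.2])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_naive_oracle(self, p):
        np.testing.assert_allclose(bh_qvalues(p), bh_oracle(p), rtol=1e-12, atol=1e-12)

    def test_order_preserved(self, rng):
        p = rng.random(50)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestLinking:
    def test_idempotent(self):
        ivs = [(0, 200), (250, 400), (1000, 1200)]
        once = link_intervals(ivs, gap=100)
        assert link_intervals(once, gap=100) == once

    def test_touching_always_merge(self):
        assert link_intervals([(0, 100), (100, 200)], gap=0) == [(0, 200)]

    def test_gap_respected(self):
        assert link_intervals([(0, 100), (300, 400)], gap=200) == [(0, 400)]
        assert link_intervals([(0, 100), (300, 400)], gap=100) == [(0, 100), (300, 400)]


def _null_sample(seed, length=400_000, condition=Condition.DRIP, idx=0):
    cfg = SimConfig(genome=[("chr1", length)], n_genes=0, n_stranded=0,
                    n_unstranded=0, seed=seed)
    genome = make_genome(cfg)
    return genome, simulate_fragments(genome, [], cfg, condition, sample_index=idx)


class TestCallPeaks:
    def test_treatment_equals_control_yields_nothing(self):
        genome, fs = _null_sample(5)
        assert call_peaks(fs, fs, genome) == []

    def test_genome_smaller_than_window_errors(self, make_frags):
        g = GenomeModel({"chr1": 50})
        fs = make_frags([("chr1", 0, 30, "+")])
        with pytest.raises(ValueError, match="window"):
            call_peaks(fs, fs, g)

    def test_empty_treatment_warns(self, make_frags):
        g = GenomeModel({"chr1": 10_000})
        empty = make_frags([])
        ctrl = make_frags([("chr1", 0, 250, "+")])
        with pytest.warns(UserWarning, match="no fragments"):
            assert call_peaks(empty, ctrl, g) == []

    def test_planted_loops_recovered(self, small_cohort):
        genome, truth, samples = small_cohort
        controls = [s for s in samples if s.condition is Condition.RNASEH]
        rep1 = next(s for s in samples if s.condition is Condition.DRIP)
        peaks = call_peaks(rep1, controls, genome)
        hit = 0
        for t in truth:
            if any(p.chrom == t.chrom and p.start < t.end and t.start < p.end
                   for p in peaks):
                hit += 1
        assert hit / len(truth) >= 0.9

    def test_modes_present_and_q_valid(self, small_cohort):
        genome, _, samples = small_cohort
        controls = [s for s in samples if s.condition is Condition.RNASEH]
        rep1 = next(s for s in samples if s.condition is Condition.DRIP)
        peaks = call_peaks(rep1, controls, genome)
        assert {p.mode for p in peaks} == {"narrow", "broad"}
        params = CallerParams()
        for p in peaks:
            assert 0 <= p.q <= 1 and p.p <= p.q + 1e-12
            assert p.end - p.start >= params.min_peak_len
            assert 0 <= p.summit < p.end - p.start

    def test_pool_fragments_counts(self, make_frags):
        a = make_frags([("chr1", 0, 100, "+")], "a")
        b = make_frags([("chr1", 200, 300, "-")], "b")
        assert len(pool_fragments([a, b])) == 2

    def test_strand_mode_filters(self, small_cohort):
        genome, _, samples = small_cohort
        rep1 = next(s for s in samples if s.condition is Condition.DRIP)
        ctrl = [s for s in samples if s.condition is Condition.RNASEH]
        plus = call_peaks(rep1, ctrl, genome, strand_mode="plus_only")
        both = call_peaks(rep1, ctrl, genome, strand_mode="both")
        assert len(plus) > 0
        assert len(both) >= len(plus) // 2  # sanity: both-strand call sees more signal


class TestCallerParams:
    def test_step_must_divide_window(self):
        with pytest.raises(ValueError):
            CallerParams(window=200, step=150)

    def test_q_threshold_range(self):
        with pytest.raises(ValueError):
            CallerParams(q_narrow=1.5)

    def test_peak_invariants(self):
        with pytest.raises(ValueError):
            Peak("chr1", 100, 100)
        with pytest.raises(ValueError):
            Peak("chr1", 0, 100, q=1.5)
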