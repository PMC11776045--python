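"""Kinetic sliding model: simulation, estimation and first-passage analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from rrmscan import transitions as tr
from rrmscan.sliding_model import (
    KineticTrack,
    ModelState,
    SequenceContext,
    SlidingParams,
    channels,
    enumerate_states,
    estimate_rates,
    kinetic_state_track,
    mfpt,
    sample_model_states,
    scanning_summary,
    simulate,
    simulate_first_passage,
    to_state_track,
    transition_class,
)


def total_exit_rate(state, params, seq):
    return sum(r for _, r, _ in channels(state, params, SequenceContext(seq)))


class TestStateSpaceAndChannels:
    def test_boundary_registers_lack_out_of_range_channels(self):
        p = SlidingParams()
        seq = SequenceContext("UUU")
        ch1 = channels(ModelState("S", 1), p, seq)
        assert all(t.j != 0 or t.kind != "V" for t, _, _ in ch1)
        kinds = [(t.kind, t.i, t.j) for t, _, _ in ch1]
        assert ("V", 1, 0) not in kinds and ("V", 1, 2) in kinds
        chn = channels(ModelState("S", 3), p, seq)
        kinds = [(t.kind, t.i, t.j) for t, _, _ in chn]
        assert ("H", 3, 4) not in kinds  # no downstream neighbour at the 3' end

    def test_alpha_multiplies_moves_placing_cytidine(self):
        p = SlidingParams(alpha_c=0.25, k_open_v=4.0)
        seq = SequenceContext("UCU")
        ch = channels(ModelState("S", 3), p, seq)
        rate = next(r for t, r, _ in ch if t == ModelState("V", 3, 2))
        assert rate == pytest.approx(1.0)  # 4.0 * 0.25 toward the C register

    def test_channel_probabilities_sum_to_one(self):
        p = SlidingParams(alpha_c=0.3)
        seq = SequenceContext("UUCU")
        for s in enumerate_states(seq):
            ch = channels(s, p, seq)
            total = sum(r for _, r, _ in ch)
            assert total > 0
            probs = [r / total for _, r, _ in ch]
            assert sum(probs) == pytest.approx(1.0)

    def test_sequence_alphabet_enforced(self):
        with pytest.raises(ValueError):
            SequenceContext("UUAG")
        with pytest.raises(ValueError):
            SequenceContext("")


class TestSimulate:
    def test_all_rates_zero_is_absorbing(self):
        p = SlidingParams(
            k_open_v=0, k_open_h=0, k_close_keep=0, k_close_shift=0,
            k_unbind=0, k_rebind=0, k_detach=0, k_attach=0,
        )
        kt = simulate(p, "UUU", 5.0, seed=0)
        assert kt.absorbing and kt.n_events == 0
        assert len(sample_model_states(kt, 1000.0)) == 6

    def test_alpha_zero_excludes_cytidine_register(self):
        kt = simulate(SlidingParams(alpha_c=0.0), "UUCUU", 200.0, seed=3)
        assert kt.n_events > 100
        for _, s in kt.entries:
            assert 3 not in s.occupied()

    def test_reproducible_given_seed(self):
        a = simulate(SlidingParams(), "UUUU", 50.0, seed=9)
        b = simulate(SlidingParams(), "UUUU", 50.0, seed=9)
        assert a.entries == b.entries

    def test_mean_dwell_matches_exit_rate(self):
        """Empirical mean dwell in S ~ 1/(total exit rate), within 3 SE."""
        p = SlidingParams()
        kt = simulate(p, "UUUUU", 4000.0, seed=17)
        target = ModelState("S", 3)
        dwells = [d for s, d, nxt in kt.dwells() if s == target and nxt is not None]
        assert len(dwells) >= 1000
        expected = 1.0 / total_exit_rate(target, p, "UUUUU")
        se = np.std(dwells) / math.sqrt(len(dwells))
        assert abs(np.mean(dwells) - expected) < 3 * se

    def test_dwell_times_exponential(self):
        p = SlidingParams()
        kt = simulate(p, "UUUUU", 8000.0, seed=23)
        target = ModelState("S", 3)
        dwells = [d for s, d, nxt in kt.dwells() if s == target and nxt is not None]
        rate = total_exit_rate(target, p, "UUUUU")
        pval = stats.kstest(dwells, "expon", args=(0, 1.0 / rate)).pvalue
        assert pval > 0.01

    def test_consecutive_states_differ(self):
        kt = simulate(SlidingParams(), "UUCU", 100.0, seed=2)
        for (_, a), (_, b) in zip(kt.entries, kt.entries[1:]):
            assert a != b


class TestDiscretization:
    def test_single_state_constant_track(self):
        p = SlidingParams(
            k_open_v=0, k_open_h=0, k_close_keep=0, k_close_shift=0,
            k_unbind=0, k_rebind=0, k_detach=0, k_attach=0,
        )
        st = to_state_track(simulate(p, "UUU", 3.0, seed=0), 100.0)
        assert len(set(st.labels)) == 1

    def test_fine_sampling_recovers_every_event(self):
        p = SlidingParams()
        kt = simulate(p, "UUUU", 20.0, seed=5)
        exact = tr.events(kinetic_state_track(kt))
        # frame interval well below any inter-event gap
        gaps = [b[0] - a[0] for a, b in zip(kt.entries, kt.entries[1:])]
        dt_ns = min(gaps) * 1000.0 * 0.4
        sampled = tr.events(to_state_track(kt, dt_ns))
        assert [(e.kind, e.direction) for e in sampled] == [
            (e.kind, e.direction) for e in exact
        ]

    def test_p_and_d_both_render_empty_pocket(self):
        seq = SequenceContext("UU")
        from rrmscan.sliding_model import model_state_to_pocket_state

        assert model_state_to_pocket_state(ModelState("P"), seq).label == "[]"
        assert model_state_to_pocket_state(ModelState("D"), seq).label == "[]"


class TestRateEstimation:
    def test_recovers_generating_rates(self):
        p = SlidingParams(
            k_open_v=2.0, k_open_h=2.0, k_close_keep=3.0, k_close_shift=3.0,
            k_unbind=2.0, k_rebind=10.0, k_detach=5.0, k_attach=20.0, alpha_c=1.0,
        )
        kt = simulate(p, "UUUUU", 2000.0, seed=31)
        est = estimate_rates(kt)
        truth = {
            "open_v": 2.0, "open_h": 2.0, "close_keep": 3.0, "close_shift": 3.0,
            "unbind": 2.0, "rebind": 10.0, "detach": 5.0, "attach": 20.0,
        }
        for cls, k in truth.items():
            e = est[cls]
            assert e.count > 200
            assert e.rate == pytest.approx(k, rel=0.15)
            assert e.ci_low <= e.rate <= e.ci_high

    def test_zero_events_with_exposure_yield_one_sided_ci(self):
        p = SlidingParams(k_detach=0.0)
        kt = simulate(p, "UUU", 200.0, seed=7)
        est = estimate_rates(kt)
        e = est["detach"]
        assert e.count == 0 and e.exposure_us > 0
        assert e.rate == 0.0 and e.ci_low == 0.0 and e.ci_high > 0.0

    def test_scale_equivariance(self):
        kt = simulate(SlidingParams(), "UUUU", 300.0, seed=11)
        doubled = KineticTrack(
            [(2.0 * t, s) for t, s in kt.entries], 2.0 * kt.t_max, kt.seq
        )
        a = estimate_rates(kt)
        b = estimate_rates(doubled)
        for cls in a:
            if a[cls].rate:
                assert b[cls].rate == pytest.approx(a[cls].rate / 2.0)

    def test_empty_track_rejected(self):
        p = SlidingParams(
            k_open_v=0, k_open_h=0, k_close_keep=0, k_close_shift=0,
            k_unbind=0, k_rebind=0, k_detach=0, k_attach=0,
        )
        kt = simulate(p, "UU", 1.0, seed=0)
        with pytest.raises(ValueError):
            estimate_rates(kt)

    def test_transition_class_total(self):
        seq = SequenceContext("UUU")
        p = SlidingParams()
        for s in enumerate_states(seq):
            for t, _, cls in channels(s, p, seq):
                assert transition_class(s, t) == cls


class TestMFPT:
    def test_start_inside_target_is_zero(self):
        assert mfpt(SlidingParams(), "UUU", ModelState("S", 2), {2}) == 0.0
        # vertical state occupying a target register also counts as arrived
        assert mfpt(SlidingParams(), "UUU", ModelState("V", 1, 2), {2}) == 0.0

    def test_matches_hand_built_linear_solve(self):
        """3-register poly-U, vertical-only moves, against an independent
        absorbing-chain solve built directly from the generator matrix."""
        p = SlidingParams(k_open_h=0.0, k_unbind=0.0, k_detach=0.0, k_attach=0.0,
                          k_rebind=0.0)
        seq = SequenceContext("UUU")
        states = [s for s in enumerate_states(seq) if s.kind in ("S", "V")]
        idx = {s: k for k, s in enumerate(states)}
        targets = {3}
        transient = [s for s in states if 3 not in s.occupied()]
        tpos = {s: k for k, s in enumerate(transient)}
        A = np.zeros((len(transient), len(transient)))
        for s in transient:
            total = 0.0
            for t, r, _ in channels(s, p, seq):
                total += r
                if t in tpos:
                    A[tpos[s], tpos[t]] += r
            A[tpos[s], tpos[s]] -= total
        tau = np.linalg.solve(A, -np.ones(len(transient)))
        expected = tau[tpos[ModelState("S", 1)]]
        assert mfpt(p, "UUU", ModelState("S", 1), targets) == pytest.approx(expected)

    def test_agrees_with_simulation(self):
        p = SlidingParams()
        solve = mfpt(p, "UUUU", ModelState("S", 1), {4})
        seeds = np.random.SeedSequence(77).spawn(1500)
        ts = [simulate_first_passage(p, "UUUU", ModelState("S", 1), {4}, s) for s in seeds]
        se = np.std(ts) / math.sqrt(len(ts))
        assert abs(np.mean(ts) - solve) < 3 * se

    def test_disconnected_target_is_infinite(self):
        # a zero-acceptance cytidine wall with no unbound pathway
        p = SlidingParams(alpha_c=0.0, k_unbind=0.0)
        assert math.isinf(mfpt(p, "UUCUU", ModelState("S", 1), {5}))

    def test_unbinding_bridges_the_cytidine_wall(self):
        p = SlidingParams(alpha_c=0.0)
        assert math.isfinite(mfpt(p, "UUCUU", ModelState("S", 1), {5}))


class TestScanning:
    def test_polyU_occupancy_matches_exact_stationary_distribution(self):
        """Simulated register occupancy vs the stationary solution of the
        generator (independent linear-algebra oracle)."""
        p = SlidingParams()
        seq = SequenceContext("UUUUU")
        states = enumerate_states(seq)
        idx = {s: k for k, s in enumerate(states)}
        Q = np.zeros((len(states), len(states)))
        for s in states:
            for t, r, _ in channels(s, p, seq):
                Q[idx[s], idx[t]] += r
                Q[idx[s], idx[s]] -= r
        # stationary distribution: pi Q = 0, sum pi = 1
        A = np.vstack([Q.T, np.ones(len(states))])
        b = np.concatenate([np.zeros(len(states)), [1.0]])
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        exact = np.zeros(seq.n)
        for s in states:
            if s.kind in ("S", "V", "H"):
                exact[s.i - 1] += pi[idx[s]]
        summary = scanning_summary(p, "UUUUU", n_reps=60, t_max=200.0, seed=19)
        np.testing.assert_allclose(summary.occupancy, exact, atol=0.02)

    def test_reflection_symmetry_without_horizontal_channel(self):
        # with vertical-only intermediates the model is register-reversal
        # symmetric, so occupancy must mirror around the centre
        p = SlidingParams(k_open_h=0.0)
        s = scanning_summary(p, "UUUUU", n_reps=80, t_max=150.0, seed=29)
        np.testing.assert_allclose(s.occupancy, s.occupancy[::-1], atol=0.02)

    def test_alpha_zero_exact_cytidine_exclusion(self):
        s = scanning_summary(SlidingParams(alpha_c=0.0), "UUCUU", 25, 50.0, seed=3)
        assert s.occupancy[2] == 0.0
        assert s.stall_events_mean == 0.0

    def test_c_occupancy_monotone_in_alpha(self):
        occ = [
            scanning_summary(SlidingParams(alpha_c=a), "UUCUU", 40, 50.0, seed=13).occupancy[2]
            for a in (0.0, 0.5, 1.0)
        ]
        assert occ[0] == 0.0
        assert occ[0] < occ[1] < occ[2]

    def test_occupancy_sums_to_at_most_one(self):
        s = scanning_summary(SlidingParams(), "UUCU", 20, 50.0, seed=8)
        total = s.occupancy.sum() + s.unbound_fraction
        assert total == pytest.approx(1.0, abs=1e-9)


class TestMutantPhenotype:
    def test_no_intermediates_means_register_changes_only_by_jumps(self):
        """With both opening channels removed, register exchange survives only
        through unbind/rebind ('jump over') events: no shift events at all."""
        p = SlidingParams(k_open_v=0.0, k_open_h=0.0)
        kt = simulate(p, "UUUUU", 500.0, seed=41)
        evs = tr.events(kinetic_state_track(kt))
        kinds = [e.kind for e in evs]
        assert "shift" not in kinds
        assert kinds.count("jump") > 10
        directional = [e for e in evs if e.direction in ("5'", "3'")]
        assert all(e.kind == "jump" for e in directional)
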