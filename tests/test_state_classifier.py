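"""Frame classification, symbolic labels and track smoothing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rrmscan.sliding_model import ModelState, SequenceContext, model_state_to_pocket_state
from rrmscan.state_classifier import (
    HYBRID,
    HORIZONTAL,
    SINGLE,
    UNBOUND,
    VERTICAL,
    ClassifierParams,
    StateTrack,
    classify,
    classify_frame,
    parse_label,
    render_label,
    smooth,
)
from rrmscan.synthetic_data import (
    GeometryTemplate,
    SynthConfig,
    _Layout,
    _render_frame,
    build_topology,
    generate,
    synthetic_pocket_config,
)
from rrmscan.trajectory_io import Frame, resolve_pocket


def _frame_for(model_state, seq):
    topo = build_topology(seq)
    layout = _Layout(GeometryTemplate())
    coords = _render_frame(topo, layout, model_state, seq)
    return Frame(0, 0.0, coords), resolve_pocket(topo, synthetic_pocket_config(seq))


@pytest.mark.parametrize(
    "model_state, seq, mode, label",
    [
        (ModelState("S", 2), "UUUUU", SINGLE, "[U2]"),
        (ModelState("V", 2, 1), "UUUUU", VERTICAL, "[U1=U2]"),
        (ModelState("V", 2, 3), "UUUUU", VERTICAL, "[U2=U3]"),
        (ModelState("H", 2, 3), "UUUUU", HORIZONTAL, "[U2/U3]"),
        (ModelState("P"), "UUUUU", UNBOUND, "[]"),
        (ModelState("S", 3), "UUCUU", HYBRID, "[C3]"),
        (ModelState("V", 2, 3), "UUCUU", HYBRID, "[U2=C3]"),
        (ModelState("H", 2, 3), "UUCUU", HYBRID, "[U2/C3]"),
    ],
)
def test_classify_frame_recovers_rendered_state(model_state, seq, mode, label):
    """Each geometric signature classifies into its generating mode/label."""
    frame, pocket = _frame_for(model_state, seq)
    state = classify_frame(frame, pocket)
    assert state.mode == mode
    assert state.label == label
    assert not state.low_confidence


def test_clamp_conflict_flags_low_confidence():
    """A wide clamp around a single occupant keeps the call but flags it."""
    frame, pocket = _frame_for(ModelState("S", 2), "UUU")
    # widen the clamp beyond 9 Å by moving the Trp CE3 along z
    wide = frame.coords.copy()
    wide[pocket.clamp_a][2] += 2.0
    state = classify_frame(Frame(0, 0.0, wide), pocket)
    assert state.mode == SINGLE
    assert state.low_confidence


def test_classification_is_total_and_deterministic(rng):
    topo = build_topology("UUU")
    pocket = resolve_pocket(topo, synthetic_pocket_config("UUU"))
    coords = rng.uniform(-20, 20, (topo.n_atoms, 3))
    f = Frame(0, 0.0, coords)
    a = classify_frame(f, pocket)
    b = classify_frame(f, pocket)
    assert a == b
    assert a.mode in (SINGLE, VERTICAL, HORIZONTAL, HYBRID, UNBOUND)


def test_classify_constant_trajectory():
    traj = generate(SynthConfig(seq="UUU", n_frames=1, seed=0))
    frame = traj.frames[0]
    pocket = resolve_pocket(traj.topology, synthetic_pocket_config("UUU"))
    frames = [Frame(i, float(i), frame.coords) for i in range(50)]
    track = classify(frames, pocket)
    assert len(set(track.labels)) == 1


def test_single_frame_track_ignores_window():
    traj = generate(SynthConfig(seq="UUU", n_frames=1, seed=0))
    pocket = resolve_pocket(traj.topology, synthetic_pocket_config("UUU"))
    track = classify(traj.frames, pocket, ClassifierParams(smoothing_window=5))
    assert len(track) == 1


class TestLabels:
    def test_render_examples(self):
        seq = SequenceContext("UUUUU")
        assert model_state_to_pocket_state(ModelState("S", 2), seq).label == "[U2]"
        assert model_state_to_pocket_state(ModelState("V", 3, 2), seq).label == "[U2=U3]"
        assert model_state_to_pocket_state(ModelState("H", 2, 3), seq).label == "[U2/U3]"

    def test_vertical_renders_5prime_first(self):
        seq = SequenceContext("UUUUU")
        down = model_state_to_pocket_state(ModelState("V", 2, 3), seq)
        up = model_state_to_pocket_state(ModelState("V", 3, 2), seq)
        assert down.label == up.label == "[U2=U3]"

    @pytest.mark.parametrize("bad", ["", "[", "[U]", "[2U]", "[U2=U2]", "[A2]", "[U2-U3]"])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_label(bad)

    label_st = st.one_of(
        st.just("[]"),
        st.builds(
            lambda b, n: f"[{b}{n}]",
            st.sampled_from("UC"),
            st.integers(1, 9),
        ),
        st.builds(
            lambda b1, b2, i, d, sep: f"[{b1}{i}{sep}{b2}{i + d}]",
            st.sampled_from("UC"),
            st.sampled_from("UC"),
            st.integers(1, 8),
            st.integers(1, 3),
            st.sampled_from("=/"),
        ),
    )

    @given(label=label_st)
    def test_parse_render_round_trip(self, label):
        state = parse_label(label)
        assert render_label(state) == label
        again = parse_label(render_label(state))
        assert again.mode == state.mode
        assert {(o.res_seq, o.base) for o in again.occupants} == {
            (o.res_seq, o.base) for o in state.occupants
        }

    def test_hybrid_mode_from_cytidine(self):
        assert parse_label("[C3]").mode == HYBRID
        assert parse_label("[U2=C3]").mode == HYBRID
        assert parse_label("[U2=U3]").mode == VERTICAL


class TestSmoothing:
    def _track(self, labels):
        return StateTrack.from_labels(labels)

    def test_window_one_is_identity(self):
        t = self._track(["[U1]", "[U2]", "[U1]"])
        assert smooth(t, 1, 1).labels == t.labels

    def test_majority_vote_removes_single_flicker(self):
        t = self._track(["[U1]", "[U1]", "[U2]", "[U1]", "[U1]"])
        assert smooth(t, 3, 1).labels == ["[U1]"] * 5

    def test_hand_computed_vote_with_clipped_edges(self):
        # A B B A A, window 3: votes are A(tie->raw), B, B, A, A
        t = self._track(["[U1]", "[U2]", "[U2]", "[U1]", "[U1]"])
        assert smooth(t, 3, 1).labels == ["[U1]", "[U2]", "[U2]", "[U1]", "[U1]"]

    def test_alternating_flicker_absorbed_into_long_runs(self):
        """Frame-by-frame flicker cannot survive min_dwell absorption: every
        run in the output is at least min_dwell frames long."""
        labels = ["[U1]", "[U2]"] * 10
        out = smooth(self._track(labels), 3, 2).labels
        runs = []
        for lab in out:
            if runs and runs[-1][0] == lab:
                runs[-1][1] += 1
            else:
                runs.append([lab, 1])
        assert all(n >= 2 for _, n in runs)
        assert len(runs) <= 2  # 20 flickering frames collapse to at most two runs

    def test_min_dwell_absorbs_into_longer_neighbor(self):
        # runs: A(3) B(1) C(4); B absorbed into the longer C run
        labels = ["[U1]"] * 3 + ["[U2]"] + ["[U3]"] * 4
        out = smooth(self._track(labels), 1, 2).labels
        assert out == ["[U1]"] * 3 + ["[U3]"] * 5

    def test_min_dwell_tie_prefers_preceding_run(self):
        # runs: A(2) B(1) C(2): tie -> absorb into preceding A
        labels = ["[U1]"] * 2 + ["[U2]"] + ["[U3]"] * 2
        out = smooth(self._track(labels), 1, 2).labels
        assert out == ["[U1]"] * 3 + ["[U3]"] * 2

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(self._track(["[]"]), 4, 1)

    @given(
        labels=st.lists(st.sampled_from(["[U1]", "[U2]", "[U1=U2]", "[]"]), min_size=1, max_size=40),
        window=st.sampled_from([1, 3, 5]),
        min_dwell=st.sampled_from([1, 2, 3]),
    )
    def test_smoothing_never_invents_labels(self, labels, window, min_dwell):
        out = smooth(self._track(labels), window, min_dwell)
        assert len(out) == len(labels)
        assert set(out.labels) <= set(labels)
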