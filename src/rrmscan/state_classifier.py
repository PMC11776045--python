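"""Per-frame classification of the RRM binding pocket into symbolic states.

Each frame is assigned one of five modes:

* ``SINGLE`` - one nucleotide stacked in the Trp215/Phe230 clamp, recognized
  by the N3-H...Cys231(O) and Cys231(N)-H...O2 hydrogen bonds;
* ``VERTICAL`` - a second nucleotide shares the clamp, its N3-H bifurcating
  onto Cys231(O) (partner may sit upstream or downstream of the deep one);
* ``HORIZONTAL`` - the deep nucleotide plus a downstream surface nucleotide
  recognized through Val228(O);
* ``HYBRID`` - any occupied arrangement involving a cytidine. Cytidine lacks
  the N3-H donor, so its participation is scored by the Cys231(N)-H...O2 bond
  and by N3 heavy-atom proximity (within the donor-acceptor cutoff) to the
  slot's acceptor;
* ``UNBOUND`` - no recognition contact present; rendered ``[]``.

The hydrogen-bond pattern is the primary evidence. The clamp width relative
to the 9.0 Å threshold (narrow for one occupant, wide for two) is a secondary
consistency check: conflicting frames keep their H-bond call but are flagged
low-confidence.

Symbolic labels follow the clamp notation: ``[U2]``, ``[U1=U2]`` (vertical,
5'-most written first), ``[U2/U3]`` (horizontal), ``[]`` (empty pocket).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .geometry import HBondCriteria, clamp_distance, distance, hbond
from .trajectory_io import Frame, PocketSpec, RNAResidue

__all__ = [
    "Mode",
    "Occupant",
    "PocketState",
    "TrackEntry",
    "StateTrack",
    "ClassifierParams",
    "FrameAnnotation",
    "classify_frame",
    "annotate_frame",
    "classify",
    "smooth",
    "render_label",
    "parse_label",
]

SINGLE = "SINGLE"
VERTICAL = "VERTICAL"
HORIZONTAL = "HORIZONTAL"
HYBRID = "HYBRID"
UNBOUND = "UNBOUND"
MODES = (SINGLE, VERTICAL, HORIZONTAL, HYBRID, UNBOUND)
Mode = str

DEEP = "deep"
OUTER_VERTICAL = "outer_vertical"
OUTER_HORIZONTAL = "outer_horizontal"


@dataclass(frozen=True)
class Occupant:
    res_seq: int
    base: str
    slot: str  # deep / outer_vertical / outer_horizontal


@dataclass(frozen=True)
class PocketState:
    """Mode + occupants + symbolic label for one frame."""

    mode: Mode
    occupants: tuple[Occupant, ...]
    label: str
    low_confidence: bool = False
    nonconsecutive: bool = False


@dataclass(frozen=True)
class TrackEntry:
    frame_index: int
    time_ns: float
    state: PocketState


@dataclass
class StateTrack:
    """Time-ordered per-frame states (the occupancy-track object)."""

    entries: list[TrackEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.state.label for e in self.entries]

    def frame_interval_ns(self, default: float = 1.0) -> float:
        if len(self.entries) >= 2:
            return self.entries[1].time_ns - self.entries[0].time_ns
        return default

    @classmethod
    def from_labels(
        cls, labels: Sequence[str], frame_interval_ns: float = 1.0
    ) -> "StateTrack":
        return cls(
            [
                TrackEntry(i, i * frame_interval_ns, parse_label(lab))
                for i, lab in enumerate(labels)
            ]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            occ = sorted(e.state.occupants, key=lambda o: o.res_seq)
            deep = next((o for o in e.state.occupants if o.slot == DEEP), None)
            partner = next((o for o in e.state.occupants if o.slot != DEEP), None)
            rows.append(
                {
                    "frame": e.frame_index,
                    "time_ns": e.time_ns,
                    "mode": e.state.mode,
                    "label": e.state.label,
                    "deep_occupant": f"{deep.base}{deep.res_seq}" if deep else "",
                    "partner_occupant": f"{partner.base}{partner.res_seq}"
                    if partner
                    else "",
                    "low_confidence": e.state.low_confidence,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StateTrack":
        entries = []
        for _, row in df.iterrows():
            entries.append(
                TrackEntry(
                    int(row["frame"]), float(row["time_ns"]), parse_label(row["label"])
                )
            )
        return cls(entries)


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable classification parameters.

    ``clamp_threshold`` separates the narrow (one-occupant) from the wide
    (two-occupant) clamp at 9.0 Å; ``smoothing_window`` is an odd majority
    vote window in frames (1 = off); runs shorter than ``min_dwell`` frames
    are absorbed into the longer neighbouring run.
    """

    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    clamp_threshold: float = 9.0
    smoothing_window: int = 1
    min_dwell: int = 1

    def __post_init__(self) -> None:
        if self.clamp_threshold <= 0:
            raise ValueError("clamp_threshold must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")
        if self.min_dwell < 1:
            raise ValueError("min_dwell must be >= 1")


@dataclass
class FrameAnnotation:
    """Full per-frame evidence: the state plus every measured feature."""

    state: PocketState
    clamp_distance: float
    features: dict


def _slot_contact(
    frame: Frame, res: RNAResidue, acceptor: int, criteria: HBondCriteria
) -> tuple[bool, float, float]:
    """(present, heavy distance, angle) for residue N3 against an acceptor.

    Uridine donates N3-H and is judged by the full H-bond criterion; cytidine
    has no N3 proton, so heavy-atom proximity within d_max stands in for the
    contact (the hybrid-state score).
    """
    obs = hbond(frame, res.n3, res.h3, acceptor, criteria)
    if res.base == "U":
        return obs.present, obs.distance, obs.angle
    return obs.distance <= criteria.d_max, obs.distance, float("nan")


def annotate_frame(
    frame: Frame, pocket: PocketSpec, params: ClassifierParams
) -> FrameAnnotation:
    """Classify one frame and record all per-bond evidence."""
    crit = params.hbond
    # --- deep-slot scoring over all RNA residues ------------------------
    per_res = {}
    for res in pocket.rna:
        b1_present, b1_dist, b1_angle = _slot_contact(
            frame, res, pocket.deep_acceptor, crit
        )
        b2 = hbond(frame, pocket.deep_donor, pocket.deep_donor_h, res.o2, crit)
        per_res[res.res_seq] = (res, b1_present, b1_dist, b1_angle, b2)

    candidates = [
        (res_seq, v) for res_seq, v in per_res.items() if v[1] or v[4].present
    ]
    clamp = clamp_distance(frame, pocket)

    features: dict = {"clamp_distance_A": clamp}

    if not candidates:
        state = PocketState(UNBOUND, (), "[]")
        return FrameAnnotation(state, clamp, features)

    # highest bond count wins; ties broken by smallest N3-Cys231(O) distance
    def score(item):
        _, (res, b1p, b1d, _, b2) = item
        return (-(int(b1p) + int(b2.present)), b1d)

    deep_seq, (deep_res, d_b1p, d_b1d, d_b1a, d_b2) = min(candidates, key=score)
    occupants = [Occupant(deep_seq, deep_res.base, DEEP)]
    features.update(
        deep_n3_cysO_present=d_b1p,
        deep_n3_cysO_dist_A=d_b1d,
        deep_cysN_o2_present=d_b2.present,
        deep_cysN_o2_dist_A=d_b2.distance,
    )

    # --- partner detection ---------------------------------------------
    arrangement: str | None = None
    nonconsecutive = False
    vert = []
    for res in pocket.rna:
        if res.res_seq == deep_seq:
            continue
        p, dd, _ = _slot_contact(frame, res, pocket.deep_acceptor, crit)
        if p:
            vert.append((dd, res))
    if vert:
        _, partner = min(vert, key=lambda t: t[0])
        occupants.append(Occupant(partner.res_seq, partner.base, OUTER_VERTICAL))
        arrangement = "vertical"
        nonconsecutive = abs(partner.res_seq - deep_seq) != 1
        features["partner_n3_cysO_dist_A"] = min(vert, key=lambda t: t[0])[0]
    else:
        horiz = []
        for res in pocket.rna:
            if res.res_seq <= deep_seq:  # horizontal partner is strictly downstream
                continue
            p, dd, _ = _slot_contact(frame, res, pocket.outer_acceptor, crit)
            if p:
                horiz.append((res.res_seq, dd, res))
        if horiz:
            _, dd, partner = min(horiz)  # prefer the nearest downstream residue
            occupants.append(
                Occupant(partner.res_seq, partner.base, OUTER_HORIZONTAL)
            )
            arrangement = "horizontal"
            nonconsecutive = partner.res_seq != deep_seq + 1
            features["partner_n3_valO_dist_A"] = dd

    # --- clamp consistency flag ----------------------------------------
    if len(occupants) == 2:
        low_confidence = clamp < params.clamp_threshold
        mode = VERTICAL if arrangement == "vertical" else HORIZONTAL
    else:
        low_confidence = clamp > params.clamp_threshold
        mode = SINGLE
    if any(o.base == "C" for o in occupants):
        mode = HYBRID

    # --- auxiliary lysine contacts (features only, never gate the call) -
    k232 = _best_lysine_bond(frame, pocket.k232_nz, pocket.k232_hs, deep_res.o4, crit)
    features.update(k232_deepO4_present=k232.present, k232_deepO4_dist_A=k232.distance)
    partner_occ = occupants[1] if len(occupants) == 2 else None
    if partner_occ is not None:
        partner_res = next(r for r in pocket.rna if r.res_seq == partner_occ.res_seq)
        k219 = _best_lysine_bond(
            frame, pocket.k219_nz, pocket.k219_hs, partner_res.o4, crit
        )
        features.update(
            k219_partnerO4_present=k219.present, k219_partnerO4_dist_A=k219.distance
        )

    state = PocketState(
        mode=mode,
        occupants=tuple(occupants),
        label=_label_for(occupants, arrangement),
        low_confidence=low_confidence,
        nonconsecutive=nonconsecutive,
    )
    return FrameAnnotation(state, clamp, features)


def _best_lysine_bond(frame, nz, hydrogens, acceptor, crit):
    obs = [hbond(frame, nz, h, acceptor, crit) for h in hydrogens]
    present = [o for o in obs if o.present]
    pool = present or obs
    return min(pool, key=lambda o: o.distance)


def classify_frame(
    frame: Frame, pocket: PocketSpec, params: ClassifierParams | None = None
) -> PocketState:
    """Deterministic, total state call for a single frame."""
    return annotate_frame(frame, pocket, params or ClassifierParams()).state


def classify(
    frame_stream: Iterable[Frame],
    pocket: PocketSpec,
    params: ClassifierParams | None = None,
) -> StateTrack:
    """Classify a frame stream and apply the configured smoothing."""
    params = params or ClassifierParams()
    entries = [
        TrackEntry(f.index, f.time_ns, classify_frame(f, pocket, params))
        for f in frame_stream
    ]
    track = StateTrack(entries)
    if params.smoothing_window > 1 or params.min_dwell > 1:
        track = smooth(track, params.smoothing_window, params.min_dwell)
    return track


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth(track: StateTrack, window: int, min_dwell: int = 1) -> StateTrack:
    """Majority-vote smoothing followed by short-run absorption.

    Each frame takes the unique majority label of the centred ``window``
    (clipped at the track edges); vote ties keep the raw label. Runs shorter
    than ``min_dwell`` frames are then absorbed into the longer adjacent run
    (length ties favour the preceding run). States for relabelled frames are
    copied from the nearest raw frame carrying the winning label, so smoothing
    never invents a state absent from the raw track.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(track.entries)
    if n == 0:
        return StateTrack([])
    raw_labels = track.labels
    raw_states = {lab: {} for lab in set(raw_labels)}
    for i, e in enumerate(track.entries):
        raw_states[e.state.label][i] = e.state

    half = window // 2
    voted: list[str] = []
    for k in range(n):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        counts = Counter(raw_labels[lo:hi])
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        voted.append(winners[0] if len(winners) == 1 else raw_labels[k])

    def nearest_state(label: str, k: int) -> PocketState:
        positions = raw_states[label]
        i = min(positions, key=lambda p: (abs(p - k), p))
        return positions[i]

    labels = _absorb_short_runs(voted, min_dwell)
    entries = []
    for k, e in enumerate(track.entries):
        st = e.state if labels[k] == e.state.label else nearest_state(labels[k], k)
        entries.append(TrackEntry(e.frame_index, e.time_ns, st))
    return StateTrack(entries)


def _runs(labels: Sequence[str]) -> list[list]:
    runs: list[list] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return runs


def _absorb_short_runs(labels: list[str], min_dwell: int) -> list[str]:
    if min_dwell <= 1:
        return labels
    runs = _runs(labels)
    while len(runs) > 1:
        idx = next((i for i, r in enumerate(runs) if r[1] < min_dwell), None)
        if idx is None:
            break
        prev_len = runs[idx - 1][1] if idx > 0 else -1
        next_len = runs[idx + 1][1] if idx + 1 < len(runs) else -1
        target = idx - 1 if prev_len >= next_len else idx + 1
        runs[target][1] += runs[idx][1]
        del runs[idx]
        # coalesce equal neighbours created by the merge
        j = 1
        while j < len(runs):
            if runs[j][0] == runs[j - 1][0]:
                runs[j - 1][1] += runs[j][1]
                del runs[j]
            else:
                j += 1
    out: list[str] = []
    for lab, ln in runs:
        out.extend([lab] * ln)
    return out


# ---------------------------------------------------------------------------
# Symbolic labels
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(
    r"^\[(?:(?P<a>[UC])(?P<an>\d+)(?:(?P<sep>[=/])(?P<b>[UC])(?P<bn>\d+))?)?\]$"
)


def _label_for(occupants: Sequence[Occupant], arrangement: str | None) -> str:
    if not occupants:
        return "[]"
    if len(occupants) == 1:
        o = occupants[0]
        return f"[{o.base}{o.res_seq}]"
    sep = "=" if arrangement == "vertical" else "/"
    first, second = sorted(occupants, key=lambda o: o.res_seq)  # 5'-most first
    return f"[{first.base}{first.res_seq}{sep}{second.base}{second.res_seq}]"


def render_label(state: PocketState) -> str:
    """Symbolic label for a state (grammar: ``[]``, ``[U2]``, ``[U1=U2]``...)."""
    if not state.occupants:
        return "[]"
    arrangement = None
    for o in state.occupants:
        if o.slot == OUTER_VERTICAL:
            arrangement = "vertical"
        elif o.slot == OUTER_HORIZONTAL:
            arrangement = "horizontal"
    return _label_for(state.occupants, arrangement)


def parse_label(text: str) -> PocketState:
    """Parse a symbolic label back into mode + occupants.

    Slot assignment is positional: the 5'-most occupant of a pair is taken as
    deep for horizontal labels (the partner is by definition downstream) and
    by convention for vertical labels, where the label does not record which
    of the two is deep.
    """
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed state label {text!r}")
    if m.group("a") is None:
        return PocketState(UNBOUND, (), "[]")
    a = Occupant(int(m.group("an")), m.group("a"), DEEP)
    if m.group("b") is None:
        mode = HYBRID if a.base == "C" else SINGLE
        return PocketState(mode, (a,), f"[{a.base}{a.res_seq}]")
    sep = m.group("sep")
    slot = OUTER_VERTICAL if sep == "=" else OUTER_HORIZONTAL
    b = Occupant(int(m.group("bn")), m.group("b"), slot)
    if a.res_seq == b.res_seq:
        raise ValueError(f"occupants must differ in {text!r}")
    mode = VERTICAL if sep == "=" else HORIZONTAL
    if a.base == "C" or b.base == "C":
        mode = HYBRID
    occupants = (a, b)
    return PocketState(mode, occupants, _label_for(occupants,
                       "vertical" if sep == "=" else "horizontal"))
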