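"""Synthetic trajectory generator with kinetic ground truth.

A continuous-time Markov simulation of the sliding model supplies a
ground-truth state per saved frame; each frame is then rendered as pseudo-atom
coordinates whose pocket geometry realizes exactly that state's hydrogen-bond
and clamp signature:

* recognition H-bonds are built at 2.9 Å heavy-atom distance and 165°
  donor-H-acceptor angle (comfortably inside the 3.5 Å / 135° criteria);
* the clamp is 8.3 Å wide for one-occupant states and 9.4 / 9.2 Å for
  vertical / horizontal two-occupant states, respecting the 9.0 Å split;
* non-occupying RNA residues are parked tens of Å away, beyond all cutoffs;
* cytidine occupants are rendered without the N3 hydrogen; their N3/O2 heavy
  atoms still sit in acceptor range, reproducing the partial contacts of
  hybrid states.

Only the atoms the classifier touches are placed (plus minimal scaffold atoms
for well-formed PDB records); there is no physical realism beyond the
geometric signatures — no solvent, no energetics, no full protein rebuild.
Isotropic Gaussian coordinate noise emulates thermal jitter. Everything is
reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sliding_model import (
    KineticTrack,
    ModelState,
    SequenceContext,
    SlidingParams,
    sample_model_states,
    simulate,
    model_state_to_pocket_state,
)
from .state_classifier import (
    ClassifierParams,
    StateTrack,
    TrackEntry,
    classify,
)
from .trajectory_io import (
    AtomRecord,
    Frame,
    PocketConfig,
    Topology,
    write_multimodel_pdb,
)

__all__ = [
    "GeometryTemplate",
    "SynthConfig",
    "GroundTruth",
    "SyntheticTrajectory",
    "build_topology",
    "synthetic_pocket_config",
    "generate",
    "round_trip_report",
    "RoundTripReport",
]


def _place_hydrogen(
    donor: np.ndarray, acceptor: np.ndarray, theta_deg: float, dh: float = 1.0
) -> np.ndarray:
    """Hydrogen position giving donor-H-acceptor angle ``theta_deg``.

    Solved in the donor-acceptor plane spanned with a deterministic
    perpendicular; the H sits ``dh`` Å from the donor.
    """
    d = acceptor - donor
    dist = float(np.linalg.norm(d))
    u = d / dist
    # deterministic perpendicular direction
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(u, ref)
    perp /= np.linalg.norm(perp)
    theta = math.radians(theta_deg)
    # law of cosines for |HA| given |DH|, |DA| and the angle at H
    # |DA|^2 = dh^2 + ha^2 - 2 dh ha cos(theta)
    b = -2.0 * dh * math.cos(theta)
    c = dh * dh - dist * dist
    ha = (-b + math.sqrt(b * b - 4 * c)) / 2.0
    # H coordinates in the (u, perp) frame relative to donor
    x = (dh * dh - ha * ha + dist * dist) / (2.0 * dist)
    y2 = dh * dh - x * x
    y = math.sqrt(max(0.0, y2))
    return donor + x * u + y * perp


@dataclass(frozen=True)
class GeometryTemplate:
    """Ideal pocket geometry per mode (Å, degrees)."""

    hbond_distance: float = 2.9
    hbond_angle: float = 165.0
    clamp_single: float = 8.3
    clamp_vertical: float = 9.4
    clamp_horizontal: float = 9.2
    clamp_threshold: float = 9.0  # the split the rendered clamps must respect
    d_max: float = 3.5
    theta_min: float = 135.0

    def validate(self) -> None:
        if not (self.clamp_single < self.clamp_threshold <= self.clamp_vertical):
            raise ValueError("clamp ordering violated: single < threshold <= vertical")
        if self.clamp_threshold > self.clamp_horizontal:
            raise ValueError("clamp ordering violated: threshold <= horizontal")
        if self.hbond_distance > self.d_max:
            raise ValueError("template H-bond distance misses the distance cutoff")
        if self.hbond_angle < self.theta_min:
            raise ValueError("template H-bond angle misses the angle cutoff")


@dataclass
class SynthConfig:
    seq: str = "UUUUU"
    params: SlidingParams = field(default_factory=SlidingParams)
    frame_interval_ns: float = 1.0
    noise_sigma: float = 0.0  # Å, isotropic per atom
    n_frames: int = 1000
    seed: int = 0
    template: GeometryTemplate = field(default_factory=GeometryTemplate)
    start: ModelState | None = None

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        self.template.validate()


@dataclass
class GroundTruth:
    """Generating truth aligned to the emitted frames."""

    state_track: StateTrack
    kinetic_track: KineticTrack
    model_states: list[ModelState]


@dataclass
class SyntheticTrajectory:
    topology: Topology
    frames: list[Frame]
    truth: GroundTruth
    pocket_config: PocketConfig


# --- topology ---------------------------------------------------------------

PROTEIN_CHAIN = "A"
RNA_CHAIN = "B"

_PROTEIN_ATOMS = [
    # (res_name, res_seq, atom_name, element)
    ("TRP", 215, "CE3", "C"),
    ("LYS", 219, "NZ", "N"),
    ("LYS", 219, "HZ1", "H"),
    ("LYS", 219, "HZ2", "H"),
    ("LYS", 219, "HZ3", "H"),
    ("VAL", 228, "O", "O"),
    ("PHE", 230, "CG", "C"),
    ("CYS", 231, "N", "N"),
    ("CYS", 231, "H", "H"),
    ("CYS", 231, "O", "O"),
    ("LYS", 232, "NZ", "N"),
    ("LYS", 232, "HZ1", "H"),
    ("LYS", 232, "HZ2", "H"),
    ("LYS", 232, "HZ3", "H"),
]


def build_topology(seq: str) -> Topology:
    """Pseudo-atom topology: pocket protein atoms + per-residue base atoms."""
    atoms: list[AtomRecord] = []
    for res_name, res_seq, name, element in _PROTEIN_ATOMS:
        atoms.append(
            AtomRecord(name, element, res_name, res_seq, PROTEIN_CHAIN, len(atoms))
        )
    for r, base in enumerate(seq, start=1):
        names = [("C1'", "C"), ("N3", "N"), ("O2", "O"), ("O4", "O")]
        if base == "U":
            names.insert(2, ("H3", "H"))
        for name, element in names:
            atoms.append(AtomRecord(name, element, base, r, RNA_CHAIN, len(atoms)))
    return Topology(atoms)


def synthetic_pocket_config(seq: str, frame_interval_ns: float = 1.0) -> PocketConfig:
    cfg = PocketConfig(
        protein_chain=PROTEIN_CHAIN,
        rna_chain=RNA_CHAIN,
        rna_residues=tuple((i, b) for i, b in enumerate(seq, start=1)),
        frame_interval_ns=frame_interval_ns,
    )
    cfg.validate()
    return cfg


# --- per-mode layout --------------------------------------------------------


class _Layout:
    """Fixed slot coordinates; computed once per template."""

    def __init__(self, template: GeometryTemplate):
        t = template
        self.cys_O = np.array([0.0, 0.0, 0.0])
        self.cys_N = np.array([2.0, -3.3, 0.0])
        # deep slot
        self.deep_N3 = np.array([t.hbond_distance, 0.0, 0.0])
        self.deep_H3 = _place_hydrogen(self.deep_N3, self.cys_O, t.hbond_angle)
        self.deep_O2 = self.cys_N + np.array([0.0, t.hbond_distance, 0.0])
        self.cys_H = _place_hydrogen(self.cys_N, self.deep_O2, t.hbond_angle)
        self.deep_O4 = np.array([3.5, 1.9, 0.0])
        self.deep_C1 = np.array([4.5, -1.5, 0.0])
        # vertical partner slot: N3 on the bifurcated Cys231(O) contact
        ang = math.radians(40.0)
        self.vp_N3 = t.hbond_distance * np.array([math.cos(ang), math.sin(ang), 0.0])
        self.vp_H3 = _place_hydrogen(self.vp_N3, self.cys_O, t.hbond_angle)
        self.vp_O2 = self.vp_N3 + np.array([0.5, 1.2, 0.0])
        self.vp_O4 = self.vp_N3 + np.array([-1.0, 1.5, 0.0])
        self.vp_C1 = self.vp_N3 + np.array([1.5, 1.5, 0.5])
        # horizontal partner slot: N3 on the Val228(O) contact
        self.val_O = np.array([6.5, -2.5, 0.0])
        self.hp_N3 = self.val_O + np.array([0.0, t.hbond_distance, 0.0])
        self.hp_H3 = _place_hydrogen(self.hp_N3, self.val_O, t.hbond_angle)
        self.hp_O2 = self.hp_N3 + np.array([1.3, 0.8, 0.0])
        self.hp_O4 = self.hp_N3 + np.array([1.2, -1.5, 0.0])
        self.hp_C1 = self.hp_N3 + np.array([0.5, 2.0, 0.5])
        # auxiliary lysines aimed at the O4 slots they contact
        self.k232_NZ = self.deep_O4 + np.array([t.hbond_distance, 0.0, 0.0])
        self.k232_HZ1 = _place_hydrogen(self.k232_NZ, self.deep_O4, t.hbond_angle)
        self.k219_NZ = self.hp_O4 + np.array([t.hbond_distance, 0.0, 0.0])
        self.k219_HZ1 = _place_hydrogen(self.k219_NZ, self.hp_O4, t.hbond_angle)
        self.clamp_center = np.array([1.5, 1.0, 0.0])
        self.template = t

    def clamp_width(self, ms: ModelState) -> float:
        t = self.template
        if ms.kind == "V":
            return t.clamp_vertical
        if ms.kind == "H":
            return t.clamp_horizontal
        return t.clamp_single

    def parked(self, res_seq: int) -> dict[str, np.ndarray]:
        base = np.array([25.0 + 7.0 * res_seq, 12.0, 0.0])
        return {
            "N3": base,
            "H3": base + np.array([0.0, 1.0, 0.0]),
            "O2": base + np.array([1.2, -0.8, 0.0]),
            "O4": base + np.array([-1.2, -0.8, 0.0]),
            "C1'": base + np.array([0.0, -2.0, 0.0]),
        }

    def slot_coords(self, role: str) -> dict[str, np.ndarray]:
        if role == "deep":
            return {
                "N3": self.deep_N3,
                "H3": self.deep_H3,
                "O2": self.deep_O2,
                "O4": self.deep_O4,
                "C1'": self.deep_C1,
            }
        if role == "vertical":
            return {
                "N3": self.vp_N3,
                "H3": self.vp_H3,
                "O2": self.vp_O2,
                "O4": self.vp_O4,
                "C1'": self.vp_C1,
            }
        if role == "horizontal":
            return {
                "N3": self.hp_N3,
                "H3": self.hp_H3,
                "O2": self.hp_O2,
                "O4": self.hp_O4,
                "C1'": self.hp_C1,
            }
        raise ValueError(role)


def _render_frame(
    topology: Topology, layout: _Layout, ms: ModelState, seq: str
) -> np.ndarray:
    coords = np.zeros((topology.n_atoms, 3))
    half = layout.clamp_width(ms) / 2.0
    fixed = {
        ("TRP", "CE3"): layout.clamp_center + np.array([0.0, 0.0, half]),
        ("PHE", "CG"): layout.clamp_center + np.array([0.0, 0.0, -half]),
        ("VAL", "O"): layout.val_O,
        ("CYS", "N"): layout.cys_N,
        ("CYS", "H"): layout.cys_H,
        ("CYS", "O"): layout.cys_O,
    }
    lys = {
        (219, "NZ"): layout.k219_NZ,
        (219, "HZ1"): layout.k219_HZ1,
        (219, "HZ2"): layout.k219_NZ + np.array([0.6, 0.6, 0.5]),
        (219, "HZ3"): layout.k219_NZ + np.array([0.6, 0.6, -0.5]),
        (232, "NZ"): layout.k232_NZ,
        (232, "HZ1"): layout.k232_HZ1,
        (232, "HZ2"): layout.k232_NZ + np.array([0.6, 0.6, 0.5]),
        (232, "HZ3"): layout.k232_NZ + np.array([0.6, 0.6, -0.5]),
    }
    roles: dict[int, str] = {}
    if ms.kind in ("S", "V", "H"):
        roles[ms.i] = "deep"
    if ms.kind == "V":
        roles[ms.j] = "vertical"
    elif ms.kind == "H":
        roles[ms.j] = "horizontal"

    for atom in topology.atoms:
        if atom.chain_id == PROTEIN_CHAIN:
            if (atom.res_name, atom.name) in fixed:
                coords[atom.index] = fixed[(atom.res_name, atom.name)]
            else:
                coords[atom.index] = lys[(atom.res_seq, atom.name)]
        else:
            role = roles.get(atom.res_seq)
            slot = (
                layout.slot_coords(role) if role else layout.parked(atom.res_seq)
            )
            coords[atom.index] = slot[atom.name]
    return coords


# --- generation -------------------------------------------------------------


def generate(
    config: SynthConfig, pdb_path: str | Path | None = None
) -> SyntheticTrajectory:
    """Simulate kinetics, render frames, optionally write a multi-model PDB.

    The emitted ground truth has exactly one state per frame; with zero noise
    the classifier recovers it at every frame by construction.
    """
    config.validate()
    seq = SequenceContext(config.seq)
    topology = build_topology(config.seq)
    layout = _Layout(config.template)

    ss = np.random.SeedSequence(config.seed)
    kin_seed, noise_seed = ss.spawn(2)
    dt_us = config.frame_interval_ns / 1000.0
    t_max = config.n_frames * dt_us  # sampling grid 0..(n_frames-1)*dt < t_max
    kt = simulate(config.params, seq, t_max, kin_seed, start=config.start)
    model_states = sample_model_states(kt, config.frame_interval_ns)[: config.n_frames]

    noise_rng = np.random.default_rng(noise_seed)
    frames: list[Frame] = []
    truth_entries: list[TrackEntry] = []
    for k, ms in enumerate(model_states):
        coords = _render_frame(topology, layout, ms, config.seq)
        if config.noise_sigma > 0:
            coords = coords + noise_rng.normal(
                0.0, config.noise_sigma, size=coords.shape
            )
        t_ns = k * config.frame_interval_ns
        frames.append(Frame(index=k, time_ns=t_ns, coords=coords))
        truth_entries.append(TrackEntry(k, t_ns, model_state_to_pocket_state(ms, seq)))

    truth = GroundTruth(
        state_track=StateTrack(truth_entries),
        kinetic_track=kt,
        model_states=model_states,
    )
    if pdb_path is not None:
        write_multimodel_pdb(topology, frames, pdb_path)
    return SyntheticTrajectory(
        topology=topology,
        frames=frames,
        truth=truth,
        pocket_config=synthetic_pocket_config(config.seq, config.frame_interval_ns),
    )


@dataclass
class RoundTripReport:
    agreement: float  # fraction of frames where classify() matches the truth
    confusion: pd.DataFrame  # truth mode x predicted mode counts
    n_frames: int


def round_trip_report(
    config: SynthConfig, cparams: ClassifierParams | None = None
) -> RoundTripReport:
    """generate -> classify -> compare, frame by frame."""
    from .trajectory_io import resolve_pocket

    traj = generate(config)
    pocket = resolve_pocket(traj.topology, traj.pocket_config)
    predicted = classify(traj.frames, pocket, cparams or ClassifierParams())
    truth = traj.truth.state_track
    n = len(truth)
    agree = sum(
        1
        for a, b in zip(truth.entries, predicted.entries)
        if a.state.label == b.state.label
    )
    modes = sorted({e.state.mode for e in truth.entries}
                   | {e.state.mode for e in predicted.entries})
    confusion = pd.DataFrame(0, index=modes, columns=modes)
    for a, b in zip(truth.entries, predicted.entries):
        confusion.loc[a.state.mode, b.state.mode] += 1
    return RoundTripReport(agreement=agree / n, confusion=confusion, n_frames=n)
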