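"""Trajectory and topology I/O.

The reference trajectory dialect is multi-model PDB (``MODEL``/``ENDMDL``
blocks over a fixed topology), which keeps every input human-inspectable and
text-stable. Binary trajectory formats (DCD/XTC, read through MDAnalysis) are
supported as an adapter behind the same :class:`Frame` contract.

Parsing is deliberately strict: the pocket criteria are atom-identity-critical,
so alternate locations, insertion codes, duplicate atoms and malformed records
are rejected with errors that name the offending line rather than silently
filtered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "RNAResidue",
    "PocketSpec",
    "PocketConfig",
    "TrajectoryIOError",
    "PDBParseError",
    "DuplicateAtomError",
    "AtomLookupError",
    "FrameShapeError",
    "FrameDataError",
    "read_topology",
    "frames",
    "frames_binary",
    "write_multimodel_pdb",
    "resolve_pocket",
    "read_pocket_config",
    "write_pocket_config",
    "write_table",
]


class TrajectoryIOError(Exception):
    """Base class for trajectory/topology I/O failures."""


class PDBParseError(TrajectoryIOError):
    """Malformed PDB record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DuplicateAtomError(TrajectoryIOError):
    """Two atoms share (chain, residue number, atom name)."""


class AtomLookupError(TrajectoryIOError):
    """A required (chain, residue number, atom name) handle is missing."""


class FrameShapeError(TrajectoryIOError):
    """Frame atom count disagrees with the topology."""


class FrameDataError(TrajectoryIOError):
    """Non-finite coordinate encountered in a frame."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology; ``index`` is contiguous and 0-based."""

    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    index: int


class Topology:
    """Ordered atom collection with (chain, res_seq, name) lookup."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self._lookup: dict[tuple[str, int, str], int] = {}
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in self._lookup:
                raise DuplicateAtomError(
                    f"duplicate atom {a.chain_id}/{a.res_seq}/{a.name}"
                )
            self._lookup[key] = a.index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, chain_id: str, res_seq: int, name: str) -> int:
        try:
            return self._lookup[(chain_id, res_seq, name)]
        except KeyError:
            raise AtomLookupError(
                f"no atom {chain_id}/{res_seq}/{name} in topology"
            ) from None

    def get(self, chain_id: str, res_seq: int, name: str) -> int | None:
        return self._lookup.get((chain_id, res_seq, name))

    def residue_name(self, chain_id: str, res_seq: int) -> str | None:
        for a in self.atoms:
            if a.chain_id == chain_id and a.res_seq == res_seq:
                return a.res_name
        return None


@dataclass
class Frame:
    """Coordinates (Å) for every topology atom at one saved time point."""

    index: int
    time_ns: float
    coords: np.ndarray  # shape (n_atoms, 3)


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord | None, np.ndarray]:
    """Parse one ATOM/HETATM record into (metadata, xyz).

    Returns metadata=None is never used; raises on any malformation.
    """
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("ATOM record shorter than coordinate fields", lineno)
    altloc = line[16]
    if altloc not in (" ", ""):
        raise PDBParseError(f"alternate location indicator {altloc!r} rejected", lineno)
    icode = line[26]
    if icode not in (" ", ""):
        raise PDBParseError(f"insertion code {icode!r} rejected", lineno)
    name = line[12:16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        res_seq = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"unreadable residue number {line[22:26]!r}", lineno)
    try:
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    except ValueError:
        raise PDBParseError(f"unreadable coordinates {line[30:54]!r}", lineno)
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the first alphabetic character of the atom name
        element = next((c for c in name if c.isalpha()), "X")
    rec = AtomRecord(
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        index=-1,  # assigned by caller
    )
    return rec, xyz


def read_topology(path: str | Path, format: str = "pdb") -> Topology:
    """Read the topology (atom metadata) from a PDB file.

    For a multi-model file the first MODEL block defines the topology; a file
    without MODEL records is treated as a single structure.
    """
    if format != "pdb":
        raise ValueError(f"unsupported topology format {format!r}")
    atoms: list[AtomRecord] = []
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if tag == "MODEL ":
                if saw_model:
                    break
                saw_model = True
                in_model = True
            elif tag == "ENDMDL":
                if saw_model:
                    break
            elif tag in ("ATOM  ", "HETATM"):
                if saw_model and not in_model:
                    continue
                rec, _ = _parse_atom_line(line, lineno)
                atoms.append(
                    AtomRecord(
                        name=rec.name,
                        element=rec.element,
                        res_name=rec.res_name,
                        res_seq=rec.res_seq,
                        chain_id=rec.chain_id,
                        index=len(atoms),
                    )
                )
    if not atoms:
        raise PDBParseError("no ATOM records found", 0)
    return Topology(atoms)


def frames(
    path: str | Path,
    topology: Topology,
    frame_interval_ns: float = 1.0,
) -> Iterator[Frame]:
    """Lazily yield coordinate frames from a (multi-model) PDB file.

    Frame times are ``frame_index * frame_interval_ns``; the PDB dialect
    carries no time stamps of its own.
    """
    n_expected = topology.n_atoms
    coords: list[np.ndarray] = []
    frame_index = 0
    saw_model = False

    def _emit() -> Frame:
        nonlocal frame_index, coords
        if len(coords) != n_expected:
            raise FrameShapeError(
                f"model {frame_index}: {len(coords)} atoms, topology has {n_expected}"
            )
        arr = np.asarray(coords, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise FrameDataError(f"non-finite coordinate in frame {frame_index}")
        f = Frame(index=frame_index, time_ns=frame_index * frame_interval_ns, coords=arr)
        frame_index += 1
        coords = []
        return f

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if tag == "MODEL ":
                saw_model = True
            elif tag == "ENDMDL":
                yield _emit()
            elif tag in ("ATOM  ", "HETATM"):
                _, xyz = _parse_atom_line(line, lineno)
                coords.append(xyz)
    if coords:
        # trailing model without ENDMDL, or a single-structure file
        yield _emit()
    elif not saw_model and frame_index == 0:
        raise PDBParseError("no coordinates found", 0)


def frames_binary(
    traj_path: str | Path,
    topology_path: str | Path,
    frame_interval_ns: float | None = None,
) -> Iterator[Frame]:
    """Adapter for binary trajectory formats (DCD/XTC/...) via MDAnalysis.

    The PDB topology file defines atom identities; coordinates are streamed
    from the binary trajectory under the same :class:`Frame` contract as
    :func:`frames`. Times come from the trajectory itself unless overridden
    by ``frame_interval_ns``.
    """
    import MDAnalysis as mda  # deferred: optional dependency

    topo = read_topology(topology_path)
    u = mda.Universe(str(topology_path), str(traj_path))
    if u.atoms.n_atoms != topo.n_atoms:
        raise FrameShapeError(
            f"trajectory has {u.atoms.n_atoms} atoms, topology has {topo.n_atoms}"
        )
    for i, ts in enumerate(u.trajectory):
        arr = np.array(ts.positions, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise FrameDataError(f"non-finite coordinate in frame {i}")
        if frame_interval_ns is not None:
            t_ns = i * frame_interval_ns
        else:
            t_ns = float(ts.time) / 1000.0  # MDAnalysis reports ps
        yield Frame(index=i, time_ns=t_ns, coords=arr)


def _format_atom_name(name: str) -> str:
    # Names of up to three characters start in column 14 (PDB convention).
    return name.ljust(4) if len(name) >= 4 else (" " + name).ljust(4)


def write_multimodel_pdb(
    topology: Topology, frame_stream: Iterable[Frame], path: str | Path
) -> int:
    """Write frames as a multi-model PDB; returns the number of models."""
    n_models = 0
    with open(path, "w") as fh:
        for frame in frame_stream:
            if frame.coords.shape != (topology.n_atoms, 3):
                raise FrameShapeError(
                    f"frame {frame.index}: coords shape {frame.coords.shape}"
                )
            n_models += 1
            fh.write(f"MODEL {n_models:>8d}\n")
            for a, (x, y, z) in zip(topology.atoms, frame.coords):
                fh.write(
                    f"ATOM  {a.index + 1:>5d} {_format_atom_name(a.name)}"
                    f"{a.res_name:>4s} {a.chain_id}{a.res_seq:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return n_models


# ---------------------------------------------------------------------------
# Pocket configuration and resolution
# ---------------------------------------------------------------------------

#: RNA base letters accepted by the pocket criteria.
BASES = ("U", "C")


@dataclass(frozen=True)
class RNAResidue:
    """Resolved base atoms of one RNA residue (5'->3' order in PocketSpec)."""

    res_seq: int
    base: str  # "U" or "C"
    n3: int
    h3: int | None  # None for cytidine (no N3-H donor)
    o2: int
    o4: int


@dataclass(frozen=True)
class PocketSpec:
    """Atom handles for every residue/atom the pocket criteria touch.

    The clamp is the Trp215(CE3)-Phe230(CG) aromatic sandwich; the deep slot
    is read out through the Cys231 backbone (O as acceptor for the uridine
    N3-H, N-H as donor toward the base O2); the outer horizontal slot is read
    out through Val228(O). Lys219/Lys232 side-chain amines are auxiliary
    feature donors that never gate the state call.
    """

    clamp_a: int  # Trp215 CE3
    clamp_b: int  # Phe230 CG
    deep_acceptor: int  # Cys231 O
    deep_donor: int  # Cys231 N
    deep_donor_h: int  # Cys231 amide H
    outer_acceptor: int  # Val228 O
    k219_nz: int
    k219_hs: tuple[int, ...]
    k232_nz: int
    k232_hs: tuple[int, ...]
    rna: tuple[RNAResidue, ...]


@dataclass
class PocketConfig:
    """Flat description of where the pocket lives in a given topology."""

    protein_chain: str = "A"
    rna_chain: str = "B"
    trp215: int = 215
    phe230: int = 230
    val228: int = 228
    cys231: int = 231
    lys219: int = 219
    lys232: int = 232
    rna_residues: tuple[tuple[int, str], ...] = ()
    frame_interval_ns: float = 1.0

    def validate(self) -> None:
        if not self.rna_residues:
            raise ValueError("rna_residues must name at least one residue")
        seqs = [r for r, _ in self.rna_residues]
        if sorted(seqs) != seqs or len(set(seqs)) != len(seqs):
            raise ValueError("rna_residues must be strictly increasing 5'->3'")
        for _, b in self.rna_residues:
            if b not in BASES:
                raise ValueError(f"unsupported base {b!r}; alphabet is {BASES}")


def read_pocket_config(path: str | Path) -> PocketConfig:
    """Read a flat ``key = value`` pocket configuration file."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line {raw.rstrip()!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    cfg = PocketConfig()
    for attr in ("protein_chain", "rna_chain"):
        if attr in kv:
            setattr(cfg, attr, kv.pop(attr))
    for attr in ("trp215", "phe230", "val228", "cys231", "lys219", "lys232"):
        if attr in kv:
            setattr(cfg, attr, int(kv.pop(attr)))
    if "frame_interval_ns" in kv:
        cfg.frame_interval_ns = float(kv.pop("frame_interval_ns"))
    if "rna_residues" in kv:
        items = []
        for tok in kv.pop("rna_residues").split(","):
            seq_s, base = tok.strip().split(":")
            items.append((int(seq_s), base.strip()))
        cfg.rna_residues = tuple(items)
    if kv:
        raise ValueError(f"unknown config keys: {sorted(kv)}")
    cfg.validate()
    return cfg


def write_pocket_config(cfg: PocketConfig, path: str | Path) -> None:
    cfg.validate()
    rna = ",".join(f"{r}:{b}" for r, b in cfg.rna_residues)
    with open(path, "w") as fh:
        fh.write(
            f"protein_chain = {cfg.protein_chain}\n"
            f"rna_chain = {cfg.rna_chain}\n"
            f"trp215 = {cfg.trp215}\n"
            f"phe230 = {cfg.phe230}\n"
            f"val228 = {cfg.val228}\n"
            f"cys231 = {cfg.cys231}\n"
            f"lys219 = {cfg.lys219}\n"
            f"lys232 = {cfg.lys232}\n"
            f"rna_residues = {rna}\n"
            f"frame_interval_ns = {cfg.frame_interval_ns}\n"
        )


def _require(topology: Topology, chain: str, res_seq: int, name: str) -> int:
    return topology.index_of(chain, res_seq, name)


def resolve_pocket(topology: Topology, config: PocketConfig) -> PocketSpec:
    """Bind every pocket handle to an internal atom index.

    Raises :class:`AtomLookupError` naming the missing handle; cytidine
    residues are resolved without an N3 hydrogen (they lack the donor).
    """
    config.validate()
    pc = config.protein_chain
    clamp_a = _require(topology, pc, config.trp215, "CE3")
    clamp_b = _require(topology, pc, config.phe230, "CG")
    deep_acceptor = _require(topology, pc, config.cys231, "O")
    deep_donor = _require(topology, pc, config.cys231, "N")
    deep_donor_h = topology.get(pc, config.cys231, "H")
    if deep_donor_h is None:
        deep_donor_h = topology.get(pc, config.cys231, "HN")
    if deep_donor_h is None:
        raise AtomLookupError(
            f"no amide hydrogen (H/HN) on {pc}/{config.cys231}"
        )
    outer_acceptor = _require(topology, pc, config.val228, "O")

    def lys_group(res_seq: int) -> tuple[int, tuple[int, ...]]:
        nz = _require(topology, pc, res_seq, "NZ")
        hs = tuple(
            idx
            for name in ("HZ1", "HZ2", "HZ3")
            if (idx := topology.get(pc, res_seq, name)) is not None
        )
        if not hs:
            raise AtomLookupError(f"no HZ hydrogens on {pc}/{res_seq}")
        return nz, hs

    k219_nz, k219_hs = lys_group(config.lys219)
    k232_nz, k232_hs = lys_group(config.lys232)

    rc = config.rna_chain
    rna: list[RNAResidue] = []
    for res_seq, base in config.rna_residues:
        n3 = _require(topology, rc, res_seq, "N3")
        o2 = _require(topology, rc, res_seq, "O2")
        o4 = _require(topology, rc, res_seq, "O4")
        h3 = _require(topology, rc, res_seq, "H3") if base == "U" else None
        rna.append(RNAResidue(res_seq=res_seq, base=base, n3=n3, h3=h3, o2=o2, o4=o4))

    return PocketSpec(
        clamp_a=clamp_a,
        clamp_b=clamp_b,
        deep_acceptor=deep_acceptor,
        deep_donor=deep_donor,
        deep_donor_h=deep_donor_h,
        outer_acceptor=outer_acceptor,
        k219_nz=k219_nz,
        k219_hs=k219_hs,
        k232_nz=k232_nz,
        k232_hs=k232_hs,
        rna=tuple(rna),
    )


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write tabular output as TSV (header always present)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)
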