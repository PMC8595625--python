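"""Structures, trajectories, segment definitions and Ballesteros–Weinstein numbering.

The in-memory containers are deliberately small: an ordered list of atom records
with author (PDB) residue numbering as the universal key, a trajectory as a
``(n_frames, n_atoms, 3)`` coordinate array over a shared topology, and a
segment definition holding named residue ranges (TM helices and loops), pivot
residues for kinked helices, and the x.50 anchor residues that define
Ballesteros–Weinstein (BW) generic numbering.

File I/O (PDB, multi-model PDB, DCD, XTC) is delegated to MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    EmptyStructureError,
    FormatError,
    InsertionCodeError,
    MissingPivotError,
    NoCBetaError,
    OutOfRangeError,
    ResidueLookupError,
    TopologyError,
)

#: 3-letter codes treated as protein residues when reading files.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Heavy atoms retained by an in-silico alanine truncation.
_ALA_HEAVY = {"N", "CA", "C", "O", "CB", "OXT"}
#: Backbone/C-beta hydrogens retained (side-chain hydrogens beyond CB removed).
_ALA_HYDRO = {"H", "HN", "HA", "HA1", "HA2", "HT1", "HT2", "HT3",
              "HB", "HB1", "HB2", "HB3"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, residue identity (author numbering) and position in Å."""

    atom_name: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    element: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Structure:
    """An ordered list of atoms, grouped contiguously by residue."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} does not match {len(self.atoms)} atoms")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label if label is not None else self.label)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain, residue_number, residue_name)`` triples."""
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_number, a.residue_name))
        return out

    def atom_indices(self, predicate: Callable[[AtomRecord], bool]) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)

    def find_atom(self, residue_number: int, atom_name: str,
                  chain_id: str | None = None) -> int:
        for i, a in enumerate(self.atoms):
            if (a.residue_number == residue_number and a.atom_name == atom_name
                    and (chain_id is None or a.chain_id == chain_id)):
                return i
        raise ResidueLookupError(
            f"atom {atom_name} of residue {residue_number} not found")

    def subset(self, predicate: Callable[[AtomRecord], bool], label: str = "") -> "Structure":
        kept = [a for a in self.atoms if predicate(a)]
        if not kept:
            raise EmptyStructureError("selection matched no atoms")
        return Structure(kept, label or self.label)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a shared topology."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology.atoms) \
                or self.frames.shape[2] != 3:
            raise TopologyError(
                f"frame array shape {self.frames.shape} does not match topology with "
                f"{len(self.topology.atoms)} atoms")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coordinates(self.frames[i])


# ---------------------------------------------------------------------------
# Ballesteros–Weinstein numbering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BWLabel:
    """Generic GPCR residue number H.NN (helix index, position)."""

    helix_index: int
    position: int

    def __post_init__(self):
        if not (1 <= self.helix_index <= 8):
            raise ValueError(f"helix index {self.helix_index} outside 1–8")

    def __str__(self) -> str:
        return f"{self.helix_index}.{self.position:02d}"

    @property
    def value(self) -> float:
        """The label as the decimal number it is printed as (e.g. 2.63)."""
        return self.helix_index + self.position / 100.0

    @classmethod
    def from_string(cls, text: str) -> "BWLabel":
        try:
            h, p = text.split(".")
            return cls(int(h), int(p))
        except (ValueError, AttributeError) as exc:
            raise FormatError(f"not a BW label: {text!r}") from exc


def _tm_index(name: str) -> int | None:
    """Helix index parsed from a TM segment name ('TM6', 'TM6-1' → 6)."""
    upper = name.upper()
    if not upper.startswith("TM"):
        return None
    digits = ""
    for ch in upper[2:]:
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits) if digits else None


@dataclass
class SegmentDefinition:
    """Named residue ranges with pivots and BW anchor residues.

    ``segments`` maps a name (TM1, ECL2, ...) to an inclusive
    ``(first_residue, last_residue)`` range in author numbering. ``pivots``
    maps a segment name to the residue at which a kinked helix is split into
    two compartments. ``bw_anchors`` maps a helix index to
    ``(anchor_position, anchor_residue)`` — the residue that carries the
    generic position ``helix.anchor_position`` (normally x.50).
    """

    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    pivots: dict[str, int] = field(default_factory=dict)
    bw_anchors: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (first, last) in self.segments.items():
            if first > last:
                raise ValueError(f"segment {name}: first {first} > last {last}")
        ranges = sorted(self.segments.values())
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping segment ranges {a0}-{a1} and {b0}-{b1}")
        for name, pivot in self.pivots.items():
            first, last = self.segments[name]
            if not (first < pivot < last):
                raise MissingPivotError(
                    f"pivot {pivot} not strictly inside segment {name} [{first}, {last}]")

    # -- segment helpers ----------------------------------------------------

    def segment_range(self, name: str) -> tuple[int, int]:
        try:
            return self.segments[name]
        except KeyError as exc:
            raise OutOfRangeError(f"unknown segment {name!r}") from exc

    def helix_segments(self) -> list[str]:
        """Segments treated as helices: names starting with 'TM' or 'H8'."""
        return [n for n in self.segments
                if n.upper().startswith("TM") or n.upper().startswith("H8")]

    def helix_for_residue(self, residue_number: int) -> int | None:
        """Helix index of the TM segment containing the residue, if any."""
        for name, (first, last) in self.segments.items():
            idx = _tm_index(name)
            if idx is not None and first <= residue_number <= last:
                return idx
        return None

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentDefinition":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        segments = {}
        for name, rng in (raw.get("segments") or {}).items():
            if isinstance(rng, Mapping):
                segments[str(name)] = (int(rng["first"]), int(rng["last"]))
            else:
                first, last = rng
                segments[str(name)] = (int(first), int(last))
        pivots = {str(k): int(v) for k, v in (raw.get("pivots") or {}).items()}
        anchors: dict[int, tuple[int, int]] = {}
        for key, res in (raw.get("bw_anchors") or {}).items():
            label = BWLabel.from_string(str(key))
            anchors[label.helix_index] = (label.position, int(res))
        return cls(segments=segments, pivots=pivots, bw_anchors=anchors)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "segments": {n: {"first": int(f), "last": int(l)}
                         for n, (f, l) in self.segments.items()},
            "pivots": {n: int(p) for n, p in self.pivots.items()},
            "bw_anchors": {f"{h}.{pos:02d}": int(res)
                           for h, (pos, res) in sorted(self.bw_anchors.items())},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def bw_to_residue(label: BWLabel, definition: SegmentDefinition) -> int:
    """Residue number carrying a BW generic position, by pure offset from the anchor."""
    try:
        anchor_pos, anchor_res = definition.bw_anchors[label.helix_index]
    except KeyError as exc:
        raise OutOfRangeError(f"no BW anchor for helix {label.helix_index}") from exc
    residue = anchor_res + (label.position - anchor_pos)
    rng = definition.segments.get(f"TM{label.helix_index}")
    if rng is not None and not (rng[0] <= residue <= rng[1]):
        raise OutOfRangeError(
            f"BW {label} maps to residue {residue}, outside TM{label.helix_index} "
            f"range {rng}")
    return residue


def residue_to_bw(residue_number: int, definition: SegmentDefinition,
                  helix_index: int | None = None) -> BWLabel:
    """Inverse of :func:`bw_to_residue` for residues inside a defined helix."""
    if helix_index is None:
        helix_index = definition.helix_for_residue(residue_number)
        if helix_index is None:
            raise OutOfRangeError(
                f"residue {residue_number} lies in no defined TM segment")
    try:
        anchor_pos, anchor_res = definition.bw_anchors[helix_index]
    except KeyError as exc:
        raise OutOfRangeError(f"no BW anchor for helix {helix_index}") from exc
    position = anchor_pos + (residue_number - anchor_res)
    if not (0 <= position <= 99):
        raise OutOfRangeError(
            f"residue {residue_number} maps to position {position}, outside 0–99")
    return BWLabel(helix_index, position)


def split_at_pivot(segment: str, definition: SegmentDefinition
                   ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Split a kinked helix at its pivot residue.

    The pivot residue belongs to the second compartment:
    ``[first, pivot-1]`` and ``[pivot, last]``.
    """
    if segment not in definition.segments:
        raise OutOfRangeError(f"unknown segment {segment!r}")
    if segment not in definition.pivots:
        raise MissingPivotError(f"segment {segment!r} has no declared pivot")
    first, last = definition.segments[segment]
    pivot = definition.pivots[segment]
    return (first, pivot - 1), (pivot, last)


def expand_segments(definition: SegmentDefinition) -> dict[str, tuple[int, int]]:
    """Segment ranges with every pivoted segment replaced by its two compartments."""
    out: dict[str, tuple[int, int]] = {}
    for name, rng in definition.segments.items():
        if name in definition.pivots:
            sub1, sub2 = split_at_pivot(name, definition)
            out[f"{name}-1"] = sub1
            out[f"{name}-2"] = sub2
        else:
            out[name] = rng
    return out


# ---------------------------------------------------------------------------
# File I/O via MDAnalysis
# ---------------------------------------------------------------------------

def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _element_of(name: str, element: str) -> str:
    el = (element or "").strip()
    if el:
        return el.capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(path: str | Path, label: str | None = None,
                   include_hetero: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure` (protein records only).

    Waters, ions and other non-protein heteroatoms are dropped; residues with
    insertion codes are rejected outright because the author-numbering key
    would become ambiguous. Of alternate locations only the first ('A' or
    blank) is kept.
    """
    mda = _import_mda()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises a zoo of types here
        raise FormatError(f"could not parse {path}: {exc}") from exc

    try:
        icodes = u.atoms.icodes
    except Exception:
        icodes = None
    try:
        altlocs = u.atoms.altLocs
    except Exception:
        altlocs = None
    try:
        elements = u.atoms.elements
    except Exception:
        elements = [""] * len(u.atoms)
    try:
        chainids = u.atoms.chainIDs
    except Exception:
        chainids = ["A"] * len(u.atoms)

    atoms: list[AtomRecord] = []
    for i, at in enumerate(u.atoms):
        resname = str(at.resname).strip().upper()
        if resname not in STANDARD_RESIDUES:
            continue
        if icodes is not None and str(icodes[i]).strip():
            raise InsertionCodeError(
                f"{path}: residue {at.resid}{icodes[i]} carries an insertion code; "
                "renumber the structure first")
        if altlocs is not None and str(altlocs[i]).strip() not in ("", "A"):
            continue  # keep only the first alternate location
        chain = str(chainids[i]).strip() or "A"
        atoms.append(AtomRecord(
            atom_name=str(at.name).strip(),
            residue_number=int(at.resid),
            residue_name=resname,
            chain_id=chain,
            position=np.array(at.position, dtype=float),
            element=_element_of(str(at.name), str(elements[i])),
        ))
    if not atoms:
        raise EmptyStructureError(f"{path}: no protein atoms found")
    return Structure(atoms, label if label is not None else path.stem)


def _as_universe(structure: Structure, n_frames: int = 1):
    """Build an in-memory MDAnalysis Universe mirroring a Structure."""
    mda = _import_mda()
    residues = structure.residues()
    res_index = {(c, r): i for i, (c, r, _) in enumerate(residues)}
    chains = []
    for c, _, _ in residues:
        if c not in chains:
            chains.append(c)
    seg_index = {c: i for i, c in enumerate(chains)}
    atom_resindex = np.array([res_index[a.residue_id] for a in structure.atoms])
    residue_segindex = np.array([seg_index[c] for c, _, _ in residues])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=len(structure.atoms),
            n_residues=len(residues),
            n_segments=len(chains),
            atom_resindex=atom_resindex,
            residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.atom_name for a in structure.atoms])
        u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
        u.add_TopologyAttr("resids", [r for _, r, _ in residues])
        u.add_TopologyAttr("resnames", [n for _, _, n in residues])
        u.add_TopologyAttr("segids", chains)
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in structure.atoms])
        u.add_TopologyAttr("occupancies", np.ones(len(structure.atoms)))
        u.add_TopologyAttr("tempfactors", np.zeros(len(structure.atoms)))
        u.atoms.positions = structure.coordinates
    return u


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure to a PDB file (coordinates at PDB precision, 1e-3 Å)."""
    u = _as_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(topology: Structure, path: str | Path) -> Trajectory:
    """Read a coordinate trajectory (DCD, XTC, or multi-model PDB) over a topology."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    u = _as_universe(topology)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except Exception as exc:
        raise TopologyError(
            f"could not load {path} over topology with {len(topology.atoms)} atoms: "
            f"{exc}") from exc
    if len(u.atoms) != len(topology.atoms):
        raise TopologyError(
            f"{path}: {len(u.atoms)} atoms, topology has {len(topology.atoms)}")
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
    return Trajectory(topology, np.array(frames))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames to multi-model PDB, DCD, or XTC (chosen by extension)."""
    mda = _import_mda()
    u = _as_universe(traj.topology)
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=len(traj.topology.atoms), multiframe=True) as w:
            for f in traj.frames:
                u.atoms.positions = f
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# In-silico alanine truncation
# ---------------------------------------------------------------------------

def truncate_to_alanine(structure: Structure, residue_number: int,
                        chain_id: str | None = None) -> Structure:
    """Replace one residue's side chain beyond C-beta with alanine.

    Backbone and C-beta coordinates are untouched; the residue is renamed ALA.
    Glycine (no C-beta) and proline (backbone-fused ring) are rejected.
    """
    target = [a for a in structure.atoms
              if a.residue_number == residue_number
              and (chain_id is None or a.chain_id == chain_id)]
    if not target:
        raise ResidueLookupError(f"residue {residue_number} not in structure")
    resname = target[0].residue_name
    if resname == "GLY":
        raise NoCBetaError(f"residue {residue_number} is glycine: no C-beta to keep")
    if resname == "PRO":
        raise NoCBetaError(f"residue {residue_number} is proline: ring fused to backbone")

    def keep(a: AtomRecord) -> bool:
        if a.residue_number != residue_number or (chain_id is not None
                                                  and a.chain_id != chain_id):
            return True
        return a.atom_name in _ALA_HEAVY or a.atom_name in _ALA_HYDRO

    atoms = [replace(a, residue_name="ALA")
             if a.residue_number == residue_number
             and (chain_id is None or a.chain_id == chain_id) else a
             for a in structure.atoms if keep(a)]
    return Structure(atoms, structure.label)
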