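"""Helix-orientation geometry: superposition, helix vectors, tilt angles, RMSD, RMSF.

The membrane normal is taken as the +Z axis throughout, so a helix "angle" is
the angle between the helix vector (N-terminal endpoint → C-terminal endpoint)
and Z, in [0, 180]°. Endpoints follow a fixed turn-of-helix rule: skip one gap
residue at the extreme terminus, take the next four residues' C/CA/N backbone
atoms and drop the single innermost of those twelve, leaving eleven atoms whose
unweighted coordinate mean is the endpoint.

Per-segment RMSD is computed with *no* re-fitting (the trajectory is globally
superposed once), so rigid shifts and tilts of a helix show up in its RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateVectorError,
    IncompleteBackboneError,
    InsufficientFramesError,
    SelectionError,
    UnderdeterminedFitError,
)
from .structure import (
    AtomRecord,
    SegmentDefinition,
    Structure,
    Trajectory,
    expand_segments,
)

#: Backbone atoms entering helix-vector endpoints.
ENDPOINT_BACKBONE = ("N", "CA", "C")
#: Backbone atoms entering per-segment no-fit RMSD.
RMSD_BACKBONE = ("C", "CA", "O", "N")
#: Residues taken per terminus and gap residues skipped at the extreme end.
ENDPOINT_WINDOW = 4
ENDPOINT_GAP = 1


@dataclass(frozen=True)
class HelixEndpoint:
    """Endpoint of a helix vector: 11 backbone atoms and their mean position."""

    terminus: str  # "N" or "C"
    atom_set: tuple[tuple[int, str], ...]  # (residue_number, atom_name)
    point: np.ndarray

    def __post_init__(self):
        if len(self.atom_set) != 11:
            raise IncompleteBackboneError(
                f"endpoint atom set has {len(self.atom_set)} atoms, expected 11")


@dataclass(frozen=True)
class HelixVector:
    segment: str
    n_point: np.ndarray
    c_point: np.ndarray

    @property
    def direction(self) -> np.ndarray:
        d = self.c_point - self.n_point
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            raise DegenerateVectorError(f"helix vector of {self.segment} has zero length")
        return d / norm


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def default_alignment_selection(definition: SegmentDefinition
                                ) -> Callable[[AtomRecord], bool]:
    """Cα atoms of all TM residues (loops excluded) — the default fit selection."""
    ranges = [definition.segments[n] for n in definition.helix_segments()]

    def predicate(a: AtomRecord) -> bool:
        return a.atom_name == "CA" and any(f <= a.residue_number <= l
                                           for f, l in ranges)
    return predicate


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Rotation, np.ndarray]:
    """Least-squares (Kabsch) fit: rotation and translation mapping mobile onto reference.

    Returns ``(R, t)`` with ``fitted = R.apply(mobile - mobile_centroid) + t``.
    """
    if mobile.shape[0] < 3:
        raise UnderdeterminedFitError(
            f"{mobile.shape[0]} atoms selected; at least 3 needed for a rigid fit")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    return rot, ref_c


def align_to_reference(traj: Trajectory, ref: Structure,
                       selection: Callable[[AtomRecord], bool] | None = None,
                       definition: SegmentDefinition | None = None) -> Trajectory:
    """Rigid-body superpose every frame onto the reference over a selection.

    With no explicit selection, Cα atoms of TM residues are used (requires a
    segment definition).
    """
    if selection is None:
        if definition is None:
            raise SelectionError("either a selection or a segment definition is required")
        selection = default_alignment_selection(definition)
    idx = traj.topology.atom_indices(selection)
    ref_idx = ref.atom_indices(selection)
    if len(idx) == 0 or len(ref_idx) == 0:
        raise SelectionError("alignment selection is empty")
    if len(idx) != len(ref_idx):
        raise SelectionError(
            f"selection sizes differ: {len(idx)} (trajectory) vs {len(ref_idx)} (reference)")
    ref_coords = ref.coordinates[ref_idx]
    out = np.empty_like(traj.frames)
    for k, frame in enumerate(traj.frames):
        rot, ref_c = superpose(frame[idx], ref_coords)
        mob_c = frame[idx].mean(axis=0)
        out[k] = rot.apply(frame - mob_c) + ref_c
    return Trajectory(traj.topology, out, traj.frame_interval)


# ---------------------------------------------------------------------------
# Helix endpoints and vectors
# ---------------------------------------------------------------------------

def _segment_residues(structure: Structure, first: int, last: int) -> list[int]:
    seen = []
    for _, num, _ in structure.residues():
        if first <= num <= last and num not in seen:
            seen.append(num)
    return sorted(seen)


def endpoint_atoms(structure: Structure, segment: str, terminus: str,
                   definition: SegmentDefinition,
                   gap: int = ENDPOINT_GAP, window: int = ENDPOINT_WINDOW
                   ) -> HelixEndpoint:
    """Select the 11 endpoint backbone atoms and their mean position.

    At the N terminus: skip ``gap`` residues, take the next ``window`` residues'
    N/CA/C atoms and drop the C atom of the innermost window residue. At the C
    terminus, mirrored: drop the N atom of the innermost window residue.
    """
    ranges = expand_segments(definition)
    if segment in ranges:
        first, last = ranges[segment]
    else:
        first, last = definition.segment_range(segment)
    residues = _segment_residues(structure, first, last)
    if len(residues) < gap + window + 1:
        raise SelectionError(
            f"segment {segment} has {len(residues)} residues; "
            f"≥ {gap + window + 1} needed for endpoint selection")
    if terminus == "N":
        window_res = residues[gap:gap + window]
        innermost = window_res[-1]
        dropped = (innermost, "C")
    elif terminus == "C":
        window_res = residues[-(gap + window):len(residues) - gap]
        innermost = window_res[0]
        dropped = (innermost, "N")
    else:
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")

    atom_set: list[tuple[int, str]] = []
    coords = []
    for res in window_res:
        for name in ENDPOINT_BACKBONE:
            if (res, name) == dropped:
                continue
            try:
                i = structure.find_atom(res, name)
            except Exception as exc:
                raise IncompleteBackboneError(
                    f"segment {segment}: residue {res} lacks backbone atom {name}"
                ) from exc
            atom_set.append((res, name))
            coords.append(structure.atoms[i].position)
    point = np.mean(np.array(coords), axis=0)
    return HelixEndpoint(terminus, tuple(atom_set), point)


def helix_vector(structure: Structure, segment: str,
                 definition: SegmentDefinition) -> HelixVector:
    n_end = endpoint_atoms(structure, segment, "N", definition)
    c_end = endpoint_atoms(structure, segment, "C", definition)
    return HelixVector(segment, n_end.point, c_end.point)


def helix_angle(vector: HelixVector | np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between a helix vector and the +Z membrane normal."""
    if isinstance(vector, HelixVector):
        d = vector.direction
    else:
        d = np.asarray(vector, dtype=float)
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            raise DegenerateVectorError("zero-length direction vector")
        d = d / norm
    return float(np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0))))


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def _backbone_indices(structure: Structure, first: int, last: int,
                      names: Sequence[str] = RMSD_BACKBONE) -> np.ndarray:
    idx = structure.atom_indices(
        lambda a: a.atom_name in names and first <= a.residue_number <= last)
    if len(idx) == 0:
        raise SelectionError(f"no backbone atoms in residues {first}-{last}")
    return idx


def segment_rmsd_nofit(frame: np.ndarray, ref: Structure, segment: str,
                       definition: SegmentDefinition) -> float:
    """No-fit RMSD over a segment's C/CA/O/N atoms (frame already aligned globally)."""
    ranges = expand_segments(definition)
    first, last = ranges[segment] if segment in ranges \
        else definition.segment_range(segment)
    idx = _backbone_indices(ref, first, last)
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (len(ref.atoms), 3):
        raise SelectionError(
            f"frame shape {frame.shape} does not match reference with "
            f"{len(ref.atoms)} atoms")
    diff = frame[idx] - ref.coordinates[idx]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsf(traj: Trajectory,
         selection: Callable[[AtomRecord], bool] | None = None,
         atom_name: str = "CA") -> pd.Series:
    """Per-residue RMSF (Å) about the time-average position, over one atom per residue.

    The trajectory is assumed to be aligned already. Defaults to Cα.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    if selection is None:
        selection = lambda a: a.atom_name == atom_name  # noqa: E731
    idx = traj.topology.atom_indices(selection)
    if len(idx) == 0:
        raise SelectionError("RMSF selection is empty")
    coords = traj.frames[:, idx, :]             # (F, M, 3)
    mean = coords.mean(axis=0)                  # (M, 3)
    dev = coords - mean
    values = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    labels = [traj.topology.atoms[i].residue_number for i in idx]
    return pd.Series(values, index=pd.Index(labels, name="residue"), name="rmsf_A")


# ---------------------------------------------------------------------------
# Per-frame angle/RMSD series
# ---------------------------------------------------------------------------

def angle_rmsd_series(traj: Trajectory, ref: Structure,
                      definition: SegmentDefinition) -> pd.DataFrame:
    """One (angle, no-fit RMSD) sample per frame per helix segment.

    Pivoted helices contribute their two compartments (e.g. TM6-1, TM6-2)
    instead of the parent segment. Returns a tidy frame with columns
    ``frame, segment, angle_deg, rmsd_A``; per-segment means are available via
    :func:`angle_rmsd_means`.
    """
    expanded = expand_segments(definition)
    helix_names = [n for n in expanded
                   if n.upper().startswith("TM") or n.upper().startswith("H8")]
    sub_def = SegmentDefinition(segments=dict(expanded))
    rows = []
    for k in range(traj.n_frames):
        frame_struct = traj.frame_structure(k)
        for name in helix_names:
            vec = helix_vector(frame_struct, name, sub_def)
            angle = helix_angle(vec)
            rmsd = segment_rmsd_nofit(traj.frames[k], ref, name, sub_def)
            rows.append((k, name, angle, rmsd))
    return pd.DataFrame(rows, columns=["frame", "segment", "angle_deg", "rmsd_A"])


def angle_rmsd_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-segment mean angle and RMSD (the marked 'average point' per helix)."""
    return (samples.groupby("segment", sort=True)[["angle_deg", "rmsd_A"]]
            .mean().reset_index())
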