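"""Interaction-energy networks and geometric contact detection.

Aggregates residue-pairwise energy matrices into residue-wise profiles and
helix/loop group matrices, differences wildtype against mutant systems, selects
residues most affected by a mutation, and detects hydrogen bonds and salt
bridges over trajectories by standard geometric criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import logging

import numpy as np
import pandas as pd

from .energetics import AveragedMatrix
from .errors import ConfigError, MatrixAlignmentError, TypingError
from .structure import SegmentDefinition, Structure, Trajectory, expand_segments

logger = logging.getLogger(__name__)

#: default per-residue |Δ energy| threshold (kcal/mol) for significance ranking
DEFAULT_SIGNIFICANCE_THRESHOLD = 1.0


# ---------------------------------------------------------------------------
# Residue-wise profiles and group matrices
# ---------------------------------------------------------------------------

@dataclass
class ResidueEnergyProfile:
    """Per-residue interaction energy: the sum of unmasked pairwise partners."""

    residues: list[tuple[str, int]]
    energy: np.ndarray

    def as_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.residues, names=["chain", "residue"])
        return pd.Series(self.energy, index=idx, name="energy_kcal_mol")


def residue_wise(matrix: AveragedMatrix) -> ResidueEnergyProfile:
    """Sum each residue's unmasked pairwise interactions (diagonal excluded)."""
    values = np.where(matrix.mask, 0.0, matrix.mean)
    np.fill_diagonal(values, 0.0)
    return ResidueEnergyProfile(list(matrix.residues), values.sum(axis=1))


@dataclass
class GroupMatrix:
    """Helix/loop-level aggregated energies (symmetric, kcal/mol)."""

    groups: list[str]
    energy: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.energy, index=self.groups, columns=self.groups)

    def total(self) -> float:
        iu = np.triu_indices(len(self.groups))
        return float(self.energy[iu].sum())


def assign_groups(residues: Sequence[tuple[str, int]],
                  definition: SegmentDefinition) -> list[str]:
    """Group name for each residue; pivoted helices split into compartments.

    Residues matching no defined segment collect into ``"other"`` (logged).
    """
    expanded = expand_segments(definition)
    names = list(expanded)
    out = []
    unassigned = 0
    for _, num in residues:
        hits = [n for n in names if expanded[n][0] <= num <= expanded[n][1]]
        if len(hits) > 1:
            raise ConfigError(f"residue {num} falls in overlapping groups {hits}")
        if hits:
            out.append(hits[0])
        else:
            out.append("other")
            unassigned += 1
    if unassigned:
        logger.info("%d residues assigned to group 'other'", unassigned)
    return out


def group_matrix(matrix: AveragedMatrix,
                 definition: SegmentDefinition) -> GroupMatrix:
    """Sum unmasked pair energies between (and within) helix/loop groups."""
    labels = assign_groups(matrix.residues, definition)
    groups = list(dict.fromkeys(expand_segments(definition)))
    if "other" in labels:
        groups.append("other")
    gindex = {g: k for k, g in enumerate(groups)}
    ng = len(groups)
    energy = np.zeros((ng, ng))
    n = len(matrix.residues)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.mask[i, j]:
                continue
            a, b = gindex[labels[i]], gindex[labels[j]]
            energy[a, b] += matrix.mean[i, j]
            if a != b:
                energy[b, a] += matrix.mean[i, j]
    return GroupMatrix(groups, energy)


# ---------------------------------------------------------------------------
# Wildtype vs mutant difference networks
# ---------------------------------------------------------------------------

def classify_change(wt_value: float, delta: float, tol: float = 1e-12) -> str:
    """Sign classification of a pairwise change ΔE = E_mut − E_wt."""
    if abs(delta) <= tol:
        return "unchanged"
    if wt_value < 0 and delta > 0:
        return "attractive-lost"
    if wt_value < 0 and delta < 0:
        return "attractive-gained"
    if wt_value >= 0 and delta > 0:
        return "repulsive-gained"
    return "repulsive-lost"


@dataclass
class DiffNetwork:
    """Per-pair energetic change after mutation, with replicate dispersion."""

    residues: list[tuple[str, int]]
    delta: np.ndarray            # E_mut − E_wt
    sem: np.ndarray              # quadrature-combined replicate sem
    mask: np.ndarray
    wt_mean: np.ndarray | None = None
    mutated_residues: list[tuple[str, int]] = field(default_factory=list)

    def pairs(self, threshold: float = 0.0) -> pd.DataFrame:
        """Tidy per-pair table of unmasked changes with |Δ| ≥ threshold."""
        rows = []
        n = len(self.residues)
        for i in range(n):
            for j in range(i + 1, n):
                if self.mask[i, j] or abs(self.delta[i, j]) < threshold:
                    continue
                wt = self.wt_mean[i, j] if self.wt_mean is not None else 0.0
                rows.append({
                    "chain_i": self.residues[i][0], "res_i": self.residues[i][1],
                    "chain_j": self.residues[j][0], "res_j": self.residues[j][1],
                    "delta_kcal_mol": self.delta[i, j],
                    "sem_kcal_mol": self.sem[i, j],
                    "class": classify_change(wt, self.delta[i, j]),
                    "mutated": (self.residues[i] in self.mutated_residues
                                or self.residues[j] in self.mutated_residues),
                })
        return pd.DataFrame(rows, columns=[
            "chain_i", "res_i", "chain_j", "res_j", "delta_kcal_mol",
            "sem_kcal_mol", "class", "mutated"])


def diff_network(wt: AveragedMatrix, mut: AveragedMatrix,
                 mutated_residues: Iterable[tuple[str, int]] = ()
                 ) -> DiffNetwork:
    """ΔE = E_mut − E_wt per residue pair, matched by (chain, residue number).

    Mutated residues keep their numbers (F→A, W→A), so the residue universes
    must coincide; their entries are flagged, not excluded.
    """
    if wt.residues != mut.residues:
        raise MatrixAlignmentError(
            "wildtype and mutant matrices cover different residue sets")
    if not np.array_equal(wt.mask, mut.mask):
        raise MatrixAlignmentError("wildtype and mutant masks differ")
    delta = mut.mean - wt.mean
    sem = np.sqrt(wt.sem**2 + mut.sem**2)
    return DiffNetwork(list(wt.residues), delta, sem, wt.mask.copy(),
                       wt_mean=wt.mean.copy(),
                       mutated_residues=list(mutated_residues))


def significant_residues(wt: ResidueEnergyProfile, mut: ResidueEnergyProfile,
                         threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
                         ) -> pd.DataFrame:
    """Residues whose residue-wise energy changes by ≥ threshold, ranked by |Δ|."""
    if wt.residues != mut.residues:
        raise MatrixAlignmentError("profiles cover different residue sets")
    delta = mut.energy - wt.energy
    df = pd.DataFrame({
        "chain": [c for c, _ in wt.residues],
        "residue": [r for _, r in wt.residues],
        "wt_kcal_mol": wt.energy,
        "mut_kcal_mol": mut.energy,
        "delta_kcal_mol": delta,
    })
    df = df[np.abs(df["delta_kcal_mol"]) >= threshold].copy()
    df["abs_delta"] = df["delta_kcal_mol"].abs()
    df = df.sort_values(["abs_delta", "residue"], ascending=[False, True])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="abs_delta").reset_index(drop=True)


def common_significant(first: pd.DataFrame, second: pd.DataFrame) -> list[int]:
    """Residue numbers significant in both conditions (e.g. both activation states)."""
    return sorted(set(first["residue"]) & set(second["residue"]))


# ---------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactCriteria:
    """Geometric contact criteria (Å, degrees)."""

    hbond_distance_max: float = 3.5   # donor–acceptor heavy atoms
    hbond_angle_min: float = 120.0    # D–H···A angle
    saltbridge_distance_max: float = 4.0


@dataclass
class ContactRecord:
    kind: str                       # "hbond" or "saltbridge"
    donor: tuple[str, int, str]     # (chain, residue, atom) — cation for salt bridges
    acceptor: tuple[str, int, str]  # anion for salt bridges
    distance: float                 # mean over qualifying frames, Å
    occupancy: float                # fraction of frames qualifying
    angle: float | None = None      # mean D–H···A over qualifying frames

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


#: donor heavy atoms (with the hydrogens that may sit on them) per residue type
HBOND_DONORS: dict[tuple[str, str], tuple[str, ...]] = {
    ("*", "N"): ("H", "HN"),
    ("SER", "OG"): ("HG", "HG1"),
    ("THR", "OG1"): ("HG1",),
    ("TYR", "OH"): ("HH",),
    ("LYS", "NZ"): ("HZ1", "HZ2", "HZ3"),
    ("ARG", "NE"): ("HE",),
    ("ARG", "NH1"): ("HH11", "HH12"),
    ("ARG", "NH2"): ("HH21", "HH22"),
    ("ASN", "ND2"): ("HD21", "HD22"),
    ("GLN", "NE2"): ("HE21", "HE22"),
    ("HIS", "ND1"): ("HD1",),
    ("HIS", "NE2"): ("HE2",),
    ("TRP", "NE1"): ("HE1",),
}

#: acceptor heavy atoms per residue type
HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

#: charged side-chain groups: residue → (atoms, sign)
CHARGED_GROUPS: dict[str, tuple[tuple[str, ...], int]] = {
    "ASP": (("OD1", "OD2"), -1),
    "GLU": (("OE1", "OE2"), -1),
    "LYS": (("NZ",), +1),
    "ARG": (("NE", "NH1", "NH2"), +1),
}


def _as_trajectory(traj: Trajectory | Structure) -> Trajectory:
    if isinstance(traj, Structure):
        return Trajectory(traj, traj.coordinates[None, :, :])
    return traj


def _donor_sites(structure: Structure):
    sites = []  # (atom_index, hydrogen_indices)
    by_res: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        by_res.setdefault(a.residue_id, {})[a.atom_name] = i
    for i, a in enumerate(structure.atoms):
        for key in ((a.residue_name, a.atom_name), ("*", a.atom_name)):
            if key in HBOND_DONORS:
                hyd = [by_res[a.residue_id][h] for h in HBOND_DONORS[key]
                       if h in by_res[a.residue_id]]
                sites.append((i, hyd))
                break
    return sites


def _acceptor_sites(structure: Structure) -> list[int]:
    out = []
    for i, a in enumerate(structure.atoms):
        names = HBOND_ACCEPTORS.get(a.residue_name, ()) + HBOND_ACCEPTORS["*"]
        if a.atom_name in names:
            out.append(i)
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the a–b–c triple."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(traj: Trajectory | Structure,
                  candidates: Iterable[tuple[int, int]] | None = None,
                  criteria: ContactCriteria = ContactCriteria()
                  ) -> list[ContactRecord]:
    """Detect hydrogen bonds over a trajectory by distance (and angle) criteria.

    A frame qualifies when the donor–acceptor heavy-atom distance is within
    ``hbond_distance_max`` and, if the donor carries hydrogens in the topology,
    the best D–H···A angle is at least ``hbond_angle_min``. Structures without
    hydrogens are evaluated in distance-only mode (logged once). ``candidates``
    optionally restricts the search to residue-number pairs.
    """
    traj = _as_trajectory(traj)
    top = traj.topology
    donors = _donor_sites(top)
    acceptors = _acceptor_sites(top)
    if not donors or not acceptors:
        raise TypingError("no donor/acceptor typing available for this structure")
    cand = {tuple(sorted(p)) for p in candidates} if candidates is not None else None
    if all(not hyd for _, hyd in donors):
        logger.info("no hydrogens present: hydrogen bonds evaluated by distance only")

    records = []
    for d_idx, hyd in donors:
        d_atom = top.atoms[d_idx]
        for a_idx in acceptors:
            a_atom = top.atoms[a_idx]
            if d_atom.residue_id == a_atom.residue_id:
                continue
            if cand is not None and tuple(sorted(
                    (d_atom.residue_number, a_atom.residue_number))) not in cand:
                continue
            dists, angles, hits = [], [], 0
            for frame in traj.frames:
                r = float(np.linalg.norm(frame[d_idx] - frame[a_idx]))
                if r > criteria.hbond_distance_max:
                    continue
                if hyd:
                    best = max(_angle_deg(frame[d_idx], frame[h], frame[a_idx])
                               for h in hyd)
                    if best < criteria.hbond_angle_min:
                        continue
                    angles.append(best)
                hits += 1
                dists.append(r)
            if hits:
                records.append(ContactRecord(
                    kind="hbond",
                    donor=(d_atom.chain_id, d_atom.residue_number, d_atom.atom_name),
                    acceptor=(a_atom.chain_id, a_atom.residue_number, a_atom.atom_name),
                    distance=float(np.mean(dists)),
                    occupancy=hits / traj.n_frames,
                    angle=float(np.mean(angles)) if angles else None,
                ))
    return records


def detect_salt_bridges(traj: Trajectory | Structure,
                        criteria: ContactCriteria = ContactCriteria()
                        ) -> list[ContactRecord]:
    """Detect salt bridges: opposite-charge side-chain groups within the cutoff.

    The contact distance is the minimum over the two groups' heavy atoms;
    same-sign pairs are never reported.
    """
    traj = _as_trajectory(traj)
    top = traj.topology
    groups = []  # (residue_id, sign, atom indices)
    by_res: dict[tuple[str, int], dict[str, int]] = {}
    resnames: dict[tuple[str, int], str] = {}
    for i, a in enumerate(top.atoms):
        by_res.setdefault(a.residue_id, {})[a.atom_name] = i
        resnames[a.residue_id] = a.residue_name
    for rid, atoms in by_res.items():
        entry = CHARGED_GROUPS.get(resnames[rid])
        if entry is None:
            continue
        names, sign = entry
        idx = [atoms[n] for n in names if n in atoms]
        if idx:
            groups.append((rid, sign, idx))
    if not groups:
        raise TypingError("no charged side-chain groups in this structure")

    records = []
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            rid_i, sign_i, idx_i = groups[gi]
            rid_j, sign_j, idx_j = groups[gj]
            if sign_i * sign_j >= 0:
                continue
            dists, hits = [], 0
            min_i = min_j = None
            for frame in traj.frames:
                d = np.linalg.norm(frame[idx_i][:, None, :] - frame[idx_j][None, :, :],
                                   axis=2)
                r = float(d.min())
                if r <= criteria.saltbridge_distance_max:
                    hits += 1
                    dists.append(r)
                    ii, jj = np.unravel_index(np.argmin(d), d.shape)
                    min_i, min_j = idx_i[ii], idx_j[jj]
            if hits:
                cation, anion = (gi, gj) if sign_i > 0 else (gj, gi)
                cat_rid = groups[cation][0]
                an_rid = groups[anion][0]
                cat_atom = top.atoms[min_i if sign_i > 0 else min_j]
                an_atom = top.atoms[min_j if sign_i > 0 else min_i]
                records.append(ContactRecord(
                    kind="saltbridge",
                    donor=(cat_rid[0], cat_rid[1], cat_atom.atom_name),
                    acceptor=(an_rid[0], an_rid[1], an_atom.atom_name),
                    distance=float(np.mean(dists)),
                    occupancy=hits / traj.n_frames,
                ))
    return records


def contacts_frame(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """Tidy table of contact records."""
    rows = [{
        "kind": r.kind,
        "donor_chain": r.donor[0], "donor_res": r.donor[1], "donor_atom": r.donor[2],
        "acceptor_chain": r.acceptor[0], "acceptor_res": r.acceptor[1],
        "acceptor_atom": r.acceptor[2],
        "mean_distance_A": r.distance,
        "mean_angle_deg": r.angle if r.angle is not None else np.nan,
        "occupancy": r.occupancy,
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "kind", "donor_chain", "donor_res", "donor_atom", "acceptor_chain",
        "acceptor_res", "acceptor_atom", "mean_distance_A", "mean_angle_deg",
        "occupancy"])
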