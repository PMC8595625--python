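"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: ideal α-helices at
prescribed tilt/azimuth, a 7TM-like bundle with a matching segment definition,
noisy trajectories with optional scheduled rigid segment motions, paired
wildtype/mutant pairwise-energy replicate matrices with planted differences,
and minimal hydrogen-bond / salt-bridge geometries.

"Tilt" is defined operationally: the generator measures the endpoint-rule axis
of the raw untilted helix and rigid-body aligns that axis to +Z before applying
the requested (tilt, azimuth) rotation, so the planted tilt is exactly what the
geometry stage measures on the noise-free structure. Backbone atoms sit on a
canonical screw (1.5 Å rise, 100°/residue by default) with fixed cylindrical
offsets per atom type; side chains carry only a C-beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .energetics import AveragedMatrix, PairwiseEnergyMatrix
from .errors import GeometryError, ParameterError
from .geometry import helix_vector
from .network import DiffNetwork
from .structure import (
    ONE_TO_THREE,
    AtomRecord,
    SegmentDefinition,
    Structure,
    Trajectory,
    expand_segments,
)

# cylindrical placement (radius Å, phase deg, z Å) per backbone atom, relative
# to CA of the same residue, for the default 2.3 Å CA radius
_ATOM_CYL = {
    "N": (1.50, -25.5, -0.94),
    "CA": (2.30, 0.0, 0.00),
    "C": (1.66, 21.0, 1.09),
    "O": (2.03, 21.0, 2.26),   # carbonyl O points toward the C terminus
    "CB": (3.30, -5.0, -0.75),
}


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of one ideal helix."""

    n_residues: int = 20
    rise: float = 1.5           # Å per residue
    twist: float = 100.0        # degrees per residue
    radius: float = 2.3         # CA radius, Å
    tilt: float = 0.0           # degrees from the membrane normal (+Z)
    azimuth: float = 0.0        # degrees about Z
    sequence: str = ""          # 1-letter codes; default poly-Ala
    first_residue: int = 1
    chain_id: str = "A"

    def __post_init__(self):
        if self.n_residues < 6:
            raise ParameterError("a helix needs ≥ 6 residues for endpoint selection")
        if not (0.0 <= self.tilt <= 180.0):
            raise ParameterError(f"tilt {self.tilt} outside [0, 180]")
        if self.sequence and len(self.sequence) != self.n_residues:
            raise ParameterError("sequence length must equal n_residues")

    def residue_names(self) -> list[str]:
        seq = self.sequence or "A" * self.n_residues
        try:
            return [ONE_TO_THREE[c.upper()] for c in seq]
        except KeyError as exc:
            raise ParameterError(f"unknown 1-letter code in sequence: {exc}") from exc


def _raw_helix_coords(spec: HelixSpec) -> dict[str, np.ndarray]:
    """Backbone coordinates on the canonical screw along +Z, per atom name."""
    out = {}
    rscale = spec.radius / 2.3
    zscale = spec.rise / 1.5
    for name, (r0, phi0, z0) in _ATOM_CYL.items():
        i = np.arange(spec.n_residues)
        phi = np.radians(i * spec.twist + phi0)
        r = r0 * rscale
        z = i * spec.rise + z0 * zscale
        out[name] = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return out


def make_ideal_helix(spec: HelixSpec = HelixSpec(), seed: int | None = None,
                     origin: np.ndarray | None = None) -> Structure:
    """Build an ideal α-helix at the requested tilt and azimuth.

    Deterministic (the seed argument is accepted for interface symmetry with
    the stochastic generators but is unused — the geometry has no randomness).
    """
    coords = _raw_helix_coords(spec)
    names = spec.residue_names()

    # assemble untilted structure to measure its endpoint-rule axis
    def assemble(transform=None) -> Structure:
        atoms = []
        for i, resname in enumerate(names):
            resnum = spec.first_residue + i
            for atom_name in ("N", "CA", "C", "O", "CB"):
                if atom_name == "CB" and resname == "GLY":
                    continue
                pos = coords[atom_name][i]
                if transform is not None:
                    pos = transform(pos)
                atoms.append(AtomRecord(atom_name, resnum, resname,
                                        spec.chain_id, pos,
                                        element=atom_name[0]))
        return Structure(atoms, label="ideal-helix")

    raw = assemble()
    segdef = SegmentDefinition(segments={
        "TM1": (spec.first_residue, spec.first_residue + spec.n_residues - 1)})
    vec = helix_vector(raw, "TM1", segdef)
    axis = vec.direction
    mid = 0.5 * (vec.n_point + vec.c_point)

    # align the measured axis to +Z, then rotate to (tilt, azimuth)
    calib, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), axis[None, :])
    tilt_rot = (Rotation.from_euler("z", spec.azimuth, degrees=True)
                * Rotation.from_euler("y", spec.tilt, degrees=True))
    shift = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    def transform(pos):
        return tilt_rot.apply(calib.apply(pos - mid)) + shift

    return assemble(transform)


def make_bundle(specs: list[HelixSpec] | None = None,
                n_helices: int = 7,
                bundle_radius: float = 14.0,
                loops: bool = True,
                loop_length: int = 4,
                clash_tolerance: float = 1.5,
                pivot_helices: tuple[int, ...] = (6, 7),
                ) -> tuple[Structure, SegmentDefinition, dict[str, float]]:
    """Arrange helices on a circle with alternating N→C direction.

    Returns the structure, a matching segment definition (TM ranges, optional
    pivots at the midpoint of ``pivot_helices``, midpoint x.50 BW anchors, and
    loop segments when connectors are generated) and the planted per-segment
    tilt angles (degrees from +Z, as measured by the endpoint rule).
    """
    if specs is None:
        specs = [HelixSpec(n_residues=22) for _ in range(n_helices)]
    if len(specs) < 2:
        raise ParameterError("a bundle needs at least 2 helices")
    n = len(specs)

    # residue numbering: helix h, then (optionally) the loop connecting it to h+1
    segments: dict[str, tuple[int, int]] = {}
    pivots: dict[str, int] = {}
    anchors: dict[int, tuple[int, int]] = {}
    truth: dict[str, float] = {}
    helix_first: list[int] = []
    loop_first: list[int] = []
    next_residue = 1
    for h, spec in enumerate(specs):
        helix_first.append(next_residue)
        first, last = next_residue, next_residue + spec.n_residues - 1
        name = f"TM{h + 1}"
        segments[name] = (first, last)
        mid_res = (first + last) // 2
        anchors[h + 1] = (50, mid_res)
        if (h + 1) in pivot_helices and spec.n_residues >= 14:
            pivots[name] = mid_res
        next_residue = last + 1
        if loops and h < n - 1:
            loop_first.append(next_residue)
            loop_name = f"ICL{h//2 + 1}" if h % 2 == 0 else f"ECL{(h + 1)//2}"
            segments[loop_name] = (next_residue, next_residue + loop_length - 1)
            next_residue += loop_length

    # place helices
    helix_blocks: list[list[AtomRecord]] = []
    for h, spec in enumerate(specs):
        # odd-index helices run C→N relative to the membrane normal
        eff_tilt = spec.tilt if h % 2 == 0 else 180.0 - spec.tilt
        angle = 2 * math.pi * h / n
        origin = np.array([bundle_radius * math.cos(angle),
                           bundle_radius * math.sin(angle), 0.0])
        placed = make_ideal_helix(
            HelixSpec(n_residues=spec.n_residues, rise=spec.rise,
                      twist=spec.twist, radius=spec.radius, tilt=eff_tilt,
                      azimuth=spec.azimuth, sequence=spec.sequence,
                      first_residue=helix_first[h], chain_id=spec.chain_id),
            origin=origin)
        truth[f"TM{h + 1}"] = eff_tilt
        helix_blocks.append(list(placed.atoms))

    # place loop connectors between consecutive helices
    loop_blocks: list[list[AtomRecord]] = []
    if loops:
        for h in range(n - 1):
            start = helix_blocks[h][-1].position
            end = helix_blocks[h + 1][0].position
            axis = end - start
            axis = axis / np.linalg.norm(axis)
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(axis, [1.0, 0.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            block: list[AtomRecord] = []
            for k in range(loop_length):
                t = (k + 1) / (loop_length + 1)
                base = start + t * (end - start)
                # push connectors outward so they never thread the bundle,
                # zig-zag so consecutive residues cannot touch
                radial = base[:2]
                norm = np.linalg.norm(radial)
                if norm > 1e-6:
                    base = base + np.array([*(radial / norm * 4.0), 0.0])
                base = base + ((-1) ** k) * 0.9 * perp
                resnum = loop_first[h] + k
                chain = specs[h].chain_id
                for offs, atom_name in zip((-0.9, 0.0, 0.9), ("N", "CA", "C")):
                    block.append(AtomRecord(atom_name, resnum, "GLY", chain,
                                            base + offs * axis,
                                            element=atom_name[0]))
                block.append(AtomRecord("O", resnum, "GLY", chain,
                                        base + 0.9 * axis + 1.23 * perp,
                                        element="O"))
            loop_blocks.append(block)

    all_atoms: list[AtomRecord] = []
    for h in range(n):
        all_atoms.extend(helix_blocks[h])
        if loops and h < n - 1:
            all_atoms.extend(loop_blocks[h])
    structure = Structure(all_atoms, label="synthetic-7tm-bundle")

    # clash guard between distinct helices
    coords_by_seg = {f"TM{h + 1}": np.array([a.position for a in helix_blocks[h]])
                     for h in range(n)}
    names_tm = list(coords_by_seg)
    for i in range(len(names_tm)):
        for j in range(i + 1, len(names_tm)):
            a, b = coords_by_seg[names_tm[i]], coords_by_seg[names_tm[j]]
            d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)).min()
            if d <= clash_tolerance:
                raise GeometryError(
                    f"helices {names_tm[i]} and {names_tm[j]} clash: "
                    f"min distance {d:.2f} Å")
    # global guard: no near-overlapping atom pair anywhere (loops included)
    coords = structure.coordinates
    dists = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 0.5:
        raise GeometryError(f"bundle placement clash: min distance {dists.min():.2f} Å")

    definition = SegmentDefinition(segments=segments, pivots=pivots,
                                   bw_anchors=anchors)
    # planted tilts for split compartments equal the parent's (rigid helix)
    for name, pivot in pivots.items():
        truth[f"{name}-1"] = truth[name]
        truth[f"{name}-2"] = truth[name]
    return structure, definition, truth


@dataclass(frozen=True)
class SegmentMotion:
    """Scheduled rigid-body motion of one named segment."""

    segment: str
    start_frame: int
    tilt_deg: float = 0.0       # rotation about X through the segment centroid
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)


def make_noisy_trajectory(structure: Structure, sigma: float, n_frames: int,
                          seed: int, rigid_motions: list[SegmentMotion] | None = None,
                          definition: SegmentDefinition | None = None,
                          frame_interval: float | None = None) -> Trajectory:
    """Frames = structure + i.i.d. Gaussian coordinate noise (+ scheduled motions)."""
    if sigma < 0:
        raise ParameterError("sigma must be ≥ 0")
    rng = np.random.default_rng(seed)
    base = structure.coordinates
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if rigid_motions:
        if definition is None:
            raise ParameterError("rigid motions need a segment definition")
        ranges = expand_segments(definition)
        for motion in rigid_motions:
            first, last = ranges[motion.segment] if motion.segment in ranges \
                else definition.segment_range(motion.segment)
            idx = structure.atom_indices(
                lambda a, f=first, l=last: f <= a.residue_number <= l)
            centroid = base[idx].mean(axis=0)
            rot = Rotation.from_euler("x", motion.tilt_deg, degrees=True)
            moved = rot.apply(base[idx] - centroid) + centroid + np.asarray(motion.shift)
            frames[motion.start_frame:, idx, :] = moved
    if sigma > 0:
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)
    return Trajectory(structure, frames, frame_interval)


# ---------------------------------------------------------------------------
# Planted wildtype/mutant energy systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEnergySpec:
    """Ground-truth specification for paired wildtype/mutant energy matrices."""

    groups: tuple[tuple[str, int], ...] = (("TM1", 5), ("TM2", 5), ("TM3", 5))
    baseline_pairs: tuple[tuple[int, int, float], ...] = ()
    mutant_deltas: tuple[tuple[int, int, float], ...] = ()
    replicate_noise_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicate_noise_sd < 0:
            raise ParameterError("noise sd must be ≥ 0")
        n = self.n_residues
        for i, j, _ in tuple(self.baseline_pairs) + tuple(self.mutant_deltas):
            if not (1 <= i <= n and 1 <= j <= n) or i == j:
                raise ParameterError(f"pair ({i},{j}) references missing residues")

    @property
    def n_residues(self) -> int:
        return sum(size for _, size in self.groups)

    def segment_definition(self) -> SegmentDefinition:
        segments = {}
        start = 1
        for name, size in self.groups:
            segments[name] = (start, start + size - 1)
            start += size
        return SegmentDefinition(segments=segments)


def make_planted_energy_system(spec: PlantedEnergySpec
                               ) -> tuple[list[PairwiseEnergyMatrix],
                                          list[PairwiseEnergyMatrix],
                                          DiffNetwork]:
    """Replicate wildtype/mutant matrices with exact planted differences.

    Replicates are baseline (+ mutant deltas) plus symmetric Gaussian noise on
    every off-diagonal entry; the returned truth records the exact planted Δ.
    """
    n = spec.n_residues
    residues = [("A", i) for i in range(1, n + 1)]
    baseline = np.zeros((n, n))
    for i, j, e in spec.baseline_pairs:
        baseline[i - 1, j - 1] = baseline[j - 1, i - 1] = e
    delta = np.zeros((n, n))
    for i, j, d in spec.mutant_deltas:
        delta[i - 1, j - 1] = delta[j - 1, i - 1] = d

    rng = np.random.default_rng(spec.seed)
    mask = np.eye(n, dtype=bool)

    def replicate(mean: np.ndarray) -> PairwiseEnergyMatrix:
        noise = rng.normal(0.0, spec.replicate_noise_sd, size=(n, n))
        noise = np.triu(noise, k=1)
        noise = noise + noise.T
        values = mean + noise
        return PairwiseEnergyMatrix(
            list(residues), values, np.zeros((n, n)), np.zeros((n, n)),
            mask.copy(), {"synthetic": True})

    wt = [replicate(baseline) for _ in range(spec.n_replicates)]
    mut = [replicate(baseline + delta) for _ in range(spec.n_replicates)]
    truth = DiffNetwork(list(residues), delta.copy(), np.zeros((n, n)),
                        mask.copy(), wt_mean=baseline.copy())
    return wt, mut, truth


# ---------------------------------------------------------------------------
# Contact fixtures
# ---------------------------------------------------------------------------

def _hydrogen_position(distance: float, angle: float) -> np.ndarray:
    """Place H at 0.96 Å from the donor so the D–H···A angle is as requested.

    Donor at the origin, acceptor at (distance, 0, 0); solved in the XY plane.
    """
    bond = 0.96
    target = math.radians(angle)
    if distance <= bond:
        raise ParameterError(
            f"donor–acceptor distance {distance} Å must exceed the D–H bond ({bond} Å)")
    if not (0.0 < angle <= 180.0):
        raise ParameterError(f"D–H···A angle {angle}° outside (0, 180]")

    def angle_at_h(alpha: float) -> float:
        h = np.array([bond * math.cos(alpha), bond * math.sin(alpha), 0.0])
        u = -h
        v = np.array([distance, 0.0, 0.0]) - h
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.acos(max(-1.0, min(1.0, c))) - target

    # alpha=0 puts H on the D–A axis (angle 180°); alpha→pi sends the angle to 0
    if abs(angle - 180.0) < 1e-12:
        alpha = 0.0
    else:
        alpha = brentq(angle_at_h, 0.0, math.pi * (1 - 1e-9))
    return np.array([bond * math.cos(alpha), bond * math.sin(alpha), 0.0])


def make_contact_fixture(kind: str, distance: float,
                         angle: float = 165.0) -> Structure:
    """Minimal two-residue geometry realizing a contact distance (and angle).

    ``hbond``: a Ser OG–HG donor facing a Gly backbone carbonyl O at exactly
    the requested O(G)···O distance and D–H···A angle. ``saltbridge``: a Lys
    NZ facing an Asp carboxylate with the closest O at exactly the requested
    distance.
    """
    if distance <= 0:
        raise ParameterError("distance must be positive")
    if kind == "hbond":
        acceptor = [
            AtomRecord("N", 1, "GLY", "A", (-2.4, -1.0, 0.0), "N"),
            AtomRecord("CA", 1, "GLY", "A", (-1.5, -2.0, 0.0), "C"),
            AtomRecord("C", 1, "GLY", "A", (0.0, -1.33, 0.0), "C"),
            AtomRecord("O", 1, "GLY", "A", (0.0, 0.0, 0.0), "O"),
        ]
        og = np.array([distance, 0.0, 0.0])
        # solved in a donor-at-origin frame with the acceptor at +x; here the
        # acceptor sits at −x from the donor, so mirror the x component
        hg = og + _hydrogen_position(distance, angle) * np.array([-1.0, 1.0, 1.0])
        away = np.array([1.0, 0.4, 0.0]) / np.linalg.norm([1.0, 0.4, 0.0])
        cb = og + 1.43 * away
        ca = cb + 1.53 * away
        donor = [
            AtomRecord("N", 2, "SER", "A", ca + np.array([1.2, -0.9, 0.0]), "N"),
            AtomRecord("CA", 2, "SER", "A", ca, "C"),
            AtomRecord("C", 2, "SER", "A", ca + np.array([1.1, 1.1, 0.0]), "C"),
            AtomRecord("O", 2, "SER", "A", ca + np.array([1.1, 1.1, 1.23]), "O"),
            AtomRecord("CB", 2, "SER", "A", cb, "C"),
            AtomRecord("OG", 2, "SER", "A", og, "O"),
            AtomRecord("HG", 2, "SER", "A", hg, "H"),
        ]
        return Structure(acceptor + donor, label=f"hbond-{distance:.2f}A")
    if kind == "saltbridge":
        asp = [
            AtomRecord("N", 1, "ASP", "A", (-4.6, -1.0, 0.0), "N"),
            AtomRecord("CA", 1, "ASP", "A", (-3.6, -1.8, 0.0), "C"),
            AtomRecord("C", 1, "ASP", "A", (-4.0, -3.2, 0.0), "C"),
            AtomRecord("O", 1, "ASP", "A", (-5.2, -3.5, 0.0), "O"),
            AtomRecord("CB", 1, "ASP", "A", (-2.2, -1.3, 0.0), "C"),
            AtomRecord("CG", 1, "ASP", "A", (-1.2, -0.6, 0.0), "C"),
            AtomRecord("OD1", 1, "ASP", "A", (0.0, 0.0, 0.0), "O"),
            AtomRecord("OD2", 1, "ASP", "A", (-1.4, 0.6, 0.0), "O"),
        ]
        nz = np.array([distance, 0.0, 0.0])
        away = np.array([1.0, 0.3, 0.0]) / np.linalg.norm([1.0, 0.3, 0.0])
        ce = nz + 1.48 * away
        lys = [
            AtomRecord("N", 2, "LYS", "A", ce + np.array([3.0, -1.0, 0.0]), "N"),
            AtomRecord("CA", 2, "LYS", "A", ce + np.array([2.6, 0.4, 0.0]), "C"),
            AtomRecord("C", 2, "LYS", "A", ce + np.array([3.6, 1.5, 0.0]), "C"),
            AtomRecord("O", 2, "LYS", "A", ce + np.array([3.6, 1.5, 1.23]), "O"),
            AtomRecord("CB", 2, "LYS", "A", ce + np.array([1.3, 0.6, 0.0]), "C"),
            AtomRecord("CE", 2, "LYS", "A", ce, "C"),
            AtomRecord("NZ", 2, "LYS", "A", nz, "N"),
        ]
        return Structure(asp + lys, label=f"saltbridge-{distance:.2f}A")
    raise ParameterError(f"unknown contact kind {kind!r}")
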