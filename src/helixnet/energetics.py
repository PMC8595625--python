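"""Residue-pairwise interaction energies: Coulomb + Lennard-Jones + generalized Born.

The decomposition follows the MM-GBSA convention: for residues I ≠ J,

    E(I,J) = Σ_{i∈I, j∈J} [ k q_i q_j / r_ij  +  LJ(r_ij)  +  GB_cross(i,j) ]

with the GB cross term the (i,j) element of the standard pairwise GB double sum,

    GB_cross(i,j) = − k (1/ε_in − exp(−κ f_ij)/ε_out) q_i q_j / f_ij,
    f_ij = sqrt(r_ij² + R_i R_j exp(−r_ij² / (4 R_i R_j))),

where R are OBC-II effective Born radii from pairwise HCT descreening. Residue
self-energies (intra-residue pairs plus atomic Born self terms) live on the
matrix diagonal, never mixed into off-diagonal entries. Helical i..i+4
neighbours are removed by a residue-level mask, mirroring how backbone
hydrogen-bonded neighbours dominate short-range helical contacts.

The nonpolar (SASA) solvation term is not pairwise-decomposable in this sense
and is omitted; this is recorded in matrix metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants

from .errors import FormatError, GeometryError, MatrixAlignmentError, ParameterError
from .params import AtomParams, ParamTable
from .structure import Structure

logger = logging.getLogger(__name__)

#: Coulomb constant in kcal·Å / (mol·e²)
COULOMB_KCAL = 332.063713
#: Default exclusion window: same-chain neighbours up to i+4 are masked.
DEFAULT_EXCLUSION_WINDOW = 4


def debye_kappa(salt_molar: float, temperature: float = 310.0,
                eps_out: float = 78.5) -> float:
    """Inverse Debye screening length (Å⁻¹) for a 1:1 salt."""
    if salt_molar <= 0:
        return 0.0
    ionic = salt_molar * 1000.0  # mol/m^3
    kappa_sq = (2 * constants.N_A * constants.e**2 * ionic
                / (constants.epsilon_0 * eps_out * constants.k * temperature))
    return math.sqrt(kappa_sq) * 1e-10


@dataclass(frozen=True)
class GBConfig:
    """Generalized-Born settings (OBC-II flavour).

    ``offset`` is the dielectric-offset subtracted from intrinsic radii before
    descreening; the default 0 makes an isolated atom's effective radius equal
    its intrinsic radius exactly.
    """

    eps_in: float = 1.0
    eps_out: float = 78.5
    salt_molar: float = 0.15
    temperature: float = 310.0
    offset: float = 0.0
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85

    @property
    def kappa(self) -> float:
        return debye_kappa(self.salt_molar, self.temperature, self.eps_out)


def _param_arrays(structure: Structure,
                  params: ParamTable | Sequence[AtomParams]):
    if isinstance(params, ParamTable):
        plist = params.for_structure(structure)
    else:
        plist = list(params)
        if len(plist) != len(structure.atoms):
            raise ParameterError(
                f"{len(plist)} parameter entries for {len(structure.atoms)} atoms")
    q = np.array([p.charge for p in plist])
    rmh = np.array([p.lj_rmin_half for p in plist])
    eps = np.array([p.lj_epsilon for p in plist])
    rho = np.array([p.gb_radius for p in plist])
    scale = np.array([p.gb_scale for p in plist])
    return q, rmh, eps, rho, scale


# ---------------------------------------------------------------------------
# Effective Born radii (HCT descreening + OBC-II rescaling)
# ---------------------------------------------------------------------------

def effective_born_radii(structure: Structure,
                         params: ParamTable | Sequence[AtomParams],
                         config: GBConfig = GBConfig()) -> np.ndarray:
    """Per-atom effective Born radii (Å) by pairwise descreening."""
    _, _, _, rho_in, scale = _param_arrays(structure, params)
    coords = structure.coordinates
    rho = rho_in - config.offset
    if np.any(rho <= 0):
        raise ParameterError("offset-reduced Born radius must stay positive")
    n = len(rho)
    if n == 1:
        integral = np.zeros(1)
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=2))
        np.fill_diagonal(r, np.inf)
        s = scale * rho  # descreening radius of the *other* atom
        sj = s[None, :]
        ri = rho[:, None]
        U = r + sj
        L = np.maximum(ri, np.abs(r - sj))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (1.0 / L - 1.0 / U
                    + 0.25 * (r - sj * sj / r) * (1.0 / U**2 - 1.0 / L**2)
                    + 0.5 * np.log(L / U) / r)
            term = term + np.where(sj > r + ri, 2.0 * (1.0 / ri - 1.0 / L), 0.0)
        term = np.where(r + sj > ri, 0.5 * term, 0.0)
        term = np.where(np.isfinite(term), term, 0.0)
        integral = term.sum(axis=1)
    psi = integral * rho
    tanh_arg = (config.obc_alpha * psi - config.obc_beta * psi**2
                + config.obc_gamma * psi**3)
    inv_reff = 1.0 / rho - np.tanh(tanh_arg) / rho_in
    if np.any(inv_reff <= 0):
        raise ParameterError("effective Born radius diverged (non-positive 1/R)")
    return 1.0 / inv_reff


# ---------------------------------------------------------------------------
# Pairwise energy matrices
# ---------------------------------------------------------------------------

@dataclass
class PairwiseEnergyMatrix:
    """Symmetric residue×residue interaction-energy matrix with components.

    ``mask`` is True for excluded entries (always the diagonal; after
    :func:`apply_exclusion` also same-chain i..i+window neighbours). Masked
    values are retained, never dropped.
    """

    residues: list[tuple[str, int]]
    coulomb: np.ndarray
    vdw: np.ndarray
    gb_polar: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.residues)
        for name in ("coulomb", "vdw", "gb_polar"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise MatrixAlignmentError(f"{name} matrix shape {m.shape} != ({n},{n})")
            if not np.allclose(m, m.T, atol=1e-9):
                raise MatrixAlignmentError(f"{name} matrix is not symmetric")
            setattr(self, name, m)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n, n):
            raise MatrixAlignmentError("mask shape mismatch")

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.vdw + self.gb_polar

    def unmasked_pair_sum(self) -> float:
        """Sum of unmasked off-diagonal pair energies, each pair counted once."""
        iu = np.triu_indices(len(self.residues), k=1)
        keep = ~self.mask[iu]
        return float(self.total[iu][keep].sum())

    def grand_total(self) -> float:
        """All pair energies plus residue self terms (mask ignored)."""
        iu = np.triu_indices(len(self.residues), k=1)
        return float(self.total[iu].sum() + np.trace(self.total))


def _atom_pair_terms(coords: np.ndarray, q, rmh, eps, radii, config: GBConfig):
    """Symmetric (n,n) atom-pair component matrices (zero diagonal) + GB self."""
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    off = ~np.eye(n, dtype=bool)
    if n > 1 and r[off].min() < 0.1:
        raise GeometryError(f"overlapping atoms: min distance {r[off].min():.3g} Å")
    np.fill_diagonal(r, np.inf)

    coul = COULOMB_KCAL * np.outer(q, q) / (config.eps_in * r)

    rmin = rmh[:, None] + rmh[None, :]
    epsij = np.sqrt(np.outer(eps, eps))
    sr6 = (rmin / r) ** 6
    lj = epsij * (sr6 * sr6 - 2.0 * sr6)

    rr = np.outer(radii, radii)
    kappa = config.kappa
    with np.errstate(invalid="ignore"):  # diagonal (r = inf) is overwritten below
        f = np.sqrt(r * r + rr * np.exp(-(r * r) / (4.0 * rr)))
        tau = 1.0 / config.eps_in - np.exp(-kappa * f) / config.eps_out
        gb = -COULOMB_KCAL * tau * np.outer(q, q) / f
    gb = np.where(np.isfinite(gb), gb, 0.0)

    np.fill_diagonal(coul, 0.0)
    np.fill_diagonal(lj, 0.0)
    np.fill_diagonal(gb, 0.0)

    tau_self = 1.0 / config.eps_in - np.exp(-kappa * radii) / config.eps_out
    gb_self = -0.5 * COULOMB_KCAL * tau_self * q * q / radii
    return coul, lj, gb, gb_self


def pairwise_interaction_energy(structure: Structure,
                                params: ParamTable | Sequence[AtomParams],
                                radii: np.ndarray | None = None,
                                config: GBConfig = GBConfig()
                                ) -> PairwiseEnergyMatrix:
    """Decompose the system energy into residue-pairwise contributions.

    Off-diagonal entry (I,J) sums every atom pair with one atom in I and one
    in J; the diagonal holds residue self terms (intra-residue pairs plus Born
    self-energies).
    """
    q, rmh, eps, rho, scale = _param_arrays(structure, params)
    if radii is None:
        radii = effective_born_radii(structure, params, config)
    radii = np.asarray(radii, dtype=float)
    coul, lj, gb, gb_self = _atom_pair_terms(
        structure.coordinates, q, rmh, eps, radii, config)

    residues = [(c, num) for c, num, _ in structure.residues()]
    index = {rid: k for k, rid in enumerate(residues)}
    res_of_atom = np.array([index[a.residue_id] for a in structure.atoms])
    nres = len(residues)
    S = np.zeros((nres, len(structure.atoms)))
    S[res_of_atom, np.arange(len(structure.atoms))] = 1.0

    def collapse(atom_matrix):
        m = S @ atom_matrix @ S.T
        # diagonal of S A S^T counts each intra-residue pair twice
        np.fill_diagonal(m, np.diag(m) / 2.0)
        return m

    coul_res = collapse(coul)
    vdw_res = collapse(lj)
    gb_res = collapse(gb)
    gb_res[np.diag_indices(nres)] += S @ gb_self

    mask = np.eye(nres, dtype=bool)
    meta = {"frames_averaged": 1, "exclusion_window": 0,
            "nonpolar_term": "omitted (not pairwise-decomposable)",
            "gb": {"eps_in": config.eps_in, "eps_out": config.eps_out,
                   "kappa_invA": config.kappa, "offset": config.offset}}
    return PairwiseEnergyMatrix(residues, coul_res, vdw_res, gb_res, mask, meta)


def total_system_energy(structure: Structure,
                        params: ParamTable | Sequence[AtomParams],
                        config: GBConfig = GBConfig()) -> float:
    """Whole-system Coulomb + LJ + GB potential (kcal/mol), computed directly."""
    q, rmh, eps, rho, scale = _param_arrays(structure, params)
    radii = effective_born_radii(structure, params, config)
    coul, lj, gb, gb_self = _atom_pair_terms(
        structure.coordinates, q, rmh, eps, radii, config)
    iu = np.triu_indices(len(q), k=1)
    return float(coul[iu].sum() + lj[iu].sum() + gb[iu].sum() + gb_self.sum())


# ---------------------------------------------------------------------------
# Exclusion mask and averaging
# ---------------------------------------------------------------------------

def apply_exclusion(matrix: PairwiseEnergyMatrix,
                    window: int = DEFAULT_EXCLUSION_WINDOW) -> PairwiseEnergyMatrix:
    """Mask same-chain residue pairs with |i − j| ≤ window (plus the diagonal).

    Inter-chain pairs are never masked. Idempotent for a given window.
    """
    if window < 0:
        raise ParameterError(f"exclusion window must be ≥ 0, got {window}")
    chains = np.array([c for c, _ in matrix.residues])
    numbers = np.array([n for _, n in matrix.residues])
    same_chain = chains[:, None] == chains[None, :]
    close = np.abs(numbers[:, None] - numbers[None, :]) <= window
    mask = (same_chain & close) | np.eye(len(numbers), dtype=bool)
    meta = dict(matrix.meta)
    meta["exclusion_window"] = window
    return PairwiseEnergyMatrix(list(matrix.residues), matrix.coulomb.copy(),
                                matrix.vdw.copy(), matrix.gb_polar.copy(),
                                mask, meta)


@dataclass
class AveragedMatrix:
    """Elementwise mean and standard error over replicate matrices."""

    residues: list[tuple[str, int]]
    mean: np.ndarray
    sem: np.ndarray
    n: int
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.sem < 0) or self.n < 1:
            raise MatrixAlignmentError("sem must be ≥ 0 and n ≥ 1")

    def unmasked_pair_sum(self) -> float:
        iu = np.triu_indices(len(self.residues), k=1)
        keep = ~self.mask[iu]
        return float(self.mean[iu][keep].sum())


def average_matrices(matrices: Sequence[PairwiseEnergyMatrix]) -> AveragedMatrix:
    """Mean and standard error of the mean over replicate total matrices."""
    if not matrices:
        raise MatrixAlignmentError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.residues != first.residues:
            raise MatrixAlignmentError("matrices have different residue lists")
        if not np.array_equal(m.mask, first.mask):
            raise MatrixAlignmentError("matrices have different masks")
    stack = np.array([m.total for m in matrices])
    # center on the first replicate so identical inputs give exactly zero sem
    centered = stack - stack[0]
    mean = stack[0] + centered.mean(axis=0)
    n = len(matrices)
    if n > 1:
        sem = centered.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return AveragedMatrix(list(first.residues), mean, sem, n, first.mask.copy(),
                          {"replicates": n})


# ---------------------------------------------------------------------------
# Decomposition-table import/export
# ---------------------------------------------------------------------------

DECOMP_COLUMNS = ["residue_i", "residue_j", "internal", "vdw", "electrostatic",
                  "polar_solv", "nonpolar_solv", "total"]


def _parse_residue(token) -> tuple[str, int]:
    text = str(token).strip()
    if ":" in text:
        chain, num = text.split(":", 1)
        return (chain.strip() or "A", int(num))
    return ("A", int(float(text)))


def export_decomposition(matrix: PairwiseEnergyMatrix, path: str | Path) -> None:
    """Write the matrix as a long-form decomposition table (upper triangle + diagonal)."""
    rows = []
    n = len(matrix.residues)
    for i in range(n):
        for j in range(i, n):
            ci, ri = matrix.residues[i]
            cj, rj = matrix.residues[j]
            rows.append({
                "residue_i": f"{ci}:{ri}", "residue_j": f"{cj}:{rj}",
                "internal": 0.0, "vdw": matrix.vdw[i, j],
                "electrostatic": matrix.coulomb[i, j],
                "polar_solv": matrix.gb_polar[i, j], "nonpolar_solv": 0.0,
                "total": matrix.total[i, j],
            })
    pd.DataFrame(rows, columns=DECOMP_COLUMNS).to_csv(path, index=False)


def import_decomposition(path: str | Path,
                         symmetry_tolerance: float = 1e-6) -> PairwiseEnergyMatrix:
    """Read a per-residue pairwise decomposition table into a matrix.

    Duplicate (i,j)/(j,i) rows are symmetrized by averaging; any discrepancy
    beyond tolerance is logged with the maximum deviation. If the table's
    ``total`` disagrees with electrostatic+vdw+polar (e.g. nonzero internal or
    nonpolar columns), the residual is folded into the polar component so the
    matrix total matches the table, and the deviation is recorded in metadata.
    """
    df = pd.read_csv(path)
    missing = [c for c in DECOMP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"decomposition table lacks columns: {missing}")

    pairs: dict[tuple, list[tuple[float, float, float, float]]] = {}
    residues: list[tuple[str, int]] = []
    seen = set()
    for row in df.itertuples(index=False):
        ri = _parse_residue(row.residue_i)
        rj = _parse_residue(row.residue_j)
        for r in (ri, rj):
            if r not in seen:
                seen.add(r)
                residues.append(r)
        key = tuple(sorted((ri, rj)))
        pairs.setdefault(key, []).append(
            (float(row.electrostatic), float(row.vdw), float(row.polar_solv),
             float(row.total)))
    residues.sort()
    index = {r: k for k, r in enumerate(residues)}
    n = len(residues)
    coul = np.zeros((n, n)); vdw = np.zeros((n, n)); gb = np.zeros((n, n))
    max_asym = 0.0
    for (ra, rb), values in pairs.items():
        arr = np.array(values)
        if len(values) > 1:
            spread = float(np.max(arr.max(axis=0) - arr.min(axis=0)))
            max_asym = max(max_asym, spread)
        e, v, p, t = arr.mean(axis=0)
        residual = t - (e + v + p)
        i, j = index[ra], index[rb]
        coul[i, j] = coul[j, i] = e
        vdw[i, j] = vdw[j, i] = v
        gb[i, j] = gb[j, i] = p + residual
    if max_asym > symmetry_tolerance:
        logger.warning("asymmetric duplicate pair rows in %s: max discrepancy %.3g",
                       path, max_asym)
    mask = np.eye(n, dtype=bool)
    meta = {"source": str(path), "max_asymmetry": max_asym, "exclusion_window": 0}
    return PairwiseEnergyMatrix(residues, coul, vdw, gb, mask, meta)
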