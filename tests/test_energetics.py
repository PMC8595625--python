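"""GB radii, pairwise decomposition, exclusion, averaging, table import/export."""

import logging
import math

import numpy as np
import pytest

from helixnet import (
    GBConfig,
    PairwiseEnergyMatrix,
    apply_exclusion,
    average_matrices,
    effective_born_radii,
    export_decomposition,
    import_decomposition,
    pairwise_interaction_energy,
)
from helixnet.energetics import COULOMB_KCAL
from helixnet.errors import (
    FormatError,
    GeometryError,
    MatrixAlignmentError,
    ParameterError,
)
from helixnet.params import AtomParams
from helixnet.structure import AtomRecord, Structure

VACUUM = GBConfig(salt_molar=0.0)


def atom(name, resnum, pos, resname="ALA", chain="A"):
    return AtomRecord(name, resnum, resname, chain, np.asarray(pos, float), name[0])


def uniform_params(n, charge=0.5, rmh=1.8, eps=0.1, radius=1.7, scale=0.8):
    return [AtomParams(charge, rmh, eps, radius, scale) for _ in range(n)]


# --------------------------------------------------------------------------
# independent scalar oracles
# --------------------------------------------------------------------------

def hct_obc_radii_oracle(coords, radii, scales, cfg):
    """Literal per-atom loop over the descreening integral + OBC rescaling."""
    n = len(coords)
    rho = np.asarray(radii) - cfg.offset
    out = np.empty(n)
    for i in range(n):
        integral = 0.0
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            sj = scales[j] * rho[j]
            if rho[i] >= r + sj:
                continue
            U = r + sj
            L = max(rho[i], abs(r - sj))
            term = (1 / L - 1 / U
                    + 0.25 * (r - sj * sj / r) * (1 / U**2 - 1 / L**2)
                    + 0.5 * math.log(L / U) / r)
            if sj > r + rho[i]:
                term += 2 * (1 / rho[i] - 1 / L)
            integral += 0.5 * term
        psi = integral * rho[i]
        th = math.tanh(cfg.obc_alpha * psi - cfg.obc_beta * psi**2
                       + cfg.obc_gamma * psi**3)
        out[i] = 1.0 / (1.0 / rho[i] - th / radii[i])
    return out


def pair_energy_oracle(ri, rj, qi, qj, pi, pj, Ri, Rj, cfg):
    """One atom pair's Coulomb + LJ + GB cross terms, written out longhand."""
    r = float(np.linalg.norm(np.asarray(ri) - np.asarray(rj)))
    coul = COULOMB_KCAL * qi * qj / (cfg.eps_in * r)
    rmin = pi.lj_rmin_half + pj.lj_rmin_half
    epsij = math.sqrt(pi.lj_epsilon * pj.lj_epsilon)
    lj = epsij * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    f = math.sqrt(r * r + Ri * Rj * math.exp(-r * r / (4 * Ri * Rj)))
    tau = 1 / cfg.eps_in - math.exp(-cfg.kappa * f) / cfg.eps_out
    gb = -COULOMB_KCAL * tau * qi * qj / f
    return coul, lj, gb


class TestBornRadii:
    def test_isolated_atom_keeps_its_intrinsic_radius(self):
        s = Structure([atom("CA", 1, (0, 0, 0))])
        R = effective_born_radii(s, uniform_params(1, radius=2.0), VACUUM)
        assert R[0] == pytest.approx(2.0, abs=1e-9)

    def test_distant_atoms_approach_the_vacuum_limit(self):
        s = Structure([atom("CA", 1, (0, 0, 0)), atom("CA", 2, (100, 0, 0))])
        R = effective_born_radii(s, uniform_params(2, radius=1.6), VACUUM)
        assert np.abs(R - 1.6).max() < 1e-6

    def test_cluster_matches_descreening_sum_oracle(self):
        rng = np.random.default_rng(21)
        coords = rng.uniform(-3, 3, size=(10, 3))
        while True:  # keep a compact but non-overlapping cluster
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            if d.min() > 1.0:
                break
            coords = rng.uniform(-3, 3, size=(10, 3))
        s = Structure([atom("CA", i + 1, c) for i, c in enumerate(coords)])
        plist = uniform_params(10, radius=1.7, scale=0.72)
        R = effective_born_radii(s, plist, VACUUM)
        expected = hct_obc_radii_oracle(coords, [1.7] * 10, [0.72] * 10, VACUUM)
        assert np.abs(R - expected).max() < 1e-9
        assert np.all(R >= 1.7 - 1e-9)  # descreening only grows the radius


class TestPairwiseDecomposition:
    def test_zero_charges_and_epsilons_give_zero_matrices(self):
        s = Structure([atom("CA", 1, (0, 0, 0)), atom("CA", 2, (4, 0, 0))])
        m = pairwise_interaction_energy(
            s, uniform_params(2, charge=0.0, eps=0.0), config=VACUUM)
        assert np.all(m.total == 0.0)

    def test_matrix_is_symmetric_for_random_systems(self, cloud50, params):
        m = pairwise_interaction_energy(cloud50, params)
        assert np.allclose(m.total, m.total.T, atol=1e-12)

    def test_two_residue_system_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        atoms, plist = [], []
        for resnum in (1, 2):
            for k, name in enumerate(("N", "CA", "C")):
                atoms.append(atom(name, resnum,
                                  rng.uniform(0, 4, 3) + [6 * resnum, 0, 0]))
                plist.append(AtomParams(rng.uniform(-0.5, 0.5), 1.8, 0.1,
                                        rng.uniform(1.3, 1.9), 0.8))
        s = Structure(atoms)
        cfg = GBConfig()
        radii = effective_born_radii(s, plist, cfg)
        m = pairwise_interaction_energy(s, plist, radii=radii, config=cfg)
        coul = lj = gb = 0.0
        for i in range(3):          # atoms of residue 1
            for j in range(3, 6):   # atoms of residue 2
                c, l, g = pair_energy_oracle(
                    atoms[i].position, atoms[j].position,
                    plist[i].charge, plist[j].charge, plist[i], plist[j],
                    radii[i], radii[j], cfg)
                coul += c; lj += l; gb += g
        assert m.coulomb[0, 1] == pytest.approx(coul, abs=1e-9)
        assert m.vdw[0, 1] == pytest.approx(lj, abs=1e-9)
        assert m.gb_polar[0, 1] == pytest.approx(gb, abs=1e-9)

    def test_single_charge_recovers_the_born_self_energy(self):
        s = Structure([atom("CA", 1, (0, 0, 0))])
        q, R = 1.0, 2.0
        m = pairwise_interaction_energy(
            s, [AtomParams(q, 1.8, 0.1, R, 0.8)], config=VACUUM)
        born = -0.5 * (1 / VACUUM.eps_in - 1 / VACUUM.eps_out) * \
            COULOMB_KCAL * q * q / R
        assert m.gb_polar[0, 0] == pytest.approx(born, abs=1e-6)

    def test_decomposition_conserves_the_direct_total(self, cloud50, params):
        cfg = GBConfig()
        plist = params.for_structure(cloud50)
        m = pairwise_interaction_energy(cloud50, plist, config=cfg)
        # independent direct sum over all atom pairs + self terms
        radii = hct_obc_radii_oracle(
            cloud50.coordinates, [p.gb_radius for p in plist],
            [p.gb_scale for p in plist], cfg)
        direct = 0.0
        n = len(plist)
        for i in range(n):
            qi, Ri = plist[i].charge, radii[i]
            tau = 1 / cfg.eps_in - math.exp(-cfg.kappa * Ri) / cfg.eps_out
            direct += -0.5 * COULOMB_KCAL * tau * qi * qi / Ri
            for j in range(i + 1, n):
                c, l, g = pair_energy_oracle(
                    cloud50.atoms[i].position, cloud50.atoms[j].position,
                    qi, plist[j].charge, plist[i], plist[j], Ri, radii[j], cfg)
                direct += c + l + g
        assert m.grand_total() == pytest.approx(direct, abs=1e-6)

    def test_pair_energy_vanishes_at_200_angstrom(self):
        s = Structure([atom("CA", 1, (0, 0, 0)), atom("CA", 2, (200, 0, 0))])
        m = pairwise_interaction_energy(s, uniform_params(2, charge=1.0),
                                        config=GBConfig())
        assert abs(m.total[0, 1]) < 1e-3
        # in vacuum-screening terms: GB cross → screened Coulomb difference
        vac = pairwise_interaction_energy(s, uniform_params(2, charge=1.0),
                                          config=VACUUM)
        r = 200.0
        expected = -(1 / VACUUM.eps_in - 1 / VACUUM.eps_out) * \
            COULOMB_KCAL * 1.0 / r
        assert vac.gb_polar[0, 1] == pytest.approx(expected, rel=1e-6)

    def test_doubling_charges_quadruples_electrostatics_only(self, cloud50):
        base = uniform_params(50, charge=0.3)
        doubled = uniform_params(50, charge=0.6)
        cfg = GBConfig()
        m1 = pairwise_interaction_energy(cloud50, base, config=cfg)
        m2 = pairwise_interaction_energy(cloud50, doubled, config=cfg)
        assert np.allclose(m2.coulomb, 4 * m1.coulomb, rtol=1e-12)
        assert np.allclose(m2.gb_polar, 4 * m1.gb_polar, rtol=1e-12)
        assert np.allclose(m2.vdw, m1.vdw, rtol=1e-12)

    def test_overlapping_atoms_are_a_geometry_error(self):
        s = Structure([atom("CA", 1, (0, 0, 0)), atom("CB", 1, (0.05, 0, 0))])
        with pytest.raises(GeometryError):
            pairwise_interaction_energy(s, uniform_params(2))


def toy_matrix(n=10, seed=0, chains=None):
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 2, (n, n))
    values = np.triu(values, 1)
    values = values + values.T
    residues = [((chains[i] if chains else "A"), i + 1) for i in range(n)]
    return PairwiseEnergyMatrix(residues, values, np.zeros((n, n)),
                                np.zeros((n, n)), np.eye(n, dtype=bool))


class TestExclusion:
    def test_ten_residue_chain_retains_15_of_45_pairs(self):
        m = apply_exclusion(toy_matrix(10), window=4)
        iu = np.triu_indices(10, 1)
        # brute-force enumeration of |i-j| > 4 pairs
        expected = sum(1 for i in range(1, 11) for j in range(i + 1, 11)
                       if j - i > 4)
        assert expected == 15
        assert int((~m.mask[iu]).sum()) == 15

    def test_window_zero_masks_only_self_pairs(self):
        m = apply_exclusion(toy_matrix(10), window=0)
        iu = np.triu_indices(10, 1)
        assert int((~m.mask[iu]).sum()) == 45
        assert np.all(np.diag(m.mask))

    def test_inter_chain_pairs_are_never_masked(self):
        chains = ["A"] * 5 + ["B"] * 5
        m = toy_matrix(10, chains=chains)
        # give chain B its own numbering close to chain A's
        m.residues = [("A", i + 1) for i in range(5)] + \
            [("B", i + 1) for i in range(5)]
        masked = apply_exclusion(m, window=100)
        for i in range(5):
            for j in range(5, 10):
                assert not masked.mask[i, j]

    def test_masking_is_idempotent_and_values_retained(self):
        m = apply_exclusion(toy_matrix(8), window=4)
        again = apply_exclusion(m, window=4)
        assert np.array_equal(m.mask, again.mask)
        assert np.allclose(m.total, toy_matrix(8).total)

    def test_negative_window_is_a_parameter_error(self):
        with pytest.raises(ParameterError):
            apply_exclusion(toy_matrix(5), window=-1)


class TestAveraging:
    def test_identical_replicates_have_zero_sem(self):
        m = toy_matrix(6)
        avg = average_matrices([m, m, m])
        assert np.allclose(avg.mean, m.total)
        assert np.all(avg.sem == 0.0)
        assert avg.n == 3

    def test_two_point_case(self):
        a, b = toy_matrix(3, seed=1), toy_matrix(3, seed=1)
        a.coulomb[0, 2] = a.coulomb[2, 0] = 0.0
        b.coulomb[0, 2] = b.coulomb[2, 0] = 2.0
        avg = average_matrices([a, b])
        assert avg.mean[0, 2] == pytest.approx(1.0)
        assert avg.sem[0, 2] == pytest.approx(1.0)

    def test_random_stack_matches_entrywise_oracle(self):
        mats = [toy_matrix(5, seed=k) for k in range(4)]
        avg = average_matrices(mats)
        stack = np.array([m.total for m in mats])
        for i in range(5):
            for j in range(5):
                vals = stack[:, i, j]
                assert avg.mean[i, j] == pytest.approx(vals.mean(), abs=1e-12)
                expected_sem = vals.std(ddof=1) / 2.0
                assert avg.sem[i, j] == pytest.approx(expected_sem, abs=1e-12)

    def test_mismatched_residues_raise(self):
        a, b = toy_matrix(4), toy_matrix(5)
        with pytest.raises(MatrixAlignmentError):
            average_matrices([a, b])

    def test_averaging_commutes_with_masking(self):
        mats = [toy_matrix(9, seed=k) for k in range(3)]
        avg_then_mask = average_matrices(
            [apply_exclusion(m, 4) for m in mats])
        masked_any = apply_exclusion(mats[0], 4).mask
        pre_avg = average_matrices(mats)
        assert np.allclose(avg_then_mask.mean, pre_avg.mean)
        assert np.array_equal(avg_then_mask.mask, masked_any)


class TestDecompositionTables:
    def test_export_import_round_trip(self, tmp_path, cloud50, params):
        m = pairwise_interaction_energy(cloud50, params)
        path = tmp_path / "decomp.csv"
        export_decomposition(m, path)
        back = import_decomposition(path)
        assert back.residues == m.residues
        assert np.abs(back.total - m.total).max() < 1e-6
        assert np.abs(back.coulomb - m.coulomb).max() < 1e-6

    def test_asymmetric_duplicates_are_averaged_with_warning(self, tmp_path, caplog):
        path = tmp_path / "asym.csv"
        path.write_text(
            "residue_i,residue_j,internal,vdw,electrostatic,polar_solv,"
            "nonpolar_solv,total\n"
            "A:1,A:2,0,0,-2.0,0,0,-2.0\n"
            "A:2,A:1,0,0,-2.2,0,0,-2.2\n")
        with caplog.at_level(logging.WARNING, logger="helixnet.energetics"):
            m = import_decomposition(path)
        assert m.total[0, 1] == pytest.approx(-2.1)
        assert any("discrepancy" in rec.message for rec in caplog.records)

    def test_packaged_style_four_residue_table(self, tmp_path):
        rows = ["residue_i,residue_j,internal,vdw,electrostatic,polar_solv,"
                "nonpolar_solv,total"]
        expected = {}
        value = -1.0
        for i in range(1, 5):
            for j in range(i, 5):
                rows.append(f"A:{i},A:{j},0,0,{value},0,0,{value}")
                expected[(i, j)] = value
                value += 0.25
        path = tmp_path / "four.csv"
        path.write_text("\n".join(rows) + "\n")
        m = import_decomposition(path)
        assert len(m.residues) == 4
        for (i, j), v in expected.items():
            assert m.total[i - 1, j - 1] == pytest.approx(v)

    def test_missing_columns_are_a_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("residue_i,residue_j,total\nA:1,A:2,-1\n")
        with pytest.raises(FormatError):
            import_decomposition(path)
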