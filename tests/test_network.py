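"""Profiles, group matrices, difference networks, significance, contacts."""

import numpy as np
import pytest

from helixnet import (
    ContactCriteria,
    PlantedEnergySpec,
    SegmentDefinition,
    Structure,
    Trajectory,
    average_matrices,
    detect_hbonds,
    detect_salt_bridges,
    diff_network,
    group_matrix,
    make_contact_fixture,
    make_planted_energy_system,
    residue_wise,
    significant_residues,
)
from helixnet.energetics import AveragedMatrix, PairwiseEnergyMatrix
from helixnet.errors import MatrixAlignmentError
from helixnet.structure import AtomRecord


def averaged(values, mask=None, sem=None, chains=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    residues = [((chains[i] if chains else "A"), i + 1) for i in range(n)]
    if mask is None:
        mask = np.eye(n, dtype=bool)
    if sem is None:
        sem = np.zeros_like(values)
    return AveragedMatrix(residues, values, sem, 1, mask)


class TestResidueWise:
    def test_zero_matrix_gives_zero_profile(self):
        profile = residue_wise(averaged(np.zeros((4, 4))))
        assert np.all(profile.energy == 0.0)

    def test_three_residue_toy(self):
        values = np.zeros((3, 3))
        values[0, 2] = values[2, 0] = -2.0
        profile = residue_wise(averaged(values))
        assert profile.energy.tolist() == [-2.0, 0.0, -2.0]

    def test_matches_row_sum_oracle_and_conservation(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (12, 12))
        values = np.triu(values, 1) + np.triu(values, 1).T
        mask = np.eye(12, dtype=bool)
        mask[0, 1] = mask[1, 0] = True  # one excluded pair
        avg = averaged(values, mask=mask)
        profile = residue_wise(avg)
        for i in range(12):  # brute-force row sums over unmasked partners
            expected = sum(values[i, j] for j in range(12)
                           if j != i and not mask[i, j])
            assert profile.energy[i] == pytest.approx(expected, abs=1e-12)
        assert profile.energy.sum() == pytest.approx(
            2 * avg.unmasked_pair_sum(), abs=1e-9)


class TestGroupMatrix:
    definition = SegmentDefinition(segments={"A1": (1, 4), "B1": (5, 8)})

    def test_planted_block_interaction_lands_on_one_entry(self):
        values = np.zeros((8, 8))
        values[1, 6] = values[6, 1] = -5.0  # residue 2 (A1) with residue 7 (B1)
        gm = group_matrix(averaged(values), self.definition)
        frame = gm.as_frame()
        assert frame.loc["A1", "B1"] == pytest.approx(-5.0)
        assert frame.loc["A1", "A1"] == 0.0
        assert frame.loc["B1", "B1"] == 0.0

    def test_total_is_conserved(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (8, 8))
        values = np.triu(values, 1) + np.triu(values, 1).T
        avg = averaged(values)
        gm = group_matrix(avg, self.definition)
        assert gm.total() == pytest.approx(avg.unmasked_pair_sum(), abs=1e-9)

    def test_single_group_collects_the_whole_total(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, (6, 6))
        values = np.triu(values, 1) + np.triu(values, 1).T
        avg = averaged(values)
        gm = group_matrix(avg, SegmentDefinition(segments={"ALL": (1, 6)}))
        assert gm.as_frame().loc["ALL", "ALL"] == pytest.approx(
            avg.unmasked_pair_sum(), abs=1e-12)

    def test_unassigned_residues_collect_into_other(self):
        values = np.zeros((8, 8))
        values[0, 7] = values[7, 0] = 1.5
        gm = group_matrix(averaged(values),
                          SegmentDefinition(segments={"A1": (1, 4)}))
        assert gm.as_frame().loc["A1", "other"] == pytest.approx(1.5)


class TestDiffNetwork:
    def test_identical_inputs_give_exactly_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 2, (7, 7))
        values = np.triu(values, 1) + np.triu(values, 1).T
        avg = averaged(values)
        dn = diff_network(avg, avg)
        assert np.all(dn.delta == 0.0)

    def test_single_zeroed_pair_shows_positive_delta(self):
        wt = np.zeros((5, 5))
        wt[0, 3] = wt[3, 0] = -3.0
        dn = diff_network(averaged(wt), averaged(np.zeros((5, 5))))
        assert dn.delta[0, 3] == pytest.approx(3.0)
        others = dn.delta.copy()
        others[0, 3] = others[3, 0] = 0.0
        assert np.all(others == 0.0)
        pairs = dn.pairs(0.5)
        assert len(pairs) == 1
        assert pairs.iloc[0]["class"] == "attractive-lost"

    def test_antisymmetric_under_condition_swap(self):
        a = averaged(np.triu(np.random.default_rng(1).normal(0, 1, (6, 6)), 1)
                     + np.triu(np.random.default_rng(1).normal(0, 1, (6, 6)), 1).T)
        b = averaged(np.triu(np.random.default_rng(2).normal(0, 1, (6, 6)), 1)
                     + np.triu(np.random.default_rng(2).normal(0, 1, (6, 6)), 1).T)
        assert np.allclose(diff_network(a, b).delta,
                           -diff_network(b, a).delta, atol=1e-15)

    def test_mismatched_universes_raise(self):
        with pytest.raises(MatrixAlignmentError):
            diff_network(averaged(np.zeros((4, 4))), averaged(np.zeros((5, 5))))

    def test_sem_combines_in_quadrature(self):
        n = 4
        sem_a = np.full((n, n), 3.0)
        sem_b = np.full((n, n), 4.0)
        dn = diff_network(averaged(np.zeros((n, n)), sem=sem_a),
                          averaged(np.zeros((n, n)), sem=sem_b))
        assert np.allclose(dn.sem, 5.0)

    def test_planted_pairs_recovered_with_no_false_positives(self):
        spec = PlantedEnergySpec(
            groups=(("G1", 10), ("G2", 10), ("G3", 10)),
            baseline_pairs=((2, 25, -4.0), (5, 18, -3.0), (11, 28, 2.0),
                            (3, 14, -2.0), (8, 22, -5.0)),
            mutant_deltas=((2, 25, 3.0), (5, 18, 1.5), (11, 28, -2.0),
                           (3, 14, 1.0), (8, 22, 2.5)),
            replicate_noise_sd=0.1, n_replicates=3, seed=123)
        wt, mut, truth = make_planted_energy_system(spec)
        dn = diff_network(average_matrices(wt), average_matrices(mut))
        flagged = {(row["res_i"], row["res_j"])
                   for _, row in dn.pairs(0.5).iterrows()}
        planted = {tuple(sorted((i, j))) for i, j, _ in spec.mutant_deltas}
        assert flagged == planted  # brute-force set comparison, zero FP/FN


class TestSignificantResidues:
    def profile(self, values):
        from helixnet.network import ResidueEnergyProfile
        values = np.asarray(values, dtype=float)
        residues = [("A", i + 1) for i in range(len(values))]
        return ResidueEnergyProfile(residues, values)

    def test_identical_profiles_select_nothing(self):
        p = self.profile([-3, 1, 0, 2])
        assert significant_residues(p, p, threshold=0.1).empty

    def test_single_change_is_rank_one(self):
        wt = self.profile([0, -4, 0])
        mut = self.profile([0, -8, 0])
        out = significant_residues(wt, mut, threshold=1.0)
        assert out["residue"].tolist() == [2]
        assert out["rank"].tolist() == [1]
        assert out["delta_kcal_mol"].iloc[0] == pytest.approx(-4.0)

    def test_matches_threshold_filter_oracle(self):
        rng = np.random.default_rng(17)
        wt = self.profile(rng.normal(0, 2, 30))
        mut = self.profile(rng.normal(0, 2, 30))
        threshold = 1.5
        out = significant_residues(wt, mut, threshold)
        expected = {i + 1 for i in range(30)
                    if abs(mut.energy[i] - wt.energy[i]) >= threshold}
        assert set(out["residue"]) == expected
        deltas = out["delta_kcal_mol"].abs().values
        assert np.all(np.diff(deltas) <= 1e-12)  # ranked by |delta| descending


class TestHydrogenBonds:
    def test_planted_geometry_inside_criteria_is_detected(self):
        fixture = make_contact_fixture("hbond", 2.9, 165.0)
        records = [r for r in detect_hbonds(fixture) if r.donor[2] == "OG"]
        assert len(records) == 1
        rec = records[0]
        assert rec.distance == pytest.approx(2.9, abs=1e-6)
        assert rec.angle == pytest.approx(165.0, abs=1e-6)
        assert rec.occupancy == 1.0

    def test_long_distance_is_not_detected(self):
        fixture = make_contact_fixture("hbond", 4.5, 165.0)
        assert [r for r in detect_hbonds(fixture) if r.donor[2] == "OG"] == []

    def test_bad_angle_is_rejected_when_hydrogens_present(self):
        fixture = make_contact_fixture("hbond", 2.9, 100.0)
        assert [r for r in detect_hbonds(fixture) if r.donor[2] == "OG"] == []

    def test_distance_only_mode_without_hydrogens(self):
        fixture = make_contact_fixture("hbond", 2.9, 100.0)
        stripped = fixture.subset(lambda a: a.element != "H")
        records = [r for r in detect_hbonds(stripped) if r.donor[2] == "OG"]
        assert len(records) == 1
        assert records[0].angle is None

    def test_alternating_frames_give_half_occupancy(self):
        near = make_contact_fixture("hbond", 2.9, 165.0)
        far = make_contact_fixture("hbond", 4.5, 165.0)
        frames = np.array([near.coordinates, far.coordinates] * 3)
        traj = Trajectory(near, frames)
        rec = [r for r in detect_hbonds(traj) if r.donor[2] == "OG"][0]
        assert rec.occupancy == pytest.approx(0.5)

    def test_occupancy_invariant_under_frame_reordering(self):
        near = make_contact_fixture("hbond", 2.9, 165.0)
        far = make_contact_fixture("hbond", 4.5, 165.0)
        frames = np.array([near.coordinates] * 2 + [far.coordinates] * 4)
        rng = np.random.default_rng(2)
        shuffled = frames[rng.permutation(6)]
        occ = [r for r in detect_hbonds(Trajectory(near, frames))
               if r.donor[2] == "OG"][0].occupancy
        occ_shuffled = [r for r in detect_hbonds(Trajectory(near, shuffled))
                        if r.donor[2] == "OG"][0].occupancy
        assert occ == occ_shuffled == pytest.approx(2 / 6)


class TestSaltBridges:
    def test_asp_lys_pair_inside_cutoff_is_detected(self):
        fixture = make_contact_fixture("saltbridge", 3.5)
        records = detect_salt_bridges(fixture)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.5, abs=1e-6)
        assert records[0].donor[1] == 2 and records[0].acceptor[1] == 1

    def test_beyond_cutoff_is_not_detected(self):
        fixture = make_contact_fixture("saltbridge", 4.5)
        assert detect_salt_bridges(fixture) == []

    def test_same_sign_pair_is_never_reported(self):
        # Asp and Glu carboxylates 3.0 Å apart: same charge sign
        atoms = [
            AtomRecord("CB", 1, "ASP", "A", (-1.4, 0, 0), "C"),
            AtomRecord("CG", 1, "ASP", "A", (-0.7, 0.7, 0), "C"),
            AtomRecord("OD1", 1, "ASP", "A", (0, 0, 0), "O"),
            AtomRecord("OD2", 1, "ASP", "A", (-0.7, 1.9, 0), "O"),
            AtomRecord("CB", 2, "GLU", "A", (5.2, 0, 0), "C"),
            AtomRecord("CG", 2, "GLU", "A", (4.8, 0.7, 0), "C"),
            AtomRecord("CD", 2, "GLU", "A", (4.2, 0.9, 0), "C"),
            AtomRecord("OE1", 2, "GLU", "A", (3.0, 0, 0), "O"),
            AtomRecord("OE2", 2, "GLU", "A", (4.2, 2.1, 0), "O"),
        ]
        assert detect_salt_bridges(Structure(atoms)) == []

    def test_random_geometries_match_min_distance_scan_oracle(self):
        rng = np.random.default_rng(33)
        criteria = ContactCriteria(saltbridge_distance_max=4.0)
        for trial in range(5):
            shift = rng.uniform(2.0, 7.0)
            fixture = make_contact_fixture("saltbridge", shift)
            # oracle: minimum distance between carboxylate O and NZ
            od = [a.position for a in fixture.atoms if a.atom_name in ("OD1", "OD2")]
            nz = [a.position for a in fixture.atoms if a.atom_name == "NZ"]
            dmin = min(np.linalg.norm(o - n) for o in od for n in nz)
            detected = bool(detect_salt_bridges(fixture, criteria))
            assert detected == (dmin <= 4.0)
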