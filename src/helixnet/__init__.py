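"""helixnet: transmembrane-helix orientation and interaction-energy networks.

Analysis toolkit for membrane-protein (GPCR) trajectories: helix tilt angles
against the membrane normal, per-segment no-fit RMSD and RMSF, residue-pairwise
interaction-energy decomposition (Coulomb + Lennard-Jones + generalized Born),
helix/loop group aggregation, wildtype-vs-mutant difference networks, and
geometric hydrogen-bond / salt-bridge detection — together with a synthetic
fixture generator carrying known ground truth.
"""

from importlib import resources

from .errors import HelixnetError
from .structure import (
    AtomRecord,
    BWLabel,
    SegmentDefinition,
    Structure,
    Trajectory,
    bw_to_residue,
    expand_segments,
    read_structure,
    read_trajectory,
    residue_to_bw,
    split_at_pivot,
    truncate_to_alanine,
    write_structure,
    write_trajectory,
)
from .geometry import (
    align_to_reference,
    angle_rmsd_means,
    angle_rmsd_series,
    endpoint_atoms,
    helix_angle,
    helix_vector,
    rmsf,
    segment_rmsd_nofit,
)
from .energetics import (
    AveragedMatrix,
    GBConfig,
    PairwiseEnergyMatrix,
    apply_exclusion,
    average_matrices,
    effective_born_radii,
    export_decomposition,
    import_decomposition,
    pairwise_interaction_energy,
    total_system_energy,
)
from .network import (
    ContactCriteria,
    ContactRecord,
    DiffNetwork,
    GroupMatrix,
    ResidueEnergyProfile,
    detect_hbonds,
    detect_salt_bridges,
    diff_network,
    group_matrix,
    residue_wise,
    significant_residues,
)
from .params import AtomParams, ParamTable, default_params
from .synthetic import (
    HelixSpec,
    PlantedEnergySpec,
    SegmentMotion,
    make_bundle,
    make_contact_fixture,
    make_ideal_helix,
    make_noisy_trajectory,
    make_planted_energy_system,
)

__version__ = "0.1.0"


def cb1_segment_definition() -> SegmentDefinition:
    """The packaged CB1 receptor segment definition.

    Pivot prolines P358 (TM6) and P394 (TM7) and the BW anchors implied by the
    published residue/BW pairs are authoritative; the TM ranges themselves are
    reconstructed approximations (see the fixture file's comments).
    """
    with resources.as_file(resources.files("helixnet.data")
                           / "cb1_segments.yaml") as path:
        return SegmentDefinition.from_yaml(path)
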