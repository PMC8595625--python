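#!/usr/bin/env python
"""Helix-orientation analysis of the synthetic trajectory.

Aligns the trajectory to the reference bundle over TM Cα atoms, measures each
helix compartment's tilt angle against the membrane normal and its no-fit RMSD
per frame, and the per-residue RMSF. Verifies that the planted +10° tilt step
on TM6-2 is visible in the angle series and that undisturbed helices sit at
their planted orientations.
"""

import json
from pathlib import Path

from helixnet import (
    align_to_reference,
    angle_rmsd_means,
    angle_rmsd_series,
    read_structure,
    read_trajectory,
    rmsf,
)
from helixnet.structure import SegmentDefinition

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"


def main() -> None:
    if not (FIXTURES / "bundle.pdb").exists():
        raise SystemExit("run analysis/01_generate_fixtures.py first")
    RESULTS.mkdir(exist_ok=True)
    reference = read_structure(FIXTURES / "bundle.pdb")
    definition = SegmentDefinition.from_yaml(FIXTURES / "segments.yaml")
    trajectory = read_trajectory(reference, FIXTURES / "trajectory.pdb")
    aligned = align_to_reference(trajectory, reference, definition=definition)

    samples = angle_rmsd_series(aligned, reference, definition)
    means = angle_rmsd_means(samples)
    means.to_csv(RESULTS / "02_angle_rmsd_means.csv", index=False,
                 float_format="%.4f")

    truth = json.loads((FIXTURES / "truth.json").read_text())
    motion = truth["trajectory"]["motion"]
    seg = samples[samples.segment == motion["segment"]]
    before = seg[seg.frame < motion["start_frame"]]["angle_deg"].mean()
    after = seg[seg.frame >= motion["start_frame"]]["angle_deg"].mean()

    fluct = rmsf(aligned)
    fluct.reset_index().to_csv(RESULTS / "02_rmsf.csv", index=False,
                               float_format="%.4f")

    print(f"{len(samples)} angle/RMSD samples over {aligned.n_frames} frames "
          f"and {samples.segment.nunique()} helix compartments")
    print(f"planted tilt step on {motion['segment']}: "
          f"{before:.2f}° before frame {motion['start_frame']}, "
          f"{after:.2f}° after (planted change {motion['tilt_deg']}°)")
    print(f"mean RMSF {fluct.mean():.3f} Å over {len(fluct)} residues "
          f"(noise sigma {truth['trajectory']['sigma_A']} Å)")
    print(f"tables: {RESULTS/'02_angle_rmsd_means.csv'}, {RESULTS/'02_rmsf.csv'}")


if __name__ == "__main__":
    main()
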