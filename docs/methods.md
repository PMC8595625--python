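# Methods

`helixnet` re-implements, as a tested library plus pipeline, a common analysis
chain for membrane-receptor (class A GPCR) simulation studies: helix
orientation statistics, residue-pairwise interaction-energy decomposition in a
generalized-Born (GB) implicit solvent, and wildtype-vs-mutant interaction
networks. This note records the models, the conventions chosen where the
procedure admits more than one reading, the defaults and their units, and what
the synthetic fixtures do and do not establish.

## Segment model and generic numbering

Structures are keyed throughout by author (PDB) residue numbering; there is no
internal renumbering. A segment definition names inclusive residue ranges
(TM1–TM7, loops, H8), optional pivot residues, and Ballesteros–Weinstein (BW)
anchors. BW arithmetic is a pure offset from the anchor: residue(H.NN) =
anchor_residue + (NN − anchor_position). No alignment or conservation profile
enters; the mapping is exact by construction wherever helices are unbroken,
and requests that leave the declared helix range raise rather than
extrapolate. Kinked helices are split at a pivot proline into two
compartments, with the pivot residue assigned to the **second** compartment
([first, pivot−1], [pivot, last]). The assignment is a convention — the kink
residue belongs equally to both halves geometrically — and is config-level,
not hard-coded into callers.

The packaged CB1 definition fixes the pivots (P358, P394) and the anchors
implied by published residue/BW identities; the TM boundary residues
themselves are reconstructed approximations and are flagged as such in the
fixture file.

## Helix vectors, angles, RMSD, RMSF

A helix vector runs from an N-terminal to a C-terminal endpoint. Each endpoint
is the unweighted mean of **11 backbone atoms** chosen by a fixed rule: skip
one gap residue at the extreme terminus (frayed-end guard), take the next four
residues' C/Cα/N atoms (one helical turn, 12 atoms), and drop the single
innermost of those twelve — the C of the innermost window residue at the N
end, the N of the innermost window residue at the C end. Two readings of the
published prose are possible ("one gap interval", "an inward backbone atom …
eliminated"); the rule above is the one reading that yields exactly 11 atoms
symmetrically at both termini, and both the gap width and the dropped-atom
convention are parameters of `endpoint_atoms`. The endpoint is a plain
coordinate mean rather than a mass-weighted one: C, Cα and N masses differ by
under 17 %, the difference in the endpoint is far below the fluctuation scale
of interest, and the unweighted mean is exactly reproducible from coordinates
alone.

The helix angle is arccos(d̂ · ẑ) in degrees, reported over [0, 180] rather
than folded to ≤ 90°, so antiparallel helices of the bundle keep distinct
orientations. Per-segment RMSD is computed over C/Cα/O/N atoms with **no
re-fitting** after one global superposition (Cα of all TM residues by
default, loops excluded), so rigid shifts and tilts of a single helix
contribute to its RMSD — that is the point of the statistic. RMSF is
per-residue over Cα about the time-average position; Cα is convention, the
atom is overridable. Global superposition is a least-squares Kabsch fit
(scipy's `Rotation.align_vectors`).

## Pairwise energy decomposition

For residues I ≠ J the interaction energy is the sum over their atom pairs of

* Coulomb: k q_i q_j / (ε_in r_ij), k = 332.063713 kcal·Å/(mol·e²);
* Lennard-Jones in the Rmin/2 convention with Lorentz–Berthelot-style
  combination (Rmin = Rmin/2_i + Rmin/2_j, ε = √(ε_i ε_j));
* the GB cross term −k (1/ε_in − e^{−κ f}/ε_out) q_i q_j / f with the
  canonical f = √(r² + R_i R_j e^{−r²/(4 R_i R_j)}).

Effective radii R follow OBC-II: pairwise HCT descreening integrals summed
per atom, then the tanh(αΨ − βΨ² + γΨ³) rescaling with α = 1.0, β = 0.8,
γ = 4.85. Defaults: ε_in = 1, ε_out = 78.5, κ from 0.15 M 1:1 salt at 310 K
(≈ 0.125 Å⁻¹, computed from physical constants, not hard-coded). The
dielectric offset subtracted from intrinsic radii before descreening defaults
to **0.0** (not the 0.09 Å some force-field implementations use), so that an
isolated atom's effective radius equals its intrinsic radius exactly — the
cleanest contract for testing the vacuum and separation limits; the offset is
a `GBConfig` field for users who want force-field parity.

Residue self-terms (intra-residue atom pairs plus atomic Born self-energies)
live on the matrix diagonal and are never mixed into off-diagonal entries.
With that bookkeeping the decomposition is exactly conservative: upper
triangle plus diagonal reproduces the directly summed whole-system potential
to float precision (tested at 1e-6 kcal/mol). The nonpolar (SASA) solvation
term is omitted from pairwise entries — it is not pairwise-decomposable in
the same sense — and this is recorded in matrix metadata.

Short-range helical neighbours are removed at residue level: same-chain pairs
with |i − j| ≤ 4 (the backbone hydrogen-bonding window of an α-helix) are
masked, never dropped — masked values stay in the matrix behind a boolean
mask, so masking is idempotent, invertible and auditable. Inter-chain pairs
are never masked. No distance cutoff is applied inside the decomposition; all
pairs are summed. There is no atom-level bonded exclusion list: at residue
granularity the i..i+4 mask covers bonded and 1-4 neighbours, which is the
granularity this analysis works at.

Atom parameters (charge, LJ, GB radius and descreening scale) come from a CSV
or the built-in table. The built-in table is a compact **synthetic** parameter
set — element-wise GB radii/scales, per-residue charges summing to formal
charges — adequate for fixtures and method validation, and explicitly not a
force field. Force-field topology import (prmtop/PSF) is out of scope;
externally produced per-residue pairwise decomposition tables can be imported
instead (the common CSV dialect with internal/vdW/electrostatic/polar/
nonpolar/total columns; duplicate (i,j)/(j,i) rows are symmetrized by
averaging with the maximum discrepancy logged, and any residual between the
table's `total` and the component sum is folded into the polar column so the
imported totals match the table).

Replicate averaging is elementwise mean with the standard error of the mean
(ddof = 1); the replicate stack is centered on the first replicate before the
moment computation so identical replicates give an SEM of exactly zero.

## Networks, differences, contacts

Residue-wise energy is the sum of a residue's unmasked pairwise entries, so
the profile total is exactly twice the unmasked pair-sum. Group (helix/loop)
matrices sum each unmasked pair into the one cell given by its residues'
groups, with pivoted helices contributing their compartments (TM6-1, TM6-2, …)
as separate groups and unassigned residues collected into an explicit
`other` group; the group total equals the unmasked pair total (conservation,
tested at 1e-9).

Difference networks are ΔE = E_mut − E_wt per pair, matched by residue number
(alanine substitutions keep their numbers; mutated residues are flagged, not
excluded), with replicate SEMs combined in quadrature and each pair classified
by (sign of wildtype energy, sign of Δ): attractive-lost, attractive-gained,
repulsive-gained, repulsive-lost. Significant residues are those with
|Δ residue-wise energy| ≥ a threshold, default **1.0 kcal/mol**, ranked by
|Δ|; the threshold is a free parameter with no published numeric criterion
behind it, so results always carry the threshold used. Note that residue-wise
sums accumulate replicate noise over every unmasked partner (√n_partners
scaling), so for weakly perturbed systems the ranking is more informative than
the raw count above threshold — the analysis drivers print the noise floor
alongside the count.

Hydrogen bonds use heavy-atom donor–acceptor distance ≤ 3.5 Å and D–H···A
angle ≥ 120° (standard geometric criteria; the published analysis states no
criterion). When the topology carries no hydrogens the angle test is skipped
and distance-only mode is logged. Salt bridges use minimum distance ≤ 4.0 Å
between opposite-charge side-chain groups (Asp/Glu carboxylate oxygens vs
Lys NZ / Arg NE,NH1,NH2); same-sign pairs are never reported. Occupancy is
the qualifying-frame fraction and is invariant under frame reordering by
construction. All criteria are config fields.

## Synthetic fixtures and what they establish

The generator builds ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å Cα
radius, backbone atoms at fixed cylindrical offsets, side chains truncated at
Cβ), 7TM-like bundles on a circle with alternating helix direction and
non-clashing loop connectors, trajectories with i.i.d. isotropic Gaussian
coordinate noise plus optional scheduled rigid segment motions, paired
wildtype/mutant replicate energy matrices with planted pairwise deltas and
Gaussian replicate noise, and minimal two-residue contact geometries realizing
requested distances/angles exactly.

"Tilt" is defined operationally: the generator measures the endpoint-rule
axis of the raw untilted helix and aligns that axis to +Z before applying the
requested rotation. This matters because the 11-atom endpoint centroids of a
finite discrete helix do not fall exactly on its geometric screw axis (the
dropped inward atom breaks the screw symmetry by a few tenths of an Å), so
without the calibration a "0° helix" would measure a degree or so of tilt.
With it, planted tilts are recovered to 1e-6° noise-free for whole helices;
split compartments, which are shorter and measured off-calibration, recover
their parent's tilt to a few tenths of a degree.

Study-scale defaults for the generated 7TM study: 7 helices × 22 residues
with 4-residue loops (178 residues), trajectory noise σ = 0.06 Å over 12
frames with a +10° tilt of TM6-2 planted mid-trajectory, and 3 replicates of
the energy system with 0.1 kcal/mol replicate noise — dispersion chosen so
that planted pairwise changes of ≥ 1 kcal/mol stand ≥ 6 combined standard
errors above the noise, mirroring a well-converged replicate analysis.

What passing these fixtures does **not** show: the noise model is atomwise
i.i.d. (no collective modes, no solvent or membrane), the synthetic parameters
are not a force field, and recovering planted deltas says nothing about
whether a 1 kcal/mol threshold is biologically meaningful for a real receptor.
The fixtures validate the machinery — selection rules, conservation,
statistics, determinism — not the physics of any particular system.

## Numerical choices and degenerate inputs

* Atom pairs closer than 0.1 Å abort the energy computation (geometry error);
  generated bundles additionally enforce > 1.5 Å between helices and > 0.5 Å
  globally.
* Helix-vector endpoints require ≥ 6 residues (gap + window + 1); zero-length
  vectors (< 1e-9 Å) raise rather than return NaN angles.
* Rigid fits require ≥ 3 selected atoms; arccos arguments are clipped to
  [−1, 1].
* Matrices are validated symmetric at 1e-9 on construction; averaging demands
  identical residue lists and masks.
* Insertion codes are rejected at read time (author numbering is the key
  everywhere, and silently renumbering risks misassigned BW labels); of
  altlocs the first ('A' or blank) is kept.
* All tabular pipeline outputs are written with a fixed float format, making
  repeat runs byte-identical for a fixed config and seed; figures carry
  sibling CSVs with exactly the plotted numbers.

## Known limitations

MD itself, system building, ligand handling and homology modeling are out of
scope — the pipeline analyzes trajectories, it does not produce them. The GB
variant, dielectrics, salt handling and frame stride behind any given external
decomposition are whatever the external tool used; imported tables are taken
at face value. Loop connectors in the synthetic bundle are geometric
placeholders, not conformationally realistic loops. The chord renderer favours
testability over typography.
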