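# Methods

This note documents the models, conventions and numerical choices behind
psychrodyn, in the order an analysis usually runs: structures and
trajectories, flexibility, surfaces, interaction networks, sequence
comparison, interfaces, and the synthetic-data generator that underwrites
the test suite.

## Structures and trajectories

Structures are parsed from PDB files (the only supported format; mmCIF and
compressed trajectory formats are out of scope) via biotite and held as flat
per-atom arrays grouped into residues by `(chain, residue number, insertion
code)`. Waters and hetero groups are excluded by default; alternate
locations resolve to the highest-occupancy conformer, first-listed on a tie.
Residue numbering is preserved exactly as read — cross-homologue
correspondence always goes through alignment columns, never through raw
numbers, because homologues are numbered inconsistently.

Multi-model files become trajectories: one topology, a frame per MODEL. An
`equilibration_fraction` (default 0.20) removes the leading frames from
every analysis, the usual convention of discarding the first fifth of a
production run as equilibration; all persistence and averaging statistics
are over the remaining frames.

Element radii are Bondi-type van der Waals values (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20, P 1.80 Å; 1.70 Å for anything else). Residues fall into
four chemical categories — non-polar (AVLIMFWP), neutral-polar (STNQYCG),
charged-positive (KRH), charged-negative (DE) — with histidine counted
charged-positive by default (it is the titratable base that most often
completes surface ion pairs); a neutral-His mode exists for the alternative
convention. Unknown residues get category "other" and are never dropped.

Superposition is the Kabsch algorithm (SVD of the weighted covariance with
determinant correction), raising an error on fewer than three points or
rank-deficient (collinear) configurations.

## RMSF

`RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²)` per atom after superposing every
analysed frame onto the first analysed frame on a fit selection (backbone of
the whole assembly by default), averaged over a reporting selection per
residue (backbone by default). For oligomers a per-chain fit mode fits each
chain onto its own first-frame conformation instead, removing inter-subunit
motion; whether inter-subunit motion should count as flexibility is a
modelling decision, so both modes are exposed and the global fit is the
default.

Two caveats the synthetic tests quantify: the rigid-body fit absorbs six
degrees of freedom, deflating RMSF by roughly `6/(3·N_fit)` in variance
(≈1–2% in RMSF for systems of ≥ 25 residues — visible as recovered values
of ~0.512 Å against the analytic 0.520 Å in the regression spec), and
heteroscedastic systems let high-σ residues dominate the fit slightly. Both
effects shrink with system size and are far below the 0.25 Å decision
threshold used downstream.

## Solvent-accessible surface

Shrake–Rupley: each atom's sphere of radius `r_vdw + probe` (probe 1.4 Å)
carries `n_points` quasi-uniform test points from a golden-spiral lattice; a
point is accessible iff outside every neighbour's expanded sphere. The
lattice is oriented per atom in a frame built from its two nearest
neighbours, so the sampling co-rotates with the molecule and SASA is exactly
invariant under rigid motion (a plain lab-frame lattice shows ~0.2%
orientation dependence at 960 points). At the default 960 points the
isolated-sphere closed form is matched to well under 1% and a Monte-Carlo
oracle to ~2% per atom.

Hydrogens are excluded by default: crystal structures lack them, and mixed
comparisons (X-ray versus MD frames) would otherwise be inconsistent.
"Hydrophobic SASA" is defined atom-wise — the surface contributed by carbon
and sulfur atoms — because residue-level definitions misattribute the
surface of mixed-polarity side chains; a residue-category alternative is
available by flag. Trajectory surface statistics report population mean ±
SD over analysed frames, divided by the chain count when per-chain
normalisation is requested (the footing on which a tetramer is comparable
with a monomeric homologue).

## Hydrogen bonds

The bond energy is a function of the hydrogen–acceptor distance: a linear
ramp with plateau, `E = 25 kJ/mol` for `d_HA ≤ 2.1 Å` falling linearly to 0
at `2.6 Å`. Bonds are retained at `E ≥ 6.25 kJ/mol`, which with the default
ramp corresponds exactly to `d_HA ≤ 2.475 Å`. The ramp's shape is this
package's documented stand-in for engine-specific energy functions that are
anchored only by that threshold and the distance dependence; all four
parameters are configurable. An angular gate (D–H…A ≥ 100°, no energy
scaling by angle) suppresses geometrically impossible assignments when the
hydrogen position is known.

Donor/acceptor chemistry is template-based per residue type (backbone amide
N donates except proline; carbonyl O accepts; side chains per standard
protein chemistry, hydroxyls both ways). For hydrogen-free input the
backbone amide H is rebuilt at ideal geometry (1.0 Å from N, opposite the
CA/C(prev) bisector); side-chain donors, whose hydrogen positions are
rotamer-dependent, are scored through the donor–acceptor distance with an
effective `d_HA = d_DA − 1.0 Å` and no angle gate. Intra-residue pairs are
excluded; each donor/acceptor atom pair is reported once.

Interaction identity over a trajectory is the (donor atom, acceptor atom)
pair for hydrogen bonds and the residue pair for salt bridges — so a
carboxylate rotation that swaps OE1/OE2 creates a new hydrogen-bond key but
the same salt bridge, which matches how the two quantities are usually
counted.

## Salt bridges and hydrophobic contacts

Salt bridges ("electrostatic pairs"): one record per (negative, positive)
residue pair whose charged-group heavy atoms (Asp OD1/OD2, Glu OE1/OE2
versus Lys NZ, Arg NE/NH1/NH2, His ND1/NE2) approach within 4.0 Å.
Hydrophobic contacts: non-polar residue pairs with any side-chain
carbon–carbon distance ≤ 5.0 Å, requiring sequence separation ≥ 2 within a
chain. Both detectors are KD-tree accelerated and tested for exact set
equality against nested-loop O(n²) oracles on dense decoys.

Persistence is `100 × frames-present / frames-analysed`; interactions below
5% are labelled unstable. Network summaries report unique interactions,
unstable count, per-frame count mean ± SD (population convention), and mean
persistence over unique keys, with optional per-chain normalisation of the
counts (persistence percentages are intensive and are never divided).

## Sequence comparison

Composition tables count all twenty amino acids (and X separately); ratios
use the full sequence length as denominator and print at one decimal.
Point corrections to database sequences (e.g. a published Val162→Asp
erratum) refuse to apply unless the stated original residue matches, and the
correction is recorded in the record's provenance.

Identity is computed over alignment columns where both rows have residues;
the default pairwise aligner is global Needleman–Wunsch with BLOSUM62, gap
open 10, extend 0.5 — the standard parameterisation, but identity on a
user-supplied (e.g. structure-based) alignment can differ by a point or two,
so reports always state comparable-column counts alongside percentages.

Cold-specific positions are fully comparable columns (no gaps in target or
any reference) where the target differs from every reference.
Substitutions are classified in the merged three-way scheme (non-polar /
neutral-polar / charged, positive and negative merged for reporting;
four-way detail retained internally); a substitution is non-conservative
when the target's category matches none of the references'.

Structural context: relative accessibility is residue SASA on the isolated
single chain divided by the theoretical Gly-X-Gly maximum (Tien et al. 2013
values), classed buried < 9% ≤ intermediate ≤ 36% < exposed, boundaries
assigned upward — the thresholds are this package's convention for a
quantity usually shown only as a colour gradient. Secondary structure is a
deliberately coarse φ/ψ-region heuristic (helix φ∈(−100°,−30°),
ψ∈(−80°,−5°); strand φ∈(−180°,−80°), ψ∈(80°,180°]∪[−180°,−170°); else
loop; termini and incomplete backbones are loop). It is not DSSP: it has no
hydrogen-bond term and will disagree near region edges; an external
per-residue annotation can override it where that matters.

## ΔRMSF comparison and region detection

RMSF profiles are mapped onto alignment columns by exact sequence match
between profile residues and alignment rows; all chains of the oligomeric
target must share one sequence and are carried as separate series. Only
columns with residues in both proteins are comparable — insertions are
excluded from Δ values and belong in a qualitative indel report instead.

A column qualifies when `ΔRMSF > threshold` (strictly greater; default
0.25 Å) in at least `min_chains` chains (default 2 of the tetramer's 4).
Maximal runs of consecutive qualifying columns form regions; `min_run`
defaults to 1 since single-residue gains are meaningful, with merging
available for reporting. Detection is monotone in both threshold and
`min_chains`, and self-comparison yields no regions for any positive
threshold — both are property-tested.

## Interfaces

Buried area is `SASA(A) + SASA(B) − SASA(AB)` from three evaluations at
identical parameters, reported as the full two-chain value (this is the
quantity that satisfies the additivity identity against per-chain SASA
loss); the halved per-side convention is printed alongside. Interface
residues are those with ΔSASA > 0.1 Ų (the numerical noise floor at default
sampling). Cross-chain hydrogen bonds, salt bridges and hydrophobic
contacts are re-detected restricted to the pair; hydrophobic clusters are
connected components of the cross-chain contact graph. Chain equivalence is
the pairwise Kabsch backbone RMSD matrix on atoms shared by residue number
and atom name.

## Synthetic data

The generator emulates exactly the statistical structure the analyses
assume, nothing more: ideal-geometry peptides (helix φ=−57°, ψ=−47°; strand
−120°/120°; extended 180°/180°; standard bond lengths and angles, amide
hydrogens placed on the bisector), C2/D2 assemblies by two-fold rotations
about orthogonal axes (D2 centroids at regular-tetrahedron vertices with
edge equal to the requested separation), and trajectories of the form
`base + iid Gaussian noise(σ_i per residue) [+ rigid-body jitter]`.

Because the noise is per-coordinate Gaussian, ground-truth RMSF is σ√3 in
closed form. Scheduled interactions hold a designated atom at its on/off
distance relative to the partner's instantaneous position in a seeded
pseudo-random subset of exactly `round(p/100 · n_analysed)` analysed frames
(a random subset, not a prefix, to exercise the bookkeeping; scheduled atoms
carry no thermal noise so presence is binary by construction). Jitter is
applied last, so it is rigid and removable by the superposition fit.
Everything is deterministic given the seed.

What this generator does **not** emulate: bonded-force correlations,
anisotropic or time-correlated fluctuations, side-chain rotamers, solvent.
Passing the recovery tests therefore demonstrates that the estimators and
bookkeeping are correct, not that any biological conclusion transfers; on
real trajectories the same code measures whatever the physics produced.

The two shipped configs (`examples/configs/`) are the primary regression
fixtures: `rmsf_recovery.yaml` (20-residue helix, σ = 0.30 Å, jitter, 2000
analysed frames; recovery within 5% of σ√3) and
`persistence_schedule.yaml` (ten salt-bridge schedules at
{100, 80, 60, 40, 20, 10, 4, 3, 2, 1}%, 200 analysed frames; recovered
exactly, with mean persistence 32.0% and four unstable).

## Problem sizes and determinism

Synthetic systems used by the tests and the acceptance script are sized so
the statistics are decisive yet quick: 2 000 analysed frames where sampling
error matters (per-residue RMSF standard error ≈ 1%), 200 analysed frames
where counts are exact by construction, 50-residue decoys for oracle
equality, 960 sphere points for production SASA and 240 where only
differences of large areas matter. All randomness flows through explicit
seeds; identical configuration and inputs give byte-identical outputs.

## Known limitations

* PDB only; no mmCIF, XTC/DCD, or hydrogen-addition force fields.
* The hydrogen-bond energy is a documented surrogate, not a physical
  potential; absolute bond counts depend on it (the threshold distance,
  2.475 Å, is the load-bearing quantity).
* The φ/ψ secondary-structure heuristic is coarse near region boundaries.
* Per-residue accessibility classes inherit the uncertainty of the
  9%/36% thresholds; values near a boundary should be read as such.
* MD itself is out of scope: the package analyses trajectories, it does not
  produce them.
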