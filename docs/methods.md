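# Methods

## Scope and data model

The package analyses the electrostatics of an antigen–antibody interface at
four levels: static crystal geometry, trajectory stability, per-residue
energetics, and solution binding kinetics/thermodynamics. Structures are
parsed from PDB format (Biopython underneath) into plain containers keyed by
author numbering — `(chain, res_seq, i_code)` — because antibody residue
labels (Kabat-style numbering of V_H/V_L) are a bookkeeping convention that
cannot be recovered from coordinates alone. The mapping from biological roles
(antigen, heavy, light) to chain identifiers is therefore always supplied by
configuration and never inferred. HETATM records, waters and hydrogens are
excluded from geometry by default; alternate locations resolve to the
highest-occupancy conformer (ties keep the first encountered). Coordinates
are assumed imaged with the complex whole: no periodic minimum-image
correction is applied anywhere, and trajectory loading warns loudly when any
atom jumps more than 20 Å between consecutive frames, the usual symptom of an
un-imaged periodic trajectory.

## Charged-group geometry

Two distance conventions coexist in the literature for salt bridges, and the
package computes both for every contact, tagging each output row with the
convention used:

* **representative-atom**: Lys NZ, Arg CZ, Asp CG, Glu CD — one well-defined
  atom per side chain, the convention used for trajectory distance series;
* **group-minimum**: the closest approach between the formally charged
  groups (Lys NZ; Arg NE/NH1/NH2; Asp OD1/OD2; Glu OE1/OE2) — the convention
  that matches statements like "the carboxyl group is 2.8 Å from the
  ε-amino group".

`find_salt_bridges` enumerates all (basic, acidic) pairs across two disjoint
chain selections and keeps those with group-minimum distance ≤ cutoff
(default 4.5 Å, a conventional salt-bridge bound); each hit records its
representative-atom distance, which becomes the default occupancy threshold
downstream. Residues with truncated side chains are skipped rather than
guessed at. The scan is exact (all pairs), not grid-accelerated — interface
residue counts make O(n²) irrelevant here.

## Trajectory metrics

Superposition uses the Kabsch algorithm: SVD of the weighted covariance
between centred point sets, with the smallest singular vector sign-corrected
so the rotation is always proper (det = +1; reflections excluded). Fewer
than three points or a (near-)collinear configuration raises a degeneracy
error, since the optimal rotation is then not unique. Fits are unweighted
over Cα atoms by default. The implementation was cross-checked against an
independent quaternion-method (Horn) solver to 10⁻⁹ Å in the tests.

`rmsd_series` superposes every frame on a fit selection and measures RMSD on
a measurement selection; **L-RMSD** is the special case fit = antigen Cα,
measure = antibody Cα with *no* re-fitting, so any reorientation or drift of
the antibody relative to the antigen appears directly. Cα selections exclude
the first and last five residues of each chain by default — terminal
residues are floppy and inflate RMSDs without carrying pose information.

Occupancy is the fraction of post-burn-in frames with contact distance at or
below threshold. Burn-in defaults to the first 20% of the trajectory span
(override in ns via config); with the standard 100 ns production runs this
discards the first 20 ns, before which RMSDs are still equilibrating. The
threshold for each contact defaults to that contact's own crystal-structure
representative distance; a generic 4.0 Å preset is available for contacts
with no crystal reference (e.g. engineered pairs absent from the wild-type
structure). Snapshot times default to frame_index × 10 ps, the standard
save interval, since multi-model PDB carries no time axis.

Replica statistics: arithmetic mean with sample standard deviation (n−1)
and standard error sd/√n. Occupancy tables report sd by convention; energy
tables report se; both are always stored. A single replica yields NaN spread
with an explicit flag, never a silent zero.

## Interaction-energy decomposition

For a chosen residue against partner chains, every (residue atom, partner
atom) pair within 12 Å contributes Coulomb `f·q₁q₂/(ε_r·r)` with
f = 1389.35458 kJ·Å·mol⁻¹·e⁻² and 12-6 Lennard-Jones
`4ε[(σ/r)¹² − (σ/r)⁶]`; σ_ij and ε_ij follow Lorentz–Berthelot combining
unless the parameter file gives explicit pair values, which take precedence.
Per-frame sums are averaged over the post-burn-in window per replica, then
aggregated with a standard error across replicas.

Deliberate simplifications, documented as systematic differences from
force-field engine rerun energies: plain truncation at the cutoff (no
switching function) and no reciprocal-space/PME long-range term, which
cannot be attributed to individual residue pairs. The relative dielectric is
1 (vacuum-style decomposition), configurable. Only inter-chain pairs are
summed, so intramolecular 1-2/1-3/1-4 exclusions never arise. The intended
use is hot-spot *ranking* across residues and variants, not absolute
enthalpies; entropic contributions are explicitly out of scope. Units are
kJ/mol internally with a kcal/mol display option (÷ 4.184).

## SPR kinetics

Association follows R(t) = R_eq·(1 − e^−(k_on·C + k_off)·t) with
R_eq = R_max·k_on·C/(k_on·C + k_off); dissociation decays as
R(t) = R(t₀)·e^−k_off(t−t₀). The default schedule is 60 s contact and 300 s
dissociation sampled at 1 Hz, with panels at 1000, 500, 250, 125, 62.5 and
31.25 nM. Mass transport, drift and bulk refractive-index steps are not
modelled; per-concentration RMS residuals are attached to every fit so
model violations are visible.

The global fit shares one (k_on, k_off, R_max) across all curves and runs in
log₁₀-parameter space (positivity and conditioning for free), restarted from
8 log-spaced initialisations over k_on ∈ [10³, 10⁶] M⁻¹s⁻¹ ×
k_off ∈ {10⁻³, 10⁻¹} s⁻¹; the lowest-RSS converged solution wins
(Levenberg–Marquardt, ftol 10⁻¹²). Parameter sds come from the
Jacobian-based covariance at the optimum, delta-method-transformed to
natural units; K_D = k_off/k_on is an identity of the result (never refit),
and sd(K_D) uses the full (log k_on, log k_off) covariance. A
single-concentration panel fits but carries an identifiability warning.

## van't Hoff thermodynamics and DSC

ln K_D regressed on 1/T: slope = ΔH/R, intercept = −ΔS/R with
R = 8.314462618 J·mol⁻¹·K⁻¹. The regression is unweighted by default
(optional per-point weights) and the (slope, intercept) covariance is
carried into (ΔH, ΔS). ΔG = ΔH − TΔS = RT ln K_D; its variance is
var(ΔH) + T²var(ΔS) − 2T·cov(ΔH, ΔS), with a covariance-free variant
exposed because "with error propagation" is ambiguous in common usage —
the covariant form is the default and was validated against Monte-Carlo
propagation (10⁴ draws, agreement within 5%). Temperatures are °C in files
and K internally.

T_m,app is the temperature of maximum heat capacity: optional odd-window
moving-average smoothing, global grid maximum (boundary maxima and flat
curves raise a no-peak error), then quadratic refinement through the three
surrounding grid points. Secondary peaks with prominence above 5% of the
signal range set a multi-peak flag, the signature of broad transitions with
shoulders.

## Synthetic-data generators

Every generator is a pure function of its seed and returns machine-readable
ground truth, so recovery tests assert against construction rather than
against a second estimate.

* **Toy complexes** place each planted charged pair in its own spatial slot
  (20 Å apart) with idealized side-chain groups (backbone N/CA/C plus the
  charged-group atoms; guanidinium N at 1.33 Å, carboxylate O at 1.25 Å
  from the representative carbon). Planted representative distances are
  exact; all non-planted charged groups sit ≥ 8 Å apart. The geometry is
  schematic, not force-field quality.
* **The interface stand-in** (`make_interface_standin`) is a synthetic
  eight-residue model of the IFNγR–A6 interface whose side-chain groups are
  placed so that the published crystal contact distances (e.g. K52–D54
  NZ–CG 3.6 Å and NZ–carboxyl-O 2.8 Å, R84–E45 CZ–CD 4.3 Å and group
  minimum 2.9 Å, E27–K98 CD–NZ 8.0 Å) hold exactly by construction. It
  exercises and demonstrates the measurement conventions without the real
  coordinate file; agreement with it shows convention correctness, not
  anything about the true crystal structure beyond the planted values.
* **Trajectories** default to the standard production geometry: 10 000
  frames at 10 ps (100 ns) with 0.5 Å isotropic Gaussian jitter, a typical
  Cα fluctuation scale. Contact occupancy is imposed by an independent
  Bernoulli(p) schedule per contact: in-frames place the pair at 0.8 × its
  threshold, out-frames at 1.5 ×, and the two contact residues are exempt
  from jitter — occupancy of the realized schedule is exact by construction,
  not emergent from a potential. Dissociation is a constant drift velocity
  applied to one chain. Contradictory targets (shared residues, or a contact
  on the drifting chain) are rejected. What this does **not** emulate:
  correlated motions, anharmonicity, solvent, or any physical binding
  free-energy surface — passing recovery tests shows the *estimators* are
  correct, not that real MD data would behave this way.
* **Sensorgrams / KD(T) / thermograms** come from the closed-form models
  above with iid Gaussian (sensorgram), multiplicative log-normal (KD) or
  additive Gaussian (thermogram) noise. The default van't Hoff grid is six
  temperatures spanning 288–310 K, a realistic SPR temperature series.

## Problem sizes

Tests and the acceptance script run at desk scale by design: trajectories of
10²–10³ frames on toy complexes of tens of residues, energy oracles on
≤ 200-atom systems, 50-seed kinetic-recovery sweeps (each a six-curve global
fit of 2 166 points, ~0.1 s). Production-scale MD statistics (three 100 ns
replicas per system) are upstream inputs, not something this package
recomputes; the pipeline accepts such trajectories as multi-model PDB or,
with MDAnalysis installed, DCD/XTC.

## Known limitations

* Energy decomposition omits long-range electrostatics; totals are
  systematically smaller in magnitude than PME rerun energies.
* The Langmuir model excludes mass transport; fits to transport-limited
  data will show structured residuals (reported, not corrected).
* PDB coordinates carry 10⁻³ Å field precision; round-trips are exact only
  to that level.
* The interface stand-in and toy complexes are geometric fixtures; no
  physical conclusions should be drawn from their absolute energies.
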