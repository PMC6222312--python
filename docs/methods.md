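# Methods

## Scope and model

The package computes electrostatic potentials and bond-projected electric
fields at a carbonyl probe inside a protein, from three ingredients: a
classical point-charge engine, a fragment-based assembly of the potential
that can delegate each piece to a quantum-chemistry backend, and the
analytic layer (vibrational Stark conversion, Eyring free energies, linear
correlation, per-group decomposition).

### Classical electrostatics

The potential is an unscreened Coulomb sum over all non-excluded atoms,
`φ(r) = (k/ε_eff) Σ q_j/|r−r_j|`, with the Coulomb constant pinned to the
literal `k = 14.399645 V·Å/e` so test values are bit-stable.  No distance
cutoff and no periodic imaging: trajectories supplied to the engine are
expected to be already imaged, and the physical sum has no cutoff.  The
effective dielectric `ε_eff` defaults to 1.0, the appropriate value when
solvent is explicit; every potential and field scales as `1/ε_eff`.

The probe-bond field is `(φ_C − φ_O)/|r_CO| × 100` MV/cm with evaluation
points optionally displaced `offset` Å from each nucleus toward the bond
midpoint.  The sign convention is literal — no hidden negation — so a field
pointing from O to C is negative, matching how active-site fields that
stabilize a C–O⁻ intermediate are conventionally reported.  The default
exclusion set is the probe C, O and every atom of the ring the carbonyl is
fused to; ring membership is declared by the ligand generator (or the
config), never perceived from geometry.

Time averages are plain means over saved frames.  Group decompositions
require an exact partition of the non-excluded atoms and are exact by
linearity; the "total" entry is always computed independently from the full
sum, so the additivity check is a real consistency test rather than a
tautology.

### Fragment assembly

The protein is cut at every peptide bond and reassembled as capped fragments
(one per interior residue, sign +1), conjugate caps (sign −1) and
generalized-concap two-body corrections for residue pairs in spatial contact
(pair +1, the two hydrogen-capped singles −1), each embedded in the point
charges of the remaining protein and ligand atoms.

Design choices, all isolated behind single functions so alternatives can be
swapped:

* **Cap extent.**  The cap donated by residue i±1 is the minimal backbone
  unit adjacent to the cut: `{CA, C, O}` on the carbonyl side, `{N, CA}`
  (plus amide H where present) on the amide side, with the Cα turned into a
  methyl-like terminus by hydrogen link atoms.  This is the smallest recipe
  for which a conjugate cap's atoms coincide index-for-index (hence
  coordinate-for-coordinate) with the caps of its two adjacent capped
  fragments — the property that makes the signed sum telescope exactly.
  The scheme records the recipe name (`minimal-backbone-v1`).
* **Terminal residues** are absorbed whole into the caps of fragments 2 and
  N−1, forced by the assembly's index ranges (capped fragments i = 2..N−1,
  concaps i = 2..N−2).
* **Link atoms** sit on the cut-bond axis at 1.09 Å from a kept carbon and
  1.01 Å from a kept nitrogen, carry zero charge, and never appear in
  embedding backgrounds.
* **Contact pairs** require sequence separation j > i+2 and minimum
  interatomic distance ≤ λ (default 4.0 Å, all-atom; a heavy-atom-only mode
  is available — all-atom is the conservative reading of an unqualified
  "closest distance").  A bound ligand participates whole as one partner.
* **Embedding backgrounds** contain protein + ligand atoms only by default;
  solvent is handled classically and can be switched in by flag.
* **Fragment charges** are the rounded member-charge sums; deviations
  > 0.01 e from an integer are logged (they only matter for real QM
  backends).

Chains are split at residue-number gaps or chain-id changes; fragmentation
never cuts across a break, and a contiguous run shorter than 3 residues is
an error (the index ranges need interior residues).

### ESP backends

The backend contract is a pure function of the request (fragment atoms +
link atoms + background + points).  The **surrogate** backend returns the
Coulomb sum of the fragment's own partial charges, ignores the background,
and is therefore exactly additive over atoms — which makes the assembled
potential identical to the whole-system Coulomb potential and every
two-body correction identically zero.  That identity is the package's
central oracle: it validates the entire bookkeeping (caps, signs, link
atoms, index ranges) at machine precision, independent of any QM engine.

The **qm** backend is a PySCF adapter: fragment + link hydrogens solved in
the background charge field, full electronic + nuclear ESP at the requested
points, JSON result cache keyed by a content hash of the request
(coordinates rounded to 1e-6 Å).  The documented production settings are
M06-2X/6-31G**; tests pin HF/STO-3G.  Without PySCF installed the backend
raises `BackendUnavailableError` — never a silent fallback — and the full
test suite passes, skipping only the engine-dependent cases.

### Single-snapshot protocol

The fragment calculation runs on one frame: the one whose classical total
field (same exclusions as everywhere else) lies closest to the trajectory's
time average, ties broken toward the earliest frame.  The ligand and solvent
contributions are classical *time averages over all frames*, not the
selected frame's instantaneous values, and are reported separately next to
the assembled protein component.  Off-center evaluation (default 0.1 Å
toward the bond midpoint) is applied to the assembled protein potential and
the classical amendments alike; on near-uniform toy fields a 0.1 Å offset
perturbs the projection by well under 1%, while keeping evaluation points
off basis-function singularities for real QM backends.

### Analytics

* Stark: `shift = −tuning_rate × ΔF`, exact inverse pair with
  `field_from_shift`.  The tuning rate is a user-supplied calibration (cm⁻¹
  per MV/cm); quadratic Stark terms are out of scope, and fields inferred
  from experimental spectra via the linear relation may carry a ~10%
  overestimate — reports carry this as a footnote rather than a correction.
* Eyring: `ΔG‡ = −RT ln[k_cat/(k_B T/h)]` with R = 1.987204×10⁻³ kcal/(mol·K),
  SI-exact k_B and h, T = 293 K default.
* OLS via `scipy.stats.linregress`; R² is the squared Pearson r (equal to
  the coefficient of determination for simple regression), rounded only at
  presentation.
* Contribution percentages round half-away-from-zero to integers, matching
  the granularity such decompositions are reported at.

## Synthetic data: what it emulates, what it does not

The generators stand in for the sampling that molecular dynamics would
provide, with ground truth known by construction:

* **Toy polypeptide** — rigid 5-atom residues (N, CA, C, O, side-centroid
  CB; named ALA so file round-trips preserve segment classification) on an
  extended, helix-like or hairpin backbone with a 3.8 Å repeat and 1.33 Å
  peptide bonds.  Designed per-residue net charges ride on CB and are
  recovered exactly by summation.  The extended geometry keeps residues i
  and i+3 more than 4 Å apart (no contact pairs at the default λ); the
  hairpin places facing-strand residues ~2–4 Å apart to exercise the
  two-body terms.
* **Probe ligand** — a 1.23 Å C=O, optionally fused to a neutral hexagonal
  ring plus two charged tail atoms; the ring + C + O (8 atoms) form the
  canonical exclusion set, while the tail gives the classical ligand
  amendment something nonzero to report.
* **Trajectories** — i.i.d. Gaussian jitter per atom per frame; optionally
  one designed donor–acceptor distance drawn per frame as bound/broken with
  probability `p_bound` (independent frames).  Independence makes occupancy
  estimators exactly binomial, giving sharp test bounds (±0.02 at
  p = 0.7, 5000 frames is the 3σ band).  Defaults: 8 residues,
  r_bound = 2.8 Å, r_broken = 5.2 Å, p_bound = 0.7, jitter chosen per test
  so that the second-order 1/r jitter bias stays well inside the sampling
  band.  All streams are seeded; a global seed derives per-stream seeds by
  fixed offsets.
* **Field benchmarks** — scenes with closed-form fields: a single +1 e
  charge (probe field k(1/3 − 1/4) × 100 ≈ 120.0 MV/cm), a symmetric dipole
  (zero at the midplane), and a discrete parallel-plate capacitor.  The
  capacitor geometry (half-width 25 Å, gap 0.6 Å, 0.15 Å lattice) was chosen
  so the infinite-sheet formula E = σ/ε₀ applies at the center to within 2%
  (measured edge effect ≈ 1.1%).

What the toys do **not** emulate: real force-field energetics or dynamics
(frames are not Boltzmann-distributed and have no autocorrelation), solvent
boxes, rotamers, hydrogen-rich backbones, or polarization.  Passing tests
therefore validate the *arithmetic and statistics* of the protocol — ESP
sums, fragment bookkeeping, averaging, occupancy estimation, selection and
regression — not the physical accuracy of any force field or QM method on
real proteins.

## Numerical choices and degenerate inputs

* Singularity guard: evaluation points must be > 1e-6 Å from any included
  source atom (1e-3 Å from fragment nuclei in backend requests); violations
  name the offending atom.
* Probe offset must satisfy 0 ≤ offset < |r_CO|/2.
* `FieldRecord` enforces `field = (φ_C − φ_O)/length × 100` to 1e-9 relative
  at construction, so inconsistent records cannot circulate.
* Snapshot selection uses `argmin`, which returns the first minimum —
  the earliest-frame tie rule for free.
* PQR is written with 6 decimals (round-trips to 1e-6); PDB with the
  fixed-width 3-decimal convention.  Alternate locations other than 'A' are
  dropped and logged.
* Assembly order independence holds to ~1e-14 relative (floating-point
  summation order), and the telescoping identity is asserted at 1e-10
  relative with two-body corrections < 1e-12 V.

## Problem sizes

Test and acceptance runs use toy systems of 3–16 residues, trajectories of
up to 5000 frames for occupancy statistics and ≤ 10 frames where full field
series are computed per frame, 20 random peptides for the telescoping suite,
1000 random series for selection, and n = 200 points for OLS recovery —
sizes at which every oracle (brute force, closed form, binomial bounds) is
exact or sharp.

## Known limitations

* The classical engine has no reaction field, Ewald summation, or induced
  polarization; the surrogate backend has none by design.
* Cap chemistry is one recipe among several used in the fragmentation
  literature; alternatives that enlarge caps would need their own concap
  pairing to preserve the telescoping identity.
* The QM adapter computes ESP values only (no energies, gradients or charge
  fitting) and assumes closed-shell singlet fragments.
* Trajectory I/O is multi-model PDB only; binary trajectory formats are out
  of scope at desk scale.
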