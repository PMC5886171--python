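# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the limitations a user should keep in mind.

## Coordinate model and conventions

Structures are read through gemmi (PDB and mmCIF) into a small hierarchy
(model → chain → residue → atom). Two conventions are fixed deliberately:

* **Author residue numbering is the only numbering.** All gelsolin
  literature speaks in mature-plasma-protein numbers (Gly167, Asp187,
  Asp259); renumbering would make every reported range ambiguous.
  Residue ranges are inclusive on both ends, so 158–166 is nine residues.
* **Alternate locations are collapsed at read time** to the
  highest-occupancy conformer (ties keep the first encountered), so every
  downstream geometric metric is a deterministic function of the file.

Hydrogens are never required: contacts, SASA and H-bonds all operate
heavy-atom-only, matching what a typical ~1.7 Å crystal structure provides.

Sequence masses use average isotopic residue masses (Biopython's tables)
minus one water per peptide bond, reported in kDa. The mature plasma
gelsolin reference is residues 26–782 of the precursor; an N-terminal
purification tag, when present, is extra mass to be accounted separately.

## Swap detection

A 3D domain swap is read from contact topology. A residue contact exists
when any heavy-atom pair sits within **4.5 Å** (the common residue-contact
convention; no value is prescribed by the source data). Each residue is
scored

    score = (# inter-chain contacts) − (# non-local intra-chain contacts),

where intra-chain contacts between residues fewer than 3 apart in sequence
are discarded — sequence neighbours touch regardless of fold and carry no
packing signal. A terminal run of inter-dominant residues (score > 0) of
length ≥ `min_segment` (default **4**, small enough to find short exchanged
elements, large enough to suppress single-residue noise) is a swapped
segment; contactless/tied residues at the very terminus are absorbed into
it, since they dangle outside any core. The ambiguous stretch (score = 0)
between the swapped run and the first intra-dominant residue is the hinge —
ties deliberately label as hinge because the hinge is, by construction, the
connector whose packing is mixed. The assembly counts as swapped only when
*both* chains donate a segment.

Interface classification follows the open/closed-monomer nomenclature: an
inter-chain contact is **O-interface** when either partner belongs to a
swapped segment or hinge (it reconstitutes packing the closed monomer has
internally), and **C-interface** otherwise (a genuinely new core–core
contact between the closed-monomer-equivalent units). For a pure swap with
no secondary interface the C count is zero.

Monomer reconstruction emits, per subunit, the *open monomer* (the full
polypeptide chain in dimer coordinates, core plus its donated segment) and
the *closed composite* (the chain's core and hinge plus the partner's
donated segment — the folded monomer-equivalent unit). Overlapping residue
numbers between core and donated segment are an error: the composite must
be indexable as one monomer.

## Surface areas

SASA is Shrake–Rupley with a **deterministic golden-spiral lattice**
(default **960** points, probe **1.4 Å**): per atom, lattice points on the
probe-expanded sphere are marked buried if inside any neighbour's expanded
sphere; the accessible fraction times the sphere area is the atom's SASA.
A deterministic lattice was chosen over random sampling so that the
table-level area numbers are bit-reproducible; doubling the lattice changes
totals by well under 1%, and the analytic one-sphere and two-sphere-cap
results are reproduced to sampling tolerance in the tests. Radii are an
element-keyed NACCESS-flavoured set (C 1.76, N 1.65, O 1.40, S 1.85 Å …),
configurable because published interface areas vary by a few percent across
radii conventions.

Two interface areas are reported per subunit:

* **buried interaction area** = SASA(open monomer) − SASA(closed monomer),
  both isolated — the exposure cost of the swap-extended conformation;
* **total interaction surface** = SASA(subunit isolated) − SASA(subunit in
  the complex) — the classical ΔSASA on complexation, the quantity
  interface servers (PISA-style) report per subunit. Whether a given
  published "interaction surface" is exactly this ΔSASA or a related field
  is not always stated; this package implements the ΔSASA convention and
  says so.

Waters are excluded from all interface metrics; hetero ligands (Ca²⁺,
citrate) enter only when explicitly selected.

## Hydrogen bonds and salt bridges

Heavy-atom criteria: N/O donor to N/O acceptor within **3.5 Å**, with the
angle at the donor between its covalent antecedent and the acceptor ≥
**90°** standing in for the unresolved hydrogen (the antecedent is the
nearest same-residue heavy atom). Salt bridges are contacts between
positively charged groups (Arg NE/NH*, Lys NZ, His ND1/NE2) and
carboxylate/C-terminal/citrate oxygens within **4.0 Å**; they are flagged
within the H-bond list and count even at 3.5–4.0 Å. These are common
literature criteria, exposed as configuration because any published count
depends on them. Unknown residue types are skipped with a warning rather
than failing the run.

## Superposition, dihedrals, coordination, trajectories

Kabsch superposition (SVD with determinant correction) always returns a
proper rotation; mirror solutions are rejected by construction, and
degenerate (collinear) point sets raise instead of returning an arbitrary
axis. Inter-structure correspondence is by author residue number over the
intersection of modeled residues, minus user-supplied masks — this is how a
"0.40 Å over 79 Cα" style number is produced: mask the hinge loop and any
disordered terminus, pair what remains. The hinge mask is a configuration
input, not a constant, because the hinge has been delimited both as 167–171
(contact-based) and 168–172 (superposition mask) in the gelsolin
literature; both must be expressible.

Backbone φ/ψ follow the IUPAC sign convention (cross-checked against
Bio.PDB in the tests). Ramachandran classification uses coarse rectangular
regions — favored/allowed for general residues plus the positive-φ extended
strip (φ ≈ 45–180°, |ψ| ≳ 110°) that only glycine occupies. The maps are
deliberately qualitative: their job is to support statements like "this
hinge conformation is accessible only to glycine", not to reproduce any
particular contour set, and they are configurable.

Metal coordination lists O/N atoms within a cutoff of the metal (default
**3.0 Å**, the standard Ca–O coordination distance), separating protein
from hetero ligands (e.g. a citrate completing a calcium site). Trajectory
r.m.s.d. over multi-model files superposes each frame on the reference by
default (the MD convention), with a flag to disable.

## Solution-state analyses

* **Chromatograms.** Species are quantified as trapezoidal peak areas over
  labeled, non-overlapping elution-volume windows, as fractions of the
  total over all windows. A straight baseline through each window's
  endpoints is subtracted by default; integration details are otherwise
  unspecified in typical reports, so the baseline is a documented choice.
* **DLS calibration.** Dimer fraction is linear in R_H between the monomer
  (2.0 nm) and dimer (3.0 nm) references, clamped to [0, 1]; readings more
  than 3 reference standard deviations (0.3 nm) outside warn. The clamp
  introduces a small downward bias in refitted rates when noise pushes
  early points below the monomer radius — visible as mean recovered rates
  a few percent under the generating value, well inside the experimental
  uncertainties being compared against.
* **Kinetics.** f(t) = f∞ − (f∞ − f₀)e^(−kt), time in hours, k in h⁻¹.
  Initialisation: k from a log-linear transform of the early points, f∞
  from the final observation; bounded least squares (k ≥ 0, fractions in
  [0, 1]) with fallback starts; a rate pinned at zero is flagged. The
  first-order form is the conventional empirical description of a slow
  conformational-gating dimerization; an explicit second-order association
  model is not offered because the underlying rate law cannot be
  discriminated without raw concentration series.
* **Equilibrium.** 2M ⇌ D with K_d = [M]²/[D] and conservation
  [M] + 2[D] = C. The dimer mass fraction has the closed form
  2[D]/C with 4D² − (4C + K_d)D + C² = 0; at C = K_d the fraction is
  exactly ½. K_d is fit in log space (positivity, scaling); mg/ml inputs
  convert through a configurable monomer mass (G2 domain ≈ 13 kDa).
* **Melts.** T_m is the maximum of |d(signal)/dT| after Savitzky–Golay
  smoothing (window 9, order 2 — the smoothing used by instrument software
  is rarely reported, so this is a package choice). Peaks must be separated
  by ≥ 3 °C and reach ≥ 5% of the strongest peak's prominence, so a single
  broad transition is never split and smoothing ripple is never promoted to
  a transition; each peak is refined by a least-squares parabola over ±3
  grid points. The result is invariant under affine rescaling of the
  signal, and shifts < 0.2 °C under ±2-point window changes on standard
  fixtures.

## Synthetic data: what it emulates, what it does not

The toy swapped dimer is a *contact-topology* model: poly-alanine backbones
(N, CA, C) on an idealized β-sheet lattice, with each chain's N-terminal
strand packing into the partner copy's slot and an elevated hinge bridge
kept clear of all other atoms. Spacings are tuned so a slot residue touches
exactly one partner-core residue, a core residue touches three same-chain
residues, and hinge residues touch nothing non-local at the 4.5 Å cutoff —
the clean signature the detector is specified to read. Generated
assemblies are verified clash-free (no non-bonded heavy atoms below 2.0 Å)
and are bitwise-deterministic per seed. The toy has no side chains, no
realistic bond geometry along the hinge, and no crystallographic context;
passing its tests shows the detection, classification, reconstruction and
area machinery is correct on unambiguous topology, not that real structures
with marginal segments or noisy interfaces will be equally clean.

Curve generators (chromatograms as sums of Gaussians at the
monomer/dimer/degradation-product elution volumes 13.5/11.5/12 ml; DLS time
courses as the inverse calibration of the first-order model; melts as
logistic transitions) use additive Gaussian noise throughout. That is
sufficient for parameter-recovery statements but makes no claim about real
instrument noise (baseline drift, heteroscedastic detectors, peak tailing).
Kinetic fixtures default to f₀ = 0 and f∞ = 0.5, reflecting a transition
started from isolated monomer that equilibrates near a 50:50 mixture.

## Problem sizes in the shipped checks

The replicate counts used by the test suite and the acceptance script —
100 seeded time courses per kinetic condition (12 points over 0–4 h for
the fast rate, 0–8 h for the slow one, 0.05 nm noise), 50 melt replicates
at 1% noise, 50 K_d replicates at 5% noise — were chosen so that the mean
estimator's sampling error is several times smaller than the experimental
uncertainties they are compared to, while a full run stays in the
seconds-to-minutes range.

## Known limitations

* Swap detection assumes exactly two polypeptide chains; runaway
  (>2-chain) swaps and swap-propensity prediction are out of scope, as are
  crystallographic symmetry expansion, secondary-structure assignment and
  any re-refinement of deposited models.
* The SASA-based areas depend at the few-percent level on the radii set
  and lattice density; comparisons against published tables should quote
  the parameters used (the report's provenance block records them).
* H-bond counts are criterion-dependent by nature; the defaults are
  reasonable, not canonical.
* The checks that run on deposited structures require those files (fetched
  or pre-downloaded); all other tests are self-contained.
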