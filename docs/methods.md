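# Methods

## Model and definitions

`hbnet` analyses instantaneous configurations (snapshots) of rigid
four-site water in an orthorhombic periodic box. All inter-molecular
geometry uses the minimum-image convention, so wrapped and unwrapped
coordinates are equivalent; every analysis begins by checking that the
largest cutoff is below half the smallest box length. Triclinic cells
are rejected.

**Bond network.** Edges are unordered oxygen pairs with minimum-image
distance strictly below `r_max` (default 3.2 Å). Strict inequality is
used for every cutoff; boundary-equal distances are excluded. Neighbor
candidates come from a periodic k-d tree, after which distances are
recomputed with the package's own minimum image and filtered, so the
pair set is exactly that of the quadratic all-pairs scan (asserted in
tests against the brute-force implementation).

**H-bond criterion.** ∠H–O···O is evaluated at the donor oxygen
between the covalent O–H vector and the donor→acceptor O···O vector.
Both molecules of a pair are tried as donor and both hydrogens as the
bonded H; the minimum of the four candidate angles decides the pair
label, and a pair contributes at most one H-bond no matter how many
candidates pass. Rationale: pairs, not directed bonds, are classified,
which keeps N(H-bonds) ≤ N(O–O). Defaults: `r_max` = 3.2 Å,
`angle_max` = 30°, `r_short` = 2.76 Å. Pairs under `r_short` that fail
the angle criterion are labelled non-bonded but counted separately as
a diagnostic. The angle histogram uses the per-pair minimum angle by
default; an `all_candidates` option histograms all four angles.

**Pair energy.** The direct (non-Ewald) two-molecule sum: one
Lennard-Jones term between oxygens and nine Coulomb terms between the
two hydrogens and the M-site of each molecule. This is a two-body
quantity; the lattice-summed electrostatics of the generating
simulation are out of scope. The M-site is always reconstructed on the
H–O–H bisector at d(OM) = 0.1546 Å from the oxygen (input M-sites, if
present, are validated against the reconstruction and replaced, for
model consistency). TIP4P/2005 constants: r(OH) = 0.9572 Å,
∠HOH = 104.52°, q_H = 0.5564 e, q_M = −1.1128 e, σ = 3.1589 Å,
ε = 0.1852 kcal/mol, k_e = 332.0636 kcal·Å/(mol·e²). The partner
molecule is shifted rigidly to its nearest periodic image before the
site sum, so molecules are never split across images.

**Structural heterogeneities.** Connected components of the graph
whose edges are short H-bonds, keeping components with at least
`size_min` = 5 molecules (groups of 2–4 are not counted). The
inclusive ≥ 5 convention follows the size table having a 5-row and the
exclusion rule naming only 2, 3, 4; `size_min` is a flag. Components
are computed on the periodic-image-resolved edge set, so a component
may wrap the box; unwrapping happens only in the PDB export. Size
tables count components of exactly size S; a cumulative ≥ S variant is
exported separately. The mean short-bond participation is reported
with two normalisations: per all molecules (2·E(SH)/N(mol), the
headline number) and per SH member, since "per molecule in the SH" is
ambiguous in general.

## Dimer energy surface

U(R, angle) scans the two-molecule energy: the donor tilts one O–H off
the O···O axis by the scan angle (rigid rotation of the whole
molecule, in-plane); the acceptor sits at distance R in a fixed
canonical near-minimum arrangement — H–O–H plane perpendicular to the
donor plane, bisector in the donor plane at `acceptor_tilt` (default
52°) from the axis, hydrogens pointing away from the donor. The exact
acceptor convention is a documented, configurable choice; it is
reported in the scan metadata. Per-angle minima are refined by bounded
scalar minimisation (tolerance 1e−4 kcal/mol) after grid bracketing.

With this construction the per-angle minimum stays below −3 kcal/mol
for every angle under 30° and its depth decreases monotonically with
angle. A caveat this package makes explicit: a rigid scan with a
favourably oriented fixed acceptor retains residual dipolar attraction
of ≈ 1–2 kcal/mol at angles of 45–60°, so the attractive interior
minimum does not vanish entirely at large angles; complete
disappearance would require partners whose overall orientation
decorrelates along with the angle, as happens for pairs sampled from
a liquid but not in a two-body scan.

## Synthetic generators

All generators are pure functions of their parameters (same seed ⇒
bit-identical frames).

* **Ice Ih.** Oxygen sublattice from the 8-molecule orthorhombic cell
  (a, a√3, c) of the hexagonal (lonsdaleite) lattice; fixture defaults
  a = 4.5181 Å, c = 7.3560 Å give a nearest O···O of ≈ 2.76 Å. Proton
  assignment satisfies the Bernal–Fowler ice rules by construction: an
  Eulerian circuit of the 4-regular O–O graph yields an orientation
  with out-degree 2 everywhere (each O donates exactly two bonds, each
  link hosts exactly one H); seeded random loop reversals — which
  preserve all out-degrees — then disorder the protons. No claim of
  equilibrium proton-disorder statistics is made. Hydrogens are placed
  with the molecular bisector along the bisector of the two donated
  bond directions; because ∠HOH (104.52°) is below the tetrahedral
  angle, each O–H tilts ≈ 2.5° off its O···O axis, safely inside the
  [0°, 10°] band expected for ice. An independent geometric audit
  (one hydrogen per link, within 15° of the link axis) runs in tests
  on every generated frame. Nearest-neighbour pairs sit at 2.76 Å
  — at, not under, the short-bond cutoff — so ice frames contain no
  short H-bonds, consistent with `r_short` being defined *as* that
  distance.
* **Dimer.** Donor at the origin (exact requested O···O distance in
  floating point), acceptor as in the scan convention above; box at
  least 10·R so the minimum image is trivial.
* **Liquid-like.** Ice supercell rescaled isotropically to a requested
  mass density (default 0.997 g/cm³), rigid per-molecule Gaussian
  translations (default σ = 0.12 Å, a mid-liquid disorder level), and
  uniform random rotations applied to a seeded subset of molecules.
  Rotations break the angle criterion, so the realized fraction of
  network pairs that are short H-bonds decreases with the rotated
  count; when a target fraction is requested the count is tuned by a
  coarse-to-fine scan until the realized fraction is within ±2 %
  (absolute) of the target, per frame, with an error (including the
  search history) if the target is infeasible. The generator provides
  controllable *statistical* structure only: it reproduces neither
  TIP4P/2005 thermodynamics nor energetic realism (noise can create
  compressed contacts with positive pair energies that real liquid
  water would relax away). Passing tests on these fixtures therefore
  demonstrate correctness of the bookkeeping — distances, angles,
  labels, components, conservation laws — not agreement with real
  water; liquid-state numbers require real MD trajectories.
* **Planted components.** Chains of molecules 2.70 Å apart with the
  donor O–H on the chain axis (every link a short H-bond), one chain
  per grid row, rows 4 Å apart, filler molecules isolated at ≥ 4 Å; no
  unplanned pair can pass the short criterion, giving exact ground
  truth for component detection.

## Averaging conventions

Per-frame series are summarised by the arithmetic mean and the
*population* standard deviation (a flag switches to the sample
estimator) over an inclusive time window. The default window is
250–1000 ps when the trajectory covers it — the equilibrated interval
of nanosecond NPT water runs — otherwise the second half of the
trajectory with a logged warning. Histograms are time-averaged
per-frame counts on left-closed, right-open bins whose edges are
anchored at zero (so 2.76 falls in [2.76, 2.77)); default bin widths
are 0.01 Å for lengths, 1° for angles, 0.1 kcal/mol for energies.

## Numerical choices and degenerate inputs

* Minimum image via d − L·floor(d/L + ½), each component in
  [−L/2, L/2); exact agreement with the 27-image brute force is a
  test invariant.
* Rigidity validation warns rather than aborts (dump files truncate
  coordinates); default tolerances 1e−3 Å and 0.1°.
* Coincident oxygens or overlapping charged sites (< 1e−6 Å) raise;
  frames with zero qualifying short bonds record the mean short-bond
  energy as missing (NaN), not zero.
* Frames are processed independently and streamed (bounded memory);
  results do not depend on processing order.
* Molecule assembly from atom records prefers explicit molecule ids
  and falls back to nearest-oxygen assignment within 1.2 Å, with a
  warning.

## Problem sizes used in tests

The test suite and acceptance script run on desk-scale inputs chosen
as the package's own verification conditions: ice supercells of 64
molecules, liquid-like fixtures of 96 molecules and 2–5 frames, random
frames of up to 500 molecules for oracle-equivalence checks, and a
0.01 Å × 1° dimer grid. These sizes exercise every code path
(including periodic wrapping and component detection) while keeping
the full suite under a minute.

## Known limitations

* Geometric H-bond criterion only; energy-based and hybrid criteria,
  and H-bond lifetime analysis, are out of scope.
* No Ewald/lattice electrostatics; pair energies are two-body.
* SHs are detected per frame; component identity is not tracked across
  frames.
* Orthorhombic boxes only; water only (one O, two H per molecule).
* The liquid-like generator is a statistical stand-in, not a
  thermodynamic model (see above).
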