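# Methods

This note records the model, the numerical choices and the limitations
behind `efmoscan`, in the order the method runs.

## Fragmentation and the interfragment metric

Fragments are one residue or one water each. Covalent bonds between
fragments are never cut: the boundary atom is *shared* — it appears in
both fragments' rosters, is owned (for charge bookkeeping) by the
fragment of its own residue, and is counted once in the partition
identity `Σ|fragment| − #shared = #atoms`. For peptides the boundary is
placed at the Cα–C(carbonyl) bond with Cα shared, so the carbonyl group
migrates to the following fragment; for any other inter-residue bond the
atom in the earlier fragment is shared into the later one. Both
electrons of the severed bond go with the fragment that keeps the
boundary atom's residue; net charges are integers per fragment and the
mock backend distributes each fragment's charge uniformly over its
sites after per-element base charges are assigned.

The near/far classification uses the unitless
`R_IJ = min over atom pairs of r_ij / (Rvdw_i + Rvdw_j)` (Bondi radii),
shared atoms excluded; covalently bonded fragment pairs are always
treated as near pairs. Defaults: `R_resdim = 1.5`; bond detection uses
`1.2 × (r_cov,i + r_cov,j)` with Pyykkö covalent radii. The radius
tables live in `constants.py`; unit conversions come from
`scipy.constants` (CODATA), and everything inside the energy machinery
is hartree/bohr, with Angstrom only at the user/file boundary.

## Backend contract and the mock model

An electronic-structure engine must provide monomer energies/gradients,
dimer energies/gradients, and distributed multipoles/polarizabilities at
the (owned) atomic sites, in hartree and hartree/bohr. Bond detachment
is the engine's business: the shipped mock engine uses hydrogen link
atoms placed at 1.09 Å along each severed bond, with the cap's gradient
chain-ruled back onto the two real atoms. A frozen-bond-orbital engine
would need no caps; the contract does not assume them.

The mock potential is harmonic bonds (k = 0.5 hartree/bohr², r₀ = sum of
covalent radii) + harmonic angles (k = 0.1 hartree/rad²; 104.52° at
oxygen centers, 109.47° elsewhere) + Lennard-Jones (ε = 3·10⁻⁴ hartree,
σ = 3 bohr) and Coulomb terms over all pairs separated by three or more
bonds. Base charges are O −0.8, H +0.4, C 0.0, N −0.4 e, neutralized per
fragment; reported multipoles are exactly these point charges, and the
`mock-pol` variant adds small isotropic site polarizabilities (H 0.4,
O 0.8, N 1.0, C 1.2 bohr³ — deliberately below the polarization-
catastrophe threshold for bonded site distances, since the bare dipole
tensor is undamped). All constants sit in one versioned table
(`MOCK_CONSTANTS`).

Two deliberate conventions make the mock backend exact where the theory
expects exactness:

* the mock potential is strictly pairwise-additive between molecules, so
  EFMO with all pairs near reproduces the supermolecule energy to
  machine precision — the assembly itself adds no error;
* in dimer calculations, link-atom caps interact only within their own
  fragment. Without this, a buffer-buffer dimer correction would depend
  on mobile active-region atoms through cap positions, and the identity
  "buffer dimers contribute nothing to the active gradient" would hold
  only approximately. With it, the identity is exact.

Monomer/dimer/moment results are cached by roster and coordinates;
counters record actual evaluations so tests can audit which QM calls a
frozen-domain energy issued.

## Electrostatics and polarization

Far pairs interact through atom-centered charges, dipoles and traceless
Cartesian (Buckingham) quadrupoles via the standard interaction-tensor
bilinear form through T⁽⁴⁾. Raw second moments are converted to the
traceless form at ingestion. Gradients follow the frozen-moment
convention (moments are geometry-independent within a step, matching the
once-per-step moment evaluation); they are evaluated by complex-step
differentiation of the pair energy — the expression is holomorphic in
the site coordinates, so the imaginary-step derivative is exact to
machine rounding and is verified against central differences in the
tests. Charge-only sets (the mock case) take a closed-form Coulomb fast
path. There is no damping or switching at the `R_resdim` boundary: the
QM-dimer/classical split is a hard cutoff, and the resulting
discontinuity in R is accepted (for the mock model it is exactly the
far-pair LJ term; see Limitations).

Induced dipoles solve `μ_i = α_i (F_static,i + Σ_{j≠i} T_ij μ_j)` with
the bare point-dipole tensor, no Thole damping. A site is not polarized
by its own fragment's permanent moments; mutual induced coupling spans
all sites. Up to 300 sites the coupled equations are solved densely;
beyond that a fixed-point iteration runs with divergence detection that
names the closest site pair (a polarization catastrophe is reported, not
damped away). `E_pol = −½ Σ μ_i·F_static,i`; the pair quantity
`E_pol,IJ` uses the isolated dimer's sites and sources only, and the
total uses every fragment — including the frozen region. Polarization
*gradients* use central finite differences of `E_pol` (h = 10⁻⁵ bohr);
analytic response gradients are out of scope, and with the default α = 0
mock the term vanishes and is skipped.

## Frozen-domain assembly

Regions are assigned by minimum atom–atom distance (all atoms, H
included) from the target fragments: active within `R_active` (default
2.0 Å), buffer within `R_buffer` (default 2.5 Å) of any active atom,
frozen otherwise. A shared atom is mobile only when *both* owning
fragments are active; individual extra atoms inside A can be pinned
(anchors). An active fragment covalently bonded to a frozen one is a
configuration error — the classical treatment of A–F couplings needs
separation. Bonded buffer–frozen pairs are constants (both sides frozen)
and are omitted rather than evaluated classically, which would be
singular at the shared atom.

The FD energy keeps A∪b monomers, QM dimers within A∪b (near pairs),
classical ES for far pairs and for every pair with one member in F, and
`E_pol,tot` over the whole system; F-internal terms are dropped as
constants. FDD additionally drops near buffer–buffer dimer corrections;
`E_FDD − E_FD` equals minus their sum identically, and FD/FDD gradients
on active atoms are identical (both identities are asserted in the
tests). Frozen-region multipole and polarizability *values* are cached
at the first evaluation of an optimization session; site positions track
the current coordinates, so moving F atoms changes classical terms
without new QM calls. The gradient skips terms that cannot touch a
mobile atom (exactly, by the cap convention above) and zeroes frozen
rows.

## Path scanning

`R = r(bond1) − r(bond2)` (breaking minus forming; negative at the
reactant). The scan steps R in 0.1 Å increments; the two bond targets
advance symmetrically (±0.05 Å per step) along the line anchored at the
reference bond lengths, which default to the starting geometry's — a
backward scan should pass the forward scan's anchor so both directions
sample identical restrained objectives. Each step minimizes
`E_FD(D) + ½k Σ (r_m − t_m)²` (k default 500 kcal mol⁻¹ Å⁻²) over the
mobile Cartesians with L-BFGS, converged when the maximum absolute
gradient component is ≤ 5·10⁻⁴ hartree/bohr (≤ 200 iterations; an
unconverged frame is flagged and propagates — barrier statistics refuse
flagged paths). Frames store the unrestrained energy and the penalty
separately; profiles exclude the penalty. Stored R is recomputed from
the optimized geometry, so it lags the targets wherever the potential is
stiffer than the restraint — with the mock model's unbreakable harmonic
bonds the realized R saturates near +0.3 Å although targets run to
+1.5 Å. A scan is resumable from the converged frames of a previous
path (a provenance hash over the settings and target anchor guards
against drift), and a region report can be fed back verbatim to pin the
same region assignment across every step and run.

The toy reaction used for scan validation is an anchored proton-transfer
core (C1–C2–H…O–C3; C1 and C3 frozen anchors standing in for the
scaffold of an enzyme pocket; the acceptor group carries −1 e) in a
two-shell water environment placed so the near shell lands in the buffer
and the far shell in the frozen region under the toy's canonical radii
(2.0/3.5 Å; the wider-than-default buffer radius is this system's study
condition so the shell classification is orientation-proof). The
generator energy-minimizes the reactant's core orientation at the exact
reactant bond lengths with a deterministic multi-start search — the desk
analog of energy-minimizing a truncated enzyme model before scanning —
and redraws the solvent shell if the relaxed core would pull a water
inside the active radius.

The independent reference for a scan is a per-step brute-force search of
the same restrained objective: a dense (r1, r2) grid with both bond
lengths fixed exactly and the remaining core degrees of freedom relaxed,
whose best point seeds a fresh restrained minimization. This certifies
that the warm-started scan found the global restrained minimum at every
step without inheriting its continuation path. Residual scan-vs-grid
barrier differences of 0.02–0.17 kcal/mol across seeds are the
convergence slack of the 5·10⁻⁴ hartree/bohr criterion on soft
orientational modes, not basin disagreements.

## ONIOM and ensemble statistics

ONIOM refinement is strictly the subtractive two-layer scheme applied to
single-point energies; the model region is extracted with the same
capping rule as the backend and computed in the gas phase (no
environment multipoles). Geometries, frame order and counts are
preserved bit-exactly; barriers are invariant under constant shifts of
either level. Multilayer EFMO single points (high-level active region)
go through `assign_layers` instead, with mixed-layer pairs computed at
the lower layer.

Over an ensemble, the activation enthalpy is estimated two ways: the
mean of the per-path barriers (each `max_R E − min_{R<0} E`) with its
sample sd and `sd/√N`, and the barrier of the pointwise-mean profile.
The first dominates the second (max/min do not commute with averaging);
the gap is reported as a transition-state-alignment diagnostic. The
ZPE/thermal correction (default 1.6 kcal/mol) is *subtracted* from the
electronic barrier — the sign is an interpretation, exposed as a signed
configurable value. Paths sharing the scan grid average exactly;
differing grids are linearly resampled onto their common overlap.

## What the synthetic systems do and do not show

The generators emulate the *structure* of a solvated-enzyme study —
residue-granular fragments, shared covalent boundaries, a charged
reactive core held by a scaffold, buffer and frozen solvent — at sizes
of 5–30 fragments. Water clusters default to liquid density (30 Å³ per
molecule) with a 2.6 Å minimum O–O separation. What passing tests show:
the EFMO/FD/FDD assembly, gradients, bookkeeping, scanning and
statistics are internally exact and agree with independent oracles on
these systems. What they do not show: accuracy of the mock potential as
chemistry (harmonic bonds cannot break, so toy "barriers" are dominated
by bond stretch and are ~100 kcal/mol), behavior of real SCF backends
(basis sets, frozen bond orbitals, electrostatic penetration), or
convergence properties at thousands of atoms.

## Known limitations

* The far-pair classical treatment carries no dispersion: with the mock
  constants, the EFMO-vs-supermolecule error of a 5-water cluster at
  `R_resdim = 1.5` is ~10⁻⁵ hartree and is exactly the far-pair LJ sum;
  it decreases monotonically with the threshold and vanishes when every
  pair is near. Real EFMO has the same structure (no dispersion in the
  multipole term at any printed threshold).
* Frozen-moment ES gradients omit moment-response terms; exact for the
  mock (geometry-independent moments), approximate for real backends.
* Polarization gradients are finite-difference; cost grows with the
  mobile-atom count and dominates for large buffers with polarizable
  sites.
* The restrained scan resolves barriers to roughly the convergence
  slack of the gradient threshold (~0.1 kcal/mol at 5·10⁻⁴
  hartree/bohr); hysteresis between forward and backward scans on the
  toy surface is below 0.5 kcal/mol per frame but nonzero.
* No Ewald/periodic electrostatics, no charge-penetration or
  exchange-repulsion terms, no transition-state refinement beyond the
  restrained scan.
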