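# Methods

## Model and procedure

`hamr` phases a flexible small molecule against measured structure-factor
amplitudes by combining rigid-body molecular replacement (MR) with a
genetic algorithm (GA) over the molecule's non-ring torsions.

**Structure factors.** Direct summation over atoms and symmetry operators,

    F(h) = Σ_s Σ_a f_a(s_h) · exp(−B s_h²) · exp(2πi h·(R_s x_a + t_s)),

with s = sinθ/λ = 1/(2d).  Electron scattering factors use the standard
5-Gaussian parameterization (International Tables C, 4.3.2.2), resolved
per element through gemmi; supported elements are H, C, N, O, F, P, S, Cl,
Br, I.  The isotropic displacement convention is exp(−B·(sinθ/λ)²) —
conventions in the field differ by factors of 4, so this is stated
explicitly.  A single overall B is used during the search (per-atom ADPs
are a refinement-stage concern and out of scope).  No solvent model of any
kind is applied.  Direct summation rather than an FFT density route was
chosen because small molecules (<200 atoms, <10⁴ reflections) make the
O(atoms × reflections) sum essentially free and avoid grid/sampling
decisions.

**Scaling and statistics.**  (k, B) minimizing Σ(|Fo| − k e^{−Bs²}|Fc|)²
are fitted by a log-linear Wilson-style regression followed by a
Levenberg–Marquardt polish, on working-set reflections only.
R = Σ||Fo| − k e^{−Bs²}|Fc|| / Σ|Fo|; the pre-filter R used inside the GA
is this scaled working-set R (the R reported by the upstream MR program it
replaces is not specified anywhere, so the package defines its own,
consistently).  Pose quality is measured by the Pearson correlation CC of
amplitudes, reported as `llg_like = −(N/2) ln(1 − CC²)` — the exact
log-likelihood gain of a one-parameter linear Gaussian amplitude model,
parameter-free, monotone in |CC| and N-scaled like a true MR LLG.

**MR search.**  Orientations come from a super-Fibonacci low-discrepancy
quaternion set (deterministic; the seed only offsets the spiral; the
identity is always member 0).  The search is hierarchical:

1. *screen*: all n_orient (default 5000) orientations are scored against
   low-resolution data (d ≥ 2·d_min when ≥60 reflections survive,
   otherwise all data) with each orientation's best amplitude correlation
   over a coarse translation grid;
2. *refine*: the best 30 orientations are re-scored at d ≥ 1.4·d_min on a
   d_min-spaced grid;
3. *translation*: the top 4 orientations receive an exhaustive grid at
   d_min/2 spacing; peaks are clustered within one grid step;
4. *polish*: the best 2 candidate poses are refined by Nelder–Mead
   simplex over the 6 rigid-body parameters, maximizing llg_like; the
   returned pose is the best ever evaluated, so the score cannot
   decrease.

Two symmetry facts shrink every translation grid: along polar directions
the origin is unobservable, so that component is fixed at 0 and excluded;
and permissible origin shifts t₀ with (R_s − I)t₀ integral for every
operator make the score periodic, so each axis is searched over one period
(½ in the orthorhombic screw groups used in the tests) instead of a full
cell edge.

`tfz_like` is the Z-score of a pose against the translation-grid null,
computed on the llg scale: a correlation is bounded by 1, so a Z of raw
CC values saturates near 6 regardless of how decisive the peak is; the
llg transform restores the contrast familiar from translation-function
Z-scores.  Grid searches run in single precision (the polish target is
~10⁻⁴ in CC); all reported solution scores are recomputed in double
precision by direct summation.

A packing test rejects poses with symmetry-contact heavy-atom distances
below 1.5 Å (minimal-image over all operators and the ±1 cell shell).
Solutions must pass tfz_like ≥ 5 or llg_like ≥ 30; both thresholds are
package defaults chosen so that placed and unplaced models separate
cleanly on synthetic data, not values taken from any external program.

**The GA loop.**  Torsions are identified on the molecular graph: every
non-ring single bond whose two ends both carry ≥2 heavy neighbours.  Ring
bonds — any bond on any simple cycle, detected as non-bridge edges, a
deliberately conservative rule — are never driven.  The agenda is ordered
by ΔRMSD (mean non-superposed heavy-atom RMSD over a full 360° scan in
10° steps), largest first, and re-ranked against the current best
conformer at the start of each pass; non-superposed RMSD is used because
the scan measures absolute atomic displacement, which is what perturbs
structure factors.  Scan candidates inherit the parent pose; MR of a
candidate starts with a local polish of that pose and falls back to the
full search only if the gates fail.  Selection is elitist (parents compete
with children), which guarantees the monotone best-score invariant the
tests assert.  De-duplication compares crystal-frame coordinates without
superposition (the registry holds *placed* solutions, so frame alignment
is already meaningful); a config flag switches to superposed RMSD.
The agenda is repeated (up to one pass per rotatable torsion by default)
until a full pass improves the ranking metric by less than 0.1% — at high
resolution one pass per torsion usually converges; the repeat matters at
low resolution.

**Packing tolerance inside the loop.**  The GA's embedded MR config
relaxes the packing threshold to 0.8 Å: mid-optimization conformers are
chemically unrelaxed and their best placements typically show 0.7–1.4 Å
symmetry contacts; rejecting them would starve the population of exactly
the intermediates the search must keep.  Standalone `run_mr` keeps the
strict 1.5 Å test.

**Element-agnostic ("adjusted") RMSD.**  At modest resolution an
electron-potential map cannot distinguish scatterers of similar power
(C vs N), so a correct structure may come back with a pseudo-symmetric
group flipped.  `adjusted_rmsd` scores positional agreement only: optimal
superposition alternates with optimal one-to-one assignment (Hungarian
algorithm on the squared-distance matrix) to convergence (10⁻⁸ Å).  The
alternation is a local optimizer; it is multi-started from the identity
mapping, the centered-coordinate assignment and 8 deterministic random
orientations, which resolves all tested pseudo-symmetric cases, but a
global optimum is not guaranteed.

## Synthetic study system

All end-to-end claims are made on generated ground-truth crystals:

* **molecule** `macrolactone12`: a 12-membered ring (9 C, 1 N, 1 O, 1 S)
  with a fixed irregular pucker and three exocyclic two-bond chains (C–O,
  C–N, C–C), 18 heavy atoms, exactly 3 rotatable torsions.  Geometry is
  idealized (1.5 Å bonds, tetrahedral-ish angles) — chemical realism is
  irrelevant to the algorithmic contracts under test, but the *shape and
  composition* are deliberately asymmetric.  A regular crown ring is so
  self-similar that near-degenerate ghost orientations dominate the
  amplitude landscape; and with C/N/O alone the mirror image matches the
  molecule under element-agnostic atom reassignment to ~0.1 Å, so the
  inverted crystal (identical |F|) is reachable almost exactly by a
  proper rotation of the model — the global analogue of the
  pseudo-symmetric flips that motivate the element-agnostic RMSD.  The
  ring sulfur, a much stronger electron scatterer pinned in the
  never-driven ring, breaks that degeneracy;
* **crystal**: P2₁22₁, a=8, b=12, c=13 Å, one molecule per asymmetric
  unit.  The true pose was chosen once (by randomized search followed by
  local optimization of the packing margin) so the crystal has a 2.4 Å
  minimum symmetry contact; 788 unique reflections at 1.0 Å;
* **data**: |F| computed by the package's own forward model with B=3 Ų,
  truncated to d_min, optionally degraded with multiplicative Gaussian
  noise F←F(1+ε), ε~N(0, σ_frac), σF = σ_frac·F.  This emulates the
  *shape* of a merged MicroED amplitude file, not electron-diffraction
  physics: no dynamical scattering, no resolution-dependent I/σ profile,
  no radiation damage, no partial-occupancy solvent.  Noise-free fixtures
  are exactly solvable, which is what makes recovery assertions sharp;
* **decoys**: the truth conformer with every rotatable torsion offset by
  ±U(40°, 120°) — the truth itself is never included.  Decoys share the
  true ring-core conformation, mirroring the method's division of labour
  (core conformations come from the input ensemble, exocyclic torsions
  from the GA).

Problem sizes used in tests and in `scripts/acceptance.py` (50-member
ensembles, 788/131/67 reflections at 1.0/2.0/2.5 Å, 10 recovery seeds)
were chosen as the smallest sizes at which the contracts are meaningfully
exercised on a single CPU.

## Numerical choices

* Torsion scans use absolute settings 0°, 10°, …, 350°; driving a torsion
  rotates exactly one connected component about the fixed b→c axis, so
  the bonded-distance multiset is preserved to 10⁻⁹ Å (asserted).
* fit_scale clamps B to [−20, 200] Ų and falls back to scale-only with a
  warning when the resolution range is degenerate.
* Intensities are converted as |F| = √max(I,0), σF = σI/(2|F|) (clamped);
  negative-intensity counts are logged.  A French–Wilson treatment is a
  documented non-goal.
* Reflection d-spacings are always recomputed from the cell; resolution
  values carried by files are ignored.
* Friedel mates (and symmetry equivalents when the group is known) are
  merged on read by inverse-variance weighting; systematic absences are
  removed with a warning count.
* Model-vs-truth RMSD is symmetry- and origin-aware: minimized over all
  space-group operators, permissible origin shifts, per-axis lattice
  translations, and continuous shifts along polar axes.

## Known limitations

* The MR scores are correlation-based stand-ins, not maximum-likelihood
  σA-based quantities; absolute values of `llg_like`/`tfz_like` are not
  comparable to any external program's LLG/TFZ, only their orderings are
  meaningful within a run.
* One molecule per asymmetric unit; no enantiomorph handling (the space
  group is taken as given); no multi-copy or fragment searches.
* The degradation study shows a *milder* failure onset than real data:
  the 18-atom, 3-torsion fixture still solves at 2.5 Å with 10% noise
  because ~67 unique reflections comfortably over-determine its few
  degrees of freedom, whereas 40+-atom, 10+-torsion molecules on real
  MicroED data break down there.  Passing the 2.0 Å test therefore shows
  robustness of the machinery, not a claim that real systems of that
  complexity solve at 2.5 Å.
* `adjusted_rmsd` is a multi-start local optimizer (above).
* Ring torsions are never optimized by design; an ensemble without a
  near-correct core cannot be rescued.
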