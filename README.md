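# hamr

High-throughput automated molecular replacement for small-molecule
electron-diffraction (MicroED/3DED) data.

## The problem

Flexible small molecules — macrocycles and other "beyond-rule-of-5"
compounds — often diffract only to ~1–2 Å in MicroED experiments, too poor
for *ab initio* (direct-methods) phasing.  Molecular replacement (MR) can
phase such data from a trial model, but it only succeeds when the trial
conformation is already very close (≲0.25 Å RMSD) to the true one, and a
stock conformer generator rarely gets a macrocycle that close.

`hamr` closes that gap with a torsion-driving genetic algorithm wrapped
around a lightweight MR engine:

1. every conformer of an input ensemble is phased by MR and ranked;
2. the exocyclic rotatable torsions of the best models are ordered by
   impact, ΔRMSD — the mean heavy-atom displacement over a full 360°
   scan in 10° steps;
3. one torsion per cycle is driven through all 36 settings for every
   population member; each setting is scored cheaply by the R factor of
   the modified conformer *in its parent's position in the lattice*;
4. the best fraction of settings (default 20%) survives the filter,
   near-duplicates of already-phased conformers (within 0.02 Å RMSD) are
   discarded, and the survivors are re-phased by MR;
5. selection is elitist: parents compete with children, the top three
   solutions seed the next cycle, until every torsion is optimized (the
   full agenda is repeated while it still improves the score).

Ring torsions are never driven — macrocycle core conformations must come
from the input ensemble.

The MR engine is self-contained: electron scattering factors (5-Gaussian
parameterization), direct-summation structure factors
F(h) = Σ_s Σ_a f_a(s) e^{−B s²} e^{2πi h·(R_s x_a + t_s)} with
s = sinθ/λ, isotropic-B Wilson scaling, and a hierarchical
orientation/translation search over low-discrepancy quaternions and
symmetry-reduced translation grids.  Poses are scored by the Pearson
correlation CC between observed and calculated amplitudes, summarized as

* `llg_like = −(N/2)·ln(1 − CC²)` — a log-likelihood-gain analogue,
* `tfz_like` — the Z-score of the pose against a translation-grid null,

and the usual `R = Σ||Fo| − k·e^{−Bs²}|Fc|| / Σ|Fo|`.

## Worked example

Generate a synthetic ground-truth crystal (a 12-membered macrolactone-like
molecule with three exocyclic torsions, P2₁22₁, 1.0 Å data), build a decoy
ensemble with every torsion perturbed by 40–120°, and let the GA recover
the generating conformer:

```python
from hamr.synthetic import FixtureSpec, build_fixture, make_decoy_ensemble
from hamr.hamr_loop import HamrConfig, run_hamr
from hamr.mr_engine import model_rmsd

fx = build_fixture(FixtureSpec())          # 788 reflections, 18 heavy atoms
decoys = make_decoy_ensemble(fx.conformer, 50, (40, 120), seed=1)
res = run_hamr(decoys, fx.reflections, HamrConfig(seed=1))
best = res.best
print(f"r_work={best.r_work:.4f}  llg_like={best.llg_like:.0f}")
print("rmsd to truth:",
      round(model_rmsd(best.conformer, best.pose, fx.true_conformer.coords,
                       fx.reflections.cell, fx.reflections.spacegroup), 3))
```

Output:

```
r_work=0.0395  llg_like=1188
rmsd to truth: 0.024
```

i.e. starting from 50 conformers that are all 40–120° wrong in every
rotatable torsion, the loop returns a model 0.024 Å RMSD from the
generating structure with a 4% R factor — the residual is set by the 10°
torsion grid, not by the search.

The same pipeline is scriptable from the shell:

```bash
hamr synth --template macrolactone12 --dmin 1.0 --out fx/
hamr run --data fx/fixture.hkl --ensemble decoys.sdf \
         --cell "8 12 13" --spacegroup "P 21 2 21" --out results/ --seed 1
hamr score --data fx/fixture.hkl --model fx/truth_posed.sdf \
           --cell "8 12 13" --spacegroup "P 21 2 21" --biso 3
```

`hamr run` writes a results bundle (best.cif, solutions.jsonl with the full
scored-candidate log, config.yaml, manifest.yaml) and exits 0 on solution,
2 on no-solution, 1 on error.

## Scope

`hamr` covers the search stage only: the best model is "pre-refinement" by
design.  Final-stage refinement (per-atom ADPs, simulated annealing),
solvent placement, map synthesis, and conformer-ensemble generation are
out of scope; ensembles are consumed from multi-record SDF or multi-model
PDB files.
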