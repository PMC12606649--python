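# fespred

Reduction-potential prediction for iron–sulfur proteins from 3D structure.

Rubredoxin-type Fe(S-Cys)₄ centers and [2Fe–2S] clusters (ferredoxins,
Rieske proteins, mitoNEETs) span a redox window of several hundred mV.
Which potential a given protein realizes is set by its structure: the
first-sphere ligands, hydrogen bonding to the bridging sulfides, the
polarity and charge of the surrounding shells, and whole-protein
electrostatics. `fespred` turns a PDB structure (plus the measurement pH)
into a fixed multiscale descriptor vector and fits a gradient-boosted
tree regressor to experimental reduction potentials (RP, in mV), for
structural biologists and protein engineers who want fast, interpretable
RP estimates and mutation-effect directions without quantum chemistry.

## The model

A fixed set of 66 region descriptors (residue-class counts plus
sum/mean/min/max of 14 physicochemical residue properties) is recomputed
at three scales around each Fe–S site:

- **long range** — the whole protein (`Protein.X`);
- **medium range** — a sphere of radius r1 ∈ [8, 16] Å centered on the
  cluster barycenter (`Bar.X`);
- **short range** — spheres of radius r2 ∈ [3, 5] Å (r2 < r1) around each
  cofactor atom (`CofAtom.{Fe,S}.k.X`), plus the residue nearest to each
  cofactor element (`NearestY.X`, 28 values) and its sequence neighbors
  (`AroundY.X`, 32 values).

With a cofactor inventory (other hetero groups per distance scope), two
site-kind flags and pH, each (r1, r2) yields exactly **765 features**.
Strategy A trains one model per (r1, r2); strategy B trains a single
model on the deduplicated union across all 27 radii pairs. Models are
evaluated by nested cross-validation (5 outer folds; 10-fold inner
MAE-minimizing grid search over a fixed 108-configuration XGBoost grid;
10 repeats), reported as MAE / RMSE / R² / Spearman mean ± sd over folds
× repeats, with leave-protein-out and leave-mutant-out generalization
tests and TreeSHAP feature attributions. See `docs/methods.md` for the
full model description and design choices.

## Worked example

The package ships a synthetic test bed: valid toy PDB structures with
known site geometry and RP values drawn from a known linear model over
named descriptors. No downloads are needed.

```bash
fespred simulate --out demo --n-proteins 20 --mutants-per-protein 4 --seed 4
# wrote 100 entries -> demo
```

`demo/` now holds `structures/*.pdb` and `dataset.csv`, the curated-table
dialect (entry id, structure reference, RP in mV, pH, protein class,
mutation label, parent protein id). Train and evaluate with a reduced
grid (config file `cfg.yaml` setting `table`, `structure_dir`, r1/r2, CV
sizes and a grid slice):

```bash
fespred train --config cfg.yaml --model gbt --out demo_train
# loaded 100 entries ({'ferredoxin': 60, 'rubredoxin': 20, 'mitoneet': 10,
#                      'rieske': 10}); RP range [-329, 309] mV
# MAE 36.5 +- 6.5 mV -> demo_train
```

The MAE is the out-of-fold error over all entries, mean ± sd across
outer folds × repeats — here ≈ 36 mV against a cohort whose RP spans
~640 mV with 20 mV of injected measurement noise. Attribution then
recovers what actually drives the synthetic potentials:

```bash
fespred explain --config cfg.yaml --out demo_explain
head -4 demo_explain/importance.csv
# ,mean_abs_attribution,spearman_rp
# Global.pH,44.2,-0.51
# Bar.TotalResidues,39.2,-0.33
# Bar.HydropathySum,10.7,-0.29
```

`mean_abs_attribution` is the average absolute TreeSHAP contribution in
mV; `spearman_rp` the rank correlation of the feature with RP (here pH
down-shifts RP, as planted). Other commands: `featurize` (matrix +
schema manifest), `scan-radii` (MAE per (r1, r2) cell), `ablate`
(spatial-scale ablations with Mann–Whitney comparisons), `holdout`
(leave-protein-out / leave-mutant-out), and `fetch-structures` (explicit
RCSB download; nothing is fetched implicitly).

To run on real data, point `--table` at a curated CSV/TSV of measured
potentials and `--structure-dir` at the corresponding PDB files.

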