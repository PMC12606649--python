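# Methods

## The problem

Iron–sulfur proteins tune the reduction potential (RP) of their cofactor —
a mononuclear rubredoxin-type Fe(S-Cys)₄ center or a binuclear [2Fe–2S]
cluster — over a range of several hundred mV through the identity of the
first-sphere ligands, hydrogen bonding to the bridging sulfides, the
polarity and charge of the surrounding residue shell, and whole-protein
electrostatics. `fespred` models RP (mV vs SHE) as a function of
descriptors computed directly from a static 3D structure, plus the
measurement pH, with a gradient-boosted tree regressor.

## Descriptor model

A fixed set of **66 region descriptors** is computed over residue regions
at three spatial scales. The 66 are: 10 residue-class counts (total;
counts of the disjoint classes polar-neutral / hydrophobic / basic /
acidic; aromatic; charged; Cys; His; Gly+Pro) and 14 numeric per-residue
properties aggregated four ways (sum, mean, min, max). The class
convention follows standard biochemistry with the choices that matter
here made explicit: **Cys is a neutral polar residue** and **His counts
with the basic residues** (Lys, Arg). The numeric properties are standard
published scales — Kyte–Doolittle hydropathy, residue volume (Å³),
side-chain bulkiness (the steric-hindrance proxy), average backbone
flexibility, Grantham polarity, isoelectric point, net charge at pH 7
(His = +0.1), side-chain H-bond donor and acceptor counts, side-chain
N/O/S atom counts, residue mass — plus a composite steric-hindrance ×
flexibility term. The property table is a versioned constant; a drop-in
replacement table is accepted by every featurizer entry point.

The regions are:

| block | scope | scale | radius |
|---|---|---|---|
| `Protein.X` | all standard residues | long | — |
| `Bar.X` | sphere of radius r1 (8–16 Å) around the cluster barycenter | medium | r1 |
| `CofAtom.{Fe,S}.k.X` | sphere of radius r2 (3–5 Å, r2 < r1) around each cofactor atom | short | r2 |
| `NearestY.X` | the single residue nearest (any-atom) to each element Y ∈ {Fe, S} | short | — |
| `AroundY.X` | that residue plus its i−1 / i+1 sequence neighbors | short | — |

Membership uses the **any-atom rule** with an inclusive boundary (a
residue belongs to a sphere if any of its heavy atoms lies inside);
Cα-only and side-chain-centroid rules are available but not the tested
default. For mononuclear sites both radii are centered on the Fe ion and
every sulfur-indexed block is exactly zero.

The short-range `CofAtom` layout uses fixed per-atom slots — four Fe and
four S — so one schema serves mono- and binuclear sites (and leaves
capacity for higher-nuclearity clusters); slots beyond the focal
cluster's atoms are zero-filled. Fe atoms fill Fe slots in file order,
likewise S. `NearestY` emits the 14 property values of the nearest
residue (ties broken by chain id, then residue number); `AroundY` emits
the 14 property sums over the ≤3-residue sequence window plus its Cys and
His counts — chain termini simply use the one existing neighbor.

Two global blocks complete the vector: a **cofactor inventory** counting
non-focal hetero groups (vocabulary of 14 codes, unknowns bucketed into
OTHER) in three scopes (whole structure / within r1 / within r2 of the
barycenter, judged by group barycenter) plus two site-kind flags, and the
**measurement pH** as a numeric condition feature. An optional variant
schema appends a one-hot measurement-technique block; it is off by
default because technique information adds cost without clear accuracy
benefit and is unavailable for novel proteins.

Per (r1, r2) the strategy-A vector is therefore

10 regions × 66 + 28 + 32 + 44 + 1 = **765 features**,

a fixed schema invariant asserted in the tests. The strategy-B vector is
the deduplicated union over the full radii grids (r1 = 8…16, r2 = 3, 4,
5; 27 pairs): radius-independent blocks once, `Bar` blocks once per r1,
`CofAtom` blocks once per r2, the inventory per scope-relevant radius.

## Structure handling

PDB files are parsed with Biopython (model 1 only). Hydrogens and waters
are dropped; alternate locations resolve to the highest-occupancy
conformer, ties to altloc 'A'. Cofactor atoms are the Fe ions and
inorganic bridging sulfides of the FES / FE hetero groups only — cysteine
thiolate sulfurs are residue atoms. A residue coordinates the cluster
when any side-chain atom is within 3.0 Å of an Fe ion (covers Fe–S(Cys)
≈ 2.3 Å and Fe–N(His) ≈ 2.1 Å with margin). Coordinates stay in the
file's native frame — every descriptor is rigid-motion invariant, which
the tests assert to 1e-9. Crystallographic resolution is metadata only
and never a feature.

## Training and evaluation protocol

The regressor is XGBoost (`tree_method="hist"`, single-threaded for
bit-reproducibility); ordinary least squares serves as the linear
baseline, switching to ridge (α = 1) whenever columns ≥ rows, where
plain least squares is ill-posed. The hyperparameter grid is fixed:
max_depth {3, 4, 5} × n_estimators {100, 150, 200} × learning_rate
{0.01, 0.1, 0.2, 0.4} × min_child_weight {1, 5, 10} — 108
configurations, enumerated lexicographically (ties in inner-CV MAE go to
the earlier configuration).

Evaluation is nested cross-validation: a 5-fold outer loop for unbiased
error estimation and a 10-fold inner MAE-minimizing grid search that sees
only the outer-training rows, the whole procedure repeated 10 times with
fresh fold assignments; metrics (MAE, RMSE, R², Spearman) are reported as
mean ± sd over all outer folds × repeats (50 by default). Fold assignment
is random at the entry level, so variants of one protein may straddle
folds; the protein-grouped regime exists separately as
`leave_proteins_out`, which drops every entry of the held-out proteins
(mutants included) before tuning and training once on the remainder.
`leave_mutants_out` holds out selected mutants (each wild type must stay
in training) and scores both the error and the predicted direction of
ΔRP = RP(mutant) − RP(WT); experimental shifts within a ±5 mV dead-band
count as "essentially unchanged", and predicted shifts are classified
with the same band. Spatial-scale ablations subset columns by schema
scale tag; pH and the other condition features stay in every variant
because they are experimental conditions, not structural scales. Model
variants are compared by two-sided Mann–Whitney U tests on their
fold-level MAEs (exact method for small tie-free samples).

Every outer split is checked programmatically for train/test overlap, and
all randomness flows from one base seed, so a rerun reproduces fold
assignments, selected hyperparameters and metrics bit-identically on the
same machine.

## Interpretation

Feature attributions are exact tree-path (TreeSHAP) values computed
natively by xgboost (`pred_contribs`); importance is the mean absolute
attribution. Local accuracy — attributions plus base value equal the
prediction — is enforced per row with a 1e-3 mV tolerance, the practical
floor of the model's single-precision arithmetic on targets of order
100 mV. For cross-validated reporting, each outer-fold model is
attributed on its own test fold and the importances averaged. The
cross-radii heatmap normalizes importances per model (each model sums to
one) and orders rows by cross-model mean. Spearman feature–RP
correlations accompany the importances; constant features are flagged
undefined rather than zero.

## Synthetic test bed

The generator builds format-valid toy PDB structures around an exact
cofactor geometry — a planar [2Fe–2S] rhombus (Fe–Fe 2.7 Å, Fe–S 2.2 Å)
or a single Fe — with four Cys/His ligands whose ligating atom sits at
exactly 2.3 Å from an Fe, and further residues on radial shells at
exactly known barycenter distances (directions jittered, radii exact, so
ground-truth distances are by construction). Mutants are 1–2 residue-code
substitutions at fixed coordinates, which suffices because descriptors
depend only on identity and geometry. Shell radii are drawn off the radii
grid (4.2–22 Å by default) to avoid exact-boundary ties.

Synthetic RP values follow a known linear model: RP = Σⱼ wⱼ zⱼ + ε, with
zⱼ the named support features standardized over the cohort, weights in mV
per population-sd, and ε ~ N(0, σ). The frozen study conditions are 50
proteins × (1 WT + 5 mutants) = 300 entries, σ = 20 mV, pH ~ U(5, 9),
weights (−60, +45, −80, −70, +50), and the support
{pH, Protein.FlexibilityMin, Bar.GlyProCount,
CofAtom.Fe.2.HydrophobicCount, Protein.AromaticCount}. The support was
chosen as weakly collinear representatives of the condition/long/medium/
short blocks: the 66-descriptor regions are intentionally redundant
(sum/mean/min/max of correlated scales), so attribution-based recovery of
a planted signal is only well-posed for features whose variance is not
duplicated by a near-collinear sibling — blocks driven entirely by the
fixed ligand architecture (`NearestY`, `AroundY`) cannot carry an
identifiable planted signal in this test bed, which is a property of the
toy geometry, not of real proteins.

What the toys do not emulate: realistic backbone geometry and packing,
rotamers, solvent, conformational heterogeneity, and any nonlinear
structure–RP physics. Green tests therefore demonstrate correctness of
the machinery (geometry, schema, protocol, attribution) and
recoverability of planted signal — not predictive accuracy on real
Fe–S proteins, which requires a curated experimental data set.

## Problem sizes and numerical choices

Tests and the acceptance script scale the protocol to desk size as the
package's own defaults for verification runs: a 4-configuration grid
slice, 3 inner folds and 1–2 repeats for nested CV on the 300-entry
cohort; 100 randomized structures × 6 queries for the geometry oracle;
20 cohort seeds for the attribution-recovery rate. The full 108 × 10 ×
5 × 10 protocol is the library default and is what a real-data study
should run. Empty regions zero-fill all 66 entries (including mean, min,
max). Count features are exact integers stored as floats. The rare
random cohort whose composition leaves a support feature constant is
rejected with an explicit error (and deterministically reseeded inside
the acceptance script).

## Known limitations

* The 66-descriptor composition and the inventory vocabulary are this
  package's documented convention; other property tables can be dropped
  in, but published results computed with a different table will not be
  numerically identical.
* Only FES and FE/FE2 hetero codes are recognized as focal sites;
  [3Fe–4S]/[4Fe–4S] (SF4, F3S) groups are counted by the inventory but
  cannot yet be focal sites, although the per-atom slot layout already
  reserves the capacity.
* mmCIF input, protonation assignment and in-silico mutagenesis are out
  of scope; the package consumes pre-built structures.
* Bit-identical reproducibility holds per machine/library build, not
  across different BLAS/xgboost builds.
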