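# stratvep

**Does protein structure determine how predictable variant effects are?**

Supervised variant-effect prediction (VEP) models are routinely used to
pre-screen enzyme variants, but their accuracy varies sharply from one
variant to the next. `stratvep` implements a structurally *stratified*
analysis that asks where that variation comes from: it partitions an
enzyme's positions by four structural characteristics — buriedness, number
of Cα contacts, distance to the active site, and secondary-structure
membership — designs combinatorial variant libraries whose variants are
class-pure for every characteristic, and contrasts cross-validated model
performance between the positive and negative class of each characteristic.

The package is aimed at protein engineers and ML-for-proteins researchers
who want to (a) run the stratified analysis on their own screen, or (b)
study the methodology itself on fully synthetic data with a known ground
truth.

## The analysis in brief

**Structural characteristics** (per residue, from a PDB structure):

* *buriedness* — shortest distance from the residue's heavy atoms to the
  convex hull of the protein (`scipy.spatial.ConvexHull`);
* *contacts* — number of Cα atoms within a cutoff radius derived from the
  chain itself (mean consecutive Cα–Cα distance + 2 SD);
* *active-site distance* — minimum Cα–Cα distance to the catalytic residues
  (D176/E208 for the B. subtilis alpha-amylase);
* *secondary structure* — helix-or-sheet vs loop from HELIX/SHEET records.

Each characteristic is binarized at its median; the 2⁴ = 16 label
combinations define factorial bins, and combinatorial variants (up to 8
mutations) are sampled within single bins so every variant belongs wholly
to one class of every characteristic.

**Models** (all linear, scikit-learn pipelines over sequence strings):

| model              | encoding                              | regressor  | dim      |
|--------------------|---------------------------------------|------------|----------|
| `residue_agnostic` | indicator of mutated positions        | ridge      | L        |
| `pls`              | one-hot                               | PLS (20)   | L·20     |
| `augmented_potts`  | one-hot ⊕ Potts sequence energy       | ridge      | L·20 + 1 |
| `embedding`        | pluggable sequence-level embedder     | ridge      | d        |

The Potts energy `E(σ) = Σᵢ hᵢ(σᵢ) + Σ_{i<j} J_ij(σᵢ, σⱼ)` comes from an
in-package pseudolikelihood trainer fitted to an MSA (21-state alphabet,
L2-regularized, gradient ascent from zero). The default embedder is a
seeded random projection of the one-hot encoding; any
`sequence -> vector` callable can be plugged in.

**Evaluation**: 10-fold cross-validation, Spearman correlation per test
fold, per-characteristic Welch t-test between the positive and negative
class fold-score distributions (position-stratified folds are provided for
single-mutation data). Plate screens are normalized as
mean(triplicates) − mean(plate blanks), with per-plate LOD = 3·σ_blank.

A synthetic-data module generates globular toy structures, Gibbs-sampled
MSAs from known Potts models, and plate-structured activity screens whose
epistasis is confined to one structural class — so the entire pipeline can
be validated against a known ground truth without any downloads.

## Worked example

```python
from stratvep import run_synthetic_study

study = run_synthetic_study(
    n_residues=200,       # synthetic enzyme size
    n_per_bin=100,        # variants sampled per factorial bin
    hard_characteristic="buried",   # class carrying pairwise epistasis
    seed=1,
)
report = study["report"]
for model in ("residue_agnostic", "pls", "augmented_potts", "embedding"):
    c = report.contrasts[(model, "buried")]
    print(f"{model:17s} buried {report.mean_score(model, 'buried', 'positive'):.3f}"
          f"  exposed {report.mean_score(model, 'buried', 'negative'):.3f}"
          f"  p={c.p_value:.1e}")
```

prints (about two minutes on one CPU):

```
residue_agnostic  buried 0.949  exposed 0.987  p=3.4e-05
pls               buried 0.915  exposed 0.975  p=2.4e-05
augmented_potts   buried 0.920  exposed 0.979  p=4.3e-06
embedding         buried 0.912  exposed 0.944  p=4.8e-03
```

Pairwise epistatic effects were injected only between buried positions, and
every model — from the residue-agnostic baseline to the Potts-augmented
regressor — scores significantly lower on the buried split than on the
exposed one. That is the signature the stratified design is built to
detect: a class-localized interaction structure that no additive-feature
model captures, surfacing as a consistent predictability gap across model
families. With the epistasis switched off
(`LandscapeParams(epistasis_fraction=0.0)`), over 90% of class contrasts
are non-significant.

The same stages are available as a CLI for real data:

```bash
strat-vep features --pdb enzyme.pdb --active-sites 176,208 --out profile.csv
strat-vep partition --profile profile.csv --out partition.csv
strat-vep design --partition partition.csv --reference ref.fasta --n-per-bin 100 --seed 7 --out library.csv
strat-vep fit-potts --msa family.a2m --gap-cutoff 1.0 --out potts.npz
strat-vep evaluate --data screen.csv --partition partition.csv --reference ref.fasta \
    --models residue_agnostic,pls,augmented_potts --potts potts.npz --folds 10 --out report/
strat-vep simulate --n-residues 200 --n-per-bin 100 --hard buried --seed 7 --out simdir/
```

## Layout

```
src/stratvep/
  structure.py     PDB parsing + the four structural characteristics
  partitioning.py  median binarization, 16 factorial bins, class splits
  design.py        combinatorial library sampling, SSM enumeration
  potts.py         Potts model + pseudolikelihood trainer
  encoding.py      sklearn transformers for the four encodings
  models.py        the four regressors as sklearn pipelines
  evaluation.py    plate normalization, folds, Spearman, contrasts
  synthetic.py     toy structures, Gibbs MSAs, landscapes, screens
  pipeline.py      end-to-end orchestration
  cli.py           `strat-vep` command line
  plots.py         optional report figures
```

See `docs/methods.md` for the statistical model, parameter choices and
limitations.
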