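# Methods

This note documents the models and procedures implemented in `stratvep`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Structural characteristics

All four characteristics are computed per residue from a single structure
(`structure.build_profile`):

* **Buriedness** — the minimum, over the residue's heavy atoms, of the
  distance to the nearest facet *plane* of the convex hull of all heavy
  atoms. Atoms on the hull score exactly 0. Hydrogens are excluded (crystal
  structures rarely resolve them). Buriedness is invariant under rigid
  transforms of the coordinate frame.
* **Contact count** — the number of other residues whose Cα lies within a
  cutoff radius of the focal Cα (self excluded, boundary inclusive). The
  radius is derived from the chain itself: mean + 2·SD (sample SD, n−1) of
  the Cα–Cα distances between *consecutive* residues. Deriving the radius
  from local chain geometry makes the cutoff adapt to resolution and
  model quality rather than being a hard-coded constant; on a well-packed
  native enzyme chain it lands near 7 Å.
* **Active-site distance** — minimum Cα–Cα distance to a user-supplied set
  of catalytic residues (for the alpha-amylase screen these are D176 and
  E208).
* **Secondary structure** — binary helix-or-sheet membership from the PDB
  HELIX/SHEET header records; turns count as loop. An external per-position
  annotation (e.g. from a DSSP-style tool) can override the header-derived
  labels.

PDB handling (via gemmi): first chain by default, highest-occupancy altloc
kept, residues lacking a Cα excluded with a warning, and a configurable
integer offset mapping author residue numbers to 1-based mature-sequence
positions (default 0; crystal structures are frequently numbered against a
precursor).

## Binarization and factorial bins

Each characteristic is thresholded at its median over all positions:
buriedness and contact count are positive strictly *above* the median,
active-site distance strictly *below* (closeness is the trait), secondary
structure passes through. Ties go to the negative class — a consequence of
the strict inequalities that matters for discrete contact counts, where
the classes can be unequal. Median splits tie class membership to the
protein's size and shape, but they are the only thresholding that
guarantees roughly balanced classes for arbitrary enzymes.

The 2⁴ label combinations define 16 factorial bins (signature order:
buried, many_contacts, close_to_active_site, helix_or_sheet). A variant
belongs to the positive (negative) class of a characteristic iff all its
mutated positions are positive (negative); variants mixing labels are
excluded from that characteristic's contrast. Libraries sampled within
single bins are class-pure by construction, so nothing is excluded.

## Library design

From each bin, variants carry 1..min(8, bin size) mutations at positions
drawn uniformly without replacement. Mutation counts are spread *exactly*
evenly over that range per bin (a uniform marginal with minimal variance):
a variant's activity scales with how many mutations it carries, so
between-class differences in the count mix would masquerade as
predictability differences. For the same reason the synthetic study skips
bins with fewer than 8 positions (they can only host low-order variants);
the run warns and the remaining classes stay class-pure and near-balanced.

Alternative residues come from a pluggable per-position scorer for 75% of
variants and uniformly over the 19 alternatives for the rest. The built-in
scorer weights substitutions by `exp(BLOSUM62[wt, alt] / T)` (T = 2),
favoring conservative substitutions the way protein-language-model
likelihoods favor expressible sequences; any `position -> 20 weights`
function can replace it. The wild-type residue's weight is zeroed and the
rest renormalized. Duplicate variants (by exact mutation set) are
resampled.

## Potts model

The sequence model is a pairwise Markov random field over the 21-state
alphabet (20 amino acids + gap):

    E(σ) = Σᵢ hᵢ(σᵢ) + Σ_{i<j} J_ij(σᵢ, σⱼ)

Fitting maximizes the site pseudolikelihood — the sum over positions of
the conditional log-likelihood of each column given the rest — averaged
over sequences, with L2 penalties 0.01 on fields and 0.1·(L−1) on
couplings (scaled with the number of pairs each site participates in).
Averaging over sequences makes the penalties independent of alignment
depth. Couplings are stored as one symmetric (L·q)² matrix with zero
diagonal blocks; the conditional logits for every site of every sequence
are then a single matrix product with the one-hot alignment, and the
gradient is the exact projection onto that tied parametrization (checked
against central finite differences to 1e-5 relative error in the tests).

Optimization is deterministic: zero initialization, monotone gradient
ascent with a backtracking step, convergence at max parameter change
< 1e-4. Non-convergence within the iteration budget returns the partial
model flagged `converged=False` with a warning — for the energy *feature*
used by the augmented regressor an early-stopped fit is still a valid
covariate, and the synthetic study caps iterations at 50 for the
200-residue demonstration scale.

Columns with gap ratio above `gap_cutoff` are dropped before fitting; the
default cutoff of 1 keeps every column so energies exist for every residue
of the query. Sequence reweighting by alignment identity (the DCA
`1/n_neighbors` convention) is implemented but off by default. Variant
energies ignore gap states, which cannot occur in assay sequences.

One caveat worth recording: with *constant* MSA columns, fields and
couplings are exactly degenerate (a coupling into a constant column acts
as a field), so any finite L2 leaves a small nonzero share of the signal
in the couplings. "No covariation" therefore means coupling norms an order
of magnitude below genuinely covarying pairs, not literally zero — the
tests assert exactly that.

## Regressors

All four models are scikit-learn pipelines over sequence strings. Ridge
(α = 0.1 by default, from the grid {0.001, 0.01, 0.1, 0.9} selected by
best mean cross-validated Spearman across datasets — a deliberately
optimistic whole-dataset selection) backs the indicator, augmented-Potts
and embedding models; PLS with 20 components (NIPALS, unscaled X, rank-safe
truncation with a warning) backs the one-hot model. Features are used
unstandardized, except the single Potts-energy column, which is centered
and unit-scaled on each training fold: one raw-scale column against
thousands of binary columns would otherwise be regularized away. The
default embedder is a seeded Gaussian random projection of the one-hot
encoding to 1024 dimensions — linear, deterministic and dependency-free;
at much lower dimension the projection noise floor dominates the model's
fold scores. `fit_ridge`/`fit_pls` also expose flattened `LinearModel`
objects (weights + intercept) with JSON serialization.

## Evaluation

Activity per variant is mean(triplicate absorbances) − mean(plate blanks);
per-plate sensitivity is LOD = 3·σ_blank over the plate's blank replicate
values (sample SD). Cross-validation is 10-fold; the fold split is shared
across models so model comparisons are paired. For single-mutation data,
position-stratified folds deal each position's variants round-robin from a
random start, so any position with ≥ 2 variants is always present in the
training complement of its test fold; single-variant positions are flagged.

Class contrasts use Welch's t-test (no variance-equality assumption is
defensible for fold scores) at 0.05, two-sided, without multiple-testing
correction; activity-distribution contrasts use the Wilcoxon rank-sum test
(normal approximation with tie correction). Constant-prediction folds
score NaN and are dropped from contrasts with a warning.

`predictability_report` subsamples the larger class of each characteristic
to the smaller one's size (seeded, stratified by mutation count) before
cross-validation, so a contrast never reflects one class simply having
more training data. Fold scores, contrasts and activity tests serialize to
JSON/CSV; `plots.py` renders box plots and a parallel-coordinates view.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, not biophysically realistic proteins:

* **Structures** are oblate-ellipsoid globules (z semi-axis half the
  equatorial one) filled with a cubic lattice at 3.8 Å spacing, thinned by
  clustered interior vacancies, chained in a snake path, jittered by
  0.35 Å, with alternating helix/sheet/loop runs and two interior
  active-site anchors. The flattened shape and the voids decorrelate depth
  from packing density — in a uniform sphere, buriedness and contact count
  are nearly redundant and the discordant factorial bins stay empty. With
  the defaults, all 16 bins are populated at n = 200 across seeds and the
  construction-intended labels agree with the computed median-binarized
  labels for ~95% of positions.
* **MSAs** are Gibbs samples from a known Potts model (parallel chains,
  burn-in in full sweeps, thinned collection; gap state frozen out). The
  generating models combine reference-sequence conservation fields with
  favored-combination couplings on chosen position pairs.
* **Landscapes** are additive per-position effects plus pairwise epistatic
  effects drawn only between positions of one designated "hard" class.
  Defaults: baseline 0.1 absorbance units, additive effects
  Normal(−0.02, 0.007) — the average substitution is clearly deleterious,
  with smaller position-to-position variation — and epistatic SD
  = additive SD · √fraction with fraction 0.5. The dominant shared
  mutation-load component keeps additive-only classes statistically
  exchangeable, so class contrasts reflect injected interaction structure
  rather than which class happened to draw the more rankable landscape;
  with a zero-mean, high-variance additive prior the prescribed fold-score
  t-test flags spurious contrasts in a large fraction of runs. An optional
  fixed-magnitude (±SD) effect distribution and a per-residue modulation
  term (`alt_modulation_sd`) are available.
* **Screens** deal variants onto 96-well plates (94 variants + 2 blanks),
  in triplicate, with Gaussian replicate noise (SD 7.55e-3), blank noise
  (SD 3.9e-3, putting the median LOD near 1.1e-2) and a per-plate
  background offset that cancels exactly under plate normalization.

What passing the synthetic tests shows: the pipeline detects
class-localized epistasis as a predictability gap, consistently across all
four model families, and does not fabricate gaps under additive truth.
What it does not show: anything about real structural mechanisms —
measured screens have non-Gaussian noise, expression failures, activity
floors and assay nonlinearities the generator deliberately omits, and the
real direction of predictability differences is dataset-specific.

## Problem sizes and numerical choices

The demonstration study runs at 200 residues, 100 variants per eligible
bin (~800–1,600 variants), a 200-sequence MSA, 10 folds and a 50-iteration
Potts fit; the coupling-recovery experiment uses a 10-position model and
5,000 Gibbs samples; the additive-only control aggregates 80 contrasts
over 20 seeds. These sizes were chosen so the whole analysis, including
tests, runs in minutes on a single CPU while keeping every statistical
conclusion stable across seeds. One global seed fans out to per-stage
child seeds (`SeedSequence.spawn`), making every artifact a pure function
of the seed. Ridge solves use scikit-learn's closed-form paths; PLS
flattening recovers the intercept by predicting the zero vector (the
underlying implementation centers internally).

## Limitations

* Secondary structure comes from header records, not a geometric
  assignment; structures without HELIX/SHEET records need an override
  table.
* The contact-radius derivation assumes consecutive residues are
  chain neighbors; chain breaks inflate the SD and hence the radius.
  On the synthetic snake-path globules the derived radius (~13 Å) is
  accordingly larger than for native chains.
* The fold-score t-test inherits the known anticonservativeness of
  cross-validation-based tests (fold scores are not independent); the
  additive-only control quantifies the realized rate at the study scale
  (~90% of contrasts non-significant) rather than guaranteeing a nominal
  5%.
* No pretrained language models or sequence databases are bundled; the
  scorer and embedder interfaces are the injection points for them.
* The Potts trainer targets desk-scale alignments (L up to a few hundred,
  thousands of sequences); it holds the full (L·q)² coupling matrix in
  memory.
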