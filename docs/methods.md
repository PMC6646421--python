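# Methods

## Model and procedure

`combosyn` treats per-cell-line synergy prediction as a QSAR regression
problem. One model is fitted per cell line because the relationship
between chemistry and synergy differs across cellular contexts; cell lines
contribute no features of their own.

**Labels.** The ComboScore of a dose–response grid is the sum over all
concentration pairs of the Bliss-expected percent growth minus the
observed combination growth, after truncating every growth value into
[−100, 100]. The Bliss expectation uses the product rule
`y_a·y_b/100` when both single-agent growths are positive and
`min(y_a, y_b)` otherwise (once one agent alone drives growth to zero or
below, independence of fractional effects no longer composes
multiplicatively on the percent-growth scale). Duplicate determinations of
one (pair, cell line, center) tuple are averaged by default. Data from
different screening centers are never pooled: their protocols differ and
their measured tuples do not overlap, so batch effects cannot be
estimated. Center `1A` data is parsed but excluded from modeling defaults.

**Features.** Each drug is a heavy-atom molecular graph with implicit
hydrogens. Six descriptor blocks are available, concatenated in a fixed
order (`mfp`, `mfpc`, `maccs`, `isida`, `sirms`, `physchem`):

* Morgan fingerprints, binary or counted, radius 2, hashed by modulo
  folding into 256 buckets (RDKit);
* the 166 public MACCS keys (RDKit);
* atom–bond sequence fragments: every undirected simple path of 2–6 heavy
  atoms, labeled by element and bond symbols (`- = # :`), canonicalized as
  the lexicographic minimum of the forward and reversed string, counted
  once per path;
* simplex fragments: every 4-atom subset with its element labels and the
  bond pattern over the six atom pairs (`.` for non-bonded), canonicalized
  over all 24 permutations; enumeration is O(n⁴) and guarded by a
  configurable atom cap (default 50);
* seven physico-chemical properties in fixed order: TPSA, molecular
  weight, logP, aliphatic rings, aromatic rings, H-bond donors, H-bond
  acceptors (RDKit).

Fragment blocks use a dataset-level vocabulary (union of fragments
observed in the library, sorted lexicographically); fragments unseen at
training time are dropped at prediction time, keeping vectors fixed-width.
The exact fragment counts depend on the labeling scheme, so two
implementations of "path fragments" need not produce identical feature
counts on the same library; what is guaranteed (and tested) is agreement
with exhaustive enumeration under this package's labeling.

Similarity between drugs is the Tanimoto coefficient, generalized to
counts as Σmin/Σmax, with both-zero vectors defined as 0 similarity.
When count blocks are mixed with physico-chemical values, the physchem
columns are min–max scaled to [0, 1] over the library first — unscaled
molecular weight would otherwise dominate the coefficient. Hierarchical
clustering uses Ward linkage on 1 − Tanimoto.

**Pair table.** A modeling row concatenates the two drugs' vectors
(stored order: lexicographic by drug id) with the ComboScore target.
Training rows are duplicated with the halves swapped (reverse-order
augmentation), strictly *after* splitting and only on the training side,
so no pair can appear on both sides of a split in either order. At
inference the model is evaluated on both orders and the two outputs are
averaged, making predictions exactly invariant to drug order.

**Learners.** Random forest (default 250 trees, a third of the features
per split; a "baseline" preset of 1000 trees with all features matches the
untuned start of the exploratory ladder), XGBoost (one fixed "recommended"
preset — 200 rounds, learning rate 0.1, depth 6 — plus a small tuning grid
selected on an inner 90/10 split of the training data only), and elastic
net as the linear baseline. All learners are seeded and deterministic
given the seed.

**Reliability.** For forests, every prediction carries `tree_SD`, the
population standard deviation (divisor T) of the individual tree
predictions, averaged over the two drug orders. Test predictions are
stratified into the ⌊qN⌋ lowest-tree_SD ("most reliable") and highest
("least reliable") subsets, q = 0.25 by default, ties broken by stable
input order. Strata are compared by RMSE: restricting to a stratum also
restricts the score variance, which makes correlation-based metrics
incomparable across strata.

**Metrics.** RMSE; R² = 1 − RMSE²/Var(y_obs) with *population* variance,
so the identity holds exactly as computed; Pearson r; Spearman r as
Pearson on average-ranked values. With constant observations the
correlation metrics are undefined and reported as NaN with a `degenerate`
flag; RMSE remains valid. R² can be negative for predictions worse than
the mean.

**Validation.** Uniform random splits (default 90/10, unstratified);
k-fold; leave-one-drug-out (one fold per drug, every combination
containing the drug in the test set — so each pair appears in exactly two
test sets across folds); Y-randomization (targets permuted across rows
before training, features untouched); and a screening-center comparison in
which per-center models are evaluated on shared partitions (identical pair
keys in the test sets) and single-agent replicate sets matched across
centers are compared by their growth SD. Replicates are defined by
distinct test dates; same-date duplicates are averaged first. LODO uses
the recommended (untuned) settings: tuning per fold and cell line is
disproportionate to its marginal gain.

## The synthetic screen

The generator emulates the *shape* of a real combination screen so every
pipeline stage can be exercised and the headline properties tested without
any download.

**Library.** Drugs are drawn reproducibly from an embedded pool of ~260
RDKit-verified drug-like SMILES (combinatorially generated and
canonicalized; labeled synthetic). Libraries of ≥10 drugs always include
one structural outlier (inorganic/polyhalogenated) so similarity analyses
have something to set apart.

**Planted truth.** Drug feature vectors (default blocks: counted Morgan +
physchem, 263 per drug) are standardized and projected onto k = 4 latent
factors; each factor loads on only 3 randomly chosen feature columns
(`latent_sparsity`). Sparse loadings matter: axis-aligned trees cannot
recover a target driven by dense random projections at this sample size.
The planted surface for pair (A, B) on cell line c is

```
g = 0.7·[m_A + m_B] + 0.3·sat₂(Σ_l w_c[l]·x_A[l]·x_B[l]),   m_D = tanh(x_D)·w_c
s_true = β · 2.5·tanh(g/σ_g/2.5) + offset_c
```

with w_c a per-cell-line weight vector and offset_c ~ N(0, 5). The
interaction term is tanh-saturated at 2 SD (`sat₂`) and the whole surface
at 2.5 SD because product interactions are heavy-tailed: a handful of
extreme planted scores at the edge of latent space would be unlearnable
from the remaining pairs and would dominate RMSE. β (default 40) is the
planted signal SD in ComboScore units. The surface is symmetric in (A, B)
by construction and nonlinear in the concatenated features, so the linear
baseline underperforms tree ensembles on it, and β = 0 leaves only the
cell-line offsets.

**Heteroscedastic noise.** Each pair carries a hardness h ∈ [0, 1): the
rank-uniformized magnitude of the pair in latent space (sum of absolute
cross-products plus per-drug magnitudes). Rank-uniformization keeps the
hardness spread independent of library geometry. The ComboScore noise SD
is `base + driver·h + center_sd` (defaults 3 + 40·h + the center's
replicate noise SD). Extreme pairs are thus both intrinsically noisier and
sit in sparser feature regions — exactly the situation tree-disagreement
reliability scores are meant to detect, which is what makes the
reliability-stratification property testable. The realized noise is a
scaled Rademacher draw (±SD with equal probability): mean 0 and SD exactly
as planted, with the per-pair error magnitude pinned to the planted scale
so stratum error compositions reflect the noise model rather than
secondary sampling noise.

**Grids.** Single-agent growths follow smooth Hill-type dose curves
bounded in (0, 85] over a 3×3 grid of concentrations {0.1, 1, 10}; the
combination cells are set at the Bliss expectation minus the noisy score
spread uniformly over the nine cells, so `combo_score(grid)` returns the
planted score plus noise exactly (and exactly `s_true` under a zero-noise
configuration — a property test). Noisy scores are clipped at ±120 to
keep all emitted growths inside the truncation window; with the saturated
surface the clip essentially never binds.

**Centers.** Two centers are configured by default, matching the
published testing intensities: FG-like (mean 3.77 test dates per
drug–cell line, replicate noise SD 6) and FF-like (mean 7.13, SD 18).
Test-date counts are 1 + Poisson(mean − 1). Both centers measure the same
tuples (unlike the real screen) so replicate sets and partitions can be
matched exactly in the paired comparison. A missing fraction of 0.0865
reproduces the published 91.35% matrix completeness.

**Randomness.** One master seed feeds named substreams (library, truth,
noise, missingness, replicates), so each stage is reproducible in
isolation.

**What the generator does not emulate.** Real pharmacology (mechanisms,
target classes, dose–response shapes beyond a generic Hill curve), the
real score distribution, center-disjoint tuple coverage, plate/batch
structure, and cell-line biology (cell lines differ only through weight
vectors and offsets). Passing tests therefore demonstrate that the
pipeline's machinery — featurization, scoring, splitting, learning,
reliability, and the analysis logic — behaves correctly and that the
claimed phenomena (reliability ordering, noise-driven center differences,
chance-level Y-randomized performance) occur when their causes are
actually present in the data; they do not certify accuracy levels on any
real screen.

## Problem sizes and numerical choices

Default study conditions: 40 drugs (780 pairs), 5 cell lines, counted
Morgan + physchem features (526 per pair). End-to-end experiments in the
test suite and acceptance script use these defaults; the Y-randomization
control runs at 25 drugs × 2 cell lines × 11 permutation seeds and the
center comparison at 30 drugs × 3 cell lines, sizes chosen so each
experiment completes in minutes on one CPU while leaving the tested
contrasts far from marginal. Reliability strata are evaluated on a 25%
test split rather than 10% so each quartile stratum holds ~45 pairs; with
~18-pair strata the stratum RMSE is dominated by sampling noise.

Ties in tree_SD and in Spearman ranks use stable order and average ranks
respectively. Strata sizes use ⌊qN⌋. The both-zero Tanimoto is 0, not
NaN, so degenerate synthetic cases compare cleanly. Structures whose
valence perception fails (some organometallics) fall back to a permissive
parse with a logged warning rather than failing the batch.

## Known limitations

* Fragment-descriptor feature counts are labeling-scheme-specific and not
  comparable across implementations.
* The XGBoost tuning grid is small and its inner validation is a single
  split; it demonstrates the tuning contract rather than exhausting the
  hyperparameter space.
* `tree_SD` is a relative, not calibrated, reliability score: it orders
  predictions within a model but its scale is not an error estimate.
* Confidently wrong predictions (all trees agreeing on a wrong value in a
  feature region unsupported by training data) receive low tree_SD; the
  stratified-RMSE ordering is a statistical, not per-point, guarantee.
* The simplex-fragment enumerator is exact and therefore O(n⁴); very large
  molecules require raising the atom cap consciously.
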