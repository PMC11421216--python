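# Methods

This note documents the models and procedures `ophpred` implements, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical and design choices made where the design was genuinely open.

## Curation

An id's observations are pooled after replacing each (lo, hi) range by its
midpoint; the id is dropped when the pooled values have standard deviation
above `std_threshold` (default 1.0 pH), otherwise labeled with the pooled
mean. Choices a user may want to know:

* **Std flavor.** "Standard deviation" is taken as the *population* std
  (divide by n), with a strict `>` comparison — so a {6.0, 8.0} pair
  (std exactly 1.0) is kept. Singletons have std 0 and are always kept.
* **Mixed points and ranges** for one id are pooled after midpointing; the
  midpoint participates in the std test like any point value.
* **Bounds.** All pH values are validated into [0, 14] at ingest.
* **Growth pH** is aggregated per organism first (unweighted mean over
  organisms of per-organism means), so heavily re-measured organisms do not
  dominate; the same std > 1.0 discard applies over per-organism means, at
  the caller's discretion.

## Homology split

Pairwise similarity is the number of identical aligned residue pairs in an
optimal global alignment scored match = 1, mismatch = 0, gap = 0 —
equivalently the longest-common-subsequence length — divided by the length
of the *shorter* raw sequence (the stricter normalization). Distance is
1 − S. DBSCAN (scikit-learn, precomputed metric) clusters the distance
matrix; all noise points are merged into a single **orphan cluster** rather
than dropped, and that cluster participates in packing like any other
(possibly very large) cluster. Whole clusters are shuffled by seed and
packed greedily into validation until |validation| ≥ round(n/4), so the
achieved fraction is within one assigned-cluster size of 3:1.

* **Leakage guarantee.** At `min_samples = 1`, DBSCAN reduces to the
  connected components of the ε-threshold graph, and every
  train/validation pair is then separated by distance > ε — this is the
  setting in which the no-leakage property is exact, and the one the test
  suite verifies against a union-find oracle. At the library-default
  `min_samples = 5`, border/noise handling can place two sequences within
  ε on opposite sides (both ends in the orphan cluster notwithstanding);
  the flag is exposed because larger values suppress chaining through
  sparse regions.
* MSA-derived or otherwise precomputed similarity/distance matrices are
  accepted as delimited text for users who prefer external aligners; the
  built-in aligner exists so the pipeline has no external binary
  dependencies.

## PFAM and EC splits

PFAM hold-out: one split per annotation accession; validation is every id
carrying it, training is everything else including unannotated ids;
accessions whose validation side would be empty or the whole dataset are
skipped and reported. EC split: the top-level class is the integer before
the first dot (truncated codes like `3.2.1.-` parse fine); ids annotated
with class 3 *and* any other class are discarded as bifunctional, pure
hydrolases are dealt into `n_folds` seeded near-equal folds, all other
annotated ids form the non-hydrolase training pool, and unannotated ids are
reported as discarded so the three parts always partition the dataset.

## k-mer baseline

Training tables store, per k-mer, the mean/min/max/count of source-sequence
labels. Each *occurrence* of a k-mer in a training sequence contributes one
copy of that sequence's label (multiset semantics), mirroring the
occurrence weighting applied at query time; a set-mode flag counts each
sequence once per distinct k-mer instead. Prediction is
(Σ P_i T_i)/N:

* **literal** mode takes N = len − k + 1 and T_i = 0 for unseen k-mers —
  the faithful definition, but absent k-mers drag predictions toward pH 0,
  which is chemically absurd for low-coverage queries;
* **present_only** divides by matched occurrences only, keeping
  predictions inside the convex hull of training labels, and falls back to
  the training median (flagged) when nothing matches. This is the
  recommended mode in practice; literal remains the default for
  faithfulness.

`k` defaults to 3 (8,000-entry canonical vocabulary — dense enough at
small n, specific enough to carry signal); the vocabulary is stored
sparsely and open (noncanonical residues form k-mers verbatim).

## Embeddings

The averaged one-hot encoding maps a sequence to its residue-composition
vector over the fixed alphabet `ACDEFGHIKLMNPQRSTVWY`; noncanonical
symbols contribute an all-zero row but count in the denominator (entries
sum to the canonical fraction), or a 21st channel when requested. Deep
embedders (e.g. ESM-2, d = 1280, mean-pooled) are *adapters* satisfying the
same contract — deterministic per-sequence transform of declared dimension
— and precomputed embedding tables import from delimited text, so the
pipeline runs offline without any deep-learning dependency. All sequences
are truncated to their first `max_length` residues (default 5000) before
embedding; truncations are counted and logged.

## Regression and model selection

KNN uses Euclidean distance with uniform or inverse-distance weights; the
gradient-boosted model is XGBoost with seeded fitting; the naive baseline
stores only the training-label median — the constant that minimizes MAE,
hence the floor any model must beat. Grid search is seeded 5-fold CV
minimizing MAE (the headline metric; Spearman available), ties broken by
grid order. Default grids: KNN n_neighbors ∈ {1, 3, 5, 10, 20} ×
weights ∈ {uniform, distance}; GBT depth ∈ {3, 6} × trees ∈ {100, 300} ×
learning rate ∈ {0.05, 0.1}; both user-overridable. One pipeline-level
seed drives fold shuffling, tree fitting, splitting and simulation.

## Evaluation

Spearman's ρ uses average ranks with product-moment correlation (the
standard tie correction), which equals 1 − 6Σd²/(n(n²−1)) exactly on
tie-free data; it is *undefined* (reported as NA) when either vector is
constant — the naive predictor's situation — rather than coerced to 0.
The δ filter removes test points with |y − center| < δ (open vicinity; a
flag switches to the closed boundary) where the center is the **training**
median, not the pooled-dataset median, so test labels never influence the
protocol beyond the filtering itself. The filter applies to the test side
only. Per-group (e.g. superkingdom) rows report n, MAE and ρ per stratum.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline exists to
handle, with defaults acting as the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_families × members | 20 × 25 | point-mutant radiations of family seeds |
| seed_length | 120 | residues per sequence |
| mutation_rate | 0.05 | per-residue substitution probability per member |
| ph_range | (4.5, 9.5) | non-neutral family base pH span |
| neutral_fraction | 0.56 | families with base pH in [6, 8] |
| label_noise_sd | 0.3 | Gaussian noise per measurement, pH units |
| measurements_per_record | 2 | observations per sequence (20% as ±0.2 ranges) |

Families cluster tightly in identity space (within-family distance ≈
2·mutation_rate ≪ between-family ≈ 0.5), so homology splitting holds
whole families out. Half the families carry hydrolase (class 3) EC codes;
PFAM accession = family id; superkingdoms are drawn at realistic
bacteria/eukaryote/archaea proportions.

**The planted signal.** Residue composition encodes the family's base pH
through three staggered logistic gradients: within each residue pair-group
(basic/aromatic vs acidic/polar, and two hydrophobic/small pairs) the
"alkaline" group's frequency share follows a logistic in
(pH − switch)/0.6 with switches at pH 5, 7 and 9. Staggered switches keep
the composition informative across the whole range (a single logistic
saturates in the tails); the mapping is a stylized stand-in for the real
correlation between surface-charge chemistry and pH optimum, not a
biochemical claim. Setting `composition_coupling=False` gives the null
generator in which sequences carry no label information.

Three further choices matter for interpretation:

* **Stratified base-pH sampling.** Family base pHs are drawn one per
  equal-width stratum (marginally uniform, jointly even coverage). An
  interpolating regressor cannot predict beyond the label span of its
  training families, so with only ~15 training families, i.i.d. draws
  frequently leave coverage holes that measure extrapolation failure
  rather than signal recovery.
* **Composition-matched seeds.** The seed sequence's residue counts are
  the largest-remainder rounding of length × probabilities (positions
  shuffled). Sampling positions i.i.d. would give every family a
  label-independent composition offset of multinomial size
  (≈ 0.2 pH-equivalent at length 120) that no regressor can remove.
* **Substitutions only, drawn from the family profile** — no indels, so
  the identity-alignment arithmetic stays exact and expected composition
  is preserved.

**What passing tests do and do not show.** On this generator, grid-searched
KNN over one-hot embeddings reaches ≈ 0.2–0.45 MAE on held-out families
versus ≈ 0.7–1.5 for the naive median. That demonstrates the *pipeline* —
curation, leakage control, model selection, evaluation — recovers a planted
sequence→pH signal without family leakage. It does not demonstrate that
real enzyme optima are predictable to that accuracy: real families share no
clean composition gradient, real signal lives partly in structure and
active-site detail that composition cannot see, and real data are far
noisier and biased. The generator also makes no attempt to mimic natural
amino-acid composition or real EC frequencies.

## Numerical notes

* Population statistics use numpy; pooled means are clamped into the
  pooled [min, max] to absorb one-ulp float drift (the invariant "labels
  lie within the observed range" is kept exact).
* Delimited files are written with `repr()` floats and parsed with
  pandas' round-trip parser, so write → read is bit-exact and reruns with
  one seed produce byte-identical artifacts.
* DBSCAN ties are resolved by input (id) order; all split, fold and grid
  operations are deterministic given the seed.
* Degenerate inputs fail loudly: empty datasets, a single all-covering
  cluster, more neighbors than samples, constant vectors in ρ (NA, not 0),
  δ-filtered sets with < 2 points (MAE only).

## Problem sizes

The shipped tests and the acceptance script run the full study at
20 families × 25 members (500 sequences, ≈ 125k pairwise alignments,
~5 s with the C aligner) and smaller fixtures elsewhere; all numbers in
README and this note come from those runs. Larger studies only change the
constants: every stage is O(n²) in the alignment step and linear
afterwards.

## Known limitations

* The built-in similarity is LCS-based identity, not an affine-gap
  substitution-matrix alignment; for distant homologs it overestimates
  similarity relative to e.g. BLOSUM scoring. Precomputed matrices are the
  escape hatch.
* The leakage guarantee is exact only at `min_samples = 1`.
* PFAM/EC evaluations produce many splits/folds; the end-to-end `run`
  command covers random and homology, while the PFAM/EC paths are driven
  through their functions or the `split` subcommand.
* Deep-embedding quality is out of scope: adapters define the contract,
  and the one-hot baseline is expected to be the weakest embedder on real
  data.
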