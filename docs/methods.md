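# Methods

`osteorda` implements an osteometric discrimination pipeline for reindeer
(*Rangifer tarandus*): descriptive dimorphism statistics, Mennerich
slenderness indices, the Mosimann isometric-size / log-shape-ratio
decomposition, and a from-scratch regularized discriminant analysis (RDA)
evaluated over bone-region variable subsets. A synthetic assemblage
generator stands in for a museum measurement database, so every stage is
testable without data downloads.

## Measurement registry and sample filters

Specimens are measured with standard osteometric calipers on six long bones
(humerus, radioulna, metacarpus, femur, tibia, metatarsus) and the pelvis.
The packaged registry enumerates 99 measurement codes, each tagged with an
axis class (length, breadth, depth, circumference, other) and a bone region
(proximal, distal, shaft, or whole for lengths spanning the bone). The
region tags drive the fragment-oriented variable subsets (`proximal`,
`distal`, `shaft`, plus `complete_reduced`, a small cross-region set for
intact bones). The packaged registry is a reasonable default assembled from
the standard code sets used in reindeer osteometry; any study can supply
its own registry or override the per-subset code lists, and all downstream
machinery is registry-agnostic.

Three inclusion rules define the analytical sample. Only osteologically
mature (fused) specimens are used, because sex and castration effects on
adult bone dimensions are fixed at epiphyseal fusion. Castrates enter only
if castrated before the skeletal-maturity cutoff (default 4.5 years, strict
`<`); castration after fusion leaves no osteometric trace. At most one side
per individual and element is kept (default: the more complete side, ties
to the left), so no element is counted twice. Records with unknown fusion
state are excluded by default (configurable).

## Size/shape decomposition

For a specimen with positive measurements V_1..V_n over the analysis's
variable subset:

    iSize = (1/n) Σ_v ln V_v
    LSR_v = ln V_v − iSize

iSize is the specimen's isometric size on the natural-log scale; the log
shape ratios (LSR) are scale-free. Scaling all measurements by c adds
ln c to iSize and leaves every LSR unchanged — the decomposition separates
size from shape exactly. The log base is fixed to natural; any other base
rescales both quantities by one common constant and changes nothing
downstream (a scale-equivariance test documents this).

The LSR vector sums to zero, so one component is linearly redundant.
Classifier feature vectors are `[iSize, LSR of all codes but one]`; the
dropped code is chosen deterministically (last code in registry order) and
recorded for audit. Dropping a component, rather than leaning on covariance
shrinkage alone, keeps the LDA limit of the classifier well-defined.
iSize is always computed over exactly the subset's variables, never over
whatever a specimen happens to have, so fragment analyses and complete-bone
analyses are internally consistent.

Mennerich's indices are computed as printed in the zooarchaeological
literature: index 1 = SD × 100 / GL, index 3 = Bd / GL × 100. Both are
dimensionless; scatter constructions plot an index or a raw measurement
against another, with group labels carried for coloring. Cluster separation
in these plots is conventionally judged visually; the package additionally
emits a pairwise bounding-box-overlap diagnostic, clearly labelled
non-canonical.

Percent differences between group means use `100 (a − b)/b` with the second
argument as the reference group; a symmetric variant (mean denominator) is
available behind a flag because the convention differs between authors.
Boxplot summaries use Tukey whiskers at 1.5 × IQR, our choice.

## Regularized discriminant analysis

The classifier is a Gaussian discriminant with Friedman-style two-parameter
shrinkage:

    Σ_k(λ)   = (1−λ) S_k + λ S_pooled
    Σ_k(λ,γ) = (1−γ) Σ_k(λ) + γ (tr Σ_k(λ)/p) I

λ = 1, γ = 0 is LDA; λ = 0, γ = 0 is QDA; γ = 1 is a nearest-mean-like
spherical rule. Scores are the usual Gaussian log-discriminants with class
priors (empirical by default, uniform by flag); posteriors are their
softmax; ties break to the lowest class index. Covariances are factorized
by Cholesky; a singular regularized covariance raises with a suggestion to
increase γ or drop a shape feature.

Protocol: an 80/20 train/test split stratified by ecotype/variety and sex
(per-stratum test counts are round-half-up with a floor of one test member
for strata of at least 5; smaller strata go entirely to train with a
warning, protecting tiny groups), then (λ, γ) selection by stratified
10-fold cross-validation on the training data maximising mean balanced
accuracy, with ties broken toward more regularization (larger λ, then
larger γ). The default grid is λ ∈ {0, .25, .5, .75, 1} × γ ∈ {0, .1, .25,
.5, 1}. Reported metrics per element × subset × partition: accuracy,
balanced accuracy (mean per-class recall over classes with support), and
macro-averaged F1 (the averaging convention is stated in the output because
it is not universal). All randomness derives from one top-level seed via
named substreams, making reports byte-reproducible.

Two experiments share this machinery: three-class ecotype/variety
classification (domestic tarandus / wild tarandus / fennicus; a two-class
tarandus-vs-fennicus mode exists because the grouping is ambiguous in
practice), and one-vs-rest castrate detection. The pelvis and the tiny
wild-male group are excluded from classification by default, overridable.

## Synthetic assemblage generator

Measurements are multivariate log-normal within group × element: log-means
are `baseline + δ_g + shape_{g,v}`, with constant-correlation covariance
(default ρ = 0.6) and axis-class log-SDs (lengths 0.025; breadth/depth
0.045; circumference/other 0.04 — lengths vary relatively less in adults).
Baselines are round, anatomically plausible magnitudes per element and axis
class (they are configuration, not claims). Because group effects act on
the log scale, group differences in iSize equal δ differences exactly,
which makes parameter recovery analytically checkable.

Defaults encode the study conditions the pipeline was built around:

* seven groups with sizes 30/25/40/3/13/27/23 (castrated, intact male,
  female domestic; male, female wild; male, female fennicus);
* δ_g strictly decreasing in the observed size order male fennicus >
  male domestic > castrate > female fennicus > male wild > female domestic
  > female wild;
* gracility offsets (zero-sum per element: lengths up, shaft dimensions
  down) make females slenderer than males of the same type and fennicus
  slenderer than tarandus at equal size, while the two tarandus varieties
  share gracility — so variety separation rests on size alone, as observed;
* the castrate mean is the intact-male mean minus a castration deficit:
  the full effect (default 0.04 log units) on breadth/depth/circumference
  variables and `castration_length_sparing` × effect (default 0.25) on
  lengths, reflecting castration near skeletal maturity. Decomposed into
  size + zero-sum shape, this places castrates between intact males and
  females in size with diaphyses relatively most affected. The deficit
  magnitudes are plausible placeholders, not estimates.

Fragmentation is region-atomic: with probability p a record keeps only one
region's variables (region drawn uniformly or fixed), mirroring
marrow-extraction breakage. What the generator does **not** emulate:
within-individual correlation across elements (records are drawn
independently per element), instrument rounding hierarchies, observer
error, pathology, hybrids, or age structure. Passing tests on this
generator therefore demonstrate correctness of the statistical machinery
under the assumed log-normal group structure, not classifier performance on
real assemblages.

## Validation design and problem sizes

The test suite and the acceptance script are fully synthetic and run in
minutes on one CPU. Problem sizes were chosen as the smallest that make
each check statistically decisive: algebraic identities on 1,000 random
specimens; Monte-Carlo checks at 2,000–10,000 draws/group; classification
scenarios at 30–40 specimens/class over 7–20 seeds with a reduced
hyperparameter grid (the full grid changes nothing qualitative and is used
in the default-conditions run).

Two validation scenarios deserve explanation:

* **Parameter recovery.** Three single-group classes separated by 4 pooled
  iSize SDs (computed analytically from the configured covariance) must be
  classified at ≥ 95% held-out balanced accuracy; permuted labels must drop
  performance to chance within Monte-Carlo error.
* **Castrate null and power.** The null/power simulation uses the
  castrate-vs-intact-male design rather than the full seven-group
  one-vs-rest. In the full design, a single Gaussian fitted to the
  multimodal "rest" mixture has lower density near the intact-male centroid
  than the tight castrate Gaussian, so even a zero castration effect yields
  above-chance balanced accuracy: castration status is confounded with
  group-size structure. That is a property of one-vs-rest Gaussian
  discriminants, not a bug; the two-group design removes the confound and
  gives an exact chance-level null. Under a strong breadth deficit with
  length sparing, detection is far above chance, and the gain is much
  larger on the shaft subset than on a length-only subset. Relatedly, in
  region-internal subsets a uniform breadth deficit appears purely as a
  size shift (region LSRs are unchanged), so in mixed assemblages castrate
  detectability lives in variable sets combining lengths with
  breadth/depth/circumference — which matches the archaeological
  observation that castrate clusters emerge only from (near) complete-bone
  variable combinations.

## Known limitations

* The registry's 99 definitions and region memberships are a packaged
  default, not an authoritative standard; studies should supply their own
  lists where they differ.
* Real assemblages violate the generator's assumptions in ways listed
  above; reported synthetic accuracies characterize the machinery, not
  expected field performance.
* The one-vs-rest castrate experiment on mixed assemblages inherits the
  confound described above; interpret its balanced accuracy against the
  appropriate mixture baseline, not against 50%.
* Hyperparameter selection replicates the procedure (grid + stratified CV
  + balanced accuracy), not any specific historical software's internal
  parameterization.
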