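# Methods

This note documents the statistical model behind `hairomics`, the
defaults it ships with, and the design decisions taken where the
analysis left genuine freedom.

## Data model

The pipeline operates on a protein × subject matrix of non-negative
integer spectral counts (peptide-spectrum matches per protein per
subject) and a metadata table with family id, role (mother/child), age
in months, sex, and a relatedness flag. Absence is encoded as a count
of 0 — never NA — so Boolean presence/absence profiles are always
well defined. Per-subject totals (summed PSMs, number of proteins
observed) are derived quantities; they are never used as inputs.

Upstream mass-spectrometry processing (acquisition, database search,
FDR control) is out of scope: the pipeline starts at the count matrix.

## Filtering

A protein is retained iff its **maximum per-subject count** reaches
`min_spectral_count` (default 3, inclusive). The inclusive reading is
the default because the protocol that produced such libraries is
described both as "3 or higher" and as "greater than 3" in different
places; `exclusive=True` selects the strict rule, and neither is
asserted to be the canonical one. Structural keratins and
keratin-associated proteins (KAPs) are removed by default: they
dominate hair digests but behave as contaminants for the biological
questions here. Filtering never alters surviving counts and is
idempotent.

## Similarity and clustering

* Spearman correlations between subjects are computed as Pearson
  correlations of average ranks, hence invariant to any strictly
  monotone transform of counts. A constant subject vector has no rank
  variance; its correlations are reported as NaN with a warning.
* Euclidean distances use log(count+1) by default; the pseudocount of
  1 maps absence to exactly 0.
* Hierarchical clustering accepts single/complete/average/Ward
  linkage. Average linkage is the default — the source analysis does
  not name its linkage — and the merge order is deterministic for a
  fixed input. Trees export to Newick with branch lengths.

## Family permutation test

Statistic: the sum over families of the Manhattan distances between
the mother's Boolean profile and each of her children's. Sibling-pair
distances are invariant under mother swapping — including them shifts
the observed and every null value by the same constant and provably
cannot change the p-value (asserted exactly in the tests) — so they
are excluded from the headline statistic by default and available
behind a flag.

Null: mothers are reassigned to families by a **derangement** (no
mother keeps her own children; siblings always stay together), sampled
uniformly by rejection from uniform permutations (acceptance → 1/e,
uniformity exact). Sampling is with replacement; with 8 families there
are D(8) = 14,833 distinct derangements, so collisions are rare but
permitted. `exact=True` enumerates the full derangement set for up to
9 families.

p-value: the add-one convention `(1 + #{null ≤ observed}) / (1 + n)`,
never zero; when the observed statistic beats every null draw the
result prints as `p < 1/n` (e.g. `p<0.0002` at n = 5000).

**Known property.** The derangement-restricted null is not an
exchangeable permutation group: the observed (own-mother) arrangement
shares no mother–child pair with any derangement, whereas two
derangements share ~1 pair on average. With as few as 8 families the
null ensemble is therefore slightly narrower than the marginal law of
the observed statistic, and the test is mildly anti-conservative: the
measured type-I rate at nominal α = 0.05 is ≈ 0.08 in the test suite's
null simulation, for the sampled and the exact null alike, and also
for an abstract iid-Gaussian family-distance matrix — i.e. the
inflation is intrinsic to the restricted null with few families, not a
property of the cohort generator. Interpret borderline p-values
accordingly; the discreteness vanishes as the family count grows.

## PCA, Total Loading Scores, driver selection

PCA treats subjects as observations and uses an exact SVD of the
log(count+1)-transformed, centered (optionally variance-scaled) data —
equivalent to an eigendecomposition of the covariance (or correlation)
matrix. Signs are fixed deterministically by making each component's
largest-magnitude loading positive.

For the first five components,

    weighted score = loading × proportion of variance
    TLS            = Σ_{PC=1..5} weighted score

with the loading entered as an **absolute value** by default: TLS is
an importance measure, and signed summation would let opposite-signed
loadings cancel. Signed mode is retained behind `magnitude=False`.
Proportions of variance enter as fractions in [0, 1]; multiplying by
100 would only rescale every TLS identically. The top 5% =
`ceil(0.05 × n_proteins)` highest-TLS proteins are reported as
drivers, with ties at the cutoff broken by protein id for determinism.

"Percent of variability explained" by a protein subset is defined
operationally as 100 × (sum of per-protein variances over the subset)
/ (total per-protein variance), on the transformed scale the PCA saw.
The source analysis does not state its computation for this quantity;
alternatives (R² of the projection onto the subset's span) are out of
scope and would give different numbers.

## tSNE

Embeddings are run `n_repeats` times (default 10) with distinct seeds
derived from one master seed, random initialisation, up to 1000
iterations, and perplexity resolved from `"max"` to
`floor((n_subjects − 1) / 3)`, the common implementation ceiling.
Conclusions should be stable across repeats; a fixed seed reproduces
an embedding exactly.

Group significance permutes **labels** over a fixed embedding: under
the null the labels are exchangeable, so this is equivalent to
permuting the dataset, at 1/1000th the cost of re-embedding. The
statistic is the mean silhouette width of the grouping by default; any
`f(embedding, labels)` callable is accepted.
`p = (1 + #{null ≥ observed}) / (1 + n)` with n = 1000 by default.

## Group differences

Log2 ratios divide group-mean counts with a pseudocount (default 0.5)
added to both means, since spectral counts contain structural zeros; a
pseudocount of 0 is allowed and yields flagged infinities. With the
default alphabetical group order (`child` before `mother`),
mother-elevated proteins carry negative ratios, matching the reported
convention. Kruskal–Wallis is tie-corrected; proteins constant across
all subjects get p = 1 by convention and a flag.
Benjamini–Hochberg adjustment is applied across the proteins of one
comparison table at a time. Rank-sum comparisons are two-sided by
default and exact for small tie-free samples.

## Family-aware Random Forest

Features are log(count+1) spectral counts; samples are subjects.
Folds partition **families** (unrelated children are singleton
families): families are shuffled, then assigned largest-first to the
least-loaded fold, so fold subject-counts differ by at most the
largest family size and no family ever straddles train and test — the
leak condition is asserted on every fold of every repeat. The study
design is k = 10 folds repeated 100 times; forests use 500 trees and
library-default feature subsampling (no tuning).

Per repeat, the pooled out-of-fold predictions cover every subject
once and are scored by AUC (classification) or R² of the linear fit of
observed on predicted (regression). The summary p-value is computed on
the per-subject mean prediction across repeats: a two-sided
Wilcoxon–Mann–Whitney test between the two classes' score
distributions, or the slope t-test of the linear fit. AUC is computed
rank-based (ties half-weighted) and internally asserted equal to
U/(n₁n₂). `shuffle_labels=True` permutes the target anew each repeat,
giving the permutation null under which AUC centres on 0.5. Repeats
whose predictions cannot be scored are excluded from the mean and
counted, never imputed.

## Synthetic cohorts

The generator emulates the design and effect structure the analysis
assumes, with every size and effect configurable:

| parameter | default | meaning |
| --- | --- | --- |
| `n_families` / `children_per_family` / `n_unrelated_children` | 8 / 2 / 16 | the enrolled design (40 subjects) |
| `n_proteins` | 2269 | realistic proteome scale |
| `structural_fraction` | 0.10 | keratin/KAP-like proteins |
| `presence_prob` | 0.50 | baseline P(subject expresses protein) |
| `family_share_boost` | 0.30 | added to a related child's presence probability where the mother expresses the protein |
| `mother_depth_multiplier` | 1.5 | scales mothers' expected counts |
| `baseline_log_abundance` | Normal(log 6, 0.8) per protein | natural-log mean of the positive count part |
| `dispersion` | 0.7 | gamma-Poisson overdispersion (Var = μ + 0.7 μ²) |
| `n_age_proteins`, `age_effect_size` | 100, 0.5 | count means scaled by exp(0.5 × standardised age) |
| `n_sex_proteins`, `sex_effect_size` | 30, 1.5 | count means × 1.5 in females |

Counts follow a two-part model: presence is Bernoulli, and conditional
on presence the count is 1 + a gamma-mixed Poisson draw, so presence
always implies a non-zero count. The two parts are decoupled
deliberately: the permutation test consumes Boolean presence while
other stages consume counts, and a single count distribution could not
plant the familial effect without also moving abundances. Age enters
log-linearly because group contrasts are reported as log ratios. No
distributional form for real spectral counts is claimed; the
gamma-Poisson is a modelling choice. Mothers' ages are drawn uniformly
in 33–45 years and children's in 0.5–6 years, matching the enrolled
ranges.

What the generator does **not** emulate: protein–protein abundance
correlation, batch/run effects, compositional (fixed-depth) coupling
between proteins, peptide-level identification noise, or any real
biological pathway structure. Tests passing on synthetic cohorts
demonstrate that the machinery detects the planted effects under this
idealised model, not that the same effect sizes hold in real hair
data.

Ground truth (`truth_table`) records per-protein structural, age- and
sex-linked labels from a dedicated RNG stream, so it is always
consistent with the matrix generated from the same seed.

## Problem sizes in the test suite

The test suite scales simulations to keep the full run fast while
preserving the tested property: cohorts of 100–600 proteins (effects
proportionally reduced), 200–5000 permutations, 2–20 CV repeats with
30–200 trees, and 400 replicates for the type-I simulation. The
acceptance computation uses the full 5000-permutation design on a
600-protein cohort.

## Known limitations

* The restricted (derangement) null's mild anti-conservatism with few
  families, described above.
* `variance_explained_by_subset` is one of several defensible
  definitions; its numbers are not comparable to projection-based R².
* Random-Forest hyperparameters are fixed, not tuned; reported metrics
  are for the default configuration.
* The packaged demographics fixture carries per-subject summaries
  only; protein-level study data are not public, so protein-level
  results are demonstrated on synthetic cohorts.
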