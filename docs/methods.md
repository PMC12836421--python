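# Methods

`delhit` implements an unsupervised triage workflow for cell-based DNA-encoded
library (DEL) selection data. This note records the model, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was genuinely open.

## Input model

A campaign consists of one pre-selection reference table (barcode counts of
the naive library) and 2 x n paired selection files: n biological replicates
pulled down with a phospho-specific antibody (enriching ligands of the
receptor's active conformation, hence agonists) and n replicates pulled down
with an antibody against the total receptor. Counts are barcode read counts;
*richness* of compound i in file f is

    R_if = (C_if / total_f) / (c_i / total_pre),

the post-selection frequency relative to the pre-selection frequency.
Richness is undefined when the pre-selection count is zero; such compounds
are flagged and excluded from richness-based statistics rather than
pseudocounted, since any pseudocount choice would dominate the estimate for
rare compounds.

## Selection Performance Descriptors

Per compound, over a *scope* of replicate files:

| Tier | Symbol | Definition |
|------|--------|-----------|
| 0 | C_i | abundance count per replicate |
| 1 | R_i | richness per replicate |
| 2 | SR, SC | sums over the scope |
| 2 | SnR, SnC | number of replicates with a non-zero value (reproducibility) |
| 2 | sigmaR, sigmaC | sample standard deviation (ddof = 1, configurable) |
| 3 | phi_eff | mean over replicates with C_i > 0 of R_i / C_i |
| 3 | kappaR, kappaC | mean / standard deviation (stability) |
| 3 | phi_bal | abs(log2(kappaR / kappaC)) (richness/count balance) |

Tier-3 values are only *valid* when SR, SC, sigmaR and sigmaC are all
non-zero; invalid compounds are removed before any Tier-3-dependent stage.

The filtering stages compute descriptors on the **phospho-arm scope** by
default (`filter_scope` config). The descriptors are defined "among repeats"
of a selection, i.e. within one antibody arm; pooling both arms into one
scope makes an agonist's phospho/total contrast register as instability
(large sigma, small kappa), so a pooled filtering scope systematically
removes exactly the compounds the workflow is designed to find. The pooled
and total-arm scopes remain available for sensitivity analysis.

## Normalization

Descriptors are max-absolute scaled to [-1, 1] before the distance-based
stages (DBSCAN, one-class SVM). Max-abs scaling preserves sign and zero and
bounds the range, which z-scoring does not; a z-score mode exists as a
config option. Under max-abs scaling, above-the-mean comparisons are
identical on raw and scaled values (the map is a positive linear rescale);
the test suite asserts this.

## Block of Descriptors Filtering (BDF)

Six descriptors form three blocks: effectiveness {SR, SC}, reproducibility
{SnR, SnC}, balance {kappaR, kappaC}. A compound is kept at level 0 iff, in
every block, all member descriptors strictly exceed the dataset mean of that
descriptor (means over the Tier-3-valid set). At level 1 a fourth
*stability* block {sigmaR, sigmaC} is added under the same above-mean rule:
among survivors that are already elite, sustained high standard deviation
tracks sustained high signal. A relative-spread alternative
(coefficient-of-variation at most the dataset median) is available via
`level1_stability_mode="cv_below_median"`; it is not the default because it
penalizes compounds whose arm contrast — the agonist signature — inflates
their pooled spread. Both the comparison (mean vs median) and the
within-block aggregation (all vs any) are config knobs.

## Auto-eps DBSCAN outlier exclusion

Three independent layers cluster the survivors on max-abs-normalized
features: phi_eff (1-D), phi_bal (1-D) and the stability array
[kappaR, kappaC] (2-D). The eps radius per layer is chosen from the data:
sort the k-nearest-neighbor distances (k = min_pts, counting the point
itself) and take the value at the knee, the index maximizing the discrete
second difference of the sorted curve (a kneedle-style chord variant is
config-selectable). A constant curve gets the constant plus 10% slack.
min_pts defaults to max(4, ceil(ln n)). The removed set is the union of the
per-layer noise points; each removal records which layer(s) flagged it.
Fewer than min_pts + 1 survivors skip the stage with a warning. The
partition is verified against an exhaustive density-reachability closure
oracle for small n, and the noise set is invariant to input order and to
common feature rescaling (eps rescales proportionally).

## APT-OCSVM classification

An RBF-kernel one-class SVM is fitted in-sample on the six normalized Tier-2
descriptors {SR, SC, SnR, SnC, sigmaR, sigmaC}; decision value >= 0 labels a
compound positive. The nu parameter is tuned automatically: a 2-means
clustering of the same features gives an unsupervised reference partition,
and among grid values (default 0.02-0.30 in steps of 0.02) whose negative
fraction falls inside the target band (default 10-20%), the nu whose labels
agree best with the reference wins (agreement = fraction of points
identically partitioned, maximized over the two label alignments; ties to
the smaller nu). If no grid point lands in the band, the closest-to-midpoint
nu is used with a warning. The band is therefore a soft constraint. At level
0 negatives are removed; at level 1 the classifier only labels, and the
positive label marks the most-promising subset.

The agreement criterion is a declared surrogate for "unsupervised similarity
computing"; it is config-replaceable. One empirical caveat the tests
document: the RBF one-class decision function is not a clean density
ranking — on idealized two-blob data ~20% of the majority fringe interleaves
into the lowest decision decile, capping blob-recovery agreement near 0.93.

## Projection, comparison indicator, conditional summation, ranking

For each phospho-arm pairing, the six Tier-2 descriptors are computed per
arm on the final candidates, log-transformed and z-scored, and the first
incremental-PCA component of the total-arm block gives x, of the phospho-arm
block y (signs oriented so each correlates non-negatively with that arm's
SR). Log + z-scoring is used here, not max-abs: with linear scaling the
bounded integer descriptors SnR/SnC dominate the component and the axis
quantizes into detection counts; and because a depth rescaling of any file
shifts the log columns by constants that centering removes, the projection
is exactly invariant to sequencing depth. Compounds with x > 0 form the
positive cluster (x = 0 ties break negative).

Per compound, over paired replicates:

* comparison indicator I = sum of sign(R_phospho,i - R_total,i); the
  dominant side is the arm preferred in strictly more than half the pairs
  (even splits are ties — "over 50%" — and fall back to full sums with a
  tie flag);
* conditional sums: richness and count sums restricted to the dominant
  replicate set, so one aberrant replicate cannot flip the contrast.

Candidates (positive side, phospho-dominant) are scored by proximity to the
global ideal vertex: features (x, y, scaled I, scaled log1p conditional
richness contrast), vertex = component-wise maximum over the candidates,
score = 1 / (1 + Euclidean distance). The 1/(1+d) form is a convenience —
any monotone map gives the same ranking. The distance to the candidate
centroid is reported as a diagnostic and can be blended 50/50 into the score
(`score_use_centroid`). Ties break toward larger y, then lexicographic
compound code. With several phospho arms each pairing is ranked
independently on the shared level-0/1 survivor set, and compounds on the
positive side of every pairing carry an overlap flag.

## Shapley attribution

The level-1 classifier's decision value is explained over the six Tier-2
features. A coalition's value is the model output on a composite point
(compound values on coalition features, background-mean values elsewhere;
background = a seeded subsample of the data). Exact mode enumerates all 2^n
coalitions (n <= 12) and satisfies efficiency, symmetry and the dummy axiom
to machine precision; sampled mode averages marginal contributions over
random feature orderings and converges at the 1/sqrt(n_samples) Monte-Carlo
rate, verified against the exact mode. Decision values can be squashed
through a logistic for probability-style displays; this is cosmetic and
never feeds the ranking.

## Dual-level orchestration

Level 0: descriptors -> validity -> normalization -> BDF -> AEC-DBSCAN ->
OCSVM (negatives removed). Level 1 re-runs the same chain on the level-0
survivors with all dataset statistics (normalization scales, block means,
eps, nu) refitted on the subset, the sigma-emphasizing BDF rule, and OCSVM
in label-only mode. Every removal is logged to a per-stage report whose
counts chain exactly; the run is deterministic given seed and inputs.

## Synthetic-data generator

The generator is the package's ground-truth instrument. Default conditions
(chosen once; every figure below is a modeling decision, not a fit):

| Parameter | Default | Rationale |
|---|---|---|
| library | 100,000 compounds on a 50x50x40 building-block grid | desk-scale stand-in for a 30M-member library |
| replicates | 6 per arm | upper end of the 5-6 used in practice |
| depth | 150,000 reads/file (~1.5 reads/compound) | most members undetected in any one file, as in real selections |
| pre-selection | lognormal(0, 0.3) frequencies, 5M-read Poisson reference | modest synthesis skew; a deep unselected reference has sampling noise only |
| nonspecific binders | 3% of library, lognormal(ln 4, 0.9) enrichment, both arms, arm-bias sigma 0.2 | a weak affinity continuum, equal in both arms in expectation |
| phospho-antibody artifacts | 1% of library, lognormal(ln 40, 0.8), phospho arm only | antibody/matrix binders, the classic false-positive mode the total-arm axis exists to reject |
| agonists | 40 planted, 50x phospho / 5x total, sigma 0.1 spread, hit probability 1.0 | strong, chemically related actives captured covalently |
| replicate jitter | lognormal, sigma 0.6 background vs 0.25 agonists | replicate stability is the signature of genuine binding; nonspecific background reproduces poorly |
| count noise | negative binomial, dispersion 8 | overdispersion beyond Poisson from PCR/cell-state variation |

Counts for file f are drawn around depth x pre-frequency x enrichment,
renormalized so each file's expected total equals the depth (sequencing is
compositional). Each population exercises one failure mode: the binder
continuum populates descriptor space so that genuine strong compounds are
not isolated islands for the density-based stages; artifacts are
phospho-dominant impostors that the positive/negative cluster split must
reject; equal-arm binders are the impostors the comparison indicator must
reject.

What the generator does **not** emulate: read-level artifacts (PCR bias,
sequencing error, barcode collisions), building-block structure-activity
relationships (codes are opaque triples), correlated binder families, and
batch effects between replicates beyond the per-replicate jitter. Passing
the planted-recovery benchmark therefore shows the pipeline's statistical
machinery is sound under this generative model; it does not certify
performance on any particular real campaign.

Under the default conditions, the end-to-end benchmark (seed 42) recovers
37 of 40 planted agonists in the top 100 ranks; other seeds give 34-35.
Disabling the comparison indicator and conditional summation worsens the
mean planted-agonist rank in essentially every campaign, which is the
package's own evidence for the two ranking metrics.

## Numerical choices and degenerate inputs

* Sample (n-1) standard deviations; ddof configurable.
* phi_bal uses log base 2 (any base is a positive rescale; configurable).
* All-zero descriptor columns scale to identity rather than dividing by zero.
* All-identical compounds fail the strict above-mean rule: BDF returns an
  empty set with a warning rather than inventing an ordering.
* Coincident points give eps a vanishing positive value; nothing is noise.
* x = 0 on the central axis is assigned to the negative cluster.
* Exact ties at 50% replicate dominance keep full sums and set a tie flag.
* Richness with a zero pre-selection count is NaN, never pseudocounted.

## Problem sizes in the test suite

The default suite exercises 8k-compound campaigns for unit-level checks, the
full 100k default conditions for the recovery benchmark and the 20-campaign
negative-band check, and 30k-compound campaigns for the 20-seed ablation
comparison. These sizes keep the whole suite in the minutes range on one
CPU while leaving every stage's input large enough for its statistics to be
meaningful.

## Known limitations

* The workflow is specific to agonist-versus-binder logic (phospho vs total
  pulldown); target-sufficient vs target-deficient designs need a different
  comparison indicator.
* The negative band is enforced only when the nu grid admits it; extreme
  datasets fall back to nearest-to-band with a warning.
* The BDF pass rule, the APT agreement surrogate, and the 1/(1+d) score are
  interpretive choices where the underlying procedure is not fully
  prescriptive; each is config-exposed and documented above.
* In-sample one-class classification labels the distribution fringe
  negative; very small, very extreme true-positive populations can be
  clipped if nothing else in the library occupies their descriptor range.
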