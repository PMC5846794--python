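# Methods

This note documents the models and procedures implemented in `signet`, the
assumptions behind them, the tunable parameters, and what the synthetic data
generator does and does not emulate.

## The classification model

The input is a subjects × proteins matrix of positive abundances (relative
fluorescence units from an aptamer assay, or any comparable positive-valued
omics readout) with a phenotype table (class ∈ {control, affected}, age in
years, a treatment flag). The classifier is rank-based and subject-centric:

1. **Pre-filter.** A two-sided Wilcoxon rank-sum test per protein on the
   training subjects; proteins with p ≤ α are retained, in input order. The
   test is exact for tiny tie-free samples and uses the normal approximation
   with tie and continuity correction otherwise (scipy's policy). α is a
   method parameter searched by the optimizer over a log-spaced grid
   (default 10⁻¹² … 0.05, 12 points).

2. **Fold-change preprocessing** (long-panel mode only). Each retained
   protein's column is divided by its mean over the training subjects; the
   training means are stored and applied unchanged to held-out subjects, so
   no information leaks from the validation fold.

3. **Subject signatures.** Each subject's retained proteins are ranked by
   descending abundance (ties broken by ascending protein id, for
   determinism); the signature is the list of the first *n1* and last *n2*
   proteins. *n1* and *n2* are shared by all subjects and searched by the
   optimizer (bounds 1–40).

4. **Weighted enrichment-score distance.** For a protein set S against a
   ranking of length P, the protein at rank r carries weight
   v_r = (P + 1 − r)^w (default w = 1; w = 0 recovers the classic unweighted
   running sum). A running sum gains v_r / Σ_hits v at each hit and loses
   1/(P − |S|) at each miss; the enrichment score ES(S) is the running-sum
   value of largest magnitude, signed (a tie between the positive and
   negative extreme resolves positive). ES = +1 exactly when S occupies the
   top of the ranking and −1 at the bottom. The similarity of subjects A
   and B is the four-term symmetrization

       s(A,B) = [ES(topA|B) − ES(botA|B) + ES(topB|A) − ES(botB|A)] / 4

   and the distance is d = (1 − s)/2 ∈ [0, 1], symmetric with d(A, A) = 0.
   When a signature side is empty (n1 = 0 or n2 = 0, possible when calling
   the library directly; the optimizer never goes below 1) the defined terms
   are averaged. Because the extrema of the running sum can only occur
   immediately before or after a hit, ES is computed from the 2|S| candidate
   values in O(|S| log |S|), vectorized over all subject pairs.

5. **Classification.** A held-out subject is ranked over the training fold's
   retained proteins using the training preprocessing statistics, and
   assigned to the class whose training subjects have the smaller mean
   distance to it. An exact tie goes to "control" (deterministic; logged).

6. **Panel aggregation.** The biomarker panel is the union of all proteins
   appearing in at least one subject signature, aggregated over the
   cross-validation folds, with a record of the contributing subjects.

## Cross-validation and the permutation null

Evaluation uses stratified k-fold cross-validation (default k = 5, i.e. 20%
held out per round) with seed-controlled shuffling; stratification matters
because a 42/28 class imbalance occasionally makes unstratified folds
degenerate. The pre-filter and preprocessing are re-fitted on each training
fold.

Significance is a permutation test: class labels are shuffled B times
(default 1000) and the full cross-validation — pre-filter included — is
re-run per permutation; p = (#{null ≥ observed} + 1)/(B + 1). A permutation
under which the pre-filter retains fewer than n1 + n2 proteins leaves the
accuracy statistic undefined; such permutations are redrawn (logged), with an
informative error if almost no permutation is computable at the given
parameters. Under label-exchangeable data the held-out subject's mean
distances to the two training groups are exchangeable, so the null accuracy
of the mean-distance rule is 0.5 — not the larger-class prior — and the
permutation p-value is valid (P(p ≤ α) ≤ α), which the test suite checks by
simulation.

## The genetic optimizer

The chromosome is (n1, n2, α-index). Fitness is evaluated by full
cross-validation at fixed folds shared across all chromosomes:

- **short mode**: maximize (mean CV accuracy, −panel size) lexicographically;
- **long mode** (fold-change preprocessing on): maximize panel size among
  chromosomes with accuracy ≥ A_min (default 0.98 — a concrete reading of
  "accuracy close to 100%"); infeasible chromosomes are ranked by accuracy so
  the search still has a gradient, and an error reports the best accuracy
  found if the floor is unreachable.

Defaults: population 40, 60 generations, tournament size 3, crossover rate
0.8, per-gene mutation rate 0.15, elitism keeping the best chromosome,
deterministic under a seed. The initial population is seeded with the
smallest signature (n_min, n_min) at every α grid value before random fill;
on small cohorts the feasible region (permissive α *and* small n1 + n2) is a
sliver that pure random initialization can miss. Per-(fold, α) pre-filter
results and rankings are cached, so a fitness evaluation costs only the
distance computations; the optimizer runs in tens of seconds at full study
size (70 × 1128) on one CPU.

## Covariate screens

- **Age**: ordinary least squares of log2(level) on age, fitted per group
  (two regression lines — the pooled-with-interaction alternative would test
  the slope difference directly but is not what the per-group workflow
  reports). Implemented in closed form (slope t-test, df = n − 2), verified
  against `scipy.stats.linregress` in tests.
- **Treatment**: two-sided Wilcoxon rank-sum of treated vs untreated affected
  subjects (exact enumeration for arm sizes ≤ 10, normal approximation with
  tie/continuity correction otherwise), with the difference of arm medians on
  the log2 scale as the location estimate.
- **Ages of cases vs controls**: two-sample Kolmogorov–Smirnov (exact for
  small samples).
- **Multiplicity**: Benjamini–Hochberg within the submitted protein family —
  by default the biomarker panel, not the whole assay — with q < 0.05 as the
  significance rule throughout.

## Enrichment

Tissue-specificity categories follow the atlas-style 5× rules, applied in
precedence order: *tissue enriched* (one tissue ≥ 5× every other tissue),
*group enriched* (a group of 2–7 tissues ≥ 5× all others; only prefixes of
the descending-expression order can qualify, so the search is linear),
*tissue enhanced* (≥ 5× the mean over all tissues), *expressed in all*,
*not detected*, *mixed*. The detection threshold defaults to 1.0 expression
unit (the conventional transcript-abundance cutoff); every rule requires
detection, so an all-zero gene is *not detected* rather than vacuously
enriched. Per-tissue panel enrichment is a one-sided Fisher exact test
against the assay background, which is identically the hypergeometric upper
tail — the suite verifies the identity exhaustively for all 2×2 tables with
N ≤ 12.

Gene-set over-representation is the upper-tail hypergeometric
P(X ≥ k | N, K, n) with the assay's mapped gene symbols as background; sets
are intersected with the background before testing, and BH is applied across
the queried collection. Multi-gene analytes contribute each mapped symbol
once; the unannotated analyte is retained for classification but excluded
from all symbol-based analyses.

## Network layer

Differential proteins are called by Welch's t-test on log2 values with BH
across the whole assay (q < 0.05). A moderated empirical-Bayes test would
shrink variances on small cohorts; the plain Welch test avoids that
machinery, and the DE set is injectable for users who compute it elsewhere.

For each transcription factor, the sub-network is the union over reachable
panel targets of a minimum-length directed path chosen, among all
minimum-length paths, to maximize the number of differentially expressed
intermediate nodes — an exact dynamic program over the shortest-path DAG
(ties broken by lexicographically smallest node sequence), verified against
exhaustive path enumeration on random graphs. Each TF sub-network is tested
against each pathway with a one-sided Fisher test over the network gene
universe; BH runs across all (TF, pathway) tests and every significant
pathway is attributed to its smallest-raw-p TF, giving the
one-regulator-per-pathway table. Pathway-map edges carry the overlap
coefficient |A∩B| / min(|A|, |B|) and the shared-gene count.

Proximity of a seed gene (e.g. the disease gene) to a pathway is the minimal
unweighted shortest-path distance from the seed to any in-network pathway
member, computed by a single multi-source search; the empirical null repeats
the statistic for genes sampled uniformly without replacement from the
network nodes excluding the seed (degree-matched and pathway-excluding
variants are available behind flags), and p is the plain proportion
#{null ≤ d_obs}/n_random (an optional +1 correction exists for conservative
reporting). Unreachable genes count as infinitely distant.

## The synthetic-data generator

Protein j in subject i has log2 abundance

    b_j + affected_i·e_j + affected_i·s_j·(age_i − 9.5) + treated_i·t_j + ε,
    ε ~ N(0, sd_j),

i.e. log-normal abundances (positive, right-skewed, as aptamer RFU data
are). Defaults: 28 controls + 42 affected (28 treated), 1128 proteins,
baselines U(8, 12) log2, noise SD U(0.3, 0.8), 52 markers with |e| ~
U(1.0, 2.5) and random sign, ages U(4, 15) drawn identically for both classes
(age-matched; the centring at 9.5 makes e_j the expected class-mean
difference), 31 age markers with slopes U(−0.30, −0.08) log2/year in affected
only (two exceptions flipped to increase), 32 treatment markers with |t| ~
U(0.6, 1.5) log2 and random sign. The treatment-shift default was set from a
design-time power calculation: with 28 vs 14 arms and the noise SDs above, a
rank-sum screen at BH q < 0.05 needs shifts of this size to recover ≥ 80% of
planted markers, and 1.5–2.8-fold changes are realistic for steroid effects
on serum proteins. Age and treatment markers are drawn from the non-strong
markers so the strong markers keep clean class separation.

Six **strong markers** (three up, three down, |shift| = 2.5 log2 ≥ 6
within-group SDs, SD fixed at 0.3) are placed at rank-extreme baselines
outside the 8–12 band (15–16 log2 for the high pair plus one riser at 15;
3.75–5.5 for the low group), emulating muscle-leakage analytes whose serum
levels in cases dwarf the rest of the panel. This placement is what makes
length-2 signatures sufficient: the control top-of-ranking alternates between
the two high decliners, every case ranking is topped by the high riser, and
symmetrically at the bottom — so the short panel is exactly these six
proteins and classification is perfect by construction.

The network generator grows a preferential-attachment graph (heavy-tailed,
connected), orients edges from lower to higher attachment index for the
signaling copy, wires one designated TF to every marker through length-2
paths with differentially-expressed intermediates plus non-DE decoy paths,
and plants, in the undirected physical copy, a seed gene at a recorded
distance from a designated pathway (a subset of the markers and
intermediates). Gene-set and tissue-table generators plant, respectively, an
enriched set padded with random members, and genes satisfying each tissue
category's defining inequality with ≥ 10% margin.

**What the generator does not emulate:** assay calibration/normalization
artifacts, batch effects, missing data, heavy-tailed or correlated noise
across proteins, realistic signaling-network motifs, or annotation noise.
Passing tests therefore show that the pipeline recovers planted structure of
realistic size under a clean log-normal model — not that it is robust to the
technical artifacts of real assay data.

## Numerical and design choices

- Gene symbols are uppercased at every ingestion point; symbol joins are the
  dominant silent-failure mode.
- Rank ties break by ascending protein id; classification ties go to
  control; both are logged — determinism everywhere under fixed seeds,
  including byte-identical run reports.
- BH via `statsmodels.multipletests(method="fdr_bh")`; rank-sum/KS/Fisher/
  hypergeometric via scipy; graphs via networkx.
- The run configuration is strict YAML: unknown keys are rejected, referenced
  paths must exist before any compute, and the report records every
  threshold and stage seed actually used.

## Problem sizes used in the checks

The packaged checks run the full study size where it matters — the 70 × 1128
cohort for panel optimization (minutes on one CPU) and B = 1000 label
permutations (~1 minute) — and reduced sizes for calibration loops
(200 null cohorts at 16–24 subjects × 25–80 proteins; 200 proximity
replicates at n_random = 100 on a 400-node network), chosen so each loop
measures a rate with a binomial tolerance rather than a single draw.

## Known limitations

- The enrichment-score distance is one faithful realization of a
  "weighted enrichment score" family; other symmetrizations are possible.
- The permutation unit is the subject class label (the only exchange that
  yields a meaningful accuracy null), not the protein identity.
- Long-mode panels absorb pre-filter false positives by construction (the
  objective maximizes panel size at an accuracy floor with α capped at
  0.05); panel precision claims belong to the short mode.
- Per-group age regressions do not test the slope *difference* between
  groups; a pooled interaction model would.
- The regulator attribution (smallest-p TF per significant pathway) is one
  consistent reading of "closest transcription factor"; upstream tools'
  unpublished scoring may differ.
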