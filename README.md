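# signet

Rank-based subject-signature biomarker panels and network-based pathway
analysis for case/control serum proteomics.

`signet` is for researchers analyzing a case/control protein-abundance matrix
(e.g. aptamer-based serum proteomics of a rare-disease cohort) who want, from
one pipeline: (i) a minimal protein panel that classifies subjects, (ii) a
longer panel suited to pathway interpretation, (iii) covariate screens (age,
treatment) on the panel, and (iv) a network layer that finds
transcription-factor-rooted sub-networks, over-represented pathways and the
network proximity of a disease gene to those pathways. A synthetic-data
module generates cohorts, networks, gene sets and tissue tables with planted
ground truth, so the whole pipeline is testable without any external
download.

## The method

Each subject *i* gets a **signature**: after a Wilcoxon pre-filter
(p ≤ α on the training subjects), the retained proteins are ranked by
abundance within the subject, and the signature is the first *n1* and last
*n2* proteins of that ranking. Signatures are compared with a weighted
Kolmogorov–Smirnov **enrichment score**: with rank weights
v_r = (P + 1 − r)^w, a running sum over subject B's ranking gains
v_r / Σ_hits v at each protein of A's list and loses 1/(P − |S|) otherwise;
ES is the extreme value of that sum (±1 when the list sits exactly at the
top/bottom). The distance

    d(A, B) = (1 − [ES(top_A|B) − ES(bot_A|B) + ES(top_B|A) − ES(bot_B|A)]/4) / 2

lies in [0, 1] and is 0 for identical rankings. A held-out subject is
assigned to the class with the smaller mean distance, under stratified 5-fold
cross-validation, with significance from 1000 class-label permutations:
p = (#{null ≥ observed} + 1)/(B + 1). A genetic optimizer searches
(n1, n2, α) for the **short** panel (smallest union of signature proteins at
maximal accuracy) or the **long** panel (largest union at accuracy ≥ 0.98,
with fold-change preprocessing). The network layer maps panel genes onto a
directed signaling network, extracts per-TF sub-networks from minimum-length
paths that pass through as many differentially expressed nodes as possible,
tests them against pathway collections (one-sided Fisher, BH), and measures
the shortest-path proximity of a seed gene to each significant pathway
against a 1000-random-gene empirical null. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Generate a synthetic study (70 subjects, 1128 proteins, 52 planted markers of
which 6 are strong) and find the short panel:

```python
import signet

dataset, truth = signet.generate_cohort(signet.CohortConfig(seed=0))
params, panel, cv = signet.optimize_parameters(
    dataset, signet.GAConfig(mode="short", seed=202)
)
print(f"n1={params.n1} n2={params.n2} alpha={params.filter_alpha:.3g}")
print(f"panel: {panel.protein_ids}")
print(f"mean CV accuracy: {cv.mean_accuracy}")
print(f"planted strong markers: {sorted(truth.strong_marker_ids)}")
```

prints

```
n1=1 n2=1 alpha=8.28e-10
panel: ['A0010', 'A0018', 'A0140', 'A0693', 'A0753', 'A0862']
mean CV accuracy: 1.0
planted strong markers: ['A0010', 'A0018', 'A0140', 'A0693', 'A0753', 'A0862']
```

Signatures of length two (one top, one bottom protein per subject) classify
every subject correctly, and the aggregated panel is exactly the six planted
strong markers — the synthetic analog of a six-protein diagnostic panel read
out from per-subject rank extremes.

The same from the shell, plus the full workflow (simulate → optimize short
and long → covariates → enrichment → network → proximity):

```
signet simulate --out-dir inputs --seed 0
signet optimize --matrix inputs/matrix.tsv --pheno inputs/phenotype.tsv \
    --annotation inputs/annotation.tsv --mode short --seed 202 --out results
signet run --config run.yaml      # see RunConfig in signet/pipeline.py
```

Each stage writes its artifacts (panel TSVs, cv_result.json,
permutation.json, distance matrices, association tables, regulators.tsv,
proximity.json) and `report.json` records every threshold and seed used; two
runs with the same config produce byte-identical reports.

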