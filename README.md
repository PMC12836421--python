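# delhit

Unsupervised hit triage for cell-based DNA-encoded library (DEL) selections.

## The problem

In a DEL selection, every library compound carries a DNA barcode; a pulldown
experiment followed by sequencing turns binding events into barcode counts.
Selections performed on live cells are biologically realistic but noisy:
background signal is heavy, enrichment is weak, and replicates reproduce
poorly. For receptor-agonist discovery, a selection campaign pulls down with
two antibodies — one against the *phosphorylated* (activated) receptor, one
against the *total* receptor — across 5–6 biological replicates each. A
genuine agonist enriches in both arms but preferentially in the phospho arm;
nonspecific binders enrich equally; antibody artifacts enrich in one arm
only. `delhit` turns the per-replicate count tables into a ranked, annotated
candidate list, fully unsupervised, with every parameter recalibrated from
the data it is given.

## The method

Per compound and antibody arm, the package computes Selection Performance
Descriptors from the replicate counts C_i and richness values
R_i = (post-selection %) / (pre-selection %): sums SR and SC,
reproducibilities SnR and SnC (non-zero replicate counts), spreads σR and
σC, and the derived ratios Φeff (mean R_i/C_i), ΚR = mean(R)/σR,
ΚC = mean(C)/σC and Φbal = |log2(ΚR/ΚC)|. Two filtering levels then run the
same chain with statistics refitted each time:

1. **Block of Descriptors Filtering** — keep compounds that strictly beat
   the dataset average in every descriptor block (effectiveness,
   reproducibility, balance; level 1 adds a σ-stability block).
2. **Auto-eps DBSCAN** — density-based outlier exclusion on three descriptor
   layers (Φeff, Φbal, [ΚR, ΚC]); the eps radius is read off the knee of the
   sorted k-nearest-neighbor distance curve, so it recalibrates per dataset.
3. **APT-OCSVM** — an RBF one-class SVM whose ν is chosen automatically by
   agreement with a 2-means reference partition, targeting a 10–20%
   negative fraction; negatives are removed at level 0 and only labeled at
   level 1.
4. **Projection and ranking** — incremental PCA maps each arm's descriptors
   to one axis (total arm → x, phospho arm → y); candidates right of the
   central axis whose replicate majority prefers the phospho arm are scored
   by Euclidean proximity to the ideal vertex of (x, y, comparison
   indicator, conditional richness contrast). The *comparison indicator*
   tallies per-replicate arm preference; *conditional summation* sums
   richness/counts only over the majority-preference replicates, so a single
   aberrant replicate cannot flip a compound's contrast.

Shapley-value attribution (exact enumeration or permutation sampling) of the
classifier's decision values over the six Tier-2 descriptors is included for
interpretability, plus a synthetic-campaign generator with planted ground
truth. See `docs/methods.md` for the full model and parameter rationale.

## Worked example

Generate a synthetic campaign (8,000 compounds, 6 paired replicates, 10
planted agonists among nonspecific and artifact binders) and run the full
dual-level workflow:

```bash
delhit simulate --spec spec.yaml -o demo --seed 7   # or write manifest + .erh files yourself
delhit run -m demo/manifest.yaml -o demo_out --seed 7
```

which prints the stage funnel and output location:

```
validity(L0): 8000->7762; bdf(L0): 7762->441; dbscan(L0): 441->438; ocsvm(L0): 438->359; validity(L1): 359->359; bdf(L1): 359->42; dbscan(L1): 42->38; ocsvm(L1): 38->38
14 ranked candidate rows written to demo_out/hits.csv
```

Reading: of 8,000 library members, 7,762 had valid descriptors, the block
filter kept the 441 that beat the dataset average everywhere, DBSCAN removed
3 outliers, the one-class SVM filtered 79 residual-background compounds, and
the level-1 re-run left 38 hit candidates, of which 14 sit on the positive
(total-arm) side with a phospho-preferring replicate majority. The top of
`hits.csv`, joined with the generator's truth labels:

```
compound  indicator    score  rank    label
 14-4-11          6 0.703231     1  agonist
19-13-14          6 0.585896     2  agonist
  13-9-1          6 0.536399     3  artifact
19-15-10          4 0.512022     4  agonist
11-13-10          6 0.509153     5  agonist
```

`indicator` = 6 means the compound out-enriched the total arm in all six
replicate pairs; the score is 1/(1 + distance) to the candidate cloud's
ideal vertex, so rank 1 is the best-supported agonist candidate. At the
default study scale (100,000 compounds, 40 planted agonists at 50× phospho /
5× total enrichment) the pipeline places 37 of the 40 planted agonists in
the top 100 ranks.

Real campaigns use the same commands with your own `manifest.yaml` pointing
at delimited ERH-style count files (column 1 `bb1-bb2-bb3` compound code,
column 2 count and/or richness), plus `delhit explain` for Shapley
attribution of the level-1 classification.

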