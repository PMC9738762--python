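# Methods

This note documents the models, conventions, and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Panel data model

IC50 values are stored as a drugs × cell-lines matrix in nM; values must be
strictly positive (log10 transforms are used throughout), so non-positive or
non-numeric entries on disk are coerced to missing with a warning rather
than rejected — sensitivity-screen exports routinely contain sentinel codes.
Inputs in µM are converted on read via a unit flag. Tissue filtering is
case-insensitive exact matching on the annotation's `tissue` column; there
is deliberately no tissue ontology or fuzzy matching, so the retained set is
exactly determined by the user-supplied include list.

## Resistance classification and secondary-drug ranking

The primary drug's non-missing IC50s define an empirical distribution;
the resistance threshold is its q-quantile using the linear-interpolation
definition of the quantile, and a line is resistant strictly above it. The
default q = 0.75 treats the upper quartile as resistant — a conservative
choice that keeps the resistant set small and clearly shifted; it is a
parameter, not a constant. At least four evaluable lines are required; below
that an empirical quantile is too unstable to classify against.

A candidate drug kills a resistant line when the line's IC50 for that drug
is at or below a kill threshold. Two rules are provided:

* `per_drug_quantile` (default, q_kill = 0.5): the threshold is the drug's
  own median over **all** lines, so "kill" means "this resistant line is in
  the more-sensitive half for this drug". A relative rule avoids artifacts
  from drugs whose potency scales differ by orders of magnitude.
* `absolute`: a fixed nM cutoff, for sensitivity analyses against a
  clinically motivated exposure level.

Ranking sorts by kill count (desc), then mean log10 IC50 over the evaluable
resistant lines (asc) — the log scale prevents one extreme line from
dominating the tie-break — then drug id, so equal inputs always produce
byte-identical output. Missing entries drop a line from both the numerator
and denominator for that drug; drugs measured on fewer than half the
resistant lines are flagged `low_coverage` but kept, since dropping them
silently would hide exactly the drugs a user might want to re-assay.

## Dose-response fitting

Percent survival is raw reading divided by the untreated-control mean × 100;
the control coefficient of variation is carried on the curve object. The
four-parameter logistic is fitted on log10 dose by trust-region least
squares, with zero-dose points excluded from the sigmoid (they anchor the
normalization only). Initialization: top = max observed, bottom = min
observed, IC50 = dose whose mean response is nearest the half-range,
hill = 1; hill is bounded positive and the bottom/top orientation is
canonicalized after fitting. Replicates enter as pooled points so the
residual sum of squares reflects replicate scatter; no weighting is applied
by default. A fit whose IC50 falls outside [min dose/10, max dose×10] is
returned with `converged = False` — an extrapolated IC50 is reported but
not trusted. Monotone non-decreasing survival raises a "no response"
diagnostic instead of returning a meaningless fit.

## Median-effect synergy

Each single agent is linearized as log(fa/fu) = m·log D − m·log Dm and
fitted by ordinary least squares; the plot's linear correlation r is
reported as the usual quality diagnostic. Points with fa outside
[ε, 1−ε] (ε = 0.005 by default) are excluded — the logit is undefined at
the boundaries and extremely noisy near them — and at least three usable
points are required.

The combination index is the two-term, mutually-exclusive form
CI = d1/Dx1 + d2/Dx2 evaluated at the **observed** combination effect
(never a predicted one). A zero dose contributes no term and has an
infinite dose-reduction index. Labels: CI ≤ 0.3 strong synergism, ≤ 0.9
synergism, ≤ 1.1 additive window, > 1.1 antagonism window, with band edges
assigned to the lower band; the outer windows follow the standard
median-effect conventions. The three-term mutually-nonexclusive CI variant
and alternative synergy models (Bliss, Loewe surfaces, HSA) are out of
scope. DRI > 1 for synergistic pairs is asserted only on generated
fixed-ratio data, where it holds by construction; it is not a theorem for
arbitrary designs.

Isobologram output gives, per effect level, the additivity-line intercepts
(Dx1, 0) and (0, Dx2), and combination points in normalized coordinates
(d1/Dx1, d2/Dx2) at the pair's own fa, so a point's coordinate sum equals
its CI.

## Single-cell screen and cluster erosion

Counts are depth-normalized to 10,000 per cell and log1p-transformed; raw
counts are kept in a layer because the positivity rule reads detection, not
magnitude. A program score per cell is the mean signed normalized expression
over the program's genes (down-direction genes such as E-cadherin in the
EMT program are negated). A cell is *positive* for a program when more than
half of the program's up-direction genes are detected (nonzero raw count) —
"the pathway is expressed" is a qualitative statement, and a
detection-fraction rule is robust to dropout where a magnitude threshold
would not be. Both the continuous mean score and the positive fraction are
reported per cluster.

The double-hit score multiplies a rank score `1 − (rank − 1)/K` by the
cell-weighted positive fraction of the drug's target-pathway program over
the flagged (resistant/stem-like) clusters, mapping every drug onto [0, 1].

Cluster erosion tests, per cluster, the 2×2 table [in-cluster vs out] ×
[pre vs post] with a two-sided Fisher exact test, Benjamini-Hochberg
adjusted across clusters; *eroded* additionally requires the post
proportion to be at most half the pre proportion, so large-sample
significance on a biologically trivial drop is not flagged. Clustering
itself is an upstream input; the package ships a deterministic
k-means-on-PCs baseline for fixture generation and a nearest-centroid label
transfer (weighted by each gene's between/within-cluster variance ratio in
the pre data) for when post-treatment cells arrive unlabeled. Graph-based
community detection, embeddings, and doublet/ambient corrections are out of
scope.

## Differential expression and reverse matching

Per gene, the two-sided Wilcoxon rank-sum (Mann-Whitney U) test: exact when
both groups have ≤ 25 samples and the gene is tie-free, otherwise the
normal approximation with continuity correction. Fold change is
log2((mean_A + 1)/(mean_B + 1)) on normalized linear-scale expression; the
pseudocount stabilizes genes near zero. A gene is significant at raw
p < 0.05 **and** |log2FC| ≥ 1; the fold-change gate is read on the log2
scale because a linear fold-change threshold of 1 excludes nothing.
BH-adjusted q-values are always reported alongside, but do not gate the
default call — the raw-p convention matches how such thresholds are usually
applied in this setting, and users who want FDR control can gate on `p_adj`
themselves. Constant genes get p = 1 and log2FC = 0. The patient-cohort
contrast uses the same Wilcoxon engine as the treatment contrast rather
than an empirical-Bayes linear model; with ~50 samples per arm the rank
test has ample power and keeps the two inputs of the reverse match
methodologically symmetric.

Reverse matching intersects the two DE tables and keeps genes significant
in both with opposite directions; genes up in recurrent patients and down
after treatment are reported first, as the actionable direction.

## Synthetic generators

All generators take a seed and are bit-reproducible; every planted element
is recorded in a manifest, and recovery tests read truth only from the
manifest.

* **IC50 panel** (defaults: 265 drugs × 136 lines, matching the scale of a
  genito-urinary subset of a large public screen): log10 IC50 ~
  Normal(μ_k, 0.3), μ_k ~ Uniform(1, 3) — nM-to-µM potencies with ~2×
  assay-level spread. A 25% resistant subgroup has the primary drug shifted
  +1.5 log10 (≈30-fold); planted secondary drugs are shifted −1.0 in
  exactly those lines; 5% of entries go missing uniformly. Tissue labels
  are drawn with the per-tissue proportions of the 136-line panel subset.
  No drug-drug correlation structure or batch effects are modeled, so
  recovery rates here say nothing about confounded real-world screens.
* **Combination measurements**: for each dose pair the fa solving
  d1/Dx1(fa) + d2/Dx2(fa) = CI_true is found by bisection (the left side is
  strictly decreasing in fa, so the root is unique); Gaussian fa noise
  (default 0.02, a typical replicate-level spread for viability assays) is
  added and clipped into (ε, 1−ε). The generator is the oracle for CI
  recovery tests precisely because it inverts the same equation the
  estimator evaluates forward.
* **Single-cell counts** (defaults: 1,000 cells per condition in four
  clusters — 50% baseline, 15% EMT-high, 15% stemness-high, 20%
  NAD-salvage/PSAT1-high; 300 genes; NB dispersion 0.5; depth ~
  LogNormal(log 5000, 0.3)): program genes are elevated/depleted 2 log2-fold
  on a shared baseline abundance profile. The default erosion collapses the
  PSAT1-high cluster from 20% to 1% post-treatment, with the post
  composition drawn multinomially so the erosion test sees honest sampling
  noise. 300 genes (named markers plus filler) keep simulations fast; real
  droplet data has two orders of magnitude more genes and far sparser
  detection, so the positivity rule's behaviour at realistic dropout is
  exercised only qualitatively. No doublets or ambient RNA are modeled.
* **Patient cohort** (defaults: 100 patients, 49 recurrent / 51 not — the
  composition of the public prostate-cancer recurrence cohort this emulates;
  500 genes; log2-scale noise SD 0.4; effect 2 log2-fold): seven planted
  recurrence genes (LTB4R, IFITM3, TMEM120B, C1S, FAS, LGALS3BP, MAT2A),
  of which LTB4R/IFITM3/TMEM120B are reversed in a 6-vs-6 pre/post
  treatment contrast and constitute the reverse-match ground truth.

## Problem sizes used by the acceptance script

Brute-force ranking agreement is checked on 40 random small panels
(≤ 6 drugs × ≤ 8 lines over a coarse IC50 grid with ties and missing
entries); planted-secDrug recovery over 200 panels at generator defaults;
sham-CI over 50 parameter draws and noisy CI recovery over 100 experiments;
4PL recovery over 50 noisy curves; Wilcoxon calibration on 10,000 null
genes (n = 20/20) and sensitivity on 100 planted of 5,000 genes
(n = 30/30); reverse matching over 200 cohorts; erosion power over 200 and
null false-flag rate over 500 simulations. These sizes give Monte-Carlo
standard errors comfortably below the margins being checked.

## Known limitations

* The ranking quantiles (q, q_kill) are conventions; different choices
  change the resistant set and kill counts, and no attempt is made to pick
  them from data.
* The 4PL fit reports a single least-squares estimate without confidence
  intervals; profile-likelihood or bootstrap uncertainty is future work.
* Median-effect OLS weights all usable points equally; points near the fa
  clipping bounds are noisier than mid-curve points.
* The erosion test conditions on cluster labels; label-transfer error
  propagates into composition counts and is not accounted for in the
  Fisher p-value.
* Generators plant clean, independent effects. Passing recovery tests
  demonstrates correctness of the estimators under the stated models, not
  robustness to correlated biology, batch structure, or annotation error.
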