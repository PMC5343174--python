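# Methods

## The clustering model

`opticlust` assigns dereplicated amplicon sequences (typically 16S rRNA gene
fragments) to operational taxonomic units (OTUs) de novo, judging every
candidate assignment by how faithfully it reproduces the pairwise
close/far relation between sequences. Two sequences are *close* when their
pairwise dissimilarity is at or below a cutoff (default 0.03); the boundary
is inclusive, so a pair at exactly the cutoff counts as close. Over all
n(n−1)/2 unordered pairs a partition induces a confusion matrix:

* TP — close pair, same OTU
* FN — close pair, different OTUs
* FP — far pair, same OTU
* TN — far pair, different OTUs

and the default quality score is the Matthews correlation coefficient,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which balances all four counts. Thirteen other registered metrics
(sensitivity, specificity, accuracy, F1, PPV, NPV, FDR, TP+TN, FP+FN and the
four raw counts) can drive the optimizer instead; each has a fixed direction.

Only the boolean close/far relation is stored after reading a distance file,
as a sparse adjacency over sequence names. Memory is proportional to the
number of close pairs, not to n².

## The optimization procedure

The search is seeded with every sequence in its own OTU (default) or all
sequences in one OTU. Each iteration interrogates every sequence once, in a
shuffled order drawn once per run from `shuffle_seed`, and scores three kinds
of placement: stay, move to a fresh OTU, or move into any OTU that contains
at least one close neighbor of the sequence. The best placement is committed
immediately (sequential update). OTUs that empty out are dropped at once.

Restricting candidates to neighbor-containing OTUs is lossless: placing a
sequence into an OTU with none of its close neighbors adds only false
positives relative to the fresh-OTU option, which therefore always scores at
least as well under every registered metric. This restriction is what makes
each iteration proportional to the number of close pairs.

The confusion matrix is maintained incrementally. Removing a sequence with c
close neighbors inside its OTU of size m subtracts c true positives and m−1
within-OTU pairs; inserting it into a candidate OTU with c′ internal
neighbors and m′ members adds c′ and m′ respectively. FN and TN follow from
the run-constant totals (FN = close − TP, TN = pairs − within − FN). A test
hook (`validate_every_move`) recomputes the matrix from scratch after every
committed move and raises on any divergence.

**Stopping.** After each iteration the metric is recorded. With `delta` > 0
(default 0.0001) the run stops the first time the absolute per-iteration
change falls below `delta`; with `delta` = 0 it stops only when the metric is
exactly unchanged, which — because moves are committed only on strict
improvement — implies a fixed point of the single-move neighborhood. A
`max_iterations` cap (default 100) bounds the run regardless. Traces are
monotone in the metric's direction by construction.

**Tie-breaking.** On equal scores the sequence stays in its current OTU; the
fresh-OTU option is preferred next; remaining candidates are scanned in a
deterministic order (decreasing size, then lexicographically smallest
member). Preferring "stay" is what makes one-sided metrics (minimize FP,
maximize specificity / PPV / TN) converge to the all-singleton partition —
zero false positives and the maximum number of true negatives — rather than
wandering among equally-scoring merges.

**Zero-denominator conventions.** MCC with FP = FN = 0 is defined as 1 (no
errors of either kind, e.g. all singletons on a graph with no close pairs);
any other zero marginal yields 0. Ratio metrics with an empty denominator
return the optimum under their direction. These states are reachable from
degenerate seedings, so the conventions matter for the optimizer's first
steps.

## Replicates and stability

`cluster_replicates` reruns the optimizer with consecutive shuffle seeds
(seed, seed+1, …). `stability_report` summarizes the final metric and OTU
count across replicates as mean, sample (n−1) standard deviation, and the
percent coefficient of variation, %CV = 100·sd/mean.

## Taxonomic splitting

`split_cluster` groups sequences by their taxonomic label at a chosen rank
(kingdom … genus), clusters each taxon independently, and merges the OTU
lists. Close pairs that straddle two taxa can never be co-clustered and are
reported as forced false negatives; the merged partition is always scored
against the full graph so this cost is visible. Sequences unclassified at
the split rank are grouped under their deepest classified label
("Xaceae_unclassified"), the usual classifier-output convention; bootstrap
confidences in parentheses are stripped on input. Per-taxon shuffle seeds
are derived from the run seed and a CRC of the taxon label, so results do
not depend on taxon enumeration order. With a single taxon the procedure
reduces bit-for-bit to plain clustering.

## Synthetic data

The planted-partition generator emits a full pairwise distance file for a
known ground-truth clustering: within-cluster distances uniform on
[0.005, 0.03], between-cluster on [0.05, 0.25], all straddling the 0.03
cutoff. An optional per-pair noise rate redraws a pair's distance from the
opposite range, flipping its close/far status — a minimal stand-in for
sequencing error pushing pairs across the threshold. Abundance profiles
follow the standard mock-community designs: *even* gives every sequence 100
reads; *staggered* draws i.i.d. uniform integers on [1, 200]. The taxonomy
generator assigns whole truth clusters to genera and misassigns individual
sequences with a configurable probability, emulating classifier error. All
generators are pure functions of spec + seed, and fixtures are always pushed
through the real text-format readers.

What the generator does *not* emulate: actual sequence content, alignment
artifacts, chimeras, non-uniform error profiles, or the metric structure of
real distance matrices (triangle-inequality violations near the cutoff,
heavy-tailed neighbor counts). Passing planted-recovery tests shows the
optimizer finds structure that is unambiguously there; it does not certify
clustering quality on real communities.

## Known limitations and degenerate landscapes

* **Local optima.** The single-move neighborhood has genuine local optima.
  On small dense random graphs (n = 7, edge probability 0.4) best-of-10
  shuffled runs from singleton seeding reaches the exhaustive global MCC
  optimum on roughly 95% of instances and lands within a few hundredths
  elsewhere — and on some instances every restart funnels into the same
  suboptimal basin. Repeating the assignment with several seeds and keeping
  the best result is recommended practice.
* **One-OTU seeding can stall.** From the single-OTU seed every pair is
  co-clustered, so TN = FN = 0 and the MCC is 0 by the zero-marginal
  convention. Extracting one sequence of degree d changes the MCC numerator
  by (n−1)(close − d·n/2): sequences of below-average degree escape, but on
  saturated, near-degree-regular graphs (e.g. noiseless planted cliques) no
  single move strictly improves the metric and the search legitimately
  stops at or near the monolith. Planted-partition instances are therefore
  reliably recovered from singleton seeding but not, in general, from
  one-OTU seeding — consistent with one-OTU seeding being the slower and
  weaker mode on real data as well. Singleton seeding is the default.
* **Pure-clique sub-problems.** A taxon whose members are all mutually close
  has TN = 0 in every state, the MCC numerator is identically zero along the
  merge path, and singleton seeding cannot assemble it. Realistic taxa hold
  many OTUs and plenty of far pairs, so this arises only in minimal toy
  fixtures; the test fixtures give each genus several planted clusters.

## Problem sizes used in the checks

The bundled verification runs use: 10,000 random confusion matrices for the
MCC formula; 500 random (partition, graph) instances with n ≤ 50 against a
brute-force pair loop; 100 full clustering runs (n ≤ 100) with per-move
recomputation of the confusion matrix; 100 random n = 7 graphs compared with
exhaustive enumeration of all 877 set partitions; a 165-sequence planted
community with cluster sizes 1–10 for recovery and stability (10 replicates);
and an 18-sequence, 4-cluster, 2-genus community with 25% misclassification
for the splitting analysis. Everything runs in seconds on one core.
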