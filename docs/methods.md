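# Methods

## Problem setting

The pipeline asks, for a case/control transcriptomics experiment of a
fibrotic disease: which biological pathways does the disease's gene
signature implicate beyond what network topology alone would produce, and
which signature-inverting drugs deserve testing priority once structural
similarity to clinically failed compounds is taken into account.  The
package implements every stage as a library function over plain-text
tables, with a synthetic-data generator standing in for the repository
downloads and web-service exports the original analyses consumed.

## Differential expression

Microarray-style intensity matrices are quantile normalized: each
column's sorted values are replaced by the row means of the column-sorted
matrix, so all columns share one empirical distribution exactly.  Ties
within a column are broken by row position (ordinal ranks); this keeps
the operation exactly idempotent and the multiset identity exact, at the
cost of an arbitrary but deterministic assignment among tied entries.
Data that arrive log2-transformed but unnormalized are unlogged,
normalized and re-logged.

Count matrices are filtered to genes with CPM ≥ 1 in ≥ 2 libraries *of
each group* — a gene expressed only in cases survives in neither reading
of the rule and is dropped — then scaled by TMM factors.  The TMM
reference sample is the one whose upper-quartile CPM is closest to the
mean upper-quartile; per sample, log2 ratios (M) and mean log abundances
(A) versus the reference are trimmed by 30% and 5% per side respectively
and combined with inverse delta-method variances; factors are rescaled to
geometric mean 1.

The per-gene test is a two-sided Welch two-sample t test on the log2
scale (log2 CPM + 0.5 for counts).  The original analyses used limma's
moderated statistics and edgeR's quasi-likelihood F test; this package
deliberately does not re-implement empirical-Bayes moderation — the
bespoke content of the protocol is the *surrounding filter logic*, and the
test is isolated behind one function (`normalize_and_test`) so a
different test can be substituted without touching the filters.  The
filter chain order is: significance cutoff first, then dual-sign-probe
removal, then lowest-p duplicate resolution, then top-150 capping by
|logFC|.  Running duplicate resolution *after* the significance filter
matters: an insignificant opposite-sign probe does not disqualify a gene.

Per-disease aggregation across experiments is the union of per-experiment
signatures (the most inclusive reading; per-gene provenance is retained
so an intersection analysis remains possible downstream).

## Gene map and pathway network

The gene map sums per-evidence-type weights (co-expression, physical,
pathway co-membership; each in (0, 1]) into one edge weight per gene
pair.  The upstream label-propagation machinery that produces such
weights in practice is not re-implemented; the module starts from the
exported weight table, which is exactly what a practitioner consumes.

The pathway network links two pathways by their shared-gene count.  All
routing uses edge length = 1/weight: heavily overlapping pathway pairs
are "close".  Topology diagnostics (weighted betweenness, strength,
degree) use the same length convention as the walker, so the flagged
top-5% hubs are precisely the nodes shortest-path traffic favors.
Whether the original diagnostics used weighted or unweighted betweenness
is not stated anywhere; weighted was chosen for internal consistency.

## The guided walk

Per iteration: draw a target pathway; traverse the weighted shortest path
from the current pathway to it; increment every pathway on the path
except the origin (a src = dst draw increments the target once);
increment traversed edges; move to the target.  In guided mode the target
is drawn by sampling a gene with probability proportional to its strength
in the gene map, then one of that gene's pathways uniformly; in the null
("random") mode the target is uniform over pathways.  Walks are confined
to the largest connected component; excluded pathways are reported, and
unreachable targets are redrawn and counted.

These precise selection/traversal rules are this package's own
operational definition.  The walk methodology it reconstructs is
described qualitatively in its source publications (shortest-path
traversal, gene-map guidance, hub bias in the null), and this
implementation realizes those properties without claiming tally-for-tally
equivalence with the original software.

Shortest paths are deterministic: among equal-cost paths the
lexicographically smallest node sequence wins (heap entries are
(cost, path) tuples, so ties resolve at pop time).  One visible
consequence: on an even cycle, antipodal pairs always route through the
low-numbered side.  Tests that rely on vertex transitivity therefore use
odd cycles.

Defaults: 5·10⁴ iterations, with a convergence diagnostic (L1 distance
between the visit distributions of two independent half-length runs;
values ≲ 0.02 indicate stability).  No burn-in is used since tallies are
cumulative by design.

## Significance of walked pathways

Freq = timesWalked/totalTimesWalked per execution; Odds = Freq/(1−Freq);
OddsRatio = guided odds / random odds.  The chi-square test is Pearson's,
1 df, no continuity correction, on the raw 2×2 count table
[(visits, total − visits) guided; same random] — counts, not frequencies,
because a frequency-based statistic would be scale-free and its p-value
meaningless.  BH adjustment runs across all pathways of one run.
Pathways never visited by the random run receive a Haldane-style 0.5
pseudo-count in all four cells before the odds are formed (logged and
flagged in the output).  Significance is strict on both thresholds:
OR > 1.3 and adjusted p < .05; OR = 1.3 or adj p = .05 exactly do not
qualify.

## Drug re-ranking and structural screening

Candidates are drugs with a connectivity score strictly below −50 in any
experiment, united with every entry of the L1000-style lists (kept
regardless of score).  Aggregation of connectivity scores across a
disease's experiments is the minimum (most inhibitory), a configurable
choice since no aggregation rule is published.  Drugability is the
satisfied fraction of {MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10} (Lipinski)
and {rotatable bonds ≤ 10, TPSA ≤ 140} (Veber), boundaries inclusive.
The composite score is an equal-weights mean of functional association,
binding affinity and drugability — the original re-ranking service's
integration formula is unpublished, so the mean is an explicit,
configurable stand-in; the pipeline only consumes the resulting order.

Structural clusters come from affinity propagation on the pairwise
Tanimoto matrix (preference = median off-diagonal similarity, damping
0.9).  Exact-duplicate fingerprints are collapsed before message passing
(identical points make the updates degenerate); non-convergence and the
degenerate all-equal-similarities case fall back to connected components
at similarity ≥ 0.5, logged.  The best-composite drug per cluster (ties
by id) is its representative.

Screening builds a candidate–candidate network at Tanimoto ≥ 0.5 and
attaches failed drugs at ≥ 0.7; candidates adjacent to a failed drug are
flagged advisory — lower testing priority, never exclusion.  The
structural grouping uses Soergel distance (1 − Tanimoto) with Ward
linkage cut at height 1.  Ward formally assumes Euclidean geometry and
Soergel is not Euclidean; the combination is the stated recipe of the
screening protocol and is kept as such rather than silently substituting
an average-linkage variant.

Fingerprints are abstract bit vectors throughout.  The fingerprint type
and length behind the original similarity networks are unstated, which is
the main barrier to reproducing them structure-for-structure; bit vectors
keep every kernel well-defined without a chemistry-toolkit dependency.

## Cross-disease synthesis

The shared-drug significance test is the hypergeometric *point*
probability C(m,x)·C(n,k−x)/C(m+n,k), computed in log-gamma space —
exactly the quantity the reproduced analysis computed, not an upper-tail
enrichment p-value.  The caveat is acknowledged; `tail=True` provides
P(X ≥ x) for callers who want a conventional test.  At the published
parameters (m = 26, n = 2448, k = 25), the point probability is .002 at
x = 3, .025 at x = 2 and .206 at x = 1, which operationalizes "sharing
two or three drugs is significant, sharing one may be chance".

Key pathways are defined operationally as guided-top pathways that are
significant by the odds-ratio test *and* not flagged topology-favored —
i.e., highlighted exclusively through the gene map.  A drug is
prioritized when its targets reach at least two distinct key pathways.

## Synthetic data: what it emulates, and what it does not

The generator fabricates, from one seed: intensity matrices (normal on
the log2 scale, per-gene baselines uniform in [4, 12], noise SD 0.25) or
count matrices (Poisson-gamma with dispersion 0.1 and per-sample library
multipliers log-uniform over a 4× range, so TMM has something to
correct); functional gene-pair weight tables; GMT pathway membership;
and a drug library (fingerprints from cluster templates with 3% per-bit
flip noise — intra-cluster Tanimoto ≈ 0.85, inter ≈ 0.18 at the 256-bit,
30%-density defaults — drug-like descriptor ranges, connectivity scores
uniform in [−100, 100], and one failed drug planted as a near-duplicate
of a candidate).  Effect size defaults to 2 log2 units.  The source
studies used real repository data, so no noise or effect magnitudes were
available to copy; these defaults are calibration choices a bench
scientist would call a clear but not trivial signal.

The end-to-end bundle (`generate_bundle`) ties the pieces into one
scenario with three deliberate design choices:

- **Planted pathways are non-hubs.** They are drawn from the
  below-median-strength half of the pathway network.  The scenario models
  map-driven discoveries; planting inside the null's own top hubs would
  make "guided ≠ random" undecidable in principle (three random picks out
  of fifty collide with the null's top three ~18% of the time).
- **Planted pathways cross-talk.** A small (2-gene) clique is added to
  all planted pathways so their mutual edges carry weight and guided
  walks route between them directly rather than detouring through hubs.
  This mirrors the biology being modeled: the perturbed pathways of one
  disease share genes.
- **The gene-map module is pathway-exclusive.** Heavy functional edges
  are generated among genes belonging to only one pathway (the planted
  one); multi-pathway genes would diffuse guidance over every pathway
  they touch, which is background, not signal.  A sparse low-weight
  background layer over 40 random genes emulates incidental signature
  genes.

What passing tests therefore show: the pipeline recovers a planted,
modular, non-hub enrichment signal under realistic noise, and its null
behaves as designed (hub-dominated).  What they do not show: performance
on real platform artifacts (probe effects, batch structure), on diffuse
enrichment spread over hub pathways, or on real chemical space — the
generator makes no attempt at valid molecular structures or real KEGG
topology.

## Numerical and determinism notes

- Every generator and the walk engine are reproducible from (inputs,
  seed); pipeline stages derive their seeds from the master seed via a
  documented rule (first draw of a generator seeded with
  [master, stage index]).
- Shortest-path cost ties are resolved lexicographically with a 1e-12
  cost tolerance; the exhaustive-oracle tests use power-of-two weights so
  inverse-weight costs sum exactly.
- The hypergeometric point probability is computed with log-gamma
  differences and is exact to ~1e-15 for the sizes used.
- Degenerate inputs fail loudly where silence would bias results: missing
  descriptors, zero-count libraries, all-zero fingerprint pairs, and
  mismatched pathway sets all raise; empty signatures and zero-margin
  chi-square tables are valid results (p = 1) with logged warnings.

## Problem sizes

The default synthetic study conditions are 50 pathways (10–30 genes,
overlap factor 0.4 over a shared pool of 3× the maximum pathway size),
3 planted pathways, 2000 genes, 10 + 10 samples, 5·10⁴ walk iterations,
and a 60-drug library in 3 structural clusters with 8 failed drugs.
Recovery statistics in the acceptance script are computed over 20
replicate bundles.
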