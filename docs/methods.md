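# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Paired differential expression

The substrate is a genes × samples matrix of log2 expression in which every
patient contributes one tumour and one normal column. All statistics operate
on the within-pair differences d_gp = tumour − normal, so patient-level
baselines cancel by construction:

- logFC_g = mean_p(d_gp); plain paired t = logFC / (s_g/√n) with n−1 df.
- Moderated t (the default): per-gene variances s_g² are shrunk toward a
  pooled prior, s̃² = (d₀s₀² + (n−1)s²)/(d₀ + n−1), with the prior scale s₀²
  and degrees of freedom d₀ estimated by moment-matching a scaled
  inverse-chi-square distribution to the observed variances on the log scale
  (digamma/trigamma matching; the trigamma inverse is solved by Newton
  iteration). The null gains the prior df. The implementation is checked in
  the test suite against the reference R implementation (limma on the
  difference matrix) to four digits.
- Multiple testing: Benjamini–Hochberg step-up, implemented directly and
  cross-checked against both a literal step-up oracle and statsmodels.
- Selection thresholds default to |logFC| > 1.5 and adjusted p < 0.01, both
  strict inequalities. Direction is the sign of logFC.

Degenerate inputs: a single pair is rejected (variance undefined); genes
constant across all samples get p = 1 with a warning; genes with missing
values are dropped at container construction with a logged count.

## Enrichment

Over-representation uses the hypergeometric upper tail of the query/set
overlap in a stated universe with BH across sets (significant at adjusted
p < 0.05). Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum
(hit increments ∝ |score|^w, default w = 1; miss increments uniform); the ES
is the maximum signed deviation. The null shuffles gene labels (equivalently
draws random same-size sets); p is one-sided in the sign of the observed ES
and NES divides the ES by the mean |null ES| of that sign. Sets with fewer
than two genes in the ranked list are skipped with a warning. Annotation
retrieval is out of scope: collections arrive as GMT files, and the
generator emits a small stand-in collection with two planted disease-module
sets so the stage has signal in synthetic runs.

## Weighted key-driver analysis

A key driver is a gene whose local network neighborhood is enriched for
disease genes. Defaults mirror the published configuration: search depth 1,
undirected edges, minimum hub overlap 0.33, edge factor 0.0.

- Neighborhood: nodes within `depth` hops of the hub (hub excluded). Each
  neighbor's weight is (heaviest path product)^edge_factor, so edge factor 0
  reduces to the unweighted analysis — the whole pipeline is then invariant
  to any positive rescaling of edge weights (tested) — and edge factor 1
  uses raw edge weights at depth 1.
- Statistic: χ = (O − E)/√E with O the summed weight of disease neighbors
  and E the total neighborhood weight times the disease fraction of the node
  set. The upstream webserver's exact statistic is not published; this is a
  reimplementation of the described behaviour, not a bit-compatible clone.
- Null: the disease set is relabeled uniformly over the node set, preserving
  its size; per-hub p is the plain Monte-Carlo upper-tail fraction over
  n_perm = 1000 draws (resolution 1/n_perm, so the strongest hubs can report
  p = 0; an add-one floor would leave BH across thousands of hubs unable to
  certify any hub at this permutation budget). FDR is BH across all
  connected nodes.
- Redundancy: hubs sorted by statistic are kept greedily; a hub whose
  neighborhood Jaccard-overlaps an already-kept neighborhood above the
  minimum hub overlap is discarded. E = 0 (no disease gene can enter any
  neighborhood) yields an undefined statistic and p = 1 with a warning.

The permutation machinery is validated against an exhaustive
disease-placement oracle on small graphs and against the hypergeometric tail
in the unweighted depth-1 case.

## Network-proximity arm

Proximity uses the closest-distance measure from the protein-network
literature: d_c = mean over mapped drug genes of the minimum unweighted hop
count to the disease (key-driver) set; shared genes contribute 0, and drug
genes with no finite path are excluded with a logged count. Hop counts are
used even on weighted networks — edge weights are a wKDA concern.

The null preserves the drug set's degree composition: nodes are sorted by
degree and grouped greedily into bins of at least 25 (small tail merged; on
networks of only a few hundred nodes a finer bin size is appropriate and
exposed as a parameter), and each drug gene is replaced by a random same-bin
node, without replacement within a sample; an exhausted bin borrows from the
nearest bins with a warning. With n_null = 1000 samples (disease set fixed;
which side to permute is not published — the drug side was chosen),
z = (d_obs − μ)/σ and the empirical p is the plain lower-tail fraction.
Self-consistency is enforced by test: drug sets drawn by the sampler itself
score mean z within ±0.15 and sd within [0.85, 1.15]. The production run
vectorizes the null as per-bin order statistics over the precomputed
distance field; its equivalence to the per-node sampler is tested. An
alternative symmetric-average distance mode is intentionally not provided;
the single closest-distance convention keeps z-scores comparable across
libraries.

## Overlap arm

Per signature against the key-driver set: Jaccard similarity, the 2×2
overlap table's odds ratio (a·d)/(b·c) and one-sided enrichment p (the
hypergeometric tail, identical to Fisher's exact test with the 'greater'
alternative; cross-checked against scipy and a combinatorial enumeration
oracle). The Haldane 0.5 correction applies only when the denominator
vanishes; a zero numerator reports an odds ratio of 0. Fold enrichment is
reported as this odds ratio, matching how the published candidate table
couples it with the exact-test p. BH runs across the whole library. The
within-species rank is 1 − (rank_desc − 1)/N over same-species signatures by
descending Jaccard with average-rank ties — a monotone surrogate for the
upstream service's unpublished formula, normalized to (0, 1] so the
published filter "within-species rank > 0" is expressible verbatim. The
universe defaults to the network's node set, consistent with the network
arm.

## Candidate selection

Overlap arm: keep adjusted p < 0.05, species Homo sapiens, within-species
rank > 0; compute the mean Jaccard of those survivors and remove signatures
strictly below it; sort by drug, rank, Jaccard, p and keep each drug's
highest-ranking record. Network arm: keep adjusted p < 0.05 and each drug's
best (lowest) proximity rank. The final table inner-joins the two arms on
the normalized lowercase drug name (an initially empty synonym-map hook is
provided), carries the overlap-arm fields plus the network-arm z, and sorts
by ascending z.

Two deliberate subtleties. The mean Jaccard is computed after the three
keep-filters and before deduplication — the order matters because it changes
the mean. And the mean cut is a one-shot calibration against the full arm
output: re-applying the composed filter to its own survivors would raise the
mean and drop more rows, so the pipeline applies it exactly once, and the
select stage offers a `--prefiltered` mode that goes straight to
intersect-and-rank for arm tables that are already filtered and
deduplicated (e.g. a published candidate table split back into its arm
projections, which is how the packaged 25-drug ESCC table is exercised in
tests).

## Synthetic data

The generator plants recoverable truth in every input; its defaults are the
study conditions used throughout the tests.

- Expression: 53 pairs over a 2000-gene universe (scaled from the original
  cohort's 14,335 genes for test speed; full size remains a config value),
  generated directly on the log2 scale — DE math operates there and
  probe-level effects are out of scope. Gene baselines are uniform on
  [4, 12]; tumour = normal + true logFC + N(0, 0.5). 150 planted genes get
  |logFC| ~ N(2.5, 0.5) with random sign, so nearly all planted effects
  clear the 1.5 cut while the paired SE (0.5/√53 ≈ 0.07) keeps null genes
  far below it.
- Network: preferential attachment (2000 nodes, 3 edges per new node) — the
  simplest generator with the heavy-tailed degrees of PPI networks. Five
  planted hubs are drawn from the highest-degree non-disease nodes and
  rewired, degree-preservingly while possible, until 80% of their neighbors
  are disease genes (background ≈ 7.5%). Edge weights are uniform on
  [0.25, 1].
- Drug library: 100 drugs with signature sizes 30–80. Five reversal drugs
  (two study-tagged signatures each, always human) draw half their genes
  from the disease module: the disease genes are covered first, and below
  that count the draw splits 60/40 between disease genes and the "regulator
  pool" — non-disease neighbors of disease genes sampled proportionally to
  the square of their disease connectivity, which concentrates the draw on
  the hub regulators a reversing drug would target. Twenty partial mimics
  take only 10% of their genes from the regulator pool: they model targeted
  compounds that hit a hub without reversing the module, populate the
  moderate-overlap range every real library contains, and give the
  mean-Jaccard cut its intended decoy mass. The remainder draw uniformly
  (a fifth tagged non-human to exercise the species filter; the first ten
  duplicated across study tags to exercise deduplication).

What the generator does not emulate: probe/platform effects, batch
structure, correlated co-expression, weighted-edge biology (weights are
random), multi-tissue signature heterogeneity, and drug-name synonymy.
Passing recovery tests therefore demonstrate that the machinery identifies
the structures it defines, at realistic sizes and noise — not that the
thresholds are optimal for any particular real cohort.

## Reproducibility

One master seed drives everything: per-stage seeds are derived by hashing
the stage name against the master seed, so any stage can be re-run in
isolation and reproduce its slice of a full run, and repeated `run-all`
invocations are byte-identical (tested). Each run directory carries a
manifest (inputs, outputs, parameters, per-stage seeds) sufficient to
re-execute any stage. All tabular outputs are TSV with a `#` metadata
header, with JSON mirrors where machine consumption is expected.

## Limitations

- The real study's headline counts (167 DEGs, 89 → 39 key drivers, 25
  drugs) depend on a specific GEO preprocessing, STRING release and
  PharmOmics library; they are represented here by the packaged candidate
  table and by parameter-recovery at the synthetic study conditions, not
  re-derived from raw data. The cohort's two-platform probe collapse is
  likewise unpublished (the probe-collapse policy provided for real data
  keeps the probe with the largest |t| per gene).
- Directed networks, depth-weighted decay beyond the heaviest-path product,
  tissue-specific Bayesian network construction and drug-combination
  prediction are out of scope; any user-supplied undirected weighted network
  is accepted as-is.
- Permutation p-values are Monte-Carlo estimates with resolution 1/n_perm;
  ranking among the strongest hits (which share p ≈ 0) is carried by the
  statistic (wKDA) or z (proximity), not by p.
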