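# Methods

## Model and procedure

The pipeline treats a community as a samples × taxa biomass table and asks
which taxon pairs co-vary more strongly than chance across sampling events
within one turbidity class. The dependence model is deliberately minimal:
pairwise Pearson correlation on autoscaled (z-scored) biomass, thresholded
at the exact two-tailed critical value of the correlation t test,

    r_crit(n, α) = t_{1−α/2, n−2} / sqrt(t² + n − 2),

so that the edge rule |r| ≥ r_crit is identical to the decision P ≤ α.
This reproduces the convention of setting correlation-coefficient ranges
"significant at P ≤ 0.05 for sample size" per class: with no missing
cells every pair in a class shares one n (158, 180 or 136), and with
missing cells each pair uses its own pairwise-complete n. The network is
undirected; the sign of r classifies the interaction (positive =
coexistence/guild effect, negative = predation/competition) and |r| is
carried as the edge weight.

Assumptions: interactions are contemporaneous (no lags), linear on the
autoscaled scale, and marginal — no conditioning on other taxa or on the
environment. Uncorrected all-pairs testing at α = 0.05 is the default
because it is the stated decision rule of the workflow being reproduced;
it implies an expected 5% spurious-edge rate among truly independent
pairs, and a Benjamini–Hochberg option is provided for users who prefer
FDR control (it can only remove edges, never add them).

## Network statistics

All global attributes and centralities are computed on the unweighted
topology, matching NetworkAnalyzer's reported statistics; |r| weights are
attributes only, with an optional weighted-distance mode (distance = sum
of weights along a path) behind a flag. Conventions that have more than
one definition in the literature were pinned as follows:

- clustering coefficient: mean local coefficient 2e_v/(k_v(k_v−1)),
  degree < 2 nodes contributing 0 (configurable to "exclude");
- centralization: Freeman-style degree formula (n/(n−2))·(k_max/(n−1) − density);
- heterogeneity: coefficient of variation of the degree sequence
  (population sd / mean);
- "shortest paths": the count of ordered connected node pairs, which
  equals n(n−1) exactly when the network is connected;
- characteristic path length: mean hop distance over finite pairs;
- NCC: 1 / mean distance to reachable nodes (0 for isolated nodes);
- NBC: Brandes betweenness normalised by (n−1)(n−2)/2, i.e. into [0,1];
- EBC: unnormalised, summed over unordered connected pairs with endpoint
  pairs included (a single edge has EBC = 1);
- communities: divisive removal of the maximum-EBC edge (Girvan–Newman)
  until a target component count k, or until modularity (on the original
  unweighted graph) is maximal when k is unset; ties in EBC are broken by
  lexicographic edge name, making the partition deterministic.

Isolated taxa are retained in the node set and flagged; `include_isolated`
switches whether they enter the global attributes. The two conventions
differ in density and mean neighbours whenever isolated taxa exist, and
published attribute tables do not always state which was used — both are
exposed rather than guessed. Note the identity density = mean
neighbours/(n−1) holds within either convention; the test suite asserts
it on every generated network.

Between-class tests use conventional one-way ANOVA df (k−1, N−k) with
Tukey HSD letter groups (letters = maximal cliques of the pairwise
"not significantly different" graph, ordered by group mean) and
Kruskal–Wallis with df k−1. Summary tables of this kind are sometimes
printed with a single df for all rows; this package always reports the
conventional pair. Degenerate all-equal inputs return statistic 0, p 1
rather than an error. Shannon H′ uses natural log by default (bases 2
and 10 selectable) and biomass shares, not abundance shares, since the
network analysis is biomass-based; J′ is undefined (None) for S < 2.

## Synthetic data generator

The generator is a Gaussian copula: latent vectors z ~ N(0, C) with C
assembled from rho_within inside each guild, rho_neg on antagonist pairs
and background_rho elsewhere, then biomass = exp(logmean + logsd·z) and
independent zeroing with probability zero_inflation. If the assembled C
is not positive semi-definite it is repaired by eigenvalue clipping at 0
followed by re-normalisation to unit diagonal; the repair and the maximum
entry drift are reported, never silent. The lognormal marginal is an
assumption — biomass is continuous and right-skewed, and a monotone
transform of a Gaussian copula is the simplest generative model whose
dependence structure Pearson-on-autoscaled-data should detect. The
exp transform attenuates Pearson correlation (planted latent ρ = 0.7
appears as raw-scale r ≈ 0.66 at log-sd 0.6); tests account for this.

Study-fixture conditions, chosen once as field-realistic: per-taxon
log-mean spread over ≈ 0.02–1 mg/l, log-sd 0.6 (moderate skew), guild
ρ = 0.65, antagonist ρ = −0.6, zero inflation 0, and planted edge
density increasing LT (8 edges) < MT (17) < HT (47) to mirror the
qualitative density ordering along the turbidity gradient. What the
fixture does *not* emulate: seasonal succession, autocorrelation between
consecutive sampling dates, taxon-specific detection limits, and
compositional effects — so passing tests demonstrate that the pipeline
recovers planted linear co-variation at the study's sample sizes, not
that every ecological signal in real data would be recovered.

## Numerical choices

- Pairs with fewer than 4 complete observations are dropped (logged),
  as the t-based threshold needs n − 2 ≥ 2.
- Zero-variance taxa are dropped at autoscaling with a warning list that
  propagates into the run manifest, keeping the taxon counts entering
  each network auditable.
- Empty cells read as missing, never zero; missing values are excluded
  pairwise, not imputed.
- NTU boundary values 15 and 25 map to the moderate class (closed
  interval), the high and low classes being strict inequalities.
- All randomness derives from a single seed; the three class fixtures use
  child seeds spawned deterministically from it, so runs are bit-identical.
- Edge-removal and shortest-path ties break lexicographically.

## Problem sizes

The test suite and the acceptance script work at the study's native
scale (n = 136–180 samples, 22–28 taxa), 200 random graphs of ≤ 8 nodes
for exhaustive centrality cross-checks, 500 replicates for the null
calibration of the edge rate, and 2000 permutations for the ANOVA
p-value uniformity check — sizes at which each check's Monte-Carlo error
is well below its decision margin.

## Known limitations

- Pearson-only dependence: nonlinear or purely rank-based associations
  are attenuated or missed (no Spearman/partial-correlation mode).
- Uncorrected thresholding inflates edge counts in wide tables; BH is
  optional rather than default for fidelity to the reproduced workflow.
- Girvan–Newman clustering is O(E²·N)-ish and intended for the tens-of-
  taxa networks this package targets, not for thousands of nodes.
- Diversity tests treat samples as independent, ignoring repeated
  measures within reservoirs.
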