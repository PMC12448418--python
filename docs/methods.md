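# Methods

## The analysis in one paragraph

The pipeline asks how bacterial lineages (ASVs) distribute across host
individuals and host phylogeny in multi-site surveys, and whether
lineages associate with one another beyond chance.  Counts are
depth-normalized (SRS), community structure is tested by PERMANOVA on
Bray–Curtis distances, and all per-lineage statistics are computed on
repeated fixed-size host subsamples per site so that sites of unequal
sample size are comparable.  Host specialization is the standardized
effect size of Faith's PD over an ASV's occupied host species;
co-occurrence is an exact hypergeometric test per ASV pair with two
tailored null constructions; community-level association is Barber
bipartite modularity of the host–ASV network against a column-shuffle
null.

## Models and assumptions

**SRS normalization.**  For a host with depth `T` and target `c_min`,
counts are scaled by `c_min/T`; integer parts are kept and the remaining
`c_min − Σ⌊·⌋` single units go to features in descending order of
fractional part.  Exact fractional-part ties are broken uniformly at
random; each host's tie RNG is seeded from the global seed plus the
host's row position, so results are independent of processing order.
Output rows sum to `c_min` exactly, and a feature with a strictly larger
input never receives a smaller output than a smaller one (tie cases
aside).  Hosts below `c_min` are reported as excluded, never silently
dropped.  `c_min` defaults to the minimum retained host depth.

**PERMANOVA.**  McArdle–Anderson partition: with `G` the Gower-centered
matrix of `−d²/2`, each term's sum of squares is `tr((H_k − H_{k−1})G)`
for cumulative hat matrices of the dummy-coded design, in the fixed
order site → host family → site:family (sequential, type-I-like; the
order is an argument).  The pseudo-F per term uses the residual mean
square; p-values come from permuting hosts jointly across factors,
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`.  An explicit permutation list can
be supplied, which makes exhaustive enumeration on toy designs possible.
Confounded terms (no added degrees of freedom) and saturated models are
errors, not silent results.  The dispersion test embeds hosts by
eigendecomposition of `G`, keeps positive- and negative-eigenvalue axes
separately, scores each host by
`sqrt(max(d₊²(centroid) − d₋²(centroid), 0))`, and runs a one-way ANOVA
on those scores; group centroids are means by default (coordinate-wise
medians by flag), and single-host groups are excluded with a warning.

**SES-PD.**  Faith's PD of a tip set is the branch-length sum of the
union of root paths (root included; a single tip scores its root-path
length).  Host individuals map to species tips, so duplicate individuals
of one species collapse.  The null preserves richness: tip sets of equal
size drawn uniformly, `n_null = 999` by default, `z` from the null mean
and SD (ddof = 1), rank-p as `(1 + #{PD_null ≤ PD_obs})/(n_null + 1)`.
Two degeneracies are flagged rather than scored: occupying every
available tip, and star-like geometry where PD depends only on richness
(detected as null SD below `1e-9` relative tolerance; `z` is NaN).

*Null pool.*  Null sets are drawn from the **host-species pool of the
community being analyzed** (the equivalent of pruning the tree to the
community), not from all tree tips.  When the hosts at hand cover only
part of the tree, an all-tips null shifts every ASV's z in the same
direction — planted uniform generalists measured a median z near −0.6
under the all-tips null versus near −0.2 with the pooled null.  A
calculator object caches one null sample per richness value, shared by
all ASVs of a replicate.

**Exact co-occurrence.**  `P(j) = C(N1,j)·C(N−N1,N2−j)/C(N,N2)`,
evaluated through log-gamma and cached as dense (N1, N2, j) tail tables
per host count N, so classifying all pairs of a replicate is a single
vectorized lookup.  Both tails include the observed value (the standard
convention for discrete exact tests); a pair is positive/negative when
the upper/lower tail is below alpha = 0.01 per tail.  All pairs of
occurring ASVs are tested with no multiple-testing correction, mirroring
the study design; an optional `min_expected` filter reproduces the
convention of dropping pairs with expected overlap below one.  The
column-shuffle null permutes each ASV column independently (column
multisets, hence prevalences, preserved exactly).  Prevalence-matched
surrogates are drawn uniformly among ASVs of identical prevalence,
falling back to nearest prevalence with a logged substitution.

**Phylum pair excess.**  Observed = share of positive pairs with both
members in the focal phylum; expected = (phylum fraction of occurring
ASVs)².  Replicates without positive pairs are undefined and excluded
from the downstream t-test.

**Bipartite modularity.**  ASVs below two hosts are excluded at network
construction, then hosts with no remaining edges.  Barber's
`Q = (1/m) Σ_s (e_s − K_s L_s/m)`; the one-module partition scores
exactly 0 and the optimizer never returns less.  Optimization is label
propagation (each node greedily adopts the module maximizing
`e_to − deg·D_module/m`, with moves to an empty module allowed) followed
by greedy pairwise module merging, iterated, over `restarts = 20`
restarts that alternate three initializations (host-side singletons,
ASV-side singletons, random coarse partition).  An exhaustive
set-partition enumerator (incremental block statistics; practical to
~12 nodes) guards correctness in the test battery.

**Inference layer.**  Welch's t-test by default (pooled by flag), with
the convention p = 1 for two constant equal groups; one-way ANOVA with
Tukey HSD (single-value groups excluded with a warning); Bonferroni as
`alpha/m`.  The corrected threshold `1.31e-4` used in the report tables
is a configuration constant of the study design, not derived in-code.
Replicate-level testing treats the 100 subsamples as observations; this
reproduces the survey's procedure and inherits its pseudo-replication —
p-values describe resampling variability of one dataset, not fresh
communities.

## Synthetic data: what it emulates, what it does not

The generator produces six sites whose host-species pools are nested
subsets (default 5, 12, 15, 15, 29, 30 species) of one Yule host tree
(30 tips, birth rate 1), with 15–30 host individuals per site drawn with
replacement from the pool — the smallest site has 15 hosts so the
standard 14-host subsample is one fewer than the smallest site.  Host
families are disjoint clades of the host tree (largest ≈ one third of
tips).  ASV roles:

- **specialists** (40): Bernoulli(0.8) occupancy inside one randomly
  chosen host clade, Bernoulli(0.02) outside;
- **generalists** (20): Bernoulli(0.35) for every host;
- **background** (240): Bernoulli(0.015), yielding a realized singleton
  fraction around 0.2–0.3;
- **cohorts** (five pairs among the generalist block): members share a
  per-host latent Bernoulli(0.5) switch that multiplies their occupancy
  odds by `boost` when on and divides when off (default boost 1000 gives
  conditional co-occupancy ≈ 0.99; `boost = ∞` forces identical
  occupancy vectors, the limiting case used in tests).

Occupied cells receive lognormal(meanlog 1, sdlog 1) abundances; each
host's row is scaled to a uniform random target depth in [2000, 20000]
by exact largest-remainder allocation with one read reserved per
occupied cell, so occupancy survives scaling and raw depths are uneven
enough for SRS to matter.  Phyla follow roles (specialists → Firmicutes,
generalists/cohorts → Proteobacteria, background spread over five
phyla), giving the two focal phyla distinct planted ecologies.  The
bacterial tree is a Yule tree over all ASVs with cohort pairs mapped to
tip pairs in the 20th–45th percentile of pairwise distances — clearly
above nearest-neighbor separations but below the all-pairs mean (tip
distances on Yule trees are left-skewed, so the band must sit below the
median).

Not emulated: read-level noise (chimeras, PCR error), geographic
distance effects, abundance–occupancy correlation, host-individual
covariates, and any temporal structure.  Passing recovery tests
therefore demonstrates that the statistics detect the planted incidence
structure at realistic sizes — not that they are robust to sequencing
artifacts or spatial confounding in field data.

## Problem sizes and numerical choices

Defaults follow the survey design (14 hosts × 100 replicates per site,
50 modularity replicates, 999 PD nulls, 999 permutations, alpha 0.01).
The packaged drivers and the acceptance script run the same computation
at reduced sizes chosen as the package's own reporting scale: 25
replicate subsamples per site (8–10 for modularity, 8 restarts), 499 PD
nulls and 199 permutations for the pipeline summaries, 200 calibration
tables, 100 cohort-recovery replicates, and three pooled 240-ASV
realizations for the SES medians.  Within one community realization all
ASVs share a single host-species draw, so SES medians are pooled across
realizations to average out that shared noise.

Seeds: every stochastic stage derives its seed from one root seed via
`numpy.random.SeedSequence` keyed by stage, site (CRC32 of the label,
process-independent) and replicate, so any replicate can be recomputed
in isolation and two runs with one root seed are byte-identical.
Floats are written with `%.10g`, keeping TSV output platform-stable.

Tie and degeneracy handling worth knowing: SRS fractional ties are
uniform-random (both branches of the documented 3-feature example occur
across seeds); hypergeometric tails are renormalized against rounding
before cumulation (sums deviate from 1 by < 1e-12); the all-zero host
row is an error for Bray–Curtis (named host); subsample replicates keep
all-zero ASV columns so richness is decided at compute time.

## Known limitations

- Pseudo-replication of replicate-level tests (above); p-values in the
  comparison tables are descriptive of the resampling design.
- The discrete exact test is conservative at N = 14: the realized
  flagged fraction at alpha 0.01 is ≈ 0.003, not 0.01, and single-count
  prevalence changes can move a pair across the threshold.
- The modularity optimizer is a heuristic; its oracle guarantee is only
  exhaustive-verified up to ~12-node networks, and Q comparisons between
  real and null replicates share one optimizer configuration.
- Under the planted-cohort conditions the real networks form *fewer,
  larger* modules than their shuffle nulls while real Q is higher in
  every site; module-count direction is a property of the community
  structure at hand, so the real-minus-null module count should not be
  read as a fixed signature.
- PERMANOVA assumes exchangeability of hosts under the null; unequal
  multivariate dispersion (which the dispersion test may detect) can
  inflate its significance, and no correction is applied.
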