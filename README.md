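# hostgen

Analysis pipeline for **bacterial host generalism** in host-associated
microbiome surveys: given a host-by-ASV count table, per-host metadata
(site, species, family) and host/bacterial phylogenies, it quantifies how
widely each bacterial lineage ranges across host individuals and host
phylogeny, and whether lineages co-occur more than chance allows.  The
motivating system is the squamate-reptile cloacal microbiome sampled along
a temperate-to-tropics gradient of host species richness, but every stage
operates on generic incidence tables.  A synthetic-community generator
with planted ground truth makes the whole pipeline verifiable without any
field data.

Intended users: microbial ecologists analyzing amplicon (16S ASV) surveys
across structured host communities, and method developers who need a
tested reference implementation of the component statistics.

## What it computes

- **SRS depth normalization** — scaling with ranked subsampling: each
  host's counts are scaled by `c_min / depth`, integer parts kept, and the
  remaining units assigned by descending fractional part (ties broken at
  random, seeded).  Conserves depth exactly and preserves within-host rank
  order.
- **Community structure** — Bray–Curtis distances
  `d(x,y) = Σ|x_i−y_i| / Σ(x_i+y_i)`, a sequential (type-I) multi-factor
  PERMANOVA over site, host family and their interaction
  (McArdle–Anderson partition of the Gower-centered matrix), and a
  betadisper-style dispersion-homogeneity test.
- **Host specialization (SES-PD)** — for each ASV, the standardized effect
  size of Faith's PD of its occupied host species,
  `z = (PD_obs − mean(PD_null)) / sd(PD_null)`, against a
  richness-preserving null drawn uniformly from the host-species pool of
  the community at hand.  `z < 0` marks host specialists, `z > 0`
  phylogenetic generalists.
- **Prevalence metrics under subsampling** — 14 hosts per site drawn 100
  times; per replicate: median within-host richness, site-wide richness,
  proportion of ASVs in fewer than five hosts, and maximum prevalence.
- **Exact pairwise co-occurrence** — for two ASVs with prevalences N1, N2
  among N hosts, the shared-host count j follows the hypergeometric law
  `P(j) = C(N1,j)·C(N−N1,N2−j)/C(N,N2)`; pairs are *positive* when
  `P(J ≥ j_obs) < 0.01` and *negative* when `P(J ≤ j_obs) < 0.01`.  Two
  bespoke nulls: the column shuffle (permute each ASV's occupancy vector,
  preserving prevalence) and prevalence-matched surrogate pairs.
- **Phylum pair excess** — the observed share of positive pairs with both
  members in a focal phylum versus the squared phylum proportion expected
  at random.
- **Bipartite modularity** — hosts and ASVs (prevalence ≥ 2) form a
  two-mode network; Barber's modularity
  `Q = (1/m) Σ_s (e_s − K_s·L_s/m)` is maximized by label propagation
  plus greedy agglomeration over random restarts, and compared between
  real subsamples and their shuffle nulls.

## Worked example

The numbered drivers under `analysis/` run the full study on the
synthetic six-site dataset (seed 42) and write their tables under
`results/`:

```sh
python analysis/01_simulate_communities.py
python analysis/02_normalize_depth.py
python analysis/03_community_structure.py
python analysis/04_replicate_analyses.py
python analysis/05_interaction_tests.py
python analysis/06_modularity.py
```

Selected output from one run:

```
simulated 141 hosts x 300 ASVs at 6 sites
  site1: 15 hosts, 5 host species
  ...
  site6: 30 hosts, 19 host species
realized singleton fraction: 0.207

SRS target depth c_min = 2000; 0 hosts below target excluded

site6: 25 replicates, mean positive pairs 7.5 (null 0.5)

per-phylum means across occupied sites:
                  mean_prevalence_proportion  mean_ses
Firmicutes                             0.117    -1.177
Proteobacteria                         0.209     0.059

positive pairs exceed the shuffle null in 6/6 sites at the corrected alpha 0.000131
Proteobacteria-Proteobacteria pair excess significant in 6/6 sites

site6: Q 0.299 vs null 0.267 (p=3.1e-05); modules 4.7 vs 4.8
```

Reading this: the planted Firmicutes specialists show strongly negative
mean SES-PD (host-phylogeny-restricted) and low prevalence, while the
Proteobacteria generalists sit near zero SES with twice the prevalence;
the five planted cohort pairs drive real positive-pair counts an order of
magnitude above the column-shuffle null in every site; and the real
host–ASV networks are consistently more modular than their nulls.

The same stages are scriptable via the CLI (`hostgen simulate`,
`hostgen normalize`, `hostgen beta`, `hostgen cooccur`, `hostgen modules`,
`hostgen run`) or the library (`hostgen.run_full`).

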