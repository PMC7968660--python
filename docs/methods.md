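# Methods

## Scope and data model

`soilconet` analyzes a taxon × sample count table from an amplicon survey
of a factorial soil experiment, together with a taxon → phylum map,
per-sample design metadata (treatment ∈ {CK, WA, WR, NA, NAWA, NAWR},
depth layer ∈ {0–2, 2–5, 5–10, 10–20, 20–30 cm}, replicate) and a
per-sample chemistry table (pH, moisture %, total C %, total N %,
NO₃-N and NH₄-N in mg/kg).  Everything upstream of the count table — read
QC, chimera removal, OTU clustering, taxonomic annotation — is out of
scope; everything downstream of it is implemented here.

## Preprocessing

**Rarefaction.**  Each sample is subsampled *without replacement* to a
common depth (default 4269 reads) by a multivariate hypergeometric draw.
Without replacement means a taxon can never gain reads and a zero count
stays zero; a sample whose total is below the target depth cannot be
subsampled this way and is dropped with a warning rather than padded.
Draws are seeded and deterministic.

**Prevalence filter.**  A taxon is retained iff it is present (count > 0)
in strictly more than half of the samples under consideration.  The strict
inequality matters at the boundary: 4 of 6 samples passes, 3 of 6 does
not.  The filter is idempotent.

**Aggregation and composition.**  Phylum aggregation sums member-taxon
counts and conserves per-sample totals exactly.  Composition summaries
keep the 10 phyla with the highest mean proportion and pool the remainder
into "others"; relative-abundance contrasts between a treatment and the
control are reported as *relative* percent change, 100·(p_t − p_c)/p_c.
(A percentage-point difference p_t − p_c is the other defensible reading;
the relative form is the default because "increased by X%" most naturally
scales by the baseline.)

## Co-occurrence networks

The similarity matrix is pairwise Spearman's ρ between taxon rows,
computed as the Pearson correlation of mid-ranks (average ranks for ties).
Rank correlation needs at least 3 samples and is invariant under strictly
monotone transforms of each row; rows with zero variance have no defined
rank correlation and are assigned ρ = 0 against every partner, with a log
message.

An edge joins taxa i ≠ j iff |ρᵢⱼ| > St, strictly, with St = 0.6 by
default.  The absolute value with retained sign is what produces the
negative-link percentages in the topology report; a correlation exactly at
the threshold yields no edge.  St is a plain parameter here: automatic
threshold selection (e.g. by random-matrix theory) is deliberately not
implemented.  Taxa left without any edge are excluded from the network,
which is why node counts differ between treatments drawn from one shared
taxon pool.  Raising St can only shrink the edge set.

Topology metrics run on the unsigned skeleton:

- average connectivity 2L/N (identically the mean degree);
- average path distance: mean unweighted shortest-path length over node
  pairs *within* connected components (pairs in different components have
  no path and are excluded, with a log message — no finite convention for
  them is imposed);
- average clustering coefficient: mean over nodes of 2eᵢ/(kᵢ(kᵢ−1)),
  with nodes of degree < 2 contributing 0;
- modularity Q = Σ_m [l_m/L − (d_m/2L)²] of the partition found by greedy
  agglomerative (Clauset–Newman–Moore) maximization.  CNM is used because
  it is parameter-free and deterministic for a deterministically built
  graph; module ids are relabelled by each module's first node in graph
  order so outputs are stable.  Greedy Q is a lower bound on the true
  optimum; tests verify it against brute-force maximization over all
  partitions on small graphs, where it attains the optimum on planted
  two-clique structures.

## Node roles

Given a module partition, each node gets

- Zi = (κᵢ − mean_m κ)/sd_m κ, the within-module degree z-score, with κᵢ
  the number of links into the node's own module and the mean/sd
  (population sd) taken over that module's nodes; a module whose nodes all
  have equal within-degree has sd = 0 and Zi = 0 by convention;
- Pi = 1 − Σ_t (k_it/kᵢ)², the participation coefficient, 0 when all links
  are internal.

Roles: module hubs have Zi ≥ 2.5 and Pi ≤ 0.62; network hubs Zi ≥ 2.5 and
Pi > 0.62; connectors Zi < 2.5 and Pi > 0.62; peripherals the rest.  The
four regions partition the plane, boundaries included, exactly as stated —
descriptions of this scheme in the literature occasionally flip a boundary
or a label, so the classifier is the single source of truth here.

## Random-network nulls

The null model is G(N, L): exactly L distinct unordered pairs drawn
uniformly at random among N nodes, matching the empirical node and link
counts.  Each of the (default 100) seeded replicates is summarized with
the same metric implementations as the empirical network, and the null
summary reports means and standard deviations of average path distance,
average clustering and modularity.  Degree sequences are *not* preserved;
a degree-preserving rewiring null is a possible extension but is not the
default because the uniform-assignment model is the stated comparison.
For dense graphs the expected null clustering approaches the density
2L/(N(N−1)), which the tests use as a closed-form check.

## Diversity and chemistry statistics

Shannon–Wiener H = −Σ pᵢ ln pᵢ is reported in nats (natural log; the base
is configurable since conventions differ).  Richness is the count of taxa
with positive count.  Chemistry is compared per layer by classical one-way
ANOVA across treatments; all-pairwise Tukey HSD at α = 0.05 feeds an
insert-and-absorb compact letter display, so two treatments share a letter
iff their pairwise Tukey p ≥ α — the familiar "mean ± SE with superscript
letters" table layout.  Groups need at least two observations; layers
without replication are skipped with a log entry rather than guessed at.

## Redundancy analysis

Y (samples × taxa) is column-centered; X (samples × chemistry covariates)
is standardized to zero mean and unit (n−1) variance, making all percent
quantities invariant to covariate units.  The fitted values of the
multivariate least-squares regression of Y on X are decomposed by SVD;
eigenvalues λ_k = s_k²/(n−1) are reported both as a percent of the *total*
variance of centered Y and of the *constrained* variance Σλ (both are
printed because axis percentages in the literature are quoted under either
convention, frequently without saying which).  Rank-deficient X raises an
error naming the collinear columns (QR with column pivoting).  The default
community transform before RDA is the Hellinger transform (square root of
relative abundances), the standard choice for linear ordination of
compositional count data; `none` and `log1p` are available.

The permutation test permutes whole rows of X (samples are the exchangeable
unit; no blocking by layer is applied by default), recomputes the
constrained trace, and reports p = (1 + #{perm ≥ obs})/(1 + n_perm) — the
add-one rule keeps p strictly positive and unbiased under the null.  At
least 99 permutations are required; the default is 999.

## Synthetic data generator

Per sample j, taxon log-abundance is

    λᵢⱼ = bᵢ + Σ_m wᵢₘ fₘⱼ + βᵢ·xⱼ + εᵢⱼ,

with fₘⱼ ~ N(0,1) shared by all taxa of planted module m (the lever that
plants supra-threshold Spearman correlations), xⱼ = (water, nitrogen) the
treatment design vector (water +1/−1 for addition/reduction, nitrogen 0/1)
and εᵢⱼ ~ N(0, noise_sd).  Counts are multinomial at the sample's depth
from softmax(λ·ⱼ), so each sample's counts sum to its drawn depth exactly;
depths are negative-binomial with configurable mean and dispersion.  The
latent-factor log-normal → multinomial construction is used instead of a
Dirichlet-multinomial because it gives direct control of the pairwise rank
correlations the network stage consumes.

Defaults mirror a six-treatment × five-layer design with 3 replicates per
cell (90 samples), 120 taxa in 30 phyla whose masses decay geometrically
(decay 0.65), which puts > 95% of the community in the top 10 phyla.
Three replicates are the smallest design in which per-layer chemistry
ANOVA (which needs ≥ 2 observations per group) and reasonably resolved
per-treatment networks (15 samples each) are both defined.  The default
planted modules sit on mid-dominance phyla (ranks 5–7 and 8–10) with
loading 1.1 — strong enough for supra-threshold phylum-level correlations,
small enough not to warp the composition summaries.  Treatment effects act
on the rare half of taxa (+0.8 per water unit, −0.6 under nitrogen), so
water addition flattens the abundance distribution and raises Shannon
diversity while nitrogen lowers it.  Chemistry is drawn with water shifting
moisture (±1.2%), nitrogen lowering pH (−0.45 units) and raising NO₃-N
(+1.6 mg/kg), with per-variable noise on the order of the replicate SEs of
typical semi-arid soils.

What the generator does *not* emulate: sequence-level artifacts (chimeras,
clustering errors), spatial autocorrelation between adjacent layers,
phylogenetic signal in the correlation structure, and overdispersion beyond
the log-normal factor model.  Passing tests therefore demonstrate that the
pipeline recovers structure *of the planted kind* at realistic scales, not
that any particular field system behaves this way.

## Numerical and reproducibility choices

- All randomness flows through seeded numpy generators; the pipeline
  derives per-stage seeds from one master seed via `SeedSequence`, and
  reruns with identical configuration are byte-identical (floats are
  written at 10 significant digits; logs carry no timestamps).
- Spearman matrices are clipped to [−1, 1] and the diagonal forced to
  exactly 1 to absorb floating-point drift.
- The treatment label "NA" (nitrogen addition) collides with the default
  missing-value token of most TSV readers; all readers in `soilconet.io`
  disable missing-value interpretation, and the test suite guards this.
- Networks with no supra-threshold edge are reported as empty (0 nodes,
  0 links, NaN metrics) rather than aborting the run, so threshold sweeps
  remain possible.

## Limitations

- Spearman correlation on very few samples is extremely coarse (with 5
  samples, ranks take only 5 values); the pipeline warns when a network
  rests on fewer than 10 samples but does not refuse.
- Greedy modularity is a heuristic; on adversarial graphs it can fall
  short of the optimal partition (tests bound it by the brute-force
  optimum on small graphs).
- The G(N, L) null preserves density but not degree heterogeneity;
  contrasts against it conflate the two.
- RDA is a linear (not unimodal) ordination; no forward selection or
  variance partitioning among covariate subsets is provided.
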