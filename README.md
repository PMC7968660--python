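# soilconet

Co-occurrence network analysis, diversity statistics and constrained
ordination for soil microbial count tables.

`soilconet` is aimed at microbial ecologists working with amplicon surveys
of factorial field experiments — for example, a desert-steppe design with
six treatments (control CK, water addition WA, water reduction WR, nitrogen
addition NA, and the combinations NAWA / NAWR) sampled across five soil
depth layers.  Starting from a taxon × sample count table, a taxonomy map,
sample metadata and a soil-chemistry table, one call reproduces the full
downstream analysis:

- **Preprocessing** — rarefaction to a common depth (multivariate
  hypergeometric subsampling, default 4269 reads/sample), a strict-majority
  prevalence filter, phylum aggregation and top-10-plus-others composition
  summaries.
- **Co-occurrence networks** — per treatment, pairwise Spearman ρ between
  taxon abundance profiles is thresholded at |ρ| > St (default 0.6) into an
  undirected signed graph; the report covers nodes, links, positive/negative
  link percentages, average connectivity 2L/N, average path distance,
  average clustering coefficient, and modularity Q from greedy (CNM)
  agglomeration.
- **Node roles** — within-module degree z-score Zi and participation
  coefficient Pi per node, classified into peripherals, connectors, module
  hubs and network hubs at the conventional thresholds Zi = 2.5, Pi = 0.62.
- **Random-network nulls** — G(N, L) graphs with the empirical node and
  link counts, summarized with the same metrics for an
  empirical-versus-random contrast.
- **Community statistics** — Shannon–Wiener diversity H = −Σ pᵢ ln pᵢ,
  taxon richness, relative-abundance change summaries, and one-way ANOVA of
  soil chemistry per layer with Tukey-HSD compact letter displays.
- **Ordination** — redundancy analysis (RDA) of the (Hellinger-transformed)
  community matrix on soil chemistry, with eigenvalues reported as percent
  of total and of constrained variance, and a Monte Carlo permutation test
  of the constrained trace (add-one rule, p = (1 + #{perm ≥ obs})/(1 + n)).

A seeded synthetic-data generator (`soilconet.simulate`) emulates the
post-clustering state of such an experiment — latent-factor log-normal
abundances with planted correlation modules, multinomial counts at a drawn
sequencing depth, treatment-linked chemistry — so the entire pipeline is
testable without any sequencing download.

## Worked example

```python
import soilconet as sc

cfg = sc.GeneratorConfig(seed=1)          # 6 treatments x 5 layers x 3 replicates
dataset = sc.generate_dataset(cfg)
paths = sc.write_dataset(dataset, "demo_data")

run = sc.RunConfig(**paths, out_dir="demo_run", seed=7)
out = sc.run_pipeline(run)

import pandas as pd
summary = pd.read_csv(out / "network_summary.tsv", sep="\t", index_col=0)
print(summary.loc[["Total nodes", "Total links", "Modularity", "Random: Modularity"]].round(3))
```

```
                        CK      WA      WR      NA    NAWA    NAWR
metric
Total nodes         11.000  11.000  12.000  10.000  12.000  10.000
Total links         19.000  16.000  21.000  11.000  21.000  15.000
Modularity           0.271   0.375   0.322   0.512   0.322   0.291
Random: Modularity   0.218   0.261   0.233   0.297   0.221   0.221
```

Each column is one treatment's phylum-level network, built from that
treatment's 15 samples.  Every empirical modularity exceeds its random-null
mean: the planted module structure compartmentalizes the networks beyond
what their density alone explains.  The same run writes the RDA:

```python
axes = pd.read_csv(out / "rda_axes.tsv", sep="\t")
print(axes[["axis", "pct_total_variance", "pct_constrained_variance"]].head(2).round(2))
perm = pd.read_csv(out / "rda_permutation.tsv", sep="\t")
print("permutation p =", perm["p_value"].iloc[0])
```

```
   axis  pct_total_variance  pct_constrained_variance
0  RDA1               11.84                     83.13
1  RDA2                1.49                     10.48
permutation p = 0.011
```

Axis 1 carries 11.8% of the total community variance (83% of the variance
explainable by chemistry), and the permutation test rejects independence
between community composition and soil chemistry at p ≈ 0.01 — as it
should, since the generator drives both from the same treatment design.

The output directory further contains per-sample diversity, the top-10
phylum composition table, the per-layer chemistry ANOVA with letters, and
per-treatment edge lists, GraphML files and Zi–Pi node-role tables.  Reruns
with the same configuration and seed are byte-identical.

The same workflow is available from the shell:

```sh
soilconet simulate --seed 1 --out demo_data
soilconet run --counts demo_data/counts.tsv --taxonomy demo_data/taxonomy.tsv \
    --metadata demo_data/metadata.tsv --chemistry demo_data/chemistry.tsv \
    --out demo_run --seed 7
soilconet null --nodes 27 --links 306 --reps 100 --seed 1
```

## Documentation

See `docs/methods.md` for the statistical model behind each stage, the
default parameters and their rationale, and known limitations.
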