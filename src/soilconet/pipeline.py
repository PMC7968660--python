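"""End-to-end orchestration: one call reproduces the full analysis.

Per treatment the pipeline rarefies, optionally aggregates to phylum level,
applies the prevalence filter, builds the co-occurrence network and writes
its topology report, Zi–Pi role table and G(N, L) null summary.  Globally
it writes per-sample diversity, the top-10 phylum composition table, the
per-layer chemistry ANOVA (mean ± SE with letters) and the RDA of the
community against chemistry with its permutation test.  Every output is
TSV (plus GraphML per network); reruns with the same configuration and
seed are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import anova_oneway, richness, shannon_index
from .io import (
    CHEM_VARS,
    LAYERS,
    read_chemistry,
    read_count_table,
    read_metadata,
    read_taxonomy,
)
from .network import build_network, edge_list, network_report, spearman_matrix
from .ordination import hellinger, monte_carlo_test, rda_fit
from .preprocess import (
    aggregate_to_phylum,
    prevalence_filter,
    rarefy,
    relative_abundance,
    top_k_with_others,
)
from .roles import node_role_table, null_summary

FLOAT_FMT = "%.10g"
MIN_NETWORK_SAMPLES = 10


@dataclass
class RunConfig:
    counts: Path
    taxonomy: Path
    metadata: Path
    chemistry: Path
    out_dir: Path
    depth: int = 4269
    st: float = 0.6
    node_level: str = "phylum"  # "phylum" | "otu"
    null_reps: int = 100
    n_perm: int = 999
    alpha: float = 0.05
    rda_transform: str = "hellinger"  # "none" | "hellinger" | "log1p"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "counts": str(self.counts),
                "taxonomy": str(self.taxonomy),
                "metadata": str(self.metadata),
                "chemistry": str(self.chemistry),
            },
            "depth": self.depth,
            "st": self.st,
            "node_level": self.node_level,
            "null_reps": self.null_reps,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "rda_transform": self.rda_transform,
            "seed": self.seed,
        }


def _transform(rel: pd.DataFrame, method: str) -> pd.DataFrame:
    if method == "none":
        return rel
    if method == "hellinger":
        return hellinger(rel)
    if method == "log1p":
        return np.log1p(rel)
    raise ValueError(f"unknown transform {method!r}")


def run_pipeline(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"soilconet {__version__}",
        f"seed {cfg.seed}",
        f"depth {cfg.depth} st {cfg.st} node_level {cfg.node_level} "
        f"null_reps {cfg.null_reps} n_perm {cfg.n_perm} alpha {cfg.alpha} "
        f"transform {cfg.rda_transform}",
    ]

    table = read_count_table(cfg.counts)
    tax = read_taxonomy(cfg.taxonomy)
    meta = read_metadata(cfg.metadata)
    chem = read_chemistry(cfg.chemistry)
    meta.require_samples(table.sample_ids)

    treatments = [
        t
        for t in dict.fromkeys(meta.data["treatment"])
        if t in set(meta.data.loc[table.sample_ids, "treatment"])
    ]
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 + len(treatments))
    seeds = [int(s % 2**31) for s in seeds]
    rarefy_seed, perm_seed, *null_seeds = seeds

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rarefied = rarefy(table, cfg.depth, rarefy_seed)
    for w in caught:
        log.append(f"rarefaction: {w.message}")
    samples = rarefied.sample_ids

    # --- per-sample diversity -------------------------------------------
    div = pd.DataFrame(
        {
            "sample_id": samples,
            "treatment": [meta.data.loc[s, "treatment"] for s in samples],
            "layer": [meta.data.loc[s, "layer"] for s in samples],
            "shannon": [shannon_index(rarefied.data[s]) for s in samples],
            "richness": [richness(rarefied.data[s]) for s in samples],
        }
    )
    div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # --- composition: top-10 phyla + others -----------------------------
    phylum_table = aggregate_to_phylum(rarefied, tax)
    rel = relative_abundance(phylum_table)
    top10 = top_k_with_others(rel, k=10)
    top10.to_csv(
        out / "relative_abundance_top10.tsv",
        sep="\t",
        index_label="phylum",
        float_format=FLOAT_FMT,
    )

    # --- chemistry ANOVA per layer and variable -------------------------
    anova_rows = []
    chem_meta = meta.data.loc[[s for s in chem.data.index if s in meta.data.index]]
    for layer in LAYERS:
        layer_samples = chem_meta[chem_meta["layer"] == layer].index
        if len(layer_samples) == 0:
            continue
        for var in CHEM_VARS:
            groups = {
                t: chem.data.loc[
                    [s for s in layer_samples if chem_meta.loc[s, "treatment"] == t],
                    var,
                ].to_numpy()
                for t in treatments
            }
            groups = {t: v for t, v in groups.items() if len(v) > 0}
            if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
                log.append(f"anova skipped for {var} in layer {layer}: <2 replicates")
                continue
            res = anova_oneway(groups, alpha=cfg.alpha)
            row = {"layer": layer, "variable": var, "F": res.F, "p": res.p}
            for t in treatments:
                row[t] = (
                    f"{res.means[t]:.4g} ± {res.sems[t]:.3g}{res.letters[t]}"
                    if t in res.means
                    else ""
                )
            anova_rows.append(row)
    pd.DataFrame(anova_rows).to_csv(
        out / "chemistry_anova.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # --- per-treatment networks -----------------------------------------
    summary_cols: dict[str, dict[str, float]] = {}
    for t, nseed in zip(treatments, null_seeds):
        t_samples = [s for s in samples if meta.data.loc[s, "treatment"] == t]
        if len(t_samples) < MIN_NETWORK_SAMPLES:
            log.append(
                f"network {t}: only {len(t_samples)} samples; Spearman ranks are coarse"
            )
        sub = rarefied.data[t_samples]
        node_table = (
            aggregate_to_phylum(
                type(rarefied)(sub), tax
            )
            if cfg.node_level == "phylum"
            else type(rarefied)(sub)
        )
        node_table = prevalence_filter(node_table)
        sim = spearman_matrix(node_table)
        rel_t = relative_abundance(node_table)
        attrs = {
            tid: {
                "phylum": tid if cfg.node_level == "phylum" else tax.phylum_of(tid),
                "mean_abundance": float(rel_t.loc[tid].mean()),
            }
            for tid in node_table.taxon_ids
        }
        net = build_network(sim, st=cfg.st, node_attrs=attrs)
        if net.graph.number_of_edges() == 0:
            # every pairwise |rho| <= St: an empty network, reported as such
            log.append(f"network {t}: no edge exceeds |rho| > {cfg.st}")
            edge_list(net).to_csv(
                out / "networks" / f"{t}_edges.tsv", sep="\t", index=False
            )
            nx.write_graphml(net.graph, out / "networks" / f"{t}.graphml")
            pd.DataFrame(
                columns=["node", "module", "Zi", "Pi", "category"]
            ).to_csv(out / "networks" / f"{t}_node_roles.tsv", sep="\t", index=False)
            summary_cols[t] = {
                "Total nodes": 0,
                "Total links": 0,
                "Negative links (%)": float("nan"),
                "Positive links (%)": float("nan"),
                "Avg. connectivity": float("nan"),
                "Avg. path distance": float("nan"),
                "Avg. clustering coefficient": float("nan"),
                "Modularity": float("nan"),
                "Random: Avg. path distance": float("nan"),
                "Random: Avg. clustering coefficient": float("nan"),
                "Random: Modularity": float("nan"),
            }
            continue
        rep = network_report(net)
        roles = node_role_table(net, rep.module_partition)
        nulls = null_summary(rep.total_nodes, rep.total_links, cfg.null_reps, nseed)

        edge_list(net).to_csv(
            out / "networks" / f"{t}_edges.tsv",
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        nx.write_graphml(net.graph, out / "networks" / f"{t}.graphml")
        roles.to_csv(
            out / "networks" / f"{t}_node_roles.tsv",
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        summary_cols[t] = {
            "Total nodes": rep.total_nodes,
            "Total links": rep.total_links,
            "Negative links (%)": rep.pct_negative_links,
            "Positive links (%)": rep.pct_positive_links,
            "Avg. connectivity": rep.avg_connectivity,
            "Avg. path distance": rep.avg_path_distance,
            "Avg. clustering coefficient": rep.avg_clustering_coefficient,
            "Modularity": rep.modularity,
            "Random: Avg. path distance": nulls.mean_avg_path_distance,
            "Random: Avg. clustering coefficient": nulls.mean_avg_clustering,
            "Random: Modularity": nulls.mean_modularity,
        }
        log.append(
            f"network {t}: {len(t_samples)} samples, {rep.total_nodes} nodes, "
            f"{rep.total_links} links"
        )

    summary = pd.DataFrame(summary_cols)
    summary.to_csv(
        out / "network_summary.tsv", sep="\t", index_label="metric",
        float_format=FLOAT_FMT,
    )

    # --- RDA of community vs chemistry ----------------------------------
    chem_samples = [s for s in samples if s in chem.data.index]
    y = _transform(rel[chem_samples].T, cfg.rda_transform)
    x = chem.data.loc[chem_samples]
    rda = rda_fit(y, x)
    axes = pd.DataFrame(
        {
            "axis": [f"RDA{i + 1}" for i in range(len(rda.eigenvalues))],
            "eigenvalue": rda.eigenvalues,
            "pct_total_variance": rda.pct_total,
            "pct_constrained_variance": rda.pct_constrained,
        }
    )
    axes.to_csv(out / "rda_axes.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    rda.sample_scores.to_csv(
        out / "rda_sample_scores.tsv", sep="\t", index_label="sample_id",
        float_format=FLOAT_FMT,
    )
    rda.taxon_scores.to_csv(
        out / "rda_taxon_scores.tsv", sep="\t", index_label="taxon",
        float_format=FLOAT_FMT,
    )
    rda.biplot_scores.to_csv(
        out / "rda_biplot.tsv", sep="\t", index_label="covariate",
        float_format=FLOAT_FMT,
    )
    perm = monte_carlo_test(y, x, n_perm=cfg.n_perm, seed=perm_seed)
    pd.DataFrame(
        [
            {
                "statistic": perm.statistic,
                "observed": perm.observed,
                "n_permutations": perm.n_permutations,
                "p_value": perm.p_value,
            }
        ]
    ).to_csv(out / "rda_permutation.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    log.append(f"rda: trace p = {perm.p_value:.6g} ({perm.n_permutations} permutations)")

    # --- provenance ------------------------------------------------------
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return out
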