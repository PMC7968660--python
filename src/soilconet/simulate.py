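"""Synthetic OTU datasets with planted structure.

Emulates the post-clustering state of a factorial soil experiment: six
treatments (control, water addition/reduction, nitrogen addition and the
two combinations) by five depth layers, with replicate samples.  Taxon
log-abundances follow a latent-factor model

    lambda_ij = b_i + sum_m w_im f_mj + beta_i . x_j + eps_ij,

where the per-sample factors f_mj are shared by the taxa of a planted
module (driving supra-threshold co-occurrence), x_j is the treatment design
vector (water axis: +1 addition / -1 reduction; nitrogen axis: 0/1) and
eps is taxon-level noise.  Counts are multinomial draws at the sample's
sequencing depth from softmax(lambda); each sample's counts therefore sum
to its drawn depth exactly.  Phylum labels follow a geometric dominance
series so the ten most abundant phyla carry >95% of the community, and
soil chemistry is drawn with treatment effects matching the design (water
shifts moisture, nitrogen lowers pH and raises nitrate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    LAYERS,
    TREATMENTS,
    ChemistryTable,
    CountTable,
    SampleMetadata,
    TaxonomyMap,
)

#: Familiar names for the dominant phyla of semi-arid grassland soils.
PHYLUM_NAMES = (
    "Actinobacteria",
    "Proteobacteria",
    "Chloroflexi",
    "Acidobacteria",
    "Bacteroidetes",
    "Planctomycetes",
    "Cyanobacteria",
    "Verrucomicrobia",
    "Gemmatimonadetes",
    "Firmicutes",
)


def phylum_name(index: int) -> str:
    if index < len(PHYLUM_NAMES):
        return PHYLUM_NAMES[index]
    return f"Phylum_{index + 1:02d}"


@dataclass
class ModuleSpec:
    """A planted co-occurrence module: taxon indices sharing one latent factor."""

    taxa: list[int]
    loading: float


@dataclass
class GeneratorConfig:
    n_taxa: int = 120
    n_phyla: int = 30
    treatments: tuple[str, ...] = TREATMENTS
    n_layers: int = 5
    replicates: int = 3
    depth_mean: float = 8000.0
    depth_dispersion: float = 100.0   # negative-binomial size parameter
    rarefaction_depth: int = 4269
    phylum_decay: float = 0.65        # geometric dominance of phylum masses
    modules: list[ModuleSpec] | None = None  # None -> default phylum modules
    module_loading: float = 1.1
    water_effect: float = 0.8         # log-abundance boost of rare taxa per water unit
    n_effect: float = 0.6             # log-abundance penalty of rare taxa under N
    noise_sd: float = 0.5
    baseline_sd: float = 0.3
    baselines: np.ndarray | None = None  # explicit per-taxon log-baselines
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < self.n_phyla:
            raise ValueError("need at least one taxon per phylum")
        if self.n_layers > len(LAYERS):
            raise ValueError(f"at most {len(LAYERS)} layers supported")
        if self.depth_mean < self.rarefaction_depth:
            raise ValueError("mean sequencing depth below rarefaction depth")
        if self.modules is not None:
            seen: set[int] = set()
            for mod in self.modules:
                if seen & set(mod.taxa):
                    raise ValueError("module taxon sets must be disjoint")
                if not all(0 <= t < self.n_taxa for t in mod.taxa):
                    raise ValueError("module taxon index out of range")
                seen |= set(mod.taxa)


def assign_phyla(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Phylum index per taxon: one anchor taxon per phylum, the rest
    allocated with probability proportional to phylum dominance."""
    w = cfg.phylum_decay ** np.arange(cfg.n_phyla)
    extra = rng.choice(cfg.n_phyla, size=cfg.n_taxa - cfg.n_phyla, p=w / w.sum())
    return np.concatenate([np.arange(cfg.n_phyla), extra])


def _default_modules(cfg: GeneratorConfig, phyla: np.ndarray) -> list[ModuleSpec]:
    # two modules over mid-dominance phyla: strong enough to be detected,
    # small enough not to warp the top-10 composition
    groups = [(4, 5, 6), (7, 8, 9)]
    return [
        ModuleSpec(
            taxa=[int(i) for i in np.flatnonzero(np.isin(phyla, g))],
            loading=cfg.module_loading,
        )
        for g in groups
    ]


def _design_vector(treatment: str) -> np.ndarray:
    water = {"WA": 1.0, "NAWA": 1.0, "WR": -1.0, "NAWR": -1.0}.get(treatment, 0.0)
    nitrogen = 1.0 if treatment.startswith("NA") else 0.0
    return np.array([water, nitrogen])


def _chemistry_row(
    treatment: str, layer_idx: int, rng: np.random.Generator
) -> dict[str, float]:
    water, nitrogen = _design_vector(treatment)
    return {
        "pH": 8.55 + 0.04 * layer_idx - 0.45 * nitrogen + rng.normal(0, 0.08),
        "moisture": max(
            0.0, 6.0 + 1.2 * water + 0.1 * layer_idx + rng.normal(0, 0.3)
        ),
        "TC": max(0.0, 1.65 - 0.06 * layer_idx + rng.normal(0, 0.1)),
        "TN": max(0.0, 0.17 - 0.003 * layer_idx + rng.normal(0, 0.012)),
        "NO3N": max(0.0, 3.5 + 1.6 * nitrogen + rng.normal(0, 0.2)),
        "NH4N": max(0.0, 2.1 + 0.15 * nitrogen + rng.normal(0, 0.12)),
    }


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[CountTable, TaxonomyMap, SampleMetadata, ChemistryTable]:
    """Draw one complete synthetic dataset; byte-identical given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    phyla = assign_phyla(cfg, rng)
    taxon_ids = [f"OTU_{i + 1:04d}" for i in range(cfg.n_taxa)]

    if cfg.baselines is not None:
        b = np.asarray(cfg.baselines, dtype=float)
        if b.shape != (cfg.n_taxa,):
            raise ValueError("baselines must have one value per taxon")
    else:
        w = cfg.phylum_decay ** phyla
        members = np.bincount(phyla, minlength=cfg.n_phyla)[phyla]
        b = np.log(w / members) + rng.normal(0, cfg.baseline_sd, cfg.n_taxa)

    modules = cfg.modules if cfg.modules is not None else _default_modules(cfg, phyla)
    loadings = np.zeros((cfg.n_taxa, len(modules)))
    for m, mod in enumerate(modules):
        loadings[np.asarray(mod.taxa, dtype=int), m] = mod.loading

    # treatment responsiveness: rare taxa gain under water, lose under nitrogen
    rare = b < np.median(b)
    beta = np.zeros((cfg.n_taxa, 2))
    beta[rare, 0] = cfg.water_effect
    beta[rare, 1] = -cfg.n_effect

    counts: dict[str, np.ndarray] = {}
    meta_rows, chem_rows = [], []
    nb_p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    for treatment in cfg.treatments:
        x = _design_vector(treatment)
        for layer_idx in range(cfg.n_layers):
            for rep in range(1, cfg.replicates + 1):
                sid = f"{treatment}_{LAYERS[layer_idx]}_r{rep}"
                f = rng.standard_normal(len(modules))
                eps = rng.normal(0, cfg.noise_sd, cfg.n_taxa)
                lam = b + loadings @ f + beta @ x + eps
                p = np.exp(lam - lam.max())
                p /= p.sum()
                depth = int(rng.negative_binomial(cfg.depth_dispersion, nb_p))
                counts[sid] = rng.multinomial(max(depth, 1), p)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "treatment": treatment,
                        "layer": LAYERS[layer_idx],
                        "replicate": rep,
                    }
                )
                chem_rows.append(
                    {"sample_id": sid, **_chemistry_row(treatment, layer_idx, rng)}
                )

    table = CountTable(pd.DataFrame(counts, index=taxon_ids).astype(np.int64))
    tax = TaxonomyMap(
        pd.Series(
            [phylum_name(p) for p in phyla], index=taxon_ids, name="phylum"
        )
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    chem = ChemistryTable(pd.DataFrame(chem_rows).set_index("sample_id"))
    return table, tax, meta, chem


def planted_edges(cfg: GeneratorConfig, phyla: np.ndarray | None = None) -> set:
    """Unordered within-module taxon index pairs implied by the module spec."""
    if cfg.modules is None:
        raise ValueError("planted_edges needs an explicit module spec")
    pairs = set()
    for mod in cfg.modules:
        taxa = sorted(mod.taxa)
        for i, a in enumerate(taxa):
            for c in taxa[i + 1 :]:
                pairs.add((a, c))
    return pairs


def generate_null_pair(
    cfg: GeneratorConfig,
    n_samples: int = 30,
    n_taxa: int = 40,
    n_covariates: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Community matrix Y and covariates X drawn from independent streams.

    Used to calibrate the ordination permutation test: since X is generated
    after Y from a separate child stream, any detected association is a
    false positive by construction.
    """
    child_y, child_x = np.random.SeedSequence(cfg.seed).spawn(2)
    rng_y = np.random.default_rng(child_y)
    rng_x = np.random.default_rng(child_x)
    y = rng_y.lognormal(mean=0.0, sigma=1.0, size=(n_samples, n_taxa))
    y = y / y.sum(axis=1, keepdims=True)
    x = rng_x.standard_normal((n_samples, n_covariates))
    return y, x


def write_dataset(
    dataset: tuple[CountTable, TaxonomyMap, SampleMetadata, ChemistryTable],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the four tables as TSV; returns the file paths."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, tax, meta, chem = dataset
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "chemistry": out / "chemistry.tsv",
    }
    io.write_count_table(table, paths["counts"])
    io.write_taxonomy(tax, paths["taxonomy"])
    io.write_metadata(meta, paths["metadata"])
    io.write_chemistry(chem, paths["chemistry"])
    return paths
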