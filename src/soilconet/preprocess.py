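"""Count-table preprocessing: rarefaction, prevalence filtering, aggregation.

Rarefaction subsamples every sample without replacement to a common depth
(the study convention behind "normalized to N sequences per sample"); the
prevalence filter keeps taxa observed in a strict majority of samples before
any correlation is computed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CountTable, TaxonomyMap, ValidationError


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Draws follow the multivariate hypergeometric distribution, so a taxon can
    never gain reads and a zero count stays zero.  Samples whose total is
    below ``depth`` cannot be subsampled without replacement and are dropped
    with a warning.  Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for sample in table.sample_ids:
        col = table.data[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} reads < depth {depth}; dropped",
                stacklevel=2,
            )
            continue
        if total == depth:
            cols[sample] = col
        else:
            cols[sample] = rng.multivariate_hypergeometric(col, depth)
    if not cols:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(cols, index=table.data.index).astype(np.int64)
    return CountTable(out)


def prevalence_filter(table: CountTable) -> CountTable:
    """Retain taxa present (count > 0) in strictly more than half of all samples."""
    if table.data.empty:
        raise ValidationError("cannot filter an empty table")
    n_samples = table.shape[1]
    present = (table.counts > 0).sum(axis=1)
    keep = present > n_samples / 2
    return CountTable(table.data.loc[keep].copy())


def aggregate_to_phylum(table: CountTable, tax: TaxonomyMap) -> CountTable:
    """Sum member-taxon counts into one row per phylum.

    Column (per-sample) totals are conserved exactly.  Output rows keep the
    order in which each phylum first appears in the input.
    """
    missing = [t for t in table.taxon_ids if t not in tax.mapping.index]
    if missing:
        raise ValidationError(f"taxa missing from taxonomy: {missing}")
    phyla = pd.Series(
        [tax.phylum_of(t) for t in table.taxon_ids], index=table.data.index
    )
    agg = table.data.groupby(phyla, sort=False).sum()
    agg.index.name = None
    return CountTable(agg)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    return table.data / sums


def top_k_with_others(
    rel: pd.DataFrame, k: int = 10, label: str = "others"
) -> pd.DataFrame:
    """Keep the ``k`` taxa with highest mean proportion; pool the rest.

    Mirrors the "top 10 phyla + others" community-composition summary; the
    pooled row is appended last so columns still sum to 1.
    """
    if len(rel) <= k:
        return rel.copy()
    order = rel.mean(axis=1).sort_values(ascending=False).index
    top = rel.loc[order[:k]]
    others = rel.loc[order[k:]].sum(axis=0).rename(label)
    return pd.concat([top, others.to_frame().T])
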