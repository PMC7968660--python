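"""Validated data containers and TSV readers/writers.

The pipeline starts from a post-clustering state: a taxon-by-sample count
table (OTUs or any other taxon unit), a taxon-to-phylum map, per-sample
design metadata (treatment, soil layer, replicate) and a per-sample soil
chemistry table.  All four are tab-separated text; ``#`` lines are comments
and the first header cell is arbitrary.

Treatment labels include the string ``NA`` (nitrogen addition), so every
reader disables pandas' default missing-value parsing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TREATMENTS: tuple[str, ...] = ("CK", "WA", "WR", "NA", "NAWA", "NAWR")
LAYERS: tuple[str, ...] = ("0-2", "2-5", "5-10", "10-20", "20-30")
CHEM_VARS: tuple[str, ...] = ("pH", "moisture", "TC", "TN", "NO3N", "NH4N")
UNASSIGNED: str = "Unassigned"


class ValidationError(ValueError):
    """Raised when an input file or table violates its schema."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV with '#' comments, never interpreting 'NA' as missing."""
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )


def _check_unique(ids, what: str) -> None:
    dups = [k for k, n in Counter(ids).items() if n > 1]
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


@dataclass
class CountTable:
    """Taxon-by-sample matrix of non-negative integer counts.

    ``data`` has taxon ids on the index and sample ids on the columns; row
    and column order are preserved by all readers and writers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class TaxonomyMap:
    """Total mapping from taxon id to phylum label.

    Taxa absent from the underlying table map to the reserved
    :data:`UNASSIGNED` label when queried through :meth:`phylum_of`.
    """

    mapping: pd.Series  # index: taxon id, values: phylum name

    def __post_init__(self) -> None:
        _check_unique(self.mapping.index, "taxon")

    def phylum_of(self, taxon_id: str) -> str:
        return str(self.mapping.get(taxon_id, UNASSIGNED))

    def phyla_for(self, table: CountTable) -> pd.Series:
        """Phylum label for every taxon of ``table``, in table order."""
        return pd.Series(
            [self.phylum_of(t) for t in table.taxon_ids],
            index=table.taxon_ids,
            name="phylum",
        )


@dataclass
class SampleMetadata:
    """Per-sample treatment, soil layer and replicate labels."""

    data: pd.DataFrame  # index: sample id; columns: treatment, layer, replicate

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("treatment", "layer", "replicate"):
            if col not in self.data.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        bad_t = set(self.data["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValidationError(f"unknown treatment(s): {sorted(bad_t)}")
        bad_l = set(self.data["layer"]) - set(LAYERS)
        if bad_l:
            raise ValidationError(f"unknown layer(s): {sorted(bad_l)}")
        self.data["replicate"] = self.data["replicate"].astype(int)

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")

    def samples_for_treatment(self, treatment: str) -> list[str]:
        sub = self.data[self.data["treatment"] == treatment]
        return list(sub.index)


@dataclass
class ChemistryTable:
    """Per-sample soil chemistry: pH, moisture %, TC %, TN %, NO3-N and NH4-N mg/kg."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [v for v in CHEM_VARS if v not in self.data.columns]
        if missing:
            raise ValidationError(f"chemistry missing column(s): {missing}")
        self.data = self.data[list(CHEM_VARS)].astype(float)
        if self.data.isna().any().any():
            col = self.data.columns[self.data.isna().any()][0]
            raise ValidationError(f"missing value in chemistry column {col!r}")
        for col in ("moisture", "TC", "TN"):
            if (self.data[col] < 0).any():
                raise ValidationError(f"negative value in chemistry column {col!r}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_count_table(path: str | Path) -> CountTable:
    """Read a taxon × sample count table from TSV.

    The first column holds taxon ids and the header row sample ids.  Cells
    must be non-negative integers; offending cells are named in the error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split("\t")
            break
    if header is None:
        raise ValidationError(f"{path}: empty file")
    _check_unique(header[1:], "sample")

    raw = _read_tsv(path)
    _check_unique(raw.index, "taxon")
    out = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        num = pd.to_numeric(raw[col], errors="coerce")
        if num.isna().any():
            taxon = raw.index[num.isna()][0]
            raise ValidationError(
                f"non-numeric or missing count at taxon {taxon!r}, sample {col!r}"
            )
        if ((num % 1) != 0).any():
            taxon = raw.index[(num % 1) != 0][0]
            raise ValidationError(
                f"non-integer count at taxon {taxon!r}, sample {col!r}"
            )
        out[col] = num.astype(np.int64)
    return CountTable(out)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    raw = _read_tsv(path)
    if raw.shape[1] < 1:
        raise ValidationError(f"{path}: taxonomy needs taxon_id and phylum columns")
    return TaxonomyMap(raw.iloc[:, 0].rename("phylum"))


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    tax.mapping.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_chemistry(path: str | Path) -> ChemistryTable:
    raw = _read_tsv(path)
    try:
        raw = raw.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric chemistry value ({exc})") from exc
    return ChemistryTable(raw)


def write_chemistry(chem: ChemistryTable, path: str | Path) -> None:
    chem.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")
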