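"""Dataset container and plain-text I/O.

The pipeline's interchange formats are deliberately simple text files:

* expression matrix — TSV, header row of feature ids, first column of
  sample ids, one decimal number per cell;
* sample metadata — TSV with required columns ``sample_id`` and
  ``diagnosis`` and optional ``age``, ``gender``, ``cohort``, ``group``;
* gene pool — one gene symbol per line, ``#`` comments allowed;
* probe map — two-column TSV ``feature_id<TAB>gene_symbol``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: diagnosis label used as the positive class throughout
AD = "AD"
CONTROL = "CONTROL"

_META_COLUMNS = ("diagnosis", "age", "gender", "cohort", "group")


class TransformState(enum.Enum):
    """Where a dataset sits in the preprocessing chain."""

    RAW = "RAW"
    LOG2 = "LOG2"
    CORRECTED = "CORRECTED"


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with aligned metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
        Raw (pre-transform) values are arbitrary positive intensities;
        after the log step they are log2 units.
    sample_meta
        DataFrame indexed by sample id with columns ``diagnosis`` and
        optionally ``age`` (years), ``gender`` (``M``/``F``), ``cohort``
        and ``group``. Missing age/gender are allowed and represented
        as NaN; they only matter to the covariate-correction step.
    feature_meta
        DataFrame indexed by feature id with column ``gene_symbol``
        (may be missing / NaN).
    transform_state
        RAW, LOG2 or CORRECTED.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    transform_state: TransformState = TransformState.RAW

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values rows and sample_meta index do not match")
        if not self.values.columns.equals(self.feature_meta.index):
            raise ValueError("values columns and feature_meta index do not match")
        for name, idx in (("sample", self.values.index), ("feature", self.values.columns)):
            if idx.has_duplicates:
                dup = idx[idx.duplicated()][0]
                raise ValueError(f"duplicated {name} id: {dup!r}")
        if "diagnosis" not in self.sample_meta.columns:
            raise ValueError("sample_meta must contain a 'diagnosis' column")
        if "gene_symbol" not in self.feature_meta.columns:
            self.feature_meta = self.feature_meta.assign(gene_symbol=np.nan)
        arr = self.values.to_numpy()
        if self.transform_state is TransformState.RAW:
            if np.nanmin(arr) < 0:
                raise ValueError("RAW dataset contains negative intensities")
        else:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.transform_state.value} dataset contains non-finite values")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def diagnoses(self) -> pd.Series:
        return self.sample_meta["diagnosis"]

    def binary_labels(self, positive: str = AD) -> np.ndarray:
        """0/1 vector with 1 for the positive diagnosis (AD by default)."""
        return (self.sample_meta["diagnosis"].to_numpy() == positive).astype(int)

    # -- subsetting ----------------------------------------------------------

    def select_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        ids = list(sample_ids)
        return replace(
            self,
            values=self.values.loc[ids],
            sample_meta=self.sample_meta.loc[ids],
        )

    def select_features(self, feature_ids: Iterable[str]) -> "ExpressionDataset":
        ids = list(feature_ids)
        return replace(
            self,
            values=self.values[ids],
            feature_meta=self.feature_meta.loc[ids],
        )

    def matrix(self, features: Iterable[str] | None = None) -> np.ndarray:
        """Expression values as a float array, optionally feature-subset."""
        if features is None:
            return self.values.to_numpy(dtype=float)
        return self.values[list(features)].to_numpy(dtype=float)


@dataclass
class GenePool:
    """A curated set of candidate gene symbols (upper-cased, deduplicated)."""

    symbols: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        symbols = frozenset(s.upper() for s in self.symbols)
        if not symbols:
            raise ValueError("gene pool is empty")
        object.__setattr__(self, "symbols", symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Load a raw expression matrix and its sample metadata.

    Samples present in the matrix but absent from the metadata are an
    error; metadata rows with no matching matrix row are dropped with a
    warning. The returned dataset is in the RAW transform state.
    """
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    with open(matrix_path) as fh:  # pandas silently renames duplicated header ids
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for fid in header:
        if fid in seen:
            raise ValueError(f"duplicated feature id in {matrix_path.name}: {fid!r}")
        seen.add(fid)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicated sample id in {matrix_path.name}: {dup!r}")
    if values.columns.has_duplicates:
        dup = values.columns[values.columns.duplicated()][0]
        raise ValueError(f"duplicated feature id in {matrix_path.name}: {dup!r}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {matrix_path.name}: {exc}") from exc

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "diagnosis" not in meta.columns:
        raise ValueError(f"{meta_path.name} must have sample_id and diagnosis columns")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id in {meta_path.name}: {dup!r}")
    meta = meta.set_index("sample_id")

    missing = values.index.difference(meta.index)
    if len(missing) == len(values.index):
        raise ValueError("empty intersection of matrix and metadata samples")
    if len(missing):
        raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
    extra = meta.index.difference(values.index)
    if len(extra):
        logger.warning("dropping %d metadata rows with no matrix sample: %s",
                       len(extra), list(extra)[:5])
    meta = meta.loc[values.index]
    for col in _META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")

    feature_meta = pd.DataFrame(index=values.columns.rename("feature_id"))
    feature_meta["gene_symbol"] = np.nan
    return ExpressionDataset(values=values, sample_meta=meta, feature_meta=feature_meta)


def write_expression(ds: ExpressionDataset, matrix_path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix and metadata back to the TSV interchange format."""
    out = ds.values.copy()
    out.index.name = "sample_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = ds.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_gene_pool(path: str | Path, source_label: str | None = None) -> GenePool:
    """Read a gene-pool file (one symbol per line; ``#`` comments)."""
    path = Path(path)
    symbols = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line.upper())
    if not symbols:
        raise ValueError(f"gene pool file {path} contains no symbols")
    return GenePool(symbols=frozenset(symbols),
                    source_label=source_label if source_label is not None else path.name)


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a feature_id -> gene_symbol two-column TSV into a Series."""
    table = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "gene_symbol"],
                        dtype=str, comment="#")
    if table["feature_id"].duplicated().any():
        dup = table.loc[table["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicated probe id in map: {dup!r}")
    return table.set_index("feature_id")["gene_symbol"]


# ---------------------------------------------------------------------------
# dataset-level operations
# ---------------------------------------------------------------------------

def filter_diagnoses(ds: ExpressionDataset, keep: Iterable[str]) -> ExpressionDataset:
    """Restrict to samples whose diagnosis label is in ``keep``."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    mask = ds.sample_meta["diagnosis"].isin(keep)
    return ds.select_samples(ds.values.index[mask])


def annotate_genes(ds: ExpressionDataset, mapping: pd.Series) -> ExpressionDataset:
    """Fill feature_meta.gene_symbol from a probe->gene mapping."""
    fm = ds.feature_meta.copy()
    mapped = ds.feature_meta.index.to_series().map(mapping)
    fm["gene_symbol"] = mapped.where(mapped.notna(), fm["gene_symbol"])
    return replace(ds, feature_meta=fm)


def restrict_to_pool(
    ds: ExpressionDataset,
    pool: GenePool,
    mapping: pd.Series | None = None,
) -> ExpressionDataset:
    """Keep exactly the features whose gene symbol belongs to the pool.

    Features with no gene symbol are dropped. Several probes mapping to
    the same pooled gene are all retained as separate features.
    """
    if mapping is not None:
        ds = annotate_genes(ds, mapping)
    symbols = ds.feature_meta["gene_symbol"].astype("string").str.upper()
    keep = symbols.isin(pool.symbols).fillna(False)
    if not keep.any():
        raise ValueError("pool/dataset intersection empty")
    return ds.select_features(ds.feature_meta.index[keep])
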