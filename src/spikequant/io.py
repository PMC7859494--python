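"""Domain types and file I/O.

All tabular formats are TSV (UTF-8, tab-delimited, ``#`` comment lines);
trees are newick.  Count tables on disk follow the common amplicon
convention of rows = OTUs, columns = samples; in memory every matrix is
samples x OTUs.  Every writer emits a comment header carrying the
package version and the run seed so outputs are traceable.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


TAXONOMY_CATEGORIES = frozenset(
    {"bacteria", "archaea", "chloroplast", "spike_in", "unassigned"}
)

LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Environmental variables used by the driver analyses, in canonical order.
ENV_VARS = (
    "temperature",
    "salinity",
    "nox",
    "drp",
    "silicate",
    "chla",
    "bacterial_abundance",
)

METADATA_COLUMNS = ENV_VARS + (
    "longitude",
    "latitude",
    "recovery_ratio",
    "volume",
)


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CountTable:
    """Integer read counts, samples x OTUs."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise FormatError("count table needs at least 1 sample and 1 OTU")
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "OTU")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count table contains non-numeric values")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        self.data = df.astype(np.int64)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class TaxonomyTable:
    """OTU -> lineage and cleaning category.

    ``data`` is indexed by OTU id with columns ``lineage`` (semicolon-joined
    ranks, domain..genus, possibly truncated) and ``category`` (one of
    ``TAXONOMY_CATEGORIES``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "OTU")
        missing = {"lineage", "category"} - set(df.columns)
        if missing:
            raise FormatError(f"taxonomy table missing columns: {sorted(missing)}")
        bad = set(df["category"]) - TAXONOMY_CATEGORIES
        if bad:
            raise FormatError(f"unknown taxonomy categories: {sorted(bad)}")

    def category_of(self, otu_id) -> str:
        return self.data.at[otu_id, "category"]

    def otus_in_category(self, category: str) -> list:
        return list(self.data.index[self.data["category"] == category])

    def rank_label(self, otu_id, rank: str) -> str:
        """Lineage label at ``rank`` or ``'Others'`` when unavailable."""
        if rank not in LINEAGE_RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
        depth = LINEAGE_RANKS.index(rank)
        if otu_id not in self.data.index:
            return "Others"
        parts = [p.strip() for p in str(self.data.at[otu_id, "lineage"]).split(";")]
        if depth >= len(parts) or not parts[depth] or parts[depth].lower() in (
            "unassigned",
            "na",
            "nan",
        ):
            return "Others"
        return parts[depth]


@dataclass
class SpikeInDesign:
    """Copies of each synthetic standard added per sample."""

    added_copies: pd.Series  # index: spikein_id

    def __post_init__(self) -> None:
        s = self.added_copies.astype(float)
        _check_unique(s.index, "spike-in")
        if (s <= 0).any():
            raise FormatError("spike-in added_copies must be > 0")
        if s.nunique() < 2:
            raise FormatError("spike-in design needs >= 2 distinct concentration levels")
        self.added_copies = s

    @property
    def spikein_ids(self) -> list:
        return list(self.added_copies.index)


@dataclass
class SampleMetadata:
    """Per-sample environmental, geographic and calibration variables."""

    data: pd.DataFrame
    longitude_convention: str = "[-180,180]"

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        missing = set(METADATA_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        df = df[list(METADATA_COLUMNS)].astype(float)
        if df.isna().any().any():
            cols = df.columns[df.isna().any()].tolist()
            raise FormatError(f"metadata contains missing values in: {cols}")
        if self.longitude_convention == "[0,360]":
            lon = df["longitude"].to_numpy()
            if np.any(lon < 0) or np.any(lon > 360):
                raise FormatError("longitude outside declared [0,360] range")
            df["longitude"] = ((lon + 180.0) % 360.0) - 180.0
        else:
            lon = df["longitude"].to_numpy()
            if np.any(lon < -180) or np.any(lon > 180):
                raise FormatError("longitude outside [-180,180]")
        lat = df["latitude"].to_numpy()
        if np.any(np.abs(lat) > 90):
            raise FormatError("latitude outside [-90,90]")
        r = df["recovery_ratio"].to_numpy()
        if np.any(r <= 0) or np.any(r > 1):
            raise FormatError("recovery_ratio must lie in (0,1]")
        if np.any(df["volume"].to_numpy() <= 0):
            raise FormatError("volume must be > 0")
        self.data = df
        self.longitude_convention = "[-180,180]"

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)


@dataclass
class RunConfig:
    """Pipeline configuration with the defaults used throughout."""

    rarefaction_depth: int | str = "min"
    abundance_threshold: float = 0.001
    corr_r_cutoff: float = 0.6
    corr_alpha: float = 0.05
    n_permutations: int = 999
    rng_seed: int = 0
    shannon_log_base: float = 2.0
    distance_metric: str = "bray-curtis"
    mantel_method: str = "spearman"

    def __post_init__(self) -> None:
        if not (0 < self.abundance_threshold < 1):
            raise ValueError("abundance_threshold must be in (0,1)")
        if not (0 <= self.corr_r_cutoff <= 1):
            raise ValueError("corr_r_cutoff must be in [0,1]")
        if not (0 < self.corr_alpha < 1):
            raise ValueError("corr_alpha must be in (0,1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.shannon_log_base <= 1:
            raise ValueError("shannon_log_base must be > 1")
        if self.rarefaction_depth != "min" and int(self.rarefaction_depth) < 1:
            raise ValueError("rarefaction_depth must be 'min' or a positive integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("sim", None)  # simulation section consumed by the CLI
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers


def _header_lines(config: RunConfig | None) -> str:
    from . import __version__

    seed = config.rng_seed if config is not None else "NA"
    return f"# spikequant v{__version__} seed={seed}\n"


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.index.name = None
    df.columns.name = None
    return df


def read_count_table(path, dialect: str = "tsv", transpose: bool = False) -> CountTable:
    """Read an OTU count table.

    TSV layout: rows = OTUs, columns = samples (pass ``transpose=True`` for
    the other orientation).  BIOM is accepted when the optional ``biom``
    package is importable.
    """
    if dialect == "biom":
        try:
            import biom  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FormatError(
                "BIOM dialect requested but the 'biom' package is not installed"
            ) from exc
        table = biom.load_table(str(path))  # pragma: no cover
        df = table.to_dataframe(dense=True).T  # pragma: no cover
        return CountTable(df)  # pragma: no cover
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    if not transpose:
        df = df.T  # disk: rows=OTUs -> memory: rows=samples
    return CountTable(df)


def write_count_table(table: CountTable, path, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        out = table.data.T.rename_axis("otu_id")  # rows=OTUs on disk
        out.to_csv(fh, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    return TaxonomyTable(df)


def write_taxonomy(table: TaxonomyTable, path, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        out = table.data.rename_axis("otu_id")
        out.to_csv(fh, sep="\t")


def read_spikein_design(path) -> SpikeInDesign:
    df = _read_tsv(path)
    if "added_copies" not in df.columns:
        raise FormatError("spike-in design needs an 'added_copies' column")
    try:
        copies = df["added_copies"].astype(float).rename(None)
    except ValueError as exc:
        raise FormatError(f"non-numeric added_copies: {exc}") from exc
    return SpikeInDesign(copies)


def write_spikein_design(
    design: SpikeInDesign, path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        out = design.added_copies.to_frame("added_copies").rename_axis("spikein_id")
        out.to_csv(fh, sep="\t")


def read_sample_metadata(path, longitude_convention: str = "[-180,180]") -> SampleMetadata:
    df = _read_tsv(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric metadata value: {exc}") from exc
    return SampleMetadata(df, longitude_convention=longitude_convention)


def write_sample_metadata(
    meta: SampleMetadata, path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        out = meta.data.rename_axis("sample_id")
        out.to_csv(fh, sep="\t")


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree, requiring branch lengths everywhere."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(
                f"missing branch length on edge above {node.name or 'internal node'}"
            )
    if tree.length is None:
        tree.length = 0.0  # root edge carries no information
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_result_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write an analysis result table with the standard comment header."""
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t")
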