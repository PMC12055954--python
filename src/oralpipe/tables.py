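"""Core data containers for amplicon count data and study metadata.

Count tables are taxa-as-rows / samples-as-columns, tab-delimited on disk,
matching common amplicon exports.  Three taxonomic levels are tracked:
``variant`` (exact sequence variants), ``species`` and ``genus``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LEVELS = ("variant", "species", "genus")
SITES = ("SA", "TO", "SU")
TIMES = ("t0", "t1", "t2")
ARMS = ("control", "juice")

#: reserved species-level label pooling variants without a species call
OTHERS_LABEL = "others"


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


@dataclass
class CountTable:
    """Integer counts of taxa (rows) per sample (columns).

    Parameters
    ----------
    data:
        DataFrame with taxon identifiers as index and sample identifiers
        as columns; non-negative integer body.
    level:
        Taxonomic level of the rows, one of ``variant``, ``species``,
        ``genus``.
    """

    data: pd.DataFrame
    level: str = "variant"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        arr = self.data.to_numpy()
        if arr.size == 0:
            raise FormatError("count table has an empty body")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("count table contains non-integer values")
            self.data = self.data.round().astype(np.int64)
            arr = self.data.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample column sums (sequencing depth)."""
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return CountTable(self.data[ids].copy(), level=self.level)

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        ids = [t for t in taxon_ids if t in self.data.index]
        return CountTable(self.data.drop(index=ids), level=self.level)

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), level=self.level)


@dataclass
class RelativeAbundanceTable:
    """Relative abundances in percent; each sample column sums to 100."""

    data: pd.DataFrame
    level: str = "variant"

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=0)
        bad = sums[(sums - 100.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"sample columns do not sum to 100%: {bad.index.tolist()}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "RelativeAbundanceTable":
        return RelativeAbundanceTable(self.data[list(sample_ids)].copy(), self.level)


@dataclass
class SampleMetadata:
    """Per-sample design labels binding the repeated-measures structure."""

    data: pd.DataFrame  # index sample_id; columns subject_id, site, time, arm

    REQUIRED = ("subject_id", "site", "time", "arm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        bad_site = set(self.data["site"]) - set(SITES)
        if bad_site:
            raise FormatError(f"unknown site labels: {sorted(bad_site)}")
        bad_time = set(self.data["time"]) - set(TIMES)
        if bad_time:
            raise FormatError(f"unknown time labels: {sorted(bad_time)}")
        bad_arm = set(self.data["arm"]) - set(ARMS)
        if bad_arm:
            raise FormatError(f"unknown arm labels: {sorted(bad_arm)}")
        key = self.data[["subject_id", "site", "time"]]
        if key.duplicated().any():
            raise FormatError("(subject, site, time) does not uniquely identify samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_for(self, site: str | None = None, time: str | None = None,
                    arm: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.data.index)
        if site is not None:
            mask &= self.data["site"] == site
        if time is not None:
            mask &= self.data["time"] == time
        if arm is not None:
            mask &= self.data["arm"] == arm
        return list(self.data.index[mask])

    def align_to(self, table: CountTable) -> "SampleMetadata":
        """Metadata restricted and reordered to a table's samples.

        Raises if any table sample lacks a metadata row.
        """
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        return SampleMetadata(self.data.loc[table.sample_ids].copy())


@dataclass
class TaxonomyMap:
    """variant_id -> genus label (mandatory) and optional species label."""

    genus: Mapping[str, str]
    species: Mapping[str, str] = field(default_factory=dict)

    def genus_of(self, variant_id: str) -> str:
        try:
            return self.genus[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} has no genus annotation") from None

    def species_of(self, variant_id: str) -> str | None:
        return self.species.get(variant_id)


# ---------------------------------------------------------------------------
# I/O

def read_count_table(path: str | Path | io.TextIOBase, level: str = "variant") -> CountTable:
    """Read a tab-delimited count table (taxa rows, sample columns).

    The first column holds taxon identifiers, the header row sample
    identifiers, and the body must be non-negative integers.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("count table file is empty") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError("count table has an empty body")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise FormatError(f"non-numeric count at taxon {row!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            row = df.index[~np.isclose(vals, np.round(vals))][0]
            raise FormatError(f"non-integer count at taxon {row!r}, sample {col!r}")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return CountTable(df, level=level)


def write_count_table(table: CountTable, path: str | Path | io.TextIOBase) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path | io.TextIOBase) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path | io.TextIOBase) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path | io.TextIOBase) -> TaxonomyMap:
    """Read a tab-delimited taxonomy map: variant_id, genus[, species]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "variant_id" not in df.columns or "genus" not in df.columns:
        raise FormatError("taxonomy must have variant_id and genus columns")
    df = df.set_index("variant_id")
    genus = df["genus"].to_dict()
    species: dict[str, str] = {}
    if "species" in df.columns:
        sp = df["species"].dropna()
        species = {k: v for k, v in sp.items() if v != ""}
    return TaxonomyMap(genus=genus, species=species)


def write_taxonomy(tax: TaxonomyMap, path: str | Path | io.TextIOBase) -> None:
    rows = []
    for vid, genus in tax.genus.items():
        rows.append({"variant_id": vid, "genus": genus,
                     "species": tax.species.get(vid, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transformations

def aggregate(table: CountTable, tax: TaxonomyMap, level: str) -> CountTable:
    """Sum variant counts into species- or genus-level taxa.

    At species level, variants without a species call pool into the
    reserved ``others`` taxon.  At genus level every variant must carry a
    genus annotation (``unclassified <rank>`` labels are kept as distinct
    taxa).
    """
    if table.level != "variant":
        raise ValueError("aggregate expects a variant-level table")
    if level not in ("species", "genus"):
        raise ValueError("aggregation level must be species or genus")
    if level == "genus":
        labels = []
        for vid in table.taxon_ids:
            labels.append(tax.genus_of(vid))
    else:
        labels = [tax.species_of(vid) or OTHERS_LABEL for vid in table.taxon_ids]
    out = table.data.groupby(pd.Index(labels, name="taxon_id"), sort=False).sum()
    return CountTable(out, level=level)


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    """Standardize counts to percentages per sample."""
    sizes = table.library_sizes()
    zero = sizes[sizes == 0]
    if len(zero):
        raise ValueError(f"zero-depth samples: {zero.index.tolist()}")
    rel = table.data.div(sizes, axis=1) * 100.0
    return RelativeAbundanceTable(rel, level=table.level)


def prevalence_filter(abund: RelativeAbundanceTable | CountTable,
                      min_prevalence: float, strict: bool = False) -> list[str]:
    """Taxa present in enough of the given samples.

    With ``strict=False`` (inclusive) a taxon is kept when its nonzero
    fraction is >= ``min_prevalence`` (the differential screens' "at least
    10%"); with ``strict=True`` the fraction must exceed it (the
    contaminant screen's "prevalence > 10%").  Prevalence is evaluated
    within whatever sample subset the table holds.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    data = abund.data
    if data.size == 0:
        raise ValueError("empty table")
    frac = (data > 0).sum(axis=1) / data.shape[1]
    keep = frac > min_prevalence if strict else frac >= min_prevalence
    return list(data.index[keep])


def screening_percentage(n_significant: int, n_tested: int) -> float:
    """Fraction of differentially distributed taxa, in percent (1 decimal).

    This is the convention used to report screening outcomes, e.g.
    48 of 179 tested taxa -> 26.8.
    """
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return round(100.0 * n_significant / n_tested, 1)
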