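"""Read, validate, normalize, and write taxon count tables and centroid tables.

File contract
-------------
A count table is a CSV/TSV with one row per sample. The first column must be
named ``sampleID`` (a unique sample identifier), the second ``read_count``
(the total read count declared for the sample), and every remaining column is
a phylotype whose header follows the naming scheme
``<rank-prefix>_<Name>`` (e.g. ``g_Bifidobacterium``) for taxa summarised at
genus rank or higher, or ``<Genus>_<species>`` for the key genera that are
resolved to species (*Lactobacillus*, *Gardnerella*, *Prevotella*,
*Atopobium*, *Sneathia*, *Mobiluncus*), e.g. ``Lactobacillus_crispatus``.

A centroid table is a CSV whose first column is ``sub_CST`` and whose
remaining columns are phylotypes; each row is the mean relative-abundance
profile of one sub-CST and must sum to 1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

SAMPLE_ID_COLUMN = "sampleID"
READ_COUNT_COLUMN = "read_count"
CENTROID_LABEL_COLUMN = "sub_CST"

#: Genera resolved to species level; all other taxa carry a rank prefix.
SPECIES_LEVEL_GENERA = (
    "Lactobacillus",
    "Gardnerella",
    "Prevotella",
    "Atopobium",
    "Sneathia",
    "Mobiluncus",
)

_RANK_PREFIX_RE = re.compile(r"^(?:d|p|c|o|f|g)_[A-Z][A-Za-z0-9]*(?:[_.\-][A-Za-z0-9]+)*$")
_SPECIES_RE = re.compile(
    r"^(?:" + "|".join(SPECIES_LEVEL_GENERA) + r")_[a-z][a-z0-9]*(?:[_.\-][a-z0-9]+)*$"
)


def is_canonical_label(label: str) -> bool:
    """True if *label* follows the phylotype naming scheme."""
    return bool(_RANK_PREFIX_RE.match(label) or _SPECIES_RE.match(label))


def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        try:
            return {"csv": ",", "tsv": "\t"}[dialect]
        except KeyError:  # pragma: no cover - defensive
            raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    # Sniffing is limited to comma vs tab, decided on the header line.
    header = Path(path).open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


@dataclass
class CountTable:
    """Raw per-sample taxon read counts plus the declared total read count.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = sample ids, columns = taxa.
    declared_totals : pandas.Series
        The ``read_count`` column, aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    declared_totals: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- container surface -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sampleID values: {dups}")
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative read counts are not allowed")
        if not self.declared_totals.index.equals(self.counts.index):
            raise ValidationError("declared_totals index does not match counts index")
        bad = self.declared_totals[self.declared_totals <= 0]
        if len(bad):
            raise ValidationError(
                f"declared read_count must be > 0; offending samples: {list(bad.index)}"
            )

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.declared_totals.copy())


@dataclass
class CentroidSet:
    """Named sub-CST reference centroids (rows on the probability simplex).

    Attributes
    ----------
    centroids : pandas.DataFrame
        Rows = sub-CST labels (in file/training order), columns = taxa,
        values = mean relative abundances; each row sums to 1.
    bootstrap_se : pandas.DataFrame, optional
        Per-taxon bootstrap standard error of each centroid.
    n_samples : pandas.Series, optional
        Number of training samples contributing to each centroid.
    """

    centroids: pd.DataFrame
    bootstrap_se: pd.DataFrame | None = None
    n_samples: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.centroids.index.has_duplicates:
            dups = self.centroids.index[self.centroids.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sub-CST labels: {dups}")
        sums = self.centroids.sum(axis=1)
        off = sums[(sums - 1.0).abs() > 1e-9]
        if len(off):
            raise ValidationError(
                f"centroid rows must sum to 1 +/- 1e-9; offending: {dict(off.round(6))}"
            )
        if self.bootstrap_se is not None and (self.bootstrap_se.fillna(0.0) < 0).any().any():
            raise ValidationError("bootstrap SEs must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.centroids.index)

    def __len__(self) -> int:
        return len(self.centroids)


def read_counts_table(
    path: str | Path,
    dialect: str | None = None,
    case_sensitive: bool = True,
) -> CountTable:
    """Read a taxon read-count table from *path*.

    The first two columns must be named ``sampleID`` and ``read_count``
    (case-sensitive unless *case_sensitive* is False); all remaining columns
    are parsed as taxa, preserving file order.

    Raises
    ------
    SchemaError
        Missing/misnamed mandatory columns.
    ParseError
        Non-numeric or non-integer count cells (message carries coordinates).
    ValidationError
        Duplicate sample ids, negative counts, non-positive read_count.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise SchemaError("count table needs at least 'sampleID' and 'read_count' columns")

    cols = list(raw.columns)
    expected = [SAMPLE_ID_COLUMN, READ_COUNT_COLUMN]
    for pos, want in enumerate(expected):
        got = cols[pos]
        ok = got == want or (not case_sensitive and got.lower() == want.lower())
        if not ok:
            raise SchemaError(
                f"column {pos + 1} must be named {want!r}, found {got!r}"
            )

    sample_ids = raw.iloc[:, 0]
    if sample_ids.duplicated().any():
        dups = sample_ids[sample_ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sampleID values: {dups}")

    numeric_cols = cols[1:]
    parsed = {}
    for col in numeric_cols:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric count in column {col!r}, row {row + 2} "
                f"(sampleID {sample_ids.iloc[row]!r}): {raw[col].iloc[row]!r}"
            )
        frac = vals % 1 != 0
        if frac.any():
            row = int(np.flatnonzero(frac)[0])
            raise ParseError(
                f"non-integer count in column {col!r}, row {row + 2} "
                f"(sampleID {sample_ids.iloc[row]!r}): {raw[col].iloc[row]!r}"
            )
        parsed[col] = vals.astype(np.int64)

    frame = pd.DataFrame(parsed)
    frame.index = pd.Index(sample_ids.astype(str), name=SAMPLE_ID_COLUMN)
    declared = frame.pop(cols[1])
    declared.name = READ_COUNT_COLUMN
    return CountTable(counts=frame, declared_totals=declared)


def write_counts_table(table: CountTable, path: str | Path, dialect: str = "csv") -> None:
    """Write *table* back to the file contract (round-trips exactly)."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    out = table.counts.copy()
    out.insert(0, READ_COUNT_COLUMN, table.declared_totals)
    out.to_csv(path, sep=sep, index_label=SAMPLE_ID_COLUMN)


def normalize_taxon_names(
    table: CountTable,
    synonym_map: Mapping[str, str],
) -> tuple[CountTable, list[str]]:
    """Rename taxon columns via *synonym_map* (raw label -> canonical label).

    Columns mapping to the same canonical label are summed. Labels not in the
    map are left unchanged and returned as the second element so callers can
    review them.

    Raises
    ------
    ValidationError
        If a map value violates the naming grammar.
    """
    for raw, canon in synonym_map.items():
        if not is_canonical_label(canon):
            raise ValidationError(
                f"synonym target {canon!r} (for {raw!r}) violates the naming scheme"
            )
    renamed = table.counts.rename(columns=dict(synonym_map))
    # groupby on columns sums duplicates; preserve first-occurrence order
    order = list(dict.fromkeys(renamed.columns))
    merged = renamed.T.groupby(level=0, sort=False).sum().T[order]
    unmapped = [t for t in merged.columns if not is_canonical_label(t)]
    return CountTable(merged, table.declared_totals.copy()), unmapped


def to_relative_abundance(
    table: CountTable,
    denominator: str = "row_sum",
    on_zero: str = "error",
) -> tuple[pd.DataFrame, pd.Series]:
    """Convert counts to per-sample relative abundances on the simplex.

    Parameters
    ----------
    denominator : {"row_sum", "declared_total"}
        ``row_sum`` divides by the sum of taxa counts (vectors sum to exactly
        1). ``declared_total`` divides by the ``read_count`` column; the
        pre-normalization sum ("coverage", < 1 when reads were assigned to
        taxa dropped upstream) is reported per sample and the vector is then
        renormalized to sum 1.
    on_zero : {"error", "drop"}
        What to do with samples whose chosen denominator or taxa row sum is
        zero: raise listing the samples, or silently exclude them.

    Returns
    -------
    (proportions, coverage)
        ``proportions`` rows sum to 1 +/- 1e-9; ``coverage`` is the
        pre-renormalization sum per sample (1.0 in row_sum mode).
    """
    if denominator not in ("row_sum", "declared_total"):
        raise ValueError(f"unknown denominator {denominator!r}")
    counts = table.counts.astype(float)
    row_sums = counts.sum(axis=1)
    denom = row_sums if denominator == "row_sum" else table.declared_totals.astype(float)

    zero = denom <= 0
    zero |= row_sums <= 0  # a sample with no taxon reads is degenerate either way
    if zero.any():
        offenders = list(counts.index[zero])
        if on_zero == "error":
            raise ValidationError(
                f"zero denominator for samples {offenders}; "
                "pass on_zero='drop' to exclude them"
            )
        counts = counts.loc[~zero]
        denom = denom.loc[~zero]
        row_sums = row_sums.loc[~zero]

    pre = counts.div(denom, axis=0)
    coverage = pre.sum(axis=1)
    coverage.name = "coverage"
    proportions = pre.div(coverage, axis=0)
    return proportions, coverage


def filter_rare_taxa(
    table: CountTable,
    threshold: float = 1e-5,
    mode: str = "pooled",
) -> tuple[CountTable, list[str]]:
    """Remove taxa below a study-wide frequency *threshold*.

    ``mode="pooled"`` (default) measures frequency as total reads of the
    taxon divided by total reads in the table; ``mode="mean_abundance"``
    uses the mean per-sample relative abundance instead.

    Returns the filtered table and the list of removed taxa.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if mode == "pooled":
        totals = table.counts.sum(axis=0)
        freq = totals / totals.sum()
    elif mode == "mean_abundance":
        props, _ = to_relative_abundance(table, on_zero="drop")
        freq = props.mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = freq >= threshold
    removed = list(table.counts.columns[~keep])
    filtered = CountTable(table.counts.loc[:, keep].copy(), table.declared_totals.copy())
    return filtered, removed


def read_centroids(path: str | Path, dialect: str | None = None) -> CentroidSet:
    """Load a reference-centroid table.

    Row sums are validated to 1 +/- 1e-6; rows within 1e-3 are renormalized
    with a warning; larger deviations (and duplicate labels) raise.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    frame = pd.read_csv(path, sep=sep)
    if frame.columns[0] != CENTROID_LABEL_COLUMN:
        raise SchemaError(
            f"first column of a centroid file must be {CENTROID_LABEL_COLUMN!r}, "
            f"found {frame.columns[0]!r}"
        )
    frame = frame.set_index(CENTROID_LABEL_COLUMN)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sub-CST labels: {dups}")
    values = frame.astype(float)
    sums = values.sum(axis=1)
    far = sums[(sums - 1.0).abs() > 1e-3]
    if len(far):
        raise ValidationError(
            f"centroid rows deviate from sum 1 by more than 1e-3: {dict(far.round(4))}"
        )
    close = (sums - 1.0).abs() > 1e-6
    if close.any():
        warnings.warn(
            f"renormalizing centroid rows with sums {dict(sums[close].round(6))}",
            UserWarning,
            stacklevel=2,
        )
    values = values.div(sums, axis=0)
    return CentroidSet(centroids=values)


def write_centroids(centroid_set: CentroidSet, path: str | Path) -> None:
    """Write a CentroidSet in the centroid-file contract (CSV)."""
    centroid_set.centroids.to_csv(path, index_label=CENTROID_LABEL_COLUMN)


def union_vocabulary(*taxa_lists: Iterable[str]) -> list[str]:
    """Union of taxon vocabularies, preserving first-seen order."""
    seen: dict[str, None] = {}
    for taxa in taxa_lists:
        for t in taxa:
            seen.setdefault(t, None)
    return list(seen)
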