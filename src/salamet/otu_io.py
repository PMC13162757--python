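"""OTU-table IO and pre-analysis filtering for fecal metabarcoding data.

The pipeline starts at a dereplicated OTU read-count table (samples x OTUs)
with a taxonomy assignment per OTU and per-sample metadata (habitat type,
primer set).  Before any dietary metric is computed two cleaning steps apply:

* **relative-read filtering** — an OTU is kept only if its within-sample
  relative read count reaches a threshold in at least one sample (low-share
  OTUs are typical tag-jumping / index-hopping noise);
* **host-DNA exclusion** — OTUs assigned to the sampled animal itself
  ("self-DNA") are removed, so prey proportions are computed among prey
  reads only.  Samples left empty by this step are flagged, not dropped
  silently.

OTUs can then be collapsed to analysis taxa or families by summing reads.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ReadMatrix",
    "read_otu_table",
    "read_taxonomy",
    "read_metadata",
    "write_otu_table",
    "filter_relative_reads",
    "exclude_host",
    "collapse_to_taxa",
]

HABITAT_TYPES = ("restored", "alternative")
PRIMERS = ("18SV9", "COI313", "Block_18SV9")
UNCLASSIFIED = "Unclassified/Other"
HOST_TAXON_ID = "HOST_SELF"


@dataclass
class ReadMatrix:
    """Integer read counts (samples x OTUs/taxa) with per-sample metadata.

    ``flags`` carries per-sample quality annotations accumulated by the
    cleaning steps (e.g. ``empty_after_host_removal``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU id(s): {dup}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("read counts must be integers")
            self.counts = c.astype(np.int64)
        if arr.size and (arr < 0).any():
            raise ValidationError("read counts must be >= 0")
        if self.sample_meta is not None:
            missing = c.index.difference(self.sample_meta.index)
            if len(missing):
                raise ValidationError(f"samples without metadata: {missing.tolist()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def with_counts(self, counts: pd.DataFrame, **extra_flags) -> "ReadMatrix":
        flags = {k: list(v) for k, v in self.flags.items()}
        for k, v in extra_flags.items():
            flags.setdefault(k, []).extend(v)
        meta = None if self.sample_meta is None else self.sample_meta.loc[counts.index]
        return ReadMatrix(counts, meta, flags)


# ---------------------------------------------------------------------------
# parsing

def _check_ids(ids, kind: str, path) -> None:
    s = pd.Index(ids)
    if s.duplicated().any():
        dup = s[s.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate {kind} id(s): {dup}")


def read_otu_table(path, dialect: str = "tsv_samples_as_rows",
                   metadata_path=None) -> ReadMatrix:
    """Read an OTU table into a ReadMatrix, normalizing orientation.

    Dialects: ``tsv_samples_as_rows`` (header = OTU ids, first column =
    sample ids), ``tsv_samples_as_cols`` (transposed), or
    ``biom_dense_json`` (a dense JSON object with ``sample_ids``,
    ``otu_ids`` and row-major ``data``).
    """
    if dialect in ("tsv_samples_as_rows", "tsv_samples_as_cols"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        if dialect == "tsv_samples_as_cols":
            df = df.T
    elif dialect == "biom_dense_json":
        with open(path) as fh:
            obj = json.load(fh)
        df = pd.DataFrame(obj["data"], index=obj["sample_ids"], columns=obj["otu_ids"])
    else:
        raise ParseError(f"unknown OTU-table dialect {dialect!r}")
    df.index.name = "sample_id"
    df.columns.name = None
    _check_ids(df.index, "sample", path)
    _check_ids(df.columns, "OTU", path)
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (np.mod(arr.astype(float), 1) != 0) | (arr.astype(float) < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-integer or negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}")
    meta = read_metadata(metadata_path) if metadata_path is not None else None
    return ReadMatrix(df.astype(np.int64), meta)


def write_otu_table(path, m: ReadMatrix) -> None:
    m.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV: ``otu_id<TAB>taxon<TAB>family<TAB>is_host``.

    ``family`` may be empty/'unknown'; ``is_host`` accepts 0/1/true/false.
    Returns a DataFrame indexed by otu_id with columns taxon, family, is_host.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"otu_id", "taxon", "family", "is_host"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: taxonomy needs columns {sorted(expected)}")
    _check_ids(df["otu_id"], "OTU", path)
    df = df.set_index("otu_id")
    df["family"] = df["family"].fillna("unknown")
    df["is_host"] = df["is_host"].str.strip().str.lower().map(
        {"1": True, "true": True, "0": False, "false": False})
    if df["is_host"].isna().any():
        raise ParseError(f"{path}: is_host must be 0/1/true/false")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV: ``sample_id<TAB>habitat_type<TAB>primer``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"sample_id", "habitat_type", "primer"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(expected)}")
    _check_ids(df["sample_id"], "sample", path)
    df = df.set_index("sample_id")
    bad = set(df["habitat_type"]) - set(HABITAT_TYPES)
    if bad:
        raise ParseError(f"{path}: unknown habitat_type value(s) {sorted(bad)}")
    bad = set(df["primer"]) - set(PRIMERS)
    if bad:
        raise ParseError(f"{path}: unknown primer value(s) {sorted(bad)}")
    return df


def _coverage(m: ReadMatrix, tax: pd.DataFrame) -> None:
    missing = m.counts.columns.difference(tax.index)
    if len(missing):
        raise ValidationError(f"taxonomy does not cover OTU(s): {missing.tolist()}")


# ---------------------------------------------------------------------------
# filtering

def filter_relative_reads(m: ReadMatrix, threshold: float,
                          mode: str = "per_otu") -> ReadMatrix:
    """Drop OTUs whose within-sample relative read count never reaches
    ``threshold`` (a fraction, e.g. 0.0001 for 0.01%).

    ``mode='per_otu'`` (default) retains or drops whole OTU columns; cells of
    retained OTUs are kept as-is.  ``mode='per_cell'`` additionally zeroes
    individual cells below the threshold (an alternative reading of
    relative-read filtering, kept behind this switch).
    """
    if not 0 <= threshold < 1:
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    if mode not in ("per_otu", "per_cell"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    counts = m.counts
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts.to_numpy(dtype=float) / totals[:, None]
    rel = np.nan_to_num(rel)
    if mode == "per_cell":
        cells = counts.to_numpy().copy()
        cells[rel < threshold] = 0
        counts = pd.DataFrame(cells, index=counts.index, columns=counts.columns)
        keep = counts.sum(axis=0) > 0 if threshold > 0 else counts.sum(axis=0) >= 0
    else:
        reaches = (rel >= threshold) & (counts.to_numpy() > 0)
        keep = pd.Series(reaches.any(axis=0), index=counts.columns)
        if threshold == 0:
            keep |= counts.sum(axis=0) >= 0  # no-op bound: keep everything
    out = counts.loc[:, keep[keep].index]
    if out.shape[1] == 0:
        warnings.warn("relative-read filter removed every OTU", stacklevel=2)
    return m.with_counts(out)


def exclude_host(m: ReadMatrix, tax: pd.DataFrame) -> ReadMatrix:
    """Remove host ('self-DNA') OTUs; flag samples left with zero reads."""
    _coverage(m, tax)
    host_cols = [o for o in m.counts.columns if bool(tax.loc[o, "is_host"])]
    out = m.counts.drop(columns=host_cols)
    emptied = out.index[(out.sum(axis=1) == 0) & (m.counts.sum(axis=1) > 0)].tolist()
    return m.with_counts(out, empty_after_host_removal=emptied)


def collapse_to_taxa(m: ReadMatrix, tax: pd.DataFrame, level: str = "taxon") -> ReadMatrix:
    """Sum reads over OTUs sharing a label at ``level`` ('taxon' or 'family').

    OTUs with unknown family are pooled into the 'Unclassified/Other' column
    when collapsing at family level.  Total reads are conserved.
    """
    if level not in ("taxon", "family"):
        raise ValidationError(f"unknown collapse level {level!r}")
    _coverage(m, tax)
    labels = tax.loc[m.counts.columns, level].astype(str)
    if level == "family":
        labels = labels.where(~labels.str.lower().isin(["unknown", "nan", ""]),
                              UNCLASSIFIED)
    grouped = m.counts.T.groupby(labels.values).sum().T
    return m.with_counts(grouped)
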