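"""Dietary summary metrics for metabarcoding read tables.

For a taxa-level read table with S samples and T prey items, with n_ik the
reads of item i in sample k and I_ik = 1 iff n_ik > 0:

* ``%FOO_i = 100 * (1/S) * sum_k I_ik`` — frequency of occurrence: how
  widespread a prey item is across samples.
* ``%RRA_i = 100 * (1/S) * sum_k n_ik / sum_j n_jk`` — relative read
  abundance: the mean within-sample read share.  Sums to 100% over items.
* ``%P_i = 100 * (sum_k n_ik) / (sum over samples containing i of total
  reads)`` — prey-specific abundance: the item's read share restricted to
  the samples where it occurs; the y-axis of the Costello diagram.

Plotting %P_i against %FOO gives the Costello feeding-strategy diagram:
high %P_i at low %FOO marks specialization / between-phenotype niche
components, points near the lower-right mark generalized feeding, and the
main diagonal separates dominant from rare prey.  The split thresholds are
configuration, not biology: the diagram's regions are qualitative.

Samples with zero prey reads (e.g. everything was host DNA) are excluded
from S for all three metrics, with the count recorded on the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .otu_io import ReadMatrix

__all__ = [
    "compute_foo",
    "compute_rra",
    "compute_prey_specific_abundance",
    "diet_profile",
    "costello_points",
    "CostelloPoint",
]


def _counts(m) -> pd.DataFrame:
    df = m.counts if isinstance(m, ReadMatrix) else pd.DataFrame(m)
    if df.shape[0] == 0:
        raise ValidationError("no samples in read table")
    return df


def _drop_empty(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    nonempty = df.sum(axis=1) > 0
    return df.loc[nonempty], int((~nonempty).sum())


def compute_foo(m) -> pd.Series:
    """Percent frequency of occurrence per taxon (empty samples excluded)."""
    df, _ = _drop_empty(_counts(m))
    if df.shape[0] == 0:
        raise ValidationError("all samples are empty")
    return (df > 0).mean(axis=0) * 100.0


def compute_rra(m) -> pd.Series:
    """Percent relative read abundance per taxon (empty samples excluded)."""
    df, _ = _drop_empty(_counts(m))
    if df.shape[0] == 0:
        raise ValidationError("all samples are empty")
    props = df.div(df.sum(axis=1), axis=0)
    return props.mean(axis=0) * 100.0


def compute_prey_specific_abundance(m) -> pd.Series:
    """Percent prey-specific abundance per taxon.

    Taxa occurring in no sample get NaN (undefined), not 0.
    """
    df, _ = _drop_empty(_counts(m))
    if df.shape[0] == 0:
        raise ValidationError("all samples are empty")
    arr = df.to_numpy(dtype=float)
    present = arr > 0
    item_reads = arr.sum(axis=0)
    sample_totals = arr.sum(axis=1)
    denom = present.T @ sample_totals  # total reads of samples containing i
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 100.0 * item_reads / denom
    pi[~present.any(axis=0)] = np.nan
    return pd.Series(pi, index=df.columns)


def diet_profile(m: ReadMatrix, group_by: str | None = None) -> pd.DataFrame:
    """Per-(stratum, taxon) diet profile: FOO, RRA, Pi and sample counts.

    ``group_by`` names a sample-metadata column (e.g. ``habitat_type``); with
    None a single 'all' stratum is produced.  Returns a tidy DataFrame with
    columns stratum, taxon, foo_pct, rra_pct, pi_pct, n_samples,
    n_empty_excluded.
    """
    df = _counts(m)
    if group_by is None:
        strata = {"all": df.index}
    else:
        if m.sample_meta is None:
            raise ValidationError("group_by requires sample metadata")
        strata = {str(g): idx.index
                  for g, idx in m.sample_meta.loc[df.index].groupby(group_by, sort=True)}
    rows = []
    for name, samples in strata.items():
        sub = df.loc[samples]
        nonempty, n_empty = _drop_empty(sub)
        if nonempty.shape[0] == 0:
            raise ValidationError(f"stratum {name!r}: all samples empty")
        foo = compute_foo(nonempty)
        rra = compute_rra(nonempty)
        pi = compute_prey_specific_abundance(nonempty)
        for taxon in sub.columns:
            rows.append({
                "stratum": name, "taxon": taxon,
                "foo_pct": foo[taxon], "rra_pct": rra[taxon], "pi_pct": pi[taxon],
                "n_samples": nonempty.shape[0], "n_empty_excluded": n_empty,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CostelloPoint:
    """One prey item on the Costello diagram with its qualitative labels."""

    taxon: str
    x: float  # %FOO
    y: float  # %Pi
    strategy_label: str   # specialized | generalized
    niche_label: str      # BPC-leaning | WPC-leaning
    importance_label: str  # dominant | rare


def costello_points(profile: pd.DataFrame, split_x: float = 50.0,
                    split_y: float = 50.0) -> list[CostelloPoint]:
    """Label each prey item of a (single-stratum) profile on the Costello
    diagram.

    Labels are pure functions of (x, y) = (foo_pct, pi_pct) and the splits:
    y above ``split_y`` reads as specialized feeding; the importance label
    compares the point's diagonal position (x+y)/2 with the mean split; the
    niche label leans BPC (between-phenotype) when y > x and WPC otherwise.
    Items with undefined %Pi (never occurring) are skipped.
    """
    pts = []
    for _, row in profile.iterrows():
        x, y = float(row["foo_pct"]), float(row["pi_pct"])
        if np.isnan(y):
            continue
        pts.append(CostelloPoint(
            taxon=str(row["taxon"]), x=x, y=y,
            strategy_label="specialized" if y > split_y else "generalized",
            niche_label="BPC-leaning" if y > x else "WPC-leaning",
            importance_label=("dominant" if (x + y) / 2 > (split_x + split_y) / 2
                              else "rare"),
        ))
    return pts
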