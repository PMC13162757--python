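"""Jacobs' prey selectivity index against field-survey availability.

For prey item i with diet share r_i (here the %RRA / 100 of the item) and
field availability p_i (its proportion of all individuals counted in the
reference survey):

    D_i = (r_i - p_i) / (r_i + p_i - 2 r_i p_i)

D ranges from -1 (complete avoidance: available but never eaten) through 0
(no preference) to +1 (complete preference: eaten but not recorded as
available).  The boundaries are exact: r = 0 with p > 0 gives -1, p = 0
with r > 0 gives +1.  D is undefined only at r = p = 0.

Diet families absent from the reference survey keep p = 0 rather than being
dropped, which is how the +1 boundary arises in practice (the survey's
taxonomic scope rarely covers everything metabarcoding detects).  Fish and
benthic-invertebrate references are normalized and compared separately via
the reference table's group column.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["jacobs_index", "normalize_reference", "selectivity_table", "read_reference"]


def jacobs_index(r, p):
    """Jacobs' D for diet share(s) r and availability proportion(s) p.

    Accepts scalars or arrays in [0, 1]; returns NaN where r = p = 0
    (undefined), exact +/-1 at the boundaries.
    """
    r_arr = np.asarray(r, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any((r_arr < 0) | (r_arr > 1)) or np.any((p_arr < 0) | (p_arr > 1)):
        raise ValidationError("r and p must lie in [0, 1]")
    num = r_arr - p_arr
    # den = r(1-p) + p(1-r) >= 0; zero only at (0,0) (undefined) and (1,1)
    # (indifference limit, D -> 0)
    den = r_arr + p_arr - 2.0 * r_arr * p_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den == 0.0,
                     np.where((r_arr == 0.0) & (p_arr == 0.0), np.nan, 0.0),
                     num / den)
    if np.isscalar(r) or isinstance(r, numbers.Number):
        return float(d)
    return d


def read_reference(path) -> pd.DataFrame:
    """Read a field-reference TSV: ``family<TAB>group<TAB>count``."""
    df = pd.read_csv(path, sep="\t")
    expected = {"family", "group", "count"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"{path}: reference needs columns {sorted(expected)}")
    if (df["count"].astype(float) < 0).any():
        raise ValidationError(f"{path}: negative reference counts")
    return df


def normalize_reference(ref: pd.DataFrame) -> pd.Series:
    """Family -> availability proportion p_i, normalized to sum to 1."""
    counts = ref.groupby("family")["count"].sum().astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("reference counts sum to zero")
    return counts / total


def selectivity_table(profile: pd.DataFrame, ref: pd.DataFrame,
                      use: str = "rra", synonyms: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Jacobs' D per family from a family-level diet profile and a reference.

    ``profile`` is a single-stratum tidy profile (from
    :func:`salamet.dietmetrics.diet_profile`); diet shares r_i default to
    rra_pct / 100 (``use='foo'`` switches to FOO shares for sensitivity
    analysis).  Families present in only one of diet/reference get the exact
    boundary D; families in neither are excluded.  ``synonyms`` maps
    reference family names onto diet names before matching.
    """
    if use not in ("rra", "foo"):
        raise ValidationError(f"unknown diet-share basis {use!r}")
    col = "rra_pct" if use == "rra" else "foo_pct"
    if profile["stratum"].nunique() > 1:
        raise ValidationError("selectivity_table expects a single-stratum profile")
    r = profile.set_index("taxon")[col].astype(float) / 100.0
    if use == "foo":  # FOO percentages do not sum to 100; renormalize to shares
        r = r / r.sum()
    p = normalize_reference(ref)
    if synonyms:
        p = p.rename(index=synonyms).groupby(level=0).sum()
    families = sorted(set(r.index) | set(p.index))
    r_full = r.reindex(families, fill_value=0.0)
    p_full = p.reindex(families, fill_value=0.0)
    both_zero = (r_full == 0) & (p_full == 0)
    if both_zero.all():
        raise ValidationError("no family has diet or reference presence")
    out = pd.DataFrame({
        "family": families,
        "r": r_full.to_numpy(),
        "p": p_full.to_numpy(),
        "D": jacobs_index(r_full.to_numpy(), p_full.to_numpy()),
    })
    return out.loc[~both_zero.to_numpy()].reset_index(drop=True)
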