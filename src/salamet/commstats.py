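"""Distance-based community comparison: Jaccard / Bray-Curtis, one-way
PERMANOVA, and rarefaction.

PERMANOVA partitions the sum of squared dissimilarities of N samples in a
groups (Anderson's distance-based formulation):

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a))

with significance from free permutation of the group labels and the add-one
convention p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never zero
and is bounded below by 1/(n_perm+1).

Presence/absence (frequency-of-occurrence) matrices are binarized before
Jaccard; read-abundance matrices are row-normalized to proportions before
Bray-Curtis.

Rarefaction gives the expected taxon richness of a random subsample of d
reads from a pool with per-taxon counts N_i (hypergeometric formulation):

    E[S_d] = sum_i [1 - C(N - N_i, d) / C(N, d)]

evaluated in log space for numerical stability at realistic read depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .errors import ValidationError

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "jaccard",
    "bray_curtis",
    "distance_matrix",
    "permanova",
    "rarefaction_curve",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with their sample ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        self.d = d


def jaccard(a, b) -> float:
    """Jaccard dissimilarity of two presence/absence vectors.

    d = 1 - |A & B| / |A | B|; two empty vectors give 0 by convention.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity of two non-negative abundance vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValidationError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(table: pd.DataFrame, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise distances between the rows (samples) of a taxa table.

    ``metric='jaccard'`` binarizes reads as n > 0 first; ``'braycurtis'``
    row-normalizes reads to proportions first (``'braycurtis_raw'`` skips
    the normalization).
    """
    X = table.to_numpy(dtype=float)
    if metric == "jaccard":
        D = pdist(X > 0, metric="jaccard")
    elif metric in ("braycurtis", "braycurtis_raw"):
        if metric == "braycurtis":
            totals = X.sum(axis=1, keepdims=True)
            if (totals == 0).any():
                raise ValidationError("cannot normalize all-zero sample row(s)")
            X = X / totals
        D = pdist(X, metric="braycurtis")
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(map(str, table.index)), squareform(D))


@dataclass
class PermanovaResult:
    """One-way PERMANOVA summary."""

    pseudo_F: float
    R2: float
    p_perm: float
    n_permutations: int
    group_sizes: dict[str, int]
    seed: int | None = None


def _ss_partition(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray,
                  ss_total: float) -> float:
    """SS_within for boolean group masks (groups x N), via quadratic forms."""
    ss_within = 0.0
    for g in range(masks.shape[0]):
        m = masks[g].astype(float)
        ss_within += (m @ d2 @ m) / (2.0 * sizes[g])
    return ss_within


def permanova(dm: DistanceMatrix, groups, n_perm: int = 9999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA with free label permutation.

    ``groups`` is a sequence (or id-indexed Series/dict) of group labels, one
    per sample of ``dm``; every group needs >= 2 members.  Deterministic for
    a fixed ``seed``.
    """
    if isinstance(groups, (pd.Series, dict)):
        s = pd.Series(groups)
        labels = np.asarray([s[i] for i in dm.ids])
    else:
        labels = np.asarray(list(groups))
    N = len(dm.ids)
    if len(labels) != N:
        raise ValidationError("one group label per sample required")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("need >= 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        small = uniq[sizes < 2].tolist()
        raise ValidationError(f"group(s) of size < 2: {small}")

    d2 = dm.d**2
    ss_total = d2.sum() / (2.0 * N)

    def f_stat(perm_inv: np.ndarray) -> float:
        masks = np.stack([perm_inv == g for g in range(a)])
        ss_within = _ss_partition(d2, masks, sizes, ss_total)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (N - a))

    f_obs = f_stat(inv)
    masks = np.stack([inv == g for g in range(a)])
    ss_within_obs = _ss_partition(d2, masks, sizes, ss_total)
    r2 = (ss_total - ss_within_obs) / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += f_stat(rng.permutation(inv)) >= f_obs
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm,
                           {str(u): int(s) for u, s in zip(uniq, sizes)}, seed)


def rarefaction_curve(counts, depths) -> pd.Series:
    """Expected taxon richness at each subsampling depth.

    ``counts`` are per-taxon read counts of one pooled sample; ``depths``
    must not exceed the total read count N.  Exact hypergeometric
    expectation, computed with log-gamma binomials.
    """
    c = np.asarray(counts, dtype=np.int64)
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    c = c[c > 0]
    N = int(c.sum())
    if N == 0:
        raise ValidationError("no reads in pooled sample")
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths < 1).any() or (depths > N).any():
        raise ValidationError(f"depths must lie in [1, {N}]")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(len(depths))
    for idx, d in enumerate(depths):
        with np.errstate(invalid="ignore"):
            # P(taxon i absent from a subsample of d) = C(N - N_i, d) / C(N, d)
            log_p_absent = log_comb(N - c, d) - log_comb(N, d)
        p_absent = np.where(N - c >= d, np.exp(log_p_absent), 0.0)
        out[idx] = float((1.0 - p_absent).sum())
    return pd.Series(out, index=pd.Index(depths, name="depth"))
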