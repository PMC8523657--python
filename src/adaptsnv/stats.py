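"""Ecological and inferential statistics on SNV and abundance profiles.

Thin, uniformly-shaped wrappers around scipy and scikit-bio: alpha
diversity (Shannon with natural log, Gini-Simpson), Bray-Curtis
dissimilarity, Pearson/Spearman correlation, the two-sided Wilcoxon
rank-sum test (exact for small untied samples), and PERMANOVA with a
seeded permutation p-value. Every test returns a :class:`StatResult`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import braycurtis, pdist, squareform

EXACT_WILCOXON_MAX_N = 20
DEFAULT_PERMUTATIONS = 999


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None


def _as_counts(profile) -> np.ndarray:
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if (x < 0).any():
        raise ValueError("profile counts must be >= 0")
    if x.sum() == 0:
        raise ValueError("profile has no positive count; diversity undefined")
    return x


def shannon(profile) -> float:
    """Shannon diversity H = -sum(p_i ln p_i) over the profile's proportions."""
    from skbio.diversity.alpha import shannon as _shannon

    return float(_shannon(_as_counts(profile), base=np.e))


def simpson(profile, variant: str = "gini") -> float:
    """Simpson diversity: Gini-Simpson ``1 - sum(p_i^2)`` (default) or inverse."""
    from skbio.diversity.alpha import simpson as _simpson

    x = _as_counts(profile)
    gini = float(_simpson(x))
    if variant == "gini":
        return gini
    if variant == "inverse":
        p = x / x.sum()
        return float(1.0 / np.sum(p ** 2))
    raise ValueError("variant must be 'gini' or 'inverse'")


def bray_curtis(profile_a, profile_b) -> float:
    """Bray-Curtis dissimilarity between two aligned profiles, in [0, 1]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must be aligned to the same species set")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero profiles")
    return float(braycurtis(a, b))


def correlate(x, y, method: str = "pearson") -> StatResult:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return StatResult(statistic=float(r.statistic), p_value=float(r.pvalue),
                      method=method)


def wilcoxon_rank_sum(a, b) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample is small
    (n <= 20) and tie-free, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    exact = (len(pooled) <= EXACT_WILCOXON_MAX_N
             and len(np.unique(pooled)) == len(pooled))
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return StatResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method="wilcoxon-rank-sum/"
                             + ("exact" if exact else "normal-approx"))


def distance_matrix(profiles: pd.DataFrame, metric: str = "braycurtis"
                    ) -> pd.DataFrame:
    """All-pairs distance matrix from a samples x features profile table."""
    dm = squareform(pdist(profiles.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(dm, index=profiles.index, columns=profiles.index)


def permanova(dist, grouping, n_permutations: int = DEFAULT_PERMUTATIONS,
              seed: int | None = None) -> StatResult:
    """PERMANOVA pseudo-F and permutation p-value on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``; deterministic
    for a fixed seed. Every group must have at least two members.
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova as _permanova

    if isinstance(dist, pd.DataFrame):
        ids = [str(i) for i in dist.index]
        dm = DistanceMatrix(dist.to_numpy(dtype=float), ids=ids)
    elif isinstance(dist, DistanceMatrix):
        dm = dist
    else:
        arr = np.asarray(dist, dtype=float)
        dm = DistanceMatrix(arr)
    groups = pd.Series(list(grouping))
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    res = _permanova(dm, groups.to_numpy(), permutations=n_permutations,
                     seed=seed)
    return StatResult(statistic=float(res["test statistic"]),
                      p_value=float(res["p-value"]), method="PERMANOVA",
                      n_permutations=n_permutations, seed=seed)


def snv_count_profiles(snv_tables: dict[str, list]) -> pd.DataFrame:
    """Per-sample SNV counts per species (samples x species table).

    Species are the genome ids of the calls; species absent from a sample
    get count 0 after alignment.
    """
    rows: dict[str, dict[str, int]] = {}
    for sample_id, calls in snv_tables.items():
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.genome_id] = counts.get(c.genome_id, 0) + 1
        rows[sample_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int) \
        .sort_index()
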