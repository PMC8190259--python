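"""AP-MS interactome enrichment statistics.

The workflow mirrors the standard label-free proteomics analysis of bait
pulldowns: filter flagged rows, log2-transform, require a minimum number of
valid values, impute missing values from a down-shifted narrowed normal
distribution (width 0.3, shift 1.8 SDs, estimated on the total matrix),
test each protein with an S0-moderated one-way statistic against a
permutation null (FDR 0.001, S0 = 2), Z-score the significant rows,
average technical/biological replicates per bait, cluster hierarchically
with Euclidean distance, and assign proteins to bait groups at a minimum
averaged Z-score of 0.3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "ModeratedAnovaFDR",
    "preprocess",
    "impute",
    "s0_anova_fdr",
    "zscore_cluster",
    "assign_groups",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the enrichment analysis.

    Defaults are the production settings: at least 5 of 6 valid values per
    protein, imputation width 0.3 / down-shift 1.8 (total-matrix scope),
    S0 = 2, permutation FDR threshold 0.001, Z-membership threshold 0.3.
    ``min_valid_scope`` selects whether the valid-value rule is applied over
    all samples ('total') or within at least one condition ('per_group').
    """

    min_valid: int = 5
    min_valid_scope: str = "per_group"
    impute_width: float = 0.3
    impute_shift: float = 1.8
    s0: float = 2.0
    fdr: float = 0.001
    n_permutations: int = 250
    z_threshold: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.impute_width <= 0:
            raise ValueError("imputation width must be > 0")
        if not 0 < self.fdr < 1:
            raise ValueError("FDR must be in (0, 1)")
        if self.s0 < 0:
            raise ValueError("S0 must be >= 0")
        if self.min_valid_scope not in ("total", "per_group"):
            raise ValueError("min_valid_scope must be 'total' or 'per_group'")


@dataclass
class EnrichmentResult:
    """Significance statistics, Z profiles, clusters and group memberships."""

    statistic: pd.Series
    qvalues: pd.Series
    significant: pd.Index
    z_profiles: pd.DataFrame | None = None
    cluster_labels: pd.Series | None = None
    linkage_matrix: np.ndarray | None = None
    memberships: dict[str, set[str]] = field(default_factory=dict)


def preprocess(
    matrix: pd.DataFrame,
    config: EnrichmentConfig = EnrichmentConfig(),
    groups: Sequence[str] | None = None,
    flags: pd.DataFrame | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Filter flagged rows, log2-transform, and apply the valid-value rule.

    ``flags`` may carry boolean columns ``reverse``, ``contaminant`` and
    ``identified_by_site``; any flagged row is removed. Zeros become missing
    before the log2 transform. Rows with fewer than ``config.min_valid``
    valid values (per condition when scope is 'per_group', requiring at
    least one condition to satisfy the rule) are removed.
    """
    data = matrix.copy()
    if flags is not None:
        flagged = pd.Series(False, index=data.index)
        for col in ("reverse", "contaminant", "identified_by_site"):
            if col in flags.columns:
                flagged |= flags[col].reindex(data.index, fill_value=False).astype(bool)
        data = data.loc[~flagged]
    if log_transform:
        if (data.fillna(0) < 0).any().any():
            raise ValueError("raw intensities must be >= 0")
        data = data.where(data > 0)
        data = np.log2(data)
    if config.min_valid_scope == "per_group" and groups is not None:
        groups = np.asarray(groups)
        ok = pd.Series(False, index=data.index)
        for g in np.unique(groups):
            cols = data.columns[groups == g]
            ok |= data[cols].notna().sum(axis=1) >= min(config.min_valid, len(cols))
        data = data.loc[ok]
    else:
        data = data.loc[data.notna().sum(axis=1) >= config.min_valid]
    if data.empty:
        raise ValueError("no rows survive preprocessing")
    return data


def impute(
    matrix: pd.DataFrame, config: EnrichmentConfig = EnrichmentConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing values from a down-shifted normal (total-matrix scope).

    Draws come from Normal(mu - shift * sd, (width * sd)^2) where mu and sd
    are the mean and SD of all observed values — the standard
    below-detection-limit assumption. Returns the complete matrix and a
    boolean mask of imputed cells. Observed entries are never altered.
    """
    observed = matrix.to_numpy(dtype=float)
    obs_mask = np.isfinite(observed)
    if not obs_mask.any():
        raise ValueError("matrix has no observed values")
    mask = ~obs_mask
    if not mask.any():
        return matrix.copy(), pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    mu = observed[obs_mask].mean()
    sd = observed[obs_mask].std(ddof=1)
    rng = np.random.default_rng(config.seed)
    draws = rng.normal(mu - config.impute_shift * sd, config.impute_width * sd, size=int(mask.sum()))
    filled = observed.copy()
    filled[mask] = draws
    return (
        pd.DataFrame(filled, index=matrix.index, columns=matrix.columns),
        pd.DataFrame(mask, index=matrix.index, columns=matrix.columns),
    )


def _moderated_statistic(data: np.ndarray, groups: np.ndarray, s0: float) -> np.ndarray:
    """S0-moderated one-way statistic per row (SAM convention).

    stat = sqrt(sum_g n_g (xbar_g - xbar)^2) / (s_pooled + s0). At s0 = 0
    this is a strictly increasing transform of the classical one-way F
    (F = stat^2 / (k - 1)), so rankings coincide.
    """
    uniq = np.unique(groups)
    n, k = data.shape[0], len(uniq)
    grand = data.mean(axis=1)
    between = np.zeros(n)
    ss_within = np.zeros(n)
    df_within = 0
    for g in uniq:
        cols = groups == g
        ng = int(cols.sum())
        gm = data[:, cols].mean(axis=1)
        between += ng * (gm - grand) ** 2
        ss_within += ((data[:, cols] - gm[:, None]) ** 2).sum(axis=1)
        df_within += ng - 1
    s_pooled = np.sqrt(ss_within / max(df_within, 1))
    return np.sqrt(between) / (s_pooled * np.sqrt(k - 1) + s0)


class ModeratedAnovaFDR(BaseEstimator):
    """S0-moderated one-way test with permutation FDR (sklearn-style).

    Parameters follow :class:`EnrichmentConfig`. :meth:`fit` takes the
    complete (imputed) matrix X of shape (n_proteins, n_samples) and the
    group label per sample, and sets ``statistic_``, ``qvalues_`` and
    ``significant_`` (boolean mask at the configured FDR).

    The null distribution is built by permuting the sample group labels
    ``n_permutations`` times; the q-value of a protein with statistic s is
    the estimated false-discovery proportion of the threshold s
    (mean permuted exceedances over observed exceedances), with
    monotonicity enforced from the top of the ranking down.
    """

    def __init__(self, s0: float = 2.0, fdr: float = 0.001, n_permutations: int = 250, seed: int = 0):
        self.s0 = s0
        self.fdr = fdr
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, X, y) -> "ModeratedAnovaFDR":
        data = np.asarray(X, dtype=float)
        groups = np.asarray(y)
        uniq, counts = np.unique(groups, return_counts=True)
        if len(uniq) < 2 or counts.min() < 2:
            raise ValueError("need >= 2 groups with >= 2 replicates each")
        obs = _moderated_statistic(data, groups, self.s0)
        rng = np.random.default_rng(self.seed)
        n = data.shape[0]
        perm_stats = np.empty((self.n_permutations, n))
        for p in range(self.n_permutations):
            perm = rng.permutation(groups)
            perm_stats[p] = _moderated_statistic(data, perm, self.s0)
        perm_flat = np.sort(perm_stats.ravel())
        order = np.argsort(-obs, kind="stable")
        q = np.empty(n)
        for rank, i in enumerate(order, start=1):
            exceed = perm_flat.size - np.searchsorted(perm_flat, obs[i], side="left")
            expected_fp = exceed / self.n_permutations
            q[i] = min(expected_fp / rank, 1.0)
        # enforce q non-decreasing along decreasing statistic
        q[order] = np.maximum.accumulate(q[order])
        self.statistic_ = obs
        self.qvalues_ = q
        self.significant_ = q <= self.fdr
        return self

    def fit_predict(self, X, y) -> np.ndarray:
        return self.fit(X, y).significant_


def s0_anova_fdr(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> EnrichmentResult:
    """Per-protein moderated statistic, permutation q-values and significance."""
    min_resolution = 1.0 / max(config.n_permutations, 1)
    if min_resolution > config.fdr * matrix.shape[0]:
        import warnings

        warnings.warn(
            "permutation count may be too low for the requested FDR resolution",
            stacklevel=2,
        )
    est = ModeratedAnovaFDR(
        s0=config.s0, fdr=config.fdr, n_permutations=config.n_permutations, seed=config.seed
    ).fit(matrix.to_numpy(dtype=float), np.asarray(groups))
    stat = pd.Series(est.statistic_, index=matrix.index, name="statistic")
    q = pd.Series(est.qvalues_, index=matrix.index, name="q")
    return EnrichmentResult(
        statistic=stat, qvalues=q, significant=matrix.index[est.significant_]
    )


def zscore_cluster(
    matrix: pd.DataFrame,
    result: EnrichmentResult,
    groups: Sequence[str],
    config: EnrichmentConfig = EnrichmentConfig(),
    n_clusters: int | None = None,
    method: str = "average",
) -> EnrichmentResult:
    """Z-score significant rows, average replicates per bait, cluster.

    Each significant row is standardized across samples (mean 0, SD 1), the
    standardized values are averaged over the replicate columns of each
    bait/condition, and the averaged profiles are clustered agglomeratively
    with Euclidean distance (average linkage by default).
    """
    if len(result.significant) == 0:
        raise ValueError("significant set is empty")
    groups = np.asarray(groups)
    sub = matrix.loc[result.significant]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    profiles = pd.DataFrame(
        {g: z.loc[:, groups == g].mean(axis=1) for g in pd.unique(groups)}
    )
    result.z_profiles = profiles
    if len(profiles) == 1:
        result.cluster_labels = pd.Series([0], index=profiles.index)
        return result
    ordered = profiles.sort_index()
    lk = linkage(ordered.to_numpy(), method=method, metric="euclidean")
    k = n_clusters if n_clusters is not None else max(2, min(6, len(profiles) // 10 or 2))
    flat = fcluster(lk, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=ordered.index).reindex(profiles.index)
    result.cluster_labels = labels
    result.linkage_matrix = lk
    return result


def assign_groups(
    result: EnrichmentResult, threshold: float = 0.3
) -> dict[str, set[str]]:
    """Bait-group membership: averaged Z >= threshold; plus Venn-style counts.

    Stores and returns ``{bait: set of protein ids}``; intersection counts
    for Venn reporting are available from the sets.
    """
    if result.z_profiles is None:
        raise ValueError("run zscore_cluster first")
    memberships: dict[str, set[str]] = {}
    for bait in result.z_profiles.columns:
        members = result.z_profiles.index[result.z_profiles[bait] >= threshold]
        memberships[str(bait)] = set(members)
    result.memberships = memberships
    return memberships
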