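"""Beta-diversity and metabolic-profile distance comparisons.

Microbiome dissimilarity uses Bray-Curtis on relative abundances at genus
level (CLR values can be negative and are invalid for Bray-Curtis);
metabolome distance is Euclidean on the processed log-z panel. Distances
are tagged within-pair (one per complete twin pair) or outside-pair
(individual vs every individual except the own co-twin), and compared with
a Shapiro-Wilk-gated two-sample test: Student's t when both groups pass
normality at p > 0.05, otherwise Wilcoxon rank-sum.

The within/outside comparison treats the pairwise distances as independent
observations, which they are not (each sample contributes many outside-pair
distances); the resulting p-values should be read as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.spatial.distance import pdist, squareform

__all__ = ["bray_curtis", "euclidean", "DistanceSet", "build_distance_set",
           "compare_distance_groups", "GroupComparison"]


def bray_curtis(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors.

    Computed on relative abundances (each vector closed to sum 1), so a
    common positive rescaling of either sample does not change the value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must share a feature set")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero sample has no composition")
    return float(_braycurtis(a / a.sum(), b / b.sum()))


def euclidean(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Euclidean distance between two metabolic profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share a feature set")
    return float(np.linalg.norm(a - b))


@dataclass
class DistanceSet:
    """Long-format pairwise distances with group tags.

    ``table`` columns: id_a, id_b, distance, relation (within_pair /
    outside_pair), zygosity (MZ / DZ / cross — the zygosity of the samples'
    pairs, 'cross' when they differ).
    """

    metric: str
    table: pd.DataFrame

    def subset(self, relation: str | None = None,
               zygosity: str | None = None) -> np.ndarray:
        t = self.table
        if relation is not None:
            t = t[t["relation"] == relation]
        if zygosity is not None:
            t = t[t["zygosity"] == zygosity]
        return t["distance"].to_numpy()


def build_distance_set(features: pd.DataFrame, metadata: pd.DataFrame,
                       metric: str = "braycurtis",
                       subsample_outside: int | None = None,
                       seed: int = 0) -> DistanceSet:
    """All pairwise distances among samples, tagged by twin-pair relation.

    ``metric`` is 'braycurtis' (counts are closed to relative abundances
    first) or 'euclidean'. Outside-pair distances exclude each sample's own
    co-twin and grow as O(n^2); ``subsample_outside`` caps them (fixed
    ``seed``), off by default.
    """
    meta = metadata.loc[features.index]
    X = features.to_numpy(dtype=float)
    if metric == "braycurtis":
        if (X < 0).any():
            raise ValueError("Bray-Curtis requires nonnegative abundances")
        rowsum = X.sum(axis=1, keepdims=True)
        if (rowsum == 0).any():
            raise ValueError("all-zero sample has no composition")
        X = X / rowsum
        dmat = squareform(pdist(X, metric="braycurtis"))
    elif metric == "euclidean":
        dmat = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")

    ids = features.index.to_numpy()
    pair = meta["pair_id"].to_numpy()
    zyg = meta["zygosity"].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    same_pair = pair[iu] == pair[ju]
    zyg_tag = np.where(zyg[iu] == zyg[ju], zyg[iu], "cross")
    table = pd.DataFrame({
        "id_a": ids[iu], "id_b": ids[ju],
        "distance": dmat[iu, ju],
        "relation": np.where(same_pair, "within_pair", "outside_pair"),
        "zygosity": zyg_tag,
    })
    if subsample_outside is not None:
        outside = table[table["relation"] == "outside_pair"]
        if len(outside) > subsample_outside:
            rng = np.random.default_rng(seed)
            keep = rng.choice(outside.index, subsample_outside, replace=False)
            table = pd.concat([table[table["relation"] == "within_pair"],
                               table.loc[np.sort(keep)]]).sort_index()
    return DistanceSet(metric=metric, table=table.reset_index(drop=True))


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test: str                  # "t" or "wilcoxon_rank_sum"
    shapiro_p: tuple[float, float]
    means: tuple[float, float]


def compare_distance_groups(group_a: np.ndarray, group_b: np.ndarray,
                            normality_alpha: float = 0.05) -> GroupComparison:
    """Shapiro-Wilk-gated two-sample comparison of two distance groups.

    Both groups are tested for normality; if both pass (Shapiro-Wilk
    p > ``normality_alpha``) a two-sided Student's t-test is used,
    otherwise the Wilcoxon rank-sum (Mann-Whitney) test. Groups need at
    least 3 values each (Shapiro-Wilk is undefined below that).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 distances")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    if sw_a > normality_alpha and sw_b > normality_alpha:
        res = stats.ttest_ind(a, b)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon_rank_sum"
    return GroupComparison(float(res.statistic), float(res.pvalue), test,
                           (float(sw_a), float(sw_b)),
                           (float(a.mean()), float(b.mean())))
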