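"""Pairwise screening layers, their overlaps, and the consistency ledger.

The analysis is organized as a pyramid of five comparisons:

* layer a — MZ pairs discordant for MD, paired signed-rank tests;
* layer b — DZ discordant pairs, paired signed-rank tests;
* layer c — all discordant pairs combined;
* layers d/e — individual-level mixed-model comparisons (see
  :mod:`cotwin.lmm`): healthy co-twins vs all MD twins (d) and all healthy
  vs all MD twins (e).

Within layers a-c each feature is tested with a two-sided Wilcoxon
signed-rank test on within-pair differences (MD minus healthy co-twin) at
a raw significance level (no multiple-testing correction in these layers
by design — correction is applied in the mixed-model layers). A feature's
*consistency* is whether it was significant in every layer where it was
tested; consistently significant features are the candidate biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ranktests import signed_rank_test

logger = logging.getLogger(__name__)

__all__ = ["LayerSpec", "pairwise_layer", "layer_overlaps", "build_ledger",
           "PAIRWISE_LAYERS"]

#: zygosity restriction of each pairwise layer
PAIRWISE_LAYERS = {"a": "MZ", "b": "DZ", "c": None}


@dataclass
class LayerSpec:
    """One pyramid layer: 'a'/'b'/'c' (pairwise) or 'd'/'e' (mixed model),
    the feature kind it runs on, and its significance level (0.05 default;
    0.1 is the convention for pathways in the MZ layer)."""

    layer: str
    feature_kind: str = "genus"
    alpha: float = 0.05

    def __post_init__(self):
        if self.layer not in "abcde":
            raise ValueError("layer must be one of a-e")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _discordant_differences(features: pd.DataFrame, metadata: pd.DataFrame,
                            zygosity: str | None) -> pd.DataFrame:
    """Within-pair differences (MD minus healthy) over discordant pairs."""
    meta = metadata.loc[features.index]
    if zygosity is not None:
        meta = meta[meta["zygosity"] == zygosity]
    n_md = meta.groupby("pair_id")["md"].transform("sum")
    n_mem = meta.groupby("pair_id")["pair_id"].transform("size")
    disc = meta[(n_md == 1) & (n_mem == 2)]
    md_rows = disc[disc["md"] == 1].sort_values("pair_id")
    healthy_rows = disc[disc["md"] == 0].sort_values("pair_id")
    diffs = (features.loc[md_rows.index].to_numpy(dtype=float)
             - features.loc[healthy_rows.index].to_numpy(dtype=float))
    return pd.DataFrame(diffs, index=md_rows["pair_id"].to_numpy(),
                        columns=features.columns)


def pairwise_layer(features: pd.DataFrame, metadata: pd.DataFrame,
                   spec: LayerSpec | str = "a",
                   alpha: float | None = None) -> pd.DataFrame:
    """Paired signed-rank screen of one pairwise layer.

    ``features`` must be on an unconstrained scale (CLR genera, log-z
    metabolites, or pathway abundances). Returns a DataFrame indexed by
    feature with columns statistic, p, n_pairs, direction (sign of the
    median within-pair difference), significant, layer.
    """
    if isinstance(spec, str):
        spec = LayerSpec(layer=spec)
    if alpha is not None:
        spec = LayerSpec(spec.layer, spec.feature_kind, alpha)
    if spec.layer not in PAIRWISE_LAYERS:
        raise ValueError(f"layer {spec.layer!r} is not a pairwise layer; "
                         "use cotwin.lmm.screen_features for d/e")
    diffs = _discordant_differences(features, metadata, PAIRWISE_LAYERS[spec.layer])
    if len(diffs) < 6:
        logger.warning("layer %s has only %d discordant pairs; the exact "
                       "test is computed but power is minimal",
                       spec.layer, len(diffs))
    rows = []
    for name in diffs.columns:
        res = signed_rank_test(diffs[name].to_numpy())
        rows.append({"feature": name, "statistic": res.statistic,
                     "p": res.p_value, "n_pairs": len(diffs),
                     "direction": res.direction,
                     "significant": res.p_value < spec.alpha})
    out = pd.DataFrame(rows).set_index("feature")
    out["layer"] = spec.layer
    out.attrs["spec"] = spec
    return out


def layer_overlaps(results: dict[str, pd.DataFrame]) -> dict[tuple[str, ...], set]:
    """Significant-feature sets per layer and all pairwise/higher-order
    intersections (the Venn counts)."""
    sig = {layer: set(df.index[df["significant"]]) for layer, df in results.items()}
    out: dict[tuple[str, ...], set] = {(layer,): s for layer, s in sig.items()}
    layers = sorted(sig)
    for k in range(2, len(layers) + 1):
        for combo in combinations(layers, k):
            out[combo] = set.intersection(*(sig[c] for c in combo))
    return out


def build_ledger(pairwise_results: dict[str, pd.DataFrame],
                 lmm_results: dict[str, pd.DataFrame] | None = None,
                 lmm_tick_alpha: float = 0.05,
                 family: dict[str, str] | None = None) -> pd.DataFrame:
    """Feature x layer significance matrix with a consistency flag.

    Pairwise layers tick at their own alpha. Mixed-model layers tick at a
    raw Wald ``p < lmm_tick_alpha`` (FDR-adjusted significance is carried
    alongside as ``{layer}_fdr``). A feature is *consistent* when ticked in
    every layer where it was tested; only features ticked somewhere are
    kept. ``family`` optionally annotates features (e.g. taxonomic family).
    """
    lmm_results = lmm_results or {}
    tested: dict[str, pd.Index] = {}
    ticks: dict[str, pd.Series] = {}
    signs: dict[str, pd.Series] = {}
    for layer, df in sorted(pairwise_results.items()):
        tested[layer] = df.index
        ticks[layer] = df["significant"]
        signs[layer] = df["direction"]
    fdr_cols = {}
    for layer, df in sorted(lmm_results.items()):
        tested[layer] = df.index
        ticks[layer] = df["p"] < lmm_tick_alpha
        signs[layer] = df["direction"]
        fdr_cols[layer] = df["significant"]

    all_feats = pd.Index(sorted(set().union(*(ix for ix in tested.values()))))
    ledger = pd.DataFrame(index=all_feats)
    for layer in sorted(tested):
        ledger[f"layer_{layer}"] = ticks[layer].reindex(all_feats)
        ledger[f"sign_{layer}"] = signs[layer].reindex(all_feats)
    for layer, flags in fdr_cols.items():
        ledger[f"layer_{layer}_fdr"] = flags.reindex(all_feats)

    tick_mat = ledger[[f"layer_{l}" for l in sorted(tested)]]
    ledger["n_ticks"] = tick_mat.sum(axis=1, skipna=True).astype(int)
    ledger["consistent"] = tick_mat.apply(
        lambda row: bool(row.dropna().all()) and row.notna().any(), axis=1)
    if family is not None:
        ledger["family"] = pd.Series(family).reindex(all_feats)
    ledger = ledger[ledger["n_ticks"] > 0]
    return ledger
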