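"""Spearman correlation network between differential genera and
differential predicted pathways.

All genus x pathway pairs among the differential features are rank
correlated in the chosen sample population; Benjamini-Hochberg adjustment
runs across all tested pairs, and an edge is retained when both
``|rho| > rho_cutoff`` (0.2) and ``q < q_cutoff`` (0.05). Genus values are
taken on the CLR scale and pathway values on their abundance scale —
Spearman is rank-based, so any monotone rescaling leaves the network
unchanged. The edge list imports directly into Cytoscape.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["spearman", "build_network", "degree_summary", "to_networkx"]


def spearman(x: np.ndarray, y: np.ndarray,
             exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (tie-corrected by
    construction). The p-value uses the t approximation, except for
    n < ``exact_below`` where an exact permutation distribution over all
    n! rank orderings is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    if n < exact_below:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        from itertools import permutations
        null = np.array([np.corrcoef(rx, np.asarray(perm))[0, 1]
                         for perm in permutations(ry)])
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(genera: pd.DataFrame, pathways: pd.DataFrame,
                  genus_ids=None, pathway_ids=None,
                  population: pd.Index | None = None,
                  rho_cutoff: float = 0.2, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Bipartite genus-pathway correlation edge list.

    ``genus_ids``/``pathway_ids`` restrict to the differential features
    from the upstream screens (default: all columns); ``population``
    restricts samples (e.g. the healthy-co-twin vs MD-twin subset). BH
    q-values are computed across all tested pairs. Returns the *retained*
    edges (source, target, rho, p, q, sign) sorted by |rho|; the full
    tested table is attached as ``attrs['all_pairs']``.
    """
    genus_ids = list(genera.columns if genus_ids is None else genus_ids)
    pathway_ids = list(pathways.columns if pathway_ids is None else pathway_ids)
    cols = ["source", "target", "rho", "p", "q", "sign"]
    if not genus_ids or not pathway_ids:
        logger.warning("empty differential feature set: network has no edges")
        return pd.DataFrame(columns=cols)
    idx = genera.index if population is None else pd.Index(population)
    G = genera.loc[idx, genus_ids].to_numpy(dtype=float)
    P = pathways.loc[idx, pathway_ids].to_numpy(dtype=float)
    n = len(idx)
    if n < 4:
        raise ValueError("need at least 4 samples to correlate")

    # rank-transform columns once; Pearson on ranks == tie-corrected Spearman
    Gr = np.apply_along_axis(stats.rankdata, 0, G)
    Pr = np.apply_along_axis(stats.rankdata, 0, P)
    Gs = (Gr - Gr.mean(axis=0)) / Gr.std(axis=0)
    Ps = (Pr - Pr.mean(axis=0)) / Pr.std(axis=0)
    rho = (Gs.T @ Ps) / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)

    gi, pi = np.meshgrid(range(len(genus_ids)), range(len(pathway_ids)),
                         indexing="ij")
    table = pd.DataFrame({
        "source": np.asarray(genus_ids, dtype=object)[gi.ravel()],
        "target": np.asarray(pathway_ids, dtype=object)[pi.ravel()],
        "rho": rho.ravel(), "p": p.ravel(),
    })
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    table["sign"] = np.where(table["rho"] >= 0, "+", "-")
    edges = table[(table["rho"].abs() > rho_cutoff) & (table["q"] < q_cutoff)]
    edges = edges.reindex(edges["rho"].abs().sort_values(ascending=False).index)
    edges = edges.reset_index(drop=True)
    edges.attrs["all_pairs"] = table
    edges.attrs["n_samples"] = n
    return edges


def degree_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Node degree table (node, kind, degree) for the retained edges."""
    rows = []
    for kind, col in (("genus", "source"), ("pathway", "target")):
        for node, deg in edges[col].value_counts().items():
            rows.append({"node": node, "kind": kind, "degree": int(deg)})
    return pd.DataFrame(rows, columns=["node", "kind", "degree"])


def to_networkx(edges: pd.DataFrame):
    """Bipartite networkx graph of the retained edges (for GraphML export)."""
    import networkx as nx
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_node(row["source"], kind="genus", bipartite=0)
        g.add_node(row["target"], kind="pathway", bipartite=1)
        g.add_edge(row["source"], row["target"], rho=float(row["rho"]),
                   q=float(row["q"]), sign=row["sign"])
    return g
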