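"""Pair-level view of a twin cohort: classification, prevalence,
proband-wise concordance, and zygosity association tests.

A twin pair is *discordant* when exactly one member carries the MD
diagnosis, *concordant-affected* when both do, and *concordant-healthy*
when neither does. Proband-wise concordance — the probability that the
co-twin of an affected individual is also affected — is 2C/(2C + D) with C
concordant-affected and D discordant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["classify_pairs", "pair_counts", "prevalence",
           "proband_concordance", "zygosity_association_tests",
           "cohort_summary"]

CLASSES = ("discordant", "concordant_affected", "concordant_healthy")


def classify_pairs(metadata: pd.DataFrame) -> pd.DataFrame:
    """Classify every complete pair by its members' MD flags.

    Pairs without exactly two members (or with missing MD status) are
    dropped and logged. Returns a DataFrame indexed by pair_id with columns
    ``zygosity`` and ``pair_class``.
    """
    rows = []
    dropped = []
    for pid, grp in metadata.groupby("pair_id", sort=False):
        if len(grp) != 2 or grp["md"].isna().any():
            dropped.append(pid)
            continue
        n_md = int(grp["md"].sum())
        cls = {0: "concordant_healthy", 1: "discordant",
               2: "concordant_affected"}[n_md]
        rows.append({"pair_id": pid, "zygosity": grp["zygosity"].iloc[0],
                     "pair_class": cls})
    if dropped:
        logger.warning("dropped %d incomplete pairs: %s", len(dropped), dropped)
    out = pd.DataFrame(rows).set_index("pair_id")
    out.attrs["dropped_pairs"] = dropped
    return out


def pair_counts(classification: pd.DataFrame) -> pd.DataFrame:
    """Zygosity x class count table (rows MZ/DZ plus ``All``)."""
    tab = (classification.groupby(["zygosity", "pair_class"]).size()
           .unstack(fill_value=0).reindex(index=["MZ", "DZ"], fill_value=0)
           .reindex(columns=list(CLASSES), fill_value=0))
    tab.loc["All"] = tab.sum(axis=0)
    tab["total_pairs"] = tab.sum(axis=1)
    return tab


def prevalence(metadata: pd.DataFrame, zygosity: str | None = None) -> float:
    """Fraction of affected individuals, optionally within one zygosity."""
    sub = metadata if zygosity is None else metadata[metadata["zygosity"] == zygosity]
    if len(sub) == 0:
        raise ValueError(f"no individuals with zygosity {zygosity!r}")
    return float(sub["md"].mean())


def proband_concordance(n_concordant_affected: int, n_discordant: int) -> float:
    """Proband-wise concordance 2C/(2C + D)."""
    denom = 2 * n_concordant_affected + n_discordant
    if denom == 0:
        raise ValueError("no affected individuals: concordance undefined")
    return 2 * n_concordant_affected / denom


@dataclass
class AssociationTest:
    name: str
    table: pd.DataFrame
    statistic: float
    p_value: float
    method: str


def _test_2x2(name: str, table: pd.DataFrame, correction: bool) -> AssociationTest:
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError(f"{name}: degenerate table with an all-zero margin")
    expected = stats.contingency.expected_freq(arr)
    if (expected < 1).any():
        logger.warning("%s: expected cell < 1, using Fisher's exact test", name)
        stat, p = stats.fisher_exact(arr)
        return AssociationTest(name, table, float(stat), float(p), "fisher")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    method = "chi2_yates" if correction else "chi2"
    return AssociationTest(name, table, float(stat), float(p), method)


def zygosity_association_tests(metadata: pd.DataFrame,
                               classification: pd.DataFrame | None = None,
                               correction: bool = True) -> list[AssociationTest]:
    """The four 2x2 contingency comparisons of zygosity with phenotype.

    1. zygosity x MD status over individuals;
    2. zygosity x pair concordance over pairs;
    3. zygosity x pair concordance among MD-diagnosed individuals;
    4. zygosity x MD status among individuals from concordant pairs.

    Pearson chi-square, with Yates continuity correction by default
    (``correction=False`` gives the uncorrected statistic); Fisher's exact
    test is substituted when an expected cell drops below 1. Each result
    carries the table it was built from.
    """
    if classification is None:
        classification = classify_pairs(metadata)
    meta = metadata.join(classification["pair_class"], on="pair_id")

    def xtab(rows, cols):
        return (pd.crosstab(rows, cols).reindex(index=["MZ", "DZ"])
                .fillna(0).astype(int))

    t1 = xtab(meta["zygosity"], meta["md"])
    pairs = classification.assign(
        concordant=classification["pair_class"] != "discordant")
    t2 = xtab(pairs["zygosity"], pairs["concordant"])
    md_ind = meta[meta["md"] == 1]
    t3 = xtab(md_ind["zygosity"], md_ind["pair_class"] != "discordant")
    conc_ind = meta[meta["pair_class"] != "discordant"]
    t4 = xtab(conc_ind["zygosity"], conc_ind["md"])

    return [
        _test_2x2("zygosity_vs_md_individuals", t1, correction),
        _test_2x2("zygosity_vs_concordance_pairs", t2, correction),
        _test_2x2("zygosity_vs_concordance_md_individuals", t3, correction),
        _test_2x2("zygosity_vs_md_concordant_individuals", t4, correction),
    ]


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Cohort-characteristics block: pair counts, prevalences, concordances."""
    classification = classify_pairs(metadata)
    counts = pair_counts(classification)
    out = {"pair_counts": counts, "n_individuals": int(2 * counts.loc["All", "total_pairs"])}
    for zyg in ("MZ", "DZ"):
        C = int(counts.loc[zyg, "concordant_affected"])
        D = int(counts.loc[zyg, "discordant"])
        out[f"prevalence_{zyg.lower()}"] = prevalence(metadata, zyg)
        out[f"proband_concordance_{zyg.lower()}"] = (
            proband_concordance(C, D) if 2 * C + D > 0 else float("nan"))
    out["prevalence_all"] = prevalence(metadata)
    return out
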