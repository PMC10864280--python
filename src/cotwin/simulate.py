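"""Synthetic twin-cohort generator.

Produces MZ/DZ twin cohorts with the statistical structure the co-twin
analysis assumes, together with a ground-truth manifest, so every
downstream stage can be exercised and scored offline:

* binary disease (MD) status from a liability-threshold model — each pair
  draws a bivariate standard-normal liability with zygosity-specific
  correlation, and MD = liability above the quantile set by prevalence, so
  MZ pairs are more phenotypically concordant than DZ pairs;
* genus counts from a log-normal-multinomial model with a pair-shared
  random effect on the latent log-abundance scale whose variance differs
  by zygosity (MZ pairs more similar than DZ), spiked disease effects on a
  chosen set of genera, and multinomial sampling at a fixed depth;
* a pair-correlated metabolite panel with spiked effects and
  missing-at-random masking;
* predicted-pathway abundances as noisy linear combinations of genus CLR
  values, so known genus-pathway correlations exist for the network stage;
* confounders (age, sex, BMI, antibiotics, vegetable/fruit intake) with
  twin-pair sharing and an optional confounder-to-feature leakage switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .io import (read_feature_table, read_metadata, write_feature_table,
                 write_metadata)
from .preprocess import clr_transform

__all__ = [
    "GroundTruth", "TwinCohort", "simulate_phenotypes", "simulate_confounders",
    "simulate_counts", "simulate_metabolites", "simulate_pathways",
    "make_ground_truth", "simulate_cohort",
]


@dataclass
class GroundTruth:
    """Which features carry a true disease effect, and how pathways load on
    genera. ``affected_genera`` / ``affected_metabolites`` map feature ID to
    the signed effect applied; ``pathway_loadings`` is pathway x genus."""

    affected_genera: dict[str, float] = field(default_factory=dict)
    affected_metabolites: dict[str, float] = field(default_factory=dict)
    pathway_loadings: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "affected_genera": self.affected_genera,
            "affected_metabolites": self.affected_metabolites,
            "pathway_loadings": {
                "index": self.pathway_loadings.index.tolist(),
                "columns": self.pathway_loadings.columns.tolist(),
                "values": self.pathway_loadings.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        pl = raw["pathway_loadings"]
        return cls(
            affected_genera=raw["affected_genera"],
            affected_metabolites=raw["affected_metabolites"],
            pathway_loadings=pd.DataFrame(
                np.asarray(pl["values"], dtype=float),
                index=pl["index"], columns=pl["columns"]),
        )


@dataclass
class TwinCohort:
    """Aligned metadata and feature tables keyed by sample ID."""

    metadata: pd.DataFrame
    counts: pd.DataFrame
    metabolites: pd.DataFrame
    pathways: pd.DataFrame
    truth: GroundTruth | None = None
    config: SimConfig | None = None

    def __post_init__(self):
        idx = self.metadata.index
        for name in ("counts", "metabolites", "pathways"):
            tab = getattr(self, name)
            if not tab.index.equals(idx):
                raise ValueError(f"{name} sample IDs do not match metadata")

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_metadata(self.metadata, path / "metadata.tsv")
        write_feature_table(self.counts, path / "counts.tsv")
        write_feature_table(self.metabolites, path / "metabolites.tsv")
        write_feature_table(self.pathways, path / "pathways.tsv")
        if self.truth is not None:
            self.truth.to_json(path / "truth.json")
        if self.config is not None:
            self.config.to_yaml(path / "sim_config.yaml")

    @classmethod
    def from_dir(cls, path: str | Path) -> "TwinCohort":
        path = Path(path)
        truth = None
        if (path / "truth.json").exists():
            truth = GroundTruth.from_json(path / "truth.json")
        counts = read_feature_table(path / "counts.tsv")
        return cls(
            metadata=read_metadata(path / "metadata.tsv"),
            counts=counts.astype(int),
            metabolites=read_feature_table(path / "metabolites.tsv"),
            pathways=read_feature_table(path / "pathways.tsv"),
            truth=truth,
        )


# ---------------------------------------------------------------------------

def simulate_phenotypes(config: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-individual MD status plus pair/zygosity labels.

    Each pair draws a bivariate standard-normal liability with correlation
    ``liability_corr_mz`` (MZ) or ``liability_corr_dz`` (DZ); MD is liability
    above ``Phi^-1(1 - prevalence)``. Expected proband-wise concordance is
    monotone increasing in the liability correlation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    thresh = stats.norm.ppf(1.0 - config.prevalence)

    rows = []
    pair_no = 0
    for zyg, n_pairs, r in (("MZ", config.n_mz_pairs, config.liability_corr_mz),
                            ("DZ", config.n_dz_pairs, config.liability_corr_dz)):
        shared = rng.standard_normal(n_pairs)
        indiv = rng.standard_normal((n_pairs, 2))
        # L = sqrt(r)*shared + sqrt(1-r)*indiv gives corr(L1, L2) = r
        liab = (np.sqrt(r) * shared[:, None]
                + np.sqrt(1.0 - r) * indiv)
        md = liab > thresh
        for j in range(n_pairs):
            pair_no += 1
            pid = f"P{pair_no:04d}"
            for k in range(2):
                rows.append({"sample_id": f"{pid}_{k + 1}", "pair_id": pid,
                             "zygosity": zyg, "md": int(md[j, k])})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_confounders(config: SimConfig, phenotypes: pd.DataFrame,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Append age, sex, BMI, antibiotics, vegetable and fruit intake.

    Age and sex are pair-shared (twin pairs are born together and the cohort
    is same-sex); BMI and dietary intake mix a pair-shared and an individual
    component; antibiotics use is individual. ``bmi_md_shift`` adds an
    MD-linked BMI shift so that, with ``confounder_leakage``, covariate
    adjustment in the mixed model can be exercised.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    meta = phenotypes.copy()
    pairs = meta["pair_id"].unique()
    npairs = len(pairs)

    age_pair = np.clip(rng.normal(64.9, 7.7, npairs), 18, 103)
    sex_pair = np.where(rng.random(npairs) < 0.968, "F", "M")
    bmi_shared = rng.normal(0.0, 3.3, npairs)
    veg_shared = rng.normal(0.0, 0.7, npairs)
    fruit_shared = rng.normal(0.0, 0.7, npairs)
    pair_pos = {p: i for i, p in enumerate(pairs)}
    ix = meta["pair_id"].map(pair_pos).to_numpy()

    n = len(meta)
    meta["age"] = np.round(age_pair[ix], 1)
    meta["sex"] = sex_pair[ix]
    bmi = 26.3 + bmi_shared[ix] + rng.normal(0.0, 3.3, n)
    bmi = bmi + config.bmi_md_shift * meta["md"].to_numpy()
    meta["bmi"] = np.round(np.clip(bmi, 15, None), 2)
    meta["antibiotics"] = (rng.random(n) < 0.08).astype(int)
    meta["veg"] = np.round(np.clip(
        2.5 + veg_shared[ix] + rng.normal(0.0, 0.7, n), 0, None), 2)
    meta["fruit"] = np.round(np.clip(
        2.0 + fruit_shared[ix] + rng.normal(0.0, 0.7, n), 0, None), 2)
    return meta


def make_ground_truth(config: SimConfig,
                      rng: np.random.Generator | None = None) -> GroundTruth:
    """Choose affected features and a sparse pathway-loading matrix.

    Affected genera/metabolites get alternating-sign effects of the
    configured magnitude. Each affected genus is guaranteed one dedicated
    pathway with loading 1.0 (so network recovery has a known target);
    remaining pathways load on two random genera with weights in
    +-[0.5, 1.5].
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    genera = [f"g{i:03d}" for i in range(config.n_genera)]
    metabs = [f"m{i:03d}" for i in range(config.n_metabolites)]
    pathways = [f"ko{i:03d}" for i in range(config.n_pathways)]

    aff_g = rng.choice(config.n_genera, config.n_affected_genera, replace=False)
    aff_m = rng.choice(config.n_metabolites, config.n_affected_metabolites,
                       replace=False)
    affected_genera = {genera[g]: config.effect_size_genus * (1 if k % 2 == 0 else -1)
                       for k, g in enumerate(np.sort(aff_g))}
    affected_metabolites = {metabs[m]: config.effect_size_metabolite * (1 if k % 2 == 0 else -1)
                            for k, m in enumerate(np.sort(aff_m))}

    load = np.zeros((config.n_pathways, config.n_genera))
    n_dedicated = min(len(affected_genera), config.n_pathways)
    for j, gname in enumerate(list(affected_genera)[:n_dedicated]):
        load[j, genera.index(gname)] = 1.0
    for j in range(n_dedicated, config.n_pathways):
        gs = rng.choice(config.n_genera, 2, replace=False)
        load[j, gs] = rng.uniform(0.5, 1.5, 2) * rng.choice([-1.0, 1.0], 2)
    return GroundTruth(
        affected_genera=affected_genera,
        affected_metabolites=affected_metabolites,
        pathway_loadings=pd.DataFrame(load, index=pathways, columns=genera),
    )


def simulate_counts(config: SimConfig, phenotypes: pd.DataFrame,
                    truth: GroundTruth,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample x genus count table.

    Latent log-abundance = genus baseline + pair-shared effect (variance
    ``pair_var_mz``/``pair_var_dz`` by zygosity) + MD effect on affected
    genera + individual noise; compositions are the softmax of the latent
    scores and counts are multinomial at ``seq_depth``, so every row sums
    to the sequencing depth.

    The total latent variance is the same for both zygosities (the
    classical equal-environments twin assumption): it equals
    ``max(pair_var_mz, pair_var_dz) + residual_var``, and the individual
    component absorbs whatever the pair-shared component does not carry.
    A larger shared variance therefore means more similar pair members,
    so MZ pairs are more alike than DZ pairs whenever
    ``pair_var_mz > pair_var_dz``.
    """
    if config.seq_depth <= 0:
        raise ValueError("seq_depth must be positive")
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    genera = list(truth.pathway_loadings.columns)
    G = len(genera)
    baseline = rng.normal(0.0, config.baseline_log_sd, G)

    pairs = phenotypes["pair_id"].unique()
    pair_zyg = phenotypes.groupby("pair_id", sort=False)["zygosity"].first()
    total_var = max(config.pair_var_mz, config.pair_var_dz) + config.residual_var
    shared_var = np.where(pair_zyg.loc[pairs] == "MZ",
                          config.pair_var_mz, config.pair_var_dz)
    pair_eff = rng.standard_normal((len(pairs), G)) * np.sqrt(shared_var)[:, None]
    pair_pos = {p: i for i, p in enumerate(pairs)}
    ix = phenotypes["pair_id"].map(pair_pos).to_numpy()

    n = len(phenotypes)
    indiv_sd = np.sqrt(total_var - shared_var)[ix]
    latent = (baseline[None, :] + pair_eff[ix]
              + rng.standard_normal((n, G)) * indiv_sd[:, None])
    md = phenotypes["md"].to_numpy()[:, None]
    effect = np.zeros(G)
    for gname, eff in truth.affected_genera.items():
        effect[genera.index(gname)] = eff
    latent = latent + md * effect[None, :]
    if config.confounder_leakage and "bmi" in phenotypes.columns:
        bmi_z = ((phenotypes["bmi"] - 26.3) / 4.7).to_numpy()[:, None]
        latent[:, 0] += config.confounder_leakage * bmi_z[:, 0]

    probs = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.seq_depth, p) for p in probs])
    return pd.DataFrame(counts, index=phenotypes.index, columns=genera)


def simulate_metabolites(config: SimConfig, phenotypes: pd.DataFrame,
                         truth: GroundTruth,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pair-correlated metabolite concentrations with MAR missingness.

    A latent Gaussian (pair-shared + MD effect + noise, the same
    equal-total-variance structure as the counts) sits on the log scale:
    the emitted concentration is ``exp(mu + latent) - 1`` (floored at 0),
    so the downstream log(1+x) transform recovers the Gaussian panel.
    Missing cells are NaN, never zero.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    metabs = [f"m{i:03d}" for i in range(config.n_metabolites)]
    M = len(metabs)
    mu = rng.uniform(1.5, 3.5, M)

    pairs = phenotypes["pair_id"].unique()
    pair_zyg = phenotypes.groupby("pair_id", sort=False)["zygosity"].first()
    total_var = max(config.pair_var_mz, config.pair_var_dz) + config.residual_var
    shared_var = np.where(pair_zyg.loc[pairs] == "MZ",
                          config.pair_var_mz, config.pair_var_dz)
    pair_eff = rng.standard_normal((len(pairs), M)) * np.sqrt(shared_var)[:, None]
    pair_pos = {p: i for i, p in enumerate(pairs)}
    ix = phenotypes["pair_id"].map(pair_pos).to_numpy()

    n = len(phenotypes)
    indiv_sd = np.sqrt(total_var - shared_var)[ix]
    latent = pair_eff[ix] + rng.standard_normal((n, M)) * indiv_sd[:, None]
    md = phenotypes["md"].to_numpy()[:, None]
    effect = np.zeros(M)
    for mname, eff in truth.affected_metabolites.items():
        effect[metabs.index(mname)] = eff
    latent = latent + md * effect[None, :]

    conc = np.maximum(np.exp(mu[None, :] + latent) - 1.0, 0.0)
    mask = rng.random((n, M)) < config.missing_rate_metabolite
    conc[mask] = np.nan
    return pd.DataFrame(conc, index=phenotypes.index, columns=metabs)


def simulate_pathways(counts: pd.DataFrame, truth: GroundTruth,
                      noise_sd: float = 0.5,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Predicted-pathway table: pathway_j = sum_g loading(j,g) * CLR(g) + noise.

    With an identity loading block and zero noise each pathway reproduces
    its genus's CLR profile exactly (Spearman rho = 1), giving the network
    stage a recoverable ground truth.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    clr = clr_transform(counts)
    load = truth.pathway_loadings
    missing = load.columns.difference(clr.columns)
    if len(missing):
        raise ValueError(f"loading matrix references unknown genera: "
                         f"{missing.tolist()[:5]}")
    vals = clr[load.columns].to_numpy() @ load.to_numpy().T
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)
    return pd.DataFrame(vals, index=counts.index, columns=load.index)


def simulate_cohort(config: SimConfig | None = None, **overrides) -> TwinCohort:
    """Generate a complete cohort (deterministic given ``config.seed``)."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    phen = simulate_phenotypes(config, rng)
    meta = simulate_confounders(config, phen, rng)
    truth = make_ground_truth(config, rng)
    counts = simulate_counts(config, meta, truth, rng)
    metab = simulate_metabolites(config, meta, truth, rng)
    pathw = simulate_pathways(counts, truth, noise_sd=config.pathway_noise_sd,
                              rng=rng)
    return TwinCohort(metadata=meta, counts=counts, metabolites=metab,
                      pathways=pathw, truth=truth, config=config)
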