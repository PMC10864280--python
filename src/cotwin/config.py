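"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic twin-cohort generator.

    The defaults mirror the cohort the analysis design assumes: 97 MZ and
    122 DZ same-sex pairs, an MD prevalence of ~0.33, and liability
    correlations calibrated so the liability-threshold model reproduces
    proband-wise concordances of ~61% (MZ) and ~36% (DZ).

    Pair-shared variances act on the latent log-abundance scale. The total
    latent variance is equalized across zygosities at
    ``max(pair_var_mz, pair_var_dz) + residual_var`` (individual noise
    absorbs the remainder), so a larger shared variance means more similar
    pair members: ``pair_var_mz > pair_var_dz`` yields the expected lower
    within-pair dissimilarity for MZ than DZ twins.
    """

    n_mz_pairs: int = 97
    n_dz_pairs: int = 122
    prevalence: float = 0.329
    liability_corr_mz: float = 0.63
    liability_corr_dz: float = 0.08
    n_genera: int = 41
    n_metabolites: int = 60
    n_pathways: int = 30
    n_affected_genera: int = 3
    n_affected_metabolites: int = 3
    effect_size_genus: float = 1.0
    effect_size_metabolite: float = 0.5
    pair_var_mz: float = 0.5
    pair_var_dz: float = 0.3
    residual_var: float = 0.5
    seq_depth: int = 20000
    missing_rate_metabolite: float = 0.05
    baseline_log_sd: float = 1.5
    pathway_noise_sd: float = 0.5
    # optional confounder->feature leakage (CLR shift per BMI SD) and an
    # MD->BMI shift, used to exercise covariate adjustment in the LMM
    confounder_leakage: float = 0.0
    bmi_md_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_genera", "n_metabolites",
                     "n_pathways", "seq_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("prevalence", "missing_rate_metabolite"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("liability_corr_mz", "liability_corr_dz"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{name} must be a correlation in [0, 1], got {v}")
        for name in ("pair_var_mz", "pair_var_dz", "residual_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_affected_genera > self.n_genera:
            raise ValueError("n_affected_genera exceeds n_genera")
        if self.n_affected_metabolites > self.n_metabolites:
            raise ValueError("n_affected_metabolites exceeds n_metabolites")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: input paths, thresholds, seed."""

    counts: str = "counts.tsv"
    metabolites: str = "metabolites.tsv"
    pathways: str = "pathways.tsv"
    metadata: str = "metadata.tsv"
    taxonomy: str | None = None
    outdir: str = "cotwin_out"
    alpha_pairwise: float = 0.05
    alpha_pairwise_pathway: float = 0.1
    fdr_features: float = 0.2
    fdr_pathways: float = 0.25
    rho_cutoff: float = 0.2
    network_fdr: float = 0.05
    min_depth: int = 10000
    zero_replacement: float = 0.5
    max_missing_frac: float = 0.25
    seed: int = 0

    def validate(self, check_paths: bool = False) -> None:
        for name in ("alpha_pairwise", "alpha_pairwise_pathway",
                     "fdr_features", "fdr_pathways", "network_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if check_paths:
            for name in ("counts", "metabolites", "pathways", "metadata"):
                p = Path(getattr(self, name))
                if not p.exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
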