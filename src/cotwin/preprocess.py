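"""Filtering and transformation of microbiome, metabolome and covariate tables.

Microbiome counts are filtered (sequencing depth, rare-taxon rules),
agglomerated to genus, and mapped to unconstrained real space with the
centered log-ratio (CLR) transform. Metabolite concentrations are screened
for missingness, median-imputed, log(1+x)-transformed and z-scaled.
Covariates are median/mode-imputed.

The two transforms are exposed both as sklearn-style transformers
(:class:`CLRTransformer`, :class:`MetabolitePreprocessor`) and as thin
module-level functions operating on DataFrames.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "CLRTransformer",
    "MetabolitePreprocessor",
    "filter_samples_by_depth",
    "filter_taxa",
    "agglomerate_to_genus",
    "clr_transform",
    "preprocess_metabolites",
    "impute_confounders",
]


# ---------------------------------------------------------------------------
# count-table filters

def filter_samples_by_depth(counts: pd.DataFrame, min_depth: int = 10000) -> pd.DataFrame:
    """Drop samples whose total read count is strictly below ``min_depth``.

    A sample with depth exactly ``min_depth`` is retained ("less than" is
    strict). Returns a (possibly empty) copy; removals are logged.
    """
    _check_counts(counts)
    depth = counts.sum(axis=1)
    keep = depth >= min_depth
    dropped = counts.index[~keep].tolist()
    if dropped:
        logger.info("depth filter removed %d samples (< %d reads): %s",
                    len(dropped), min_depth, dropped)
    return counts.loc[keep].copy()


def filter_taxa(counts: pd.DataFrame) -> pd.DataFrame:
    """Apply the rare-taxon / empty-row filters, in order.

    1. taxa observed only once in the whole dataset (total count 1) removed;
    2. taxa must appear in more than one sample;
    3. taxa with no counts at all removed;
    4. empty samples removed.

    Rules 1-3 overlap (a singleton taxon also fails rule 2); they are applied
    sequentially as stated, and a per-rule removal log is recorded.
    """
    _check_counts(counts)
    out = counts
    removed: dict[str, list] = {}

    total = out.sum(axis=0)
    rule1 = out.columns[total == 1]
    removed["singleton_taxa"] = rule1.tolist()
    out = out.drop(columns=rule1)

    n_samples_present = (out > 0).sum(axis=0)
    rule2 = out.columns[n_samples_present <= 1]
    removed["single_sample_taxa"] = rule2.tolist()
    out = out.drop(columns=rule2)

    rule3 = out.columns[out.sum(axis=0) == 0]
    removed["zero_taxa"] = rule3.tolist()
    out = out.drop(columns=rule3)

    rule4 = out.index[out.sum(axis=1) == 0]
    removed["empty_samples"] = rule4.tolist()
    out = out.drop(index=rule4)

    for rule, ids in removed.items():
        if ids:
            logger.info("taxon filter [%s] removed %d: %s", rule, len(ids), ids)
    out = out.copy()
    out.attrs["filter_log"] = removed
    return out


def agglomerate_to_genus(counts: pd.DataFrame, taxonomy: dict[str, str]) -> pd.DataFrame:
    """Sum feature counts within genus.

    ``taxonomy`` maps feature (e.g. ASV) IDs to genus labels; features
    unclassified at genus level should already carry labels such as
    ``"unclassified Ruminococcaceae"`` (the parent rank). Features absent
    from the map raise.
    """
    _check_counts(counts)
    missing = [c for c in counts.columns if c not in taxonomy]
    if missing:
        raise KeyError(f"features missing from taxonomy map: {missing[:5]}")
    genus = counts.columns.map(taxonomy)
    agg = counts.T.groupby(genus, sort=False).sum().T
    agg.columns.name = counts.columns.name
    return agg


def _check_counts(counts: pd.DataFrame) -> None:
    vals = counts.to_numpy()
    if vals.size and ((vals < 0).any() or np.any(vals != np.floor(vals))):
        raise ValueError("count table must contain nonnegative integers")


# ---------------------------------------------------------------------------
# CLR

class CLRTransformer(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform for compositional count data.

    Each sample's counts are divided by their geometric mean and
    log-transformed: ``clr(x)_i = log(x_i) - mean(log x)``. Zeros are first
    replaced by ``zero_replacement`` (half a count by default), the standard
    multiplicative-replacement convention for count zeros. The transform is
    stateless; ``fit`` only records the feature names.

    Per-sample CLR values sum to zero, and the transform is invariant to
    scaling a sample's counts by a positive constant.
    """

    def __init__(self, zero_replacement: float = 0.5):
        self.zero_replacement = zero_replacement

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        was_frame = isinstance(X, pd.DataFrame)
        Xv = np.asarray(self._validate(X), dtype=float)
        Xv = np.where(Xv == 0, self.zero_replacement, Xv)
        logx = np.log(Xv)
        clr = logx - logx.mean(axis=1, keepdims=True)
        if was_frame:
            return pd.DataFrame(clr, index=X.index, columns=X.columns)
        return clr

    def _validate(self, X):
        vals = np.asarray(X, dtype=float)
        if vals.ndim != 2:
            raise ValueError("expected a 2-D samples x features array")
        if (vals < 0).any():
            raise ValueError("negative counts are not compositional")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("empty samples cannot be CLR-transformed")
        return X


def clr_transform(counts: pd.DataFrame, zero_replacement: float = 0.5) -> pd.DataFrame:
    """Functional form of :class:`CLRTransformer` for a count DataFrame."""
    return CLRTransformer(zero_replacement=zero_replacement).fit_transform(counts)


# ---------------------------------------------------------------------------
# metabolites

class MetabolitePreprocessor(BaseEstimator, TransformerMixin):
    """Missingness filtering, imputation, log transform and z-scaling.

    Steps, in the only order in which each is well defined:

    1. drop features missing in more than ``max_missing_frac`` of samples;
    2. impute remaining missing cells with the feature's median of observed
       values (medians learned at ``fit`` time);
    3. ``log(1 + x)`` transform;
    4. center each feature to mean 0 and scale to SD 1 (population SD,
       divisor n; means/SDs learned at ``fit`` time).

    Features with zero variance after the log transform cannot be scaled and
    are dropped with a warning.
    """

    def __init__(self, max_missing_frac: float = 0.25, population_sd: bool = True):
        self.max_missing_frac = max_missing_frac
        self.population_sd = population_sd

    def fit(self, X, y=None):
        X = self._as_frame(X)
        miss_frac = X.isna().mean(axis=0)
        keep = miss_frac[miss_frac <= self.max_missing_frac].index
        dropped = miss_frac.index.difference(keep).tolist()
        if dropped:
            logger.info("missingness rule dropped %d metabolites: %s",
                        len(dropped), dropped)
        kept = X[keep]
        medians = kept.median(axis=0, skipna=True)
        logged = np.log1p(kept.fillna(medians))
        ddof = 0 if self.population_sd else 1
        sds = logged.std(axis=0, ddof=ddof)
        constant = sds.index[sds == 0].tolist()
        if constant:
            logger.warning("dropping zero-variance metabolites (scaling "
                           "undefined): %s", constant)
        final = [c for c in keep if c not in set(constant)]
        self.features_out_ = pd.Index(final)
        self.dropped_missing_ = dropped
        self.dropped_constant_ = constant
        self.medians_ = medians[final]
        self.means_ = logged[final].mean(axis=0)
        self.sds_ = sds[final]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "features_out_")
        X = self._as_frame(X)
        kept = X[self.features_out_].fillna(self.medians_)
        logged = np.log1p(kept)
        return (logged - self.means_) / self.sds_

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if (X.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise ValueError("metabolite concentrations must be nonnegative")
        return X


def preprocess_metabolites(metab: pd.DataFrame,
                           max_missing_frac: float = 0.25) -> pd.DataFrame:
    """Functional form of :class:`MetabolitePreprocessor` (fit and transform
    on the same table, the usual single-cohort use)."""
    return MetabolitePreprocessor(max_missing_frac=max_missing_frac).fit_transform(metab)


# ---------------------------------------------------------------------------
# covariates

def impute_confounders(metadata: pd.DataFrame) -> pd.DataFrame:
    """Median-impute numeric covariates; mode-impute binary/categorical ones.

    For binary 0/1 covariates the median is ambiguous at a 50/50 split, so
    the mode is used with ties broken toward 0 (no exposure).
    """
    out = metadata.copy()
    for col in out.columns:
        s = out[col]
        if not s.isna().any():
            continue
        if pd.api.types.is_numeric_dtype(s):
            uniq = set(s.dropna().unique())
            if uniq <= {0, 1}:
                counts = s.value_counts()
                fill = 0 if counts.get(0, 0) >= counts.get(1, 0) else 1
            else:
                fill = s.median(skipna=True)
        else:
            modes = s.mode(dropna=True)
            fill = modes.iloc[0] if len(modes) else s.dropna().iloc[0]
        out[col] = s.fillna(fill)
    return out
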