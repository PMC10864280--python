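"""Power calibration oracles for the end-to-end recovery experiments.

These utilities answer two planning questions by replicate simulation on
the default cohort geometry (97 MZ + 122 DZ pairs):

* at what spiked effect size does the healthy-co-twin vs MD-twin
  mixed-model screen (layer d) detect a single spiked genus with a target
  probability? (:func:`calibrate_genus_effect`, probit interpolation over
  a candidate grid);
* how often is a spiked genus recovered *consistently* — ticked in every
  pyramid layer a-e — at a given effect size?
  (:func:`consistency_recovery`).

The single-spike configuration keeps every other genus null, so detection
probabilities are attributable to the spike alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .config import SimConfig
from .lmm import screen_features
from .preprocess import clr_transform
from .pyramid import build_ledger, pairwise_layer
from .simulate import simulate_cohort

__all__ = ["single_spike_config", "layer_d_power", "calibrate_genus_effect",
           "consistency_recovery"]


def single_spike_config(effect: float, seed: int, **overrides) -> SimConfig:
    """Default cohort with exactly one spiked genus and noise-free
    pathways (each affected genus keeps a dedicated identity-loading
    pathway). The metabolite panel is minimal: it plays no role in the
    genus analyses."""
    kwargs = dict(n_affected_genera=1, effect_size_genus=effect,
                  pathway_noise_sd=0.0, n_metabolites=2,
                  n_affected_metabolites=0, n_pathways=5, seed=seed)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def layer_d_power(effect: float, n_reps: int = 40, seed: int = 0,
                  fdr_threshold: float = 0.2) -> float:
    """Probability that the spiked genus passes the layer-d screen at
    FDR < ``fdr_threshold``, estimated over ``n_reps`` cohorts."""
    hits = 0
    for s in _rep_seeds(seed, n_reps):
        cohort = simulate_cohort(single_spike_config(effect, int(s)))
        genus = next(iter(cohort.truth.affected_genera))
        clr = clr_transform(cohort.counts)
        res = screen_features(clr, cohort.metadata, setup="d",
                              fdr_threshold=fdr_threshold)
        hits += bool(res.loc[genus, "significant"])
    return hits / n_reps


def calibrate_genus_effect(target_power: float = 0.9,
                           candidates: tuple[float, ...] = (0.3, 0.5, 0.7),
                           n_reps: int = 40, seed: int = 0) -> float:
    """Effect size whose layer-d detection power is ``target_power``.

    Powers are estimated at each candidate effect and a probit model
    power = Phi(a + b*effect) is fitted by least squares; the target
    quantile is read off the fitted line. Estimates are clipped away from
    0/1 before the probit transform.
    """
    powers = np.array([layer_d_power(e, n_reps=n_reps, seed=seed + k)
                       for k, e in enumerate(candidates)])
    z = stats.norm.ppf(np.clip(powers, 1.0 / (n_reps + 1),
                               n_reps / (n_reps + 1.0)))
    b, a = np.polyfit(np.asarray(candidates, dtype=float), z, 1)
    if b <= 0:
        raise RuntimeError("estimated power is not increasing in effect size")
    return float((stats.norm.ppf(target_power) - a) / b)


def consistency_recovery(effect: float, n_runs: int = 50, seed: int = 0,
                         alpha: float = 0.05,
                         fdr_threshold: float = 0.2) -> dict:
    """Fraction of seeded runs in which the spiked genus is ticked in
    every pyramid layer (a-e) and hence flagged consistent.

    Also reports per-layer tick rates and the Spearman correlation between
    the spiked genus and its dedicated identity-loading pathway (noise-free,
    computed on the layer-d population) averaged over runs.
    """
    from .lmm import select_setup
    from .network import spearman

    per_layer = {l: 0 for l in "abcde"}
    consistent = 0
    rhos = []
    for s in _rep_seeds(seed, n_runs):
        cohort = simulate_cohort(single_spike_config(effect, int(s)))
        genus = next(iter(cohort.truth.affected_genera))
        clr = clr_transform(cohort.counts)
        pairwise = {l: pairwise_layer(clr, cohort.metadata, l) for l in "abc"}
        screens = {l: screen_features(clr, cohort.metadata, setup=l,
                                      fdr_threshold=fdr_threshold)
                   for l in "de"}
        ledger = build_ledger(pairwise, screens, lmm_tick_alpha=alpha)
        for l in "abc":
            per_layer[l] += bool(pairwise[l].loc[genus, "significant"])
        for l in "de":
            per_layer[l] += bool(screens[l].loc[genus, "p"] < alpha)
        consistent += bool(genus in ledger.index
                           and ledger.loc[genus, "consistent"])
        pathway = cohort.truth.pathway_loadings.index[
            cohort.truth.pathway_loadings[genus] == 1.0][0]
        pop = select_setup(cohort.metadata, "d")
        rho, _ = spearman(clr.loc[pop, genus].to_numpy(),
                          cohort.pathways.loc[pop, pathway].to_numpy())
        rhos.append(rho)
    return {
        "recovery": consistent / n_runs,
        "tick_rate": {l: per_layer[l] / n_runs for l in "abcde"},
        "identity_pathway_rho": float(np.mean(rhos)),
        "effect": effect, "n_runs": n_runs,
    }
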