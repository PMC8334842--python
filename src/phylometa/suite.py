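"""The full model battery for the inbreeding-avoidance meta-analysis.

Models (responses on the Fisher-Z scale unless noted):

* 1.1 / 1.4 / 1.7 — intercept-only meta-analyses of ZrPairs, ZrAverage and
  ZrDepression, quantifying heterogeneity (H2, I2_total).
* 2 — ZrPairs ~ ZrAverage.  A slope of 1 means mated pairs are as related as
  random male-female pairs (no avoidance); the slope's deviation from 1 is
  the headline test of inbreeding avoidance.
* 3 — ZrPairs ~ ZrAverage x reported inbreeding depression; per-class slopes
  and their deviations from 1.
* 4 — binomial: pairs with any avoidance mechanism vs pairs without, with
  reported inbreeding depression as the fixed effect (all species).
* 5 — ZrPairs ~ mechanism x ZrAverage on the depression subset, with all
  pairwise mechanism contrasts.
* 6 — ZrAverage ~ mechanism on the depression subset.
* 7 — binomial: random mating vs not (pair counts), mechanism as the fixed
  effect, with per-level probabilities on the data scale.
* 8 — ZrPairs ~ cooperative breeding x ZrAverage on the depression subset
  (the non-classifiable social taxon excluded), per-class slopes vs 1.

Publication-bias battery: funnel data (meta-analytic residuals vs
precision), Egger-style regression on the effect's standard error, and a
time-lag regression on publication year.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import bpmm
from .bpmm import (ChainSet, MCMCSettings, ModelSpec, PosteriorSummary,
                   TEST_SETTINGS, gelman_rubin, heterogeneity, r2_marginal,
                   summarize)
from .phylo import PhyloCovariance, match_taxa

__all__ = [
    "ModelResult",
    "SuiteResult",
    "MODEL_NAMES",
    "prepare_table",
    "run_model",
    "run_suite",
    "run_intercept_models",
    "run_avoidance_models",
    "run_mechanism_models",
    "egger_test",
    "time_lag_test",
    "funnel_data",
    "level_effect_draws",
    "flags_bias",
]

MODEL_NAMES = ["1.1", "1.4", "1.7", "2", "3", "4", "5", "6", "7", "8"]

REFERENCES = {"depression_analysis": "no", "mechanism": "none", "cooperative": "no"}


@dataclass
class ModelResult:
    name: str
    spec: ModelSpec
    chains: ChainSet
    n_used: int
    summaries: dict = field(default_factory=dict)
    heterogeneity: Optional[bpmm.HeterogeneityReport] = None
    r2_marginal: Optional[PosteriorSummary] = None
    psrf: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    selected_chain: Optional[int] = None

    def as_dict(self) -> dict:
        d = {
            "model": self.name,
            "n_species": self.n_used,
            "selected_chain": self.selected_chain,
            "summaries": {k: s.as_dict() for k, s in self.summaries.items()},
            "psrf": self.psrf,
            "warnings": self.warnings,
        }
        if self.heterogeneity is not None:
            d["heterogeneity"] = {
                "H2": self.heterogeneity.h2.as_dict(),
                "I2_total": self.heterogeneity.i2_total.as_dict(),
                "sigma_m2": self.heterogeneity.sigma_m2,
            }
        if self.r2_marginal is not None:
            d["R2_marginal"] = self.r2_marginal.as_dict()
        return d


@dataclass
class SuiteResult:
    models: dict = field(default_factory=dict)   # name -> ModelResult
    funnel: dict = field(default_factory=dict)   # effect name -> DataFrame
    convergence: Optional[pd.DataFrame] = None
    subset_sizes: dict = field(default_factory=dict)


def prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived analysis columns to a built species table.

    ``mech_pairs``: number of pairs counted as having an avoidance mechanism
    (the species' pair count when any mechanism is reported, else 0);
    ``random_pairs``: same construction for random mating; ``se_pairs`` /
    ``se_average`` / ``se_depression``: effect-size standard errors.
    """
    t = table.copy()
    t["mech_pairs"] = np.where(t["mechanism"] != "none", t["n_pairs"], 0)
    t["random_pairs"] = np.where(t["random_mating"] == "yes", t["n_pairs"], 0)
    t["se_pairs"] = np.sqrt(t["var_pairs"])
    t["se_average"] = np.sqrt(t["var_average"])
    if "var_depression" in t:
        t["se_depression"] = np.sqrt(t["var_depression"])
    return t


def _subset(table: pd.DataFrame, name: str) -> tuple:
    """Rows a given model runs on, plus subset warnings."""
    warns = []
    if name == "1.7":
        sub = table[np.isfinite(table["zr_depression"].astype(float))]
    elif name in ("5", "6", "7"):
        sub = table[table["depression_analysis"] == "yes"]
    elif name == "8":
        sub = table[(table["depression_analysis"] == "yes")
                    & (table["cooperative"] != "not_applicable")]
    else:
        sub = table
    sub = sub.reset_index(drop=True)
    if name in ("5", "6", "7"):
        present = set(sub["mechanism"])
        absent = sorted({"active_mate_choice", "sex_biased_dispersal",
                         "post_mating_avoidance", "none"} - present)
        if absent:
            warns.append(f"mechanism levels absent from the subset and dropped: {absent}")
        counts = sub["mechanism"].value_counts()
        small = counts[counts < 3]
        for lev, c in small.items():
            warns.append(f"mechanism level {str(lev)!r} has only {c} species")
    if name == "3":
        counts = sub["depression_analysis"].value_counts()
        for lev in ("yes", "no"):
            if counts.get(lev, 0) < 3:
                warns.append(f"depression class {lev!r} has fewer than 3 species")
    return sub, warns


def _model_spec(name: str) -> ModelSpec:
    refs = dict(REFERENCES)
    if name == "1.1":
        return ModelSpec("zr_pairs", mev="var_pairs", name=name)
    if name == "1.4":
        return ModelSpec("zr_average", mev="var_average", name=name)
    if name == "1.7":
        return ModelSpec("zr_depression", mev="var_depression", name=name)
    if name == "2":
        return ModelSpec("zr_pairs", fixed_terms=["zr_average"], mev="var_pairs", name=name)
    if name == "3":
        return ModelSpec("zr_pairs", fixed_terms=["depression_analysis*zr_average"],
                         mev="var_pairs", reference_levels=refs, name=name)
    if name == "4":
        return ModelSpec("mech_pairs", family="binomial", trials="n_pairs",
                         fixed_terms=["depression_analysis"], reference_levels=refs, name=name)
    if name == "5":
        return ModelSpec("zr_pairs", fixed_terms=["mechanism*zr_average"],
                         mev="var_pairs", reference_levels=refs, name=name)
    if name == "6":
        return ModelSpec("zr_average", fixed_terms=["mechanism"],
                         mev="var_average", reference_levels=refs, name=name)
    if name == "7":
        return ModelSpec("random_pairs", family="binomial", trials="n_pairs",
                         fixed_terms=["mechanism"], reference_levels=refs, name=name)
    if name == "8":
        return ModelSpec("zr_pairs", fixed_terms=["cooperative*zr_average"],
                         mev="var_pairs", reference_levels=refs, name=name)
    raise ValueError(f"unknown model {name!r}")


def level_effect_draws(chains: ChainSet, factor: str, chain: Optional[int] = None) -> dict:
    """Per-level draws of a factor's main effect (reference level = 0)."""
    levels = chains.design.factor_levels.get(factor)
    if levels is None:
        raise KeyError(f"{factor!r} is not a factor in this model")
    nd = len(chains.draws(chains.param_names[0], chain=chain))
    out = {levels[0]: np.zeros(nd)}
    for lev in levels[1:]:
        out[lev] = chains.draws(f"{factor}[{lev}]", chain=chain)
    return out


def _slope_draws(chains: ChainSet, factor: str, covariate: str,
                 chain: Optional[int] = None) -> dict:
    """Per-level slope draws for a factor x covariate interaction."""
    levels = chains.design.factor_levels[factor]
    base = chains.draws(covariate, chain=chain)
    out = {levels[0]: base}
    for lev in levels[1:]:
        inter = f"{factor}[{lev}]:{covariate}"
        alt = f"{covariate}:{factor}[{lev}]"
        if inter in chains.param_names:
            out[lev] = base + chains.draws(inter, chain=chain)
        elif alt in chains.param_names:
            out[lev] = base + chains.draws(alt, chain=chain)
        else:
            out[lev] = base
    return out


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def run_model(name: str, table: pd.DataFrame, cov: PhyloCovariance,
              settings: MCMCSettings = TEST_SETTINGS,
              selected_chain: Optional[int] = None) -> ModelResult:
    """Fit one named model and compute its reported summaries.

    ``selected_chain`` picks which chain the parameter summaries come from
    (convergence diagnostics always use all chains); ``None`` pools chains.
    """
    sub, warns = _subset(table, name)
    if len(sub) < 4:
        raise ValueError(f"model {name}: only {len(sub)} usable species (need >= 4)")
    spec = _model_spec(name)
    sub_cov = match_taxa(cov, sub)
    st = settings
    chains = bpmm.fit(spec, sub, sub_cov, st)
    ch = selected_chain
    res = ModelResult(name=name, spec=spec, chains=chains, n_used=len(sub),
                      warnings=warns, selected_chain=ch)
    if settings.n_chains >= 2:
        res.psrf = gelman_rubin(chains)
    s = res.summaries
    s["intercept"] = summarize(chains, "(Intercept)", chain=ch)
    s["sigma2_phylo"] = summarize(chains, "sigma2_phylo", chain=ch)

    if name in ("1.1", "1.4", "1.7"):
        res.heterogeneity = heterogeneity(chains, chain=ch)
    if name == "2":
        slope = chains.draws("zr_average", chain=ch)
        s["slope_zr_average"] = summarize(chains, "zr_average", chain=ch)
        s["slope_minus_1"] = summarize(slope - 1.0)
    if name == "3":
        slopes = _slope_draws(chains, "depression_analysis", "zr_average", chain=ch)
        for lev, d in slopes.items():
            s[f"slope[depression={lev}]"] = summarize(d)
            s[f"slope[depression={lev}]_minus_1"] = summarize(d - 1.0)
        levels = chains.design.factor_levels["depression_analysis"]
        if len(levels) == 2:
            eff = level_effect_draws(chains, "depression_analysis", chain=ch)
            s["depression_yes_minus_no"] = summarize(eff["yes"] - eff["no"])
    if name == "4":
        eff = level_effect_draws(chains, "depression_analysis", chain=ch)
        b0 = chains.draws("(Intercept)", chain=ch)
        if "yes" in eff and "no" in eff:
            s["depression_yes_minus_no_liability"] = summarize(eff["yes"] - eff["no"])
            s["p_mechanism[depression=no]"] = summarize(_logistic(b0 + eff["no"]), test_value=0.5)
            s["p_mechanism[depression=yes]"] = summarize(_logistic(b0 + eff["yes"]), test_value=0.5)
            s["p_mechanism_yes_minus_no"] = summarize(
                _logistic(b0 + eff["yes"]) - _logistic(b0 + eff["no"]))
    if name in ("5", "6"):
        eff = level_effect_draws(chains, "mechanism", chain=ch)
        for la, lb in itertools.combinations(sorted(eff), 2):
            s[f"{la}_minus_{lb}"] = summarize(eff[la] - eff[lb])
        if name == "5":
            for lev, d in _slope_draws(chains, "mechanism", "zr_average", chain=ch).items():
                s[f"slope[mechanism={lev}]"] = summarize(d)
    if name == "7":
        eff = level_effect_draws(chains, "mechanism", chain=ch)
        b0 = chains.draws("(Intercept)", chain=ch)
        for lev, d in eff.items():
            s[f"p_random[{lev}]"] = summarize(_logistic(b0 + d), test_value=0.5)
    if name == "8":
        eff = level_effect_draws(chains, "cooperative", chain=ch)
        if "yes" in eff:
            s["cooperative_yes_minus_no"] = summarize(eff["yes"] - eff["no"])
        for lev, d in _slope_draws(chains, "cooperative", "zr_average", chain=ch).items():
            s[f"slope[cooperative={lev}]"] = summarize(d)
            s[f"slope[cooperative={lev}]_minus_1"] = summarize(d - 1.0)
    if spec.family == "gaussian":
        res.r2_marginal = r2_marginal(chains, chain=ch)
    return res


def run_suite(table: pd.DataFrame, cov: PhyloCovariance,
              settings: MCMCSettings = TEST_SETTINGS,
              models: Optional[list] = None,
              chain_selection_seed: Optional[int] = None) -> SuiteResult:
    """Run the requested models (default: all) and bundle the results.

    When several chains are run, each model's reported parameters come from
    one chain selected at random (all chains still feed the convergence
    diagnostics); the selection seed defaults to the MCMC seed.
    """
    models = models or MODEL_NAMES
    table = prepare_table(table)
    sel_rng = np.random.default_rng(
        settings.seed if chain_selection_seed is None else chain_selection_seed)
    out = SuiteResult()
    conv_rows = []
    for name in models:
        sel = int(sel_rng.integers(settings.n_chains)) if settings.n_chains > 1 else None
        res = run_model(name, table, cov, settings, selected_chain=sel)
        out.models[name] = res
        out.subset_sizes[name] = res.n_used
        for pname, val in res.psrf.items():
            conv_rows.append({"model": name, "parameter": pname, "psrf": val})
    out.convergence = pd.DataFrame(conv_rows)
    for name, effect in (("1.1", "zr_pairs"), ("1.7", "zr_depression")):
        if name in out.models:
            out.funnel[effect] = funnel_data(out.models[name].chains, None)
    return out


# convenience wrappers matching the three stages of the analysis ------------

def run_intercept_models(table, cov, settings=TEST_SETTINGS) -> SuiteResult:
    return run_suite(table, cov, settings, models=["1.1", "1.4", "1.7"])


def run_avoidance_models(table, cov, settings=TEST_SETTINGS) -> SuiteResult:
    return run_suite(table, cov, settings, models=["2", "3"])


def run_mechanism_models(table, cov, settings=TEST_SETTINGS) -> SuiteResult:
    return run_suite(table, cov, settings, models=["4", "5", "6", "7", "8"])


# publication-bias battery ---------------------------------------------------

_EFFECT_VARS = {"zr_pairs": "var_pairs", "zr_average": "var_average",
                "zr_depression": "var_depression", "y": "v"}


def _bias_table(effect_column: str, table: pd.DataFrame):
    var_col = _EFFECT_VARS.get(effect_column)
    if var_col is None or var_col not in table.columns:
        raise ValueError(f"no sampling-variance column known for {effect_column!r}")
    t = table[np.isfinite(table[effect_column].astype(float))].reset_index(drop=True)
    t = t.copy()
    t["_se"] = np.sqrt(t[var_col].astype(float))
    return t, var_col


def egger_test(effect_column: str, table: pd.DataFrame, cov: PhyloCovariance,
               settings: MCMCSettings = TEST_SETTINGS) -> PosteriorSummary:
    """Egger-style funnel-asymmetry regression under the same random effects.

    The effect size is regressed (with mev weighting and the phylogenetic
    random effect) on its own standard error; for ZrPairs the ZrAverage
    covariate is included, since bias is expected in the residual variation
    around that relationship.  Bias is flagged when the 95% CI of the SE
    coefficient excludes zero (see :func:`flags_bias`).
    """
    t, var_col = _bias_table(effect_column, table)
    if t["_se"].nunique() == 1:
        raise ValueError("all standard errors identical; Egger slope inestimable")
    terms = ["_se"] + (["zr_average"] if effect_column == "zr_pairs" else [])
    spec = ModelSpec(effect_column, fixed_terms=terms, mev=var_col, name="egger")
    chains = bpmm.fit(spec, t, match_taxa(cov, t), settings)
    return summarize(chains, "_se")


def time_lag_test(effect_column: str, table: pd.DataFrame, cov: PhyloCovariance,
                  settings: MCMCSettings = TEST_SETTINGS) -> PosteriorSummary:
    """Time-lag bias test: the Egger model with publication year as the
    fixed effect instead of the standard error.  Year is centred, which
    leaves the slope unchanged."""
    t, var_col = _bias_table(effect_column, table)
    if t["year"].nunique() < 2:
        raise ValueError("publication year is constant; time-lag slope inestimable")
    t["_year_c"] = t["year"].astype(float) - t["year"].astype(float).mean()
    terms = ["_year_c"] + (["zr_average"] if effect_column == "zr_pairs" else [])
    spec = ModelSpec(effect_column, fixed_terms=terms, mev=var_col, name="time_lag")
    chains = bpmm.fit(spec, t, match_taxa(cov, t), settings)
    return summarize(chains, "_year_c")


def flags_bias(summary: PosteriorSummary) -> bool:
    """A bias test flags when its coefficient's 95% CI excludes zero."""
    return not (summary.ci_lower <= 0.0 <= summary.ci_upper)


def funnel_data(intercept_fit: ChainSet, table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Meta-analytic residuals against precision for funnel plots.

    Residual = observed effect minus the posterior-mean fitted value (fixed
    part plus phylogenetic effect); precision = sqrt(1 / sampling variance).
    """
    chains = intercept_fit
    if chains.mev is None:
        raise ValueError("funnel data need a fit with measurement-error variances")
    X = chains.design.matrix
    beta_pm = chains.beta_draws().mean(axis=0)
    a_pm = np.mean(chains.a_means, axis=0)
    if table is not None:
        y = table[chains.spec.response].to_numpy(float)
        species = list(table["species_id"])
    else:
        y = chains.response
        species = chains.taxa
    resid = y - (X @ beta_pm + a_pm)
    return pd.DataFrame({
        "species_id": species,
        "residual": resid,
        "precision": np.sqrt(1.0 / chains.mev),
    })
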