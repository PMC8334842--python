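"""Synthetic comparative datasets with known ground truth.

The generator emulates the statistical structure of the comparative
inbreeding-avoidance table: a Yule phylogeny; latent species-level
relatedness effect sizes with phylogenetic signal; a depression-dependent
slope of pair relatedness on population relatedness (species suffering
inbreeding depression avoid related mates, so their pair relatedness is
decoupled from population relatedness; species without depression sit on the
1:1 line); Fisher-Z sampling noise with variance 1/(n-3); and the
categorical structure in which avoidance mechanisms occur only in species
with inbreeding depression.

Defaults mirror the shape of the real comparative sample: 41 species, 34 of
them with reported inbreeding depression, and mechanism frequencies among
depression species of 9/34 active mate choice, 9/34 sex-biased dispersal,
5/34 post-mating avoidance and 11/34 none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import effect_sizes as es
from .phylo import PhyloCovariance, phylo_correlation, simulate_yule

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "generate",
    "simulate_regression_dataset",
    "simulate_funnel_dataset",
    "censor_for_bias",
]

MECHANISMS = ["active_mate_choice", "sex_biased_dispersal", "post_mating_avoidance", "none"]
CLASSES = ["Aves", "Mammalia", "Reptilia", "Amphibia", "Insecta", "Actinopterygii"]


@dataclass
class GeneratorParams:
    """Ground-truth parameters of a synthetic comparative dataset."""

    k_species: int = 41
    prop_depression: float = 34 / 41
    #: slope of ZrPairs on ZrAverage in species with inbreeding depression
    slope_depression: float = 0.2
    #: slope in species without depression (1 = no avoidance, mating at random)
    slope_no_depression: float = 1.0
    intercept_depression: float = 0.0
    intercept_no_depression: float = 0.0
    #: mean of the latent ZrAverage across species
    mean_zr_average: float = 0.05
    sigma2_phylo: float = 0.05
    sigma2_resid: float = 0.02
    n_pairs_range: tuple = (10, 100)
    n_average_range: tuple = (50, 200)
    #: P(mechanism | depression); without depression, mechanism is "none"
    mechanism_probs: tuple = (9 / 34, 9 / 34, 5 / 34, 11 / 34)
    #: P(random mating | mechanism), in MECHANISMS order
    p_random_mating: tuple = (0.01, 0.58, 0.34, 0.89)
    p_cooperative: float = 0.2
    #: fraction of depression species with quantitative inbred/outbred summaries
    prop_quantitative_depression: float = 16 / 34
    dep_mean_outbred: float = 1.0
    dep_mean_inbred: float = 0.7
    dep_sd: float = 0.3
    dep_group_n_range: tuple = (10, 50)
    year_range: tuple = (1990, 2020)
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.mechanism_probs) + list(self.p_random_mating) + [
            self.p_cooperative, self.prop_depression, self.prop_quantitative_depression,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.mechanism_probs) - 1.0) > 1e-9:
            raise ValueError("mechanism_probs must sum to 1")
        if self.sigma2_phylo < 0 or self.sigma2_resid < 0:
            raise ValueError("variance components must be non-negative")
        if self.k_species < 4:
            raise ValueError("need at least 4 species")


@dataclass
class SyntheticTruth:
    """Realized latent values, serialized alongside each dataset."""

    params: GeneratorParams
    true_zr_average: np.ndarray
    true_zr_pairs: np.ndarray
    phylo_effects_average: np.ndarray
    phylo_effects_pairs: np.ndarray
    species: list = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "params": asdict(self.params),
            "species": list(self.species),
            "true_zr_average": self.true_zr_average.tolist(),
            "true_zr_pairs": self.true_zr_pairs.tolist(),
            "phylo_effects_average": self.phylo_effects_average.tolist(),
            "phylo_effects_pairs": self.phylo_effects_pairs.tolist(),
        }
        return json.dumps(d, indent=1)


def _mvn_phylo(rng: np.random.Generator, s2: float, A: np.ndarray) -> np.ndarray:
    k = A.shape[0]
    if s2 == 0:
        return np.zeros(k)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(k))
    return np.sqrt(s2) * (L @ rng.standard_normal(k))


def generate(params: Optional[GeneratorParams] = None):
    """Generate one synthetic dataset.

    Returns ``(table, tree, truth)``: a population-level DataFrame in the
    input-CSV schema, the dendropy tree it was simulated on, and the
    :class:`SyntheticTruth` needed to score parameter recovery.
    """
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    tree = simulate_yule(params.k_species, seed=int(rng.integers(2 ** 31)))
    cov = phylo_correlation(tree)
    A = cov.matrix
    k = params.k_species

    depression = rng.random(k) < params.prop_depression
    mech = np.where(
        depression,
        rng.choice(MECHANISMS, size=k, p=params.mechanism_probs),
        "none",
    )
    p_rand = dict(zip(MECHANISMS, params.p_random_mating))
    random_mating = np.where(
        rng.random(k) < np.array([p_rand[m] for m in mech]), "yes", "no"
    )
    cooperative = np.where(rng.random(k) < params.p_cooperative, "yes", "no")

    ap_avg = _mvn_phylo(rng, params.sigma2_phylo, A)
    ap_pairs = _mvn_phylo(rng, params.sigma2_phylo, A)
    true_avg = (
        params.mean_zr_average + ap_avg
        + rng.normal(0, np.sqrt(params.sigma2_resid), k)
    )
    slope = np.where(depression, params.slope_depression, params.slope_no_depression)
    intercept = np.where(
        depression, params.intercept_depression, params.intercept_no_depression
    )
    true_pairs = (
        intercept + slope * true_avg + ap_pairs
        + rng.normal(0, np.sqrt(params.sigma2_resid), k)
    )

    n_pairs = rng.integers(params.n_pairs_range[0], params.n_pairs_range[1] + 1, k)
    n_avg = rng.integers(params.n_average_range[0], params.n_average_range[1] + 1, k)
    obs_pairs = true_pairs + rng.normal(0, 1.0, k) / np.sqrt(n_pairs - 3)
    obs_avg = true_avg + rng.normal(0, 1.0, k) / np.sqrt(n_avg - 3)

    quantitative = depression & (rng.random(k) < params.prop_quantitative_depression)
    gn = rng.integers(params.dep_group_n_range[0], params.dep_group_n_range[1] + 1, (k, 2))

    rows = []
    for i in range(k):
        row = {
            "species_id": cov.taxa[i],
            "class_name": CLASSES[i % len(CLASSES)],
            "r_pairs": np.tanh(obs_pairs[i]),
            "n_pairs": int(n_pairs[i]),
            "r_average": np.tanh(obs_avg[i]),
            "n_average": int(n_avg[i]),
            "depression_reported": "yes" if depression[i] else "no",
            "mechanism": mech[i],
            "random_mating": random_mating[i],
            "cooperative": cooperative[i],
            "year": int(rng.integers(params.year_range[0], params.year_range[1] + 1)),
            "dep_r": np.nan, "dep_n": np.nan,
            "dep_mean_in": np.nan, "dep_sd_in": np.nan, "dep_n_in": np.nan,
            "dep_mean_out": np.nan, "dep_sd_out": np.nan, "dep_n_out": np.nan,
            "fitness_category": "",
        }
        if quantitative[i]:
            n_in, n_out = int(gn[i, 0]), int(gn[i, 1])
            sd = params.dep_sd
            row.update({
                "dep_mean_in": params.dep_mean_inbred + rng.normal(0, sd / np.sqrt(n_in)),
                "dep_sd_in": sd,
                "dep_n_in": n_in,
                "dep_mean_out": params.dep_mean_outbred + rng.normal(0, sd / np.sqrt(n_out)),
                "dep_sd_out": sd,
                "dep_n_out": n_out,
                "fitness_category": ["reproductive_success", "mortality", "body_mass"][i % 3],
            })
        rows.append(row)
    table = pd.DataFrame(rows, columns=es.SCHEMA_COLUMNS)
    truth = SyntheticTruth(
        params=params,
        true_zr_average=true_avg, true_zr_pairs=true_pairs,
        phylo_effects_average=ap_avg, phylo_effects_pairs=ap_pairs,
        species=list(cov.taxa),
    )
    return table, tree, truth


def simulate_regression_dataset(
    k: int = 40,
    slope: float = 0.2,
    intercept: float = 0.0,
    sigma2_phylo: float = 0.05,
    sigma2_resid: float = 0.02,
    n_range: tuple = (10, 100),
    x_sd: float = 0.3,
    seed: int = 0,
):
    """Simulate directly from the Gaussian meta-regression model.

    The covariate ``x`` is drawn once and treated as fixed (this is the
    model the sampler actually fits, so recovery and coverage checks are
    well posed: no attenuation from noise in the covariate).  Returns
    ``(table, cov)`` where the table has columns species_id, y, x, v.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_yule(k, seed=int(rng.integers(2 ** 31)))
    cov = phylo_correlation(tree)
    x = rng.normal(0.0, x_sd, k)
    n = rng.integers(n_range[0], n_range[1] + 1, k)
    v = 1.0 / (n - 3)
    a = _mvn_phylo(rng, sigma2_phylo, cov.matrix)
    y = (
        intercept + slope * x + a
        + rng.normal(0, np.sqrt(sigma2_resid), k)
        + rng.normal(0, np.sqrt(v))
    )
    table = pd.DataFrame({
        "species_id": cov.taxa, "y": y, "x": x, "v": v, "n": n,
        "year": rng.integers(1990, 2021, k),
    })
    table["se"] = np.sqrt(table["v"])
    return table, cov


def simulate_funnel_dataset(k: int = 80, mean_effect: float = 0.5,
                            sigma2_phylo: float = 0.01, sigma2_resid: float = 0.005,
                            n_range: tuple = (4, 200), seed: int = 0):
    """Canonical fixture for calibrating the publication-bias battery.

    An intercept-only meta-analytic funnel: effects share a common positive
    mean (publication bias presupposes a preferred direction), heterogeneity
    is small relative to sampling noise, and study sizes span a wide range so
    precision varies strongly.  The simulated literature is larger than the
    comparative dataset (default 80 effect sizes) so the funnel-asymmetry
    regression has workable power when the fixture is censored.

    Returns ``(table, cov)`` with columns species_id, y, v, n, se, year.
    """
    table, cov = simulate_regression_dataset(
        k=k, slope=0.0, intercept=mean_effect, sigma2_phylo=sigma2_phylo,
        sigma2_resid=sigma2_resid, n_range=n_range, seed=seed,
    )
    return table.drop(columns=["x"]), cov


def censor_for_bias(dataset: pd.DataFrame, strength: float,
                    effect_col: str = "r_pairs", n_col: str = "n_pairs",
                    seed: int = 0) -> pd.DataFrame:
    """Emulate publication bias by dropping imprecise, small-effect records.

    Records whose precision is below the median AND whose absolute effect is
    below the median are removed with probability ``strength``; at strength 1
    all such records go, at 0 the dataset is returned unchanged.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    if strength == 0.0:
        return dataset.copy()
    rng = np.random.default_rng(seed)
    eff = np.abs(np.asarray(dataset[effect_col], float))
    prec = np.asarray(dataset[n_col], float)
    weak = (prec < np.median(prec)) & (eff < np.median(eff))
    drop = weak & (rng.random(len(dataset)) < strength)
    return dataset.loc[~drop].reset_index(drop=True)
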