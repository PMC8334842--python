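"""Bayesian phylogenetic multi-level (meta-)regression by MCMC.

The Gaussian hierarchy is

    y_i = x_i' beta + a_i + e_i + m_i,
    a ~ N(0, sigma2_phylo * A),   e ~ N(0, sigma2_resid * I),
    m_i ~ N(0, v_i)               (optional, v_i known sampling variances),

where A is the phylogenetic correlation matrix.  The known-variance term m
("mev") is what makes the model a meta-analysis: each effect size is weighted
by its inverse sampling variance.  Fixed effects get independent N(0, 1e10)
priors; variance components get inverse-gamma priors with shape nu/2 and rate
nu*V/2 (defaults V = 1, nu = 0.002).

Sampling is blocked Gibbs.  The phylogenetic effects are updated in the
eigenbasis of A, where their full conditional is diagonal, so a sweep costs
O(n^2) with no per-sweep decompositions.  Binomial responses use a latent
liability l_i with y_i ~ Binomial(n_i, logistic(l_i)); liabilities are updated
by adaptive univariate Metropolis steps (conditionally independent given the
other blocks, so the update vectorizes), everything else stays conjugate.
The liability-scale residual variance is not identifiable from binomial data
and is held fixed (default 1.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import Design, build_design
from .phylo import PhyloCovariance

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "REFERENCE_GAUSSIAN_SETTINGS",
    "REFERENCE_BINOMIAL_SETTINGS",
    "TEST_SETTINGS",
    "ChainSet",
    "PosteriorSummary",
    "HeterogeneityReport",
    "fit",
    "fit_gaussian",
    "fit_binomial",
    "summarize",
    "gelman_rubin",
    "effective_sample_size",
    "heterogeneity",
    "higgins_sigma2_m",
    "r2_marginal",
]


@dataclass
class ModelSpec:
    """Declarative description of one model."""

    response: str
    family: str = "gaussian"
    trials: Optional[str] = None
    fixed_terms: list = field(default_factory=list)
    mev: Optional[str] = None
    reference_levels: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not self.trials:
            raise ValueError("binomial models require a trials column")


@dataclass
class MCMCSettings:
    iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 20
    n_chains: int = 3
    seed: int = 0
    prior_fixed_variance: float = 1e10
    prior_V: float = 1.0
    prior_nu: float = 0.002
    binomial_residual_fix: float = 1.0
    # test hooks: hold a variance component fixed at a given value
    fix_sigma2_phylo: Optional[float] = None
    fix_sigma2_resid: Optional[float] = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin >= 1 and n_chains >= 1 required")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: full-length reference chain settings for final analyses
REFERENCE_GAUSSIAN_SETTINGS = MCMCSettings(iterations=2_000_000, burn_in=1_000_000, thin=1000)
REFERENCE_BINOMIAL_SETTINGS = MCMCSettings(iterations=6_000_000, burn_in=1_000_000, thin=5000)
#: desk-scale settings for test suites and simulation batteries
TEST_SETTINGS = MCMCSettings(iterations=30_000, burn_in=10_000, thin=20, n_chains=3)


@dataclass
class PosteriorSummary:
    """Posterior mean, 95% equal-tail CI, pMCMC, ESS and (optionally) PSRF."""

    pm: float
    ci_lower: float
    ci_upper: float
    pmcmc: float
    ess: float
    n_draws: int
    psrf: Optional[float] = None
    note: str = ""

    def as_dict(self) -> dict:
        d = {
            "pm": self.pm, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "pmcmc": self.pmcmc, "ess": self.ess, "n_draws": self.n_draws,
        }
        if self.psrf is not None:
            d["psrf"] = self.psrf
        if self.note:
            d["note"] = self.note
        return d


@dataclass
class HeterogeneityReport:
    """Phylogenetic heritability H2 and total heterogeneity I2."""

    h2: PosteriorSummary
    i2_total: PosteriorSummary
    sigma_m2: float


@dataclass
class ChainSet:
    """Thinned post-burn-in draws from one or more chains of a fit."""

    spec: ModelSpec
    design: Design
    settings: MCMCSettings
    chains: list                      # list of DataFrames, one per chain
    seeds: list
    mev: Optional[np.ndarray] = None
    response: Optional[np.ndarray] = None
    a_means: list = field(default_factory=list)      # posterior-mean phylo effects per chain
    liability_means: list = field(default_factory=list)
    accept_rates: list = field(default_factory=list)
    taxa: list = field(default_factory=list)

    @property
    def param_names(self) -> list:
        return list(self.chains[0].columns)

    def draws(self, name: str, chain: Optional[int] = None) -> np.ndarray:
        """Pooled (or single-chain) draws of a named parameter."""
        if chain is not None:
            return self.chains[chain][name].to_numpy()
        return np.concatenate([c[name].to_numpy() for c in self.chains])

    def beta_draws(self, chain: Optional[int] = None) -> np.ndarray:
        cols = self.design.names
        if chain is not None:
            return self.chains[chain][cols].to_numpy()
        return np.vstack([c[cols].to_numpy() for c in self.chains])


def _invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _prepare_phylo(cov: PhyloCovariance):
    lam, Q = np.linalg.eigh(cov.matrix)
    lam = np.clip(lam, 1e-10, None)  # tolerate numerically singular trees
    return lam, Q


def _check_inputs(spec: ModelSpec, table: pd.DataFrame, cov: PhyloCovariance):
    if spec.response not in table.columns:
        raise ValueError(f"response column {spec.response!r} missing from table")
    if list(cov.taxa) != list(table["species_id"]):
        raise ValueError("phylogenetic matrix taxa do not match the table order; "
                         "use phylo.match_taxa first")
    if spec.mev is not None:
        v = table[spec.mev].to_numpy(float)
        if not np.all(v > 0):
            raise ValueError(f"mev column {spec.mev!r} must be strictly positive")


def fit(spec: ModelSpec, table: pd.DataFrame, cov: PhyloCovariance,
        settings: MCMCSettings = TEST_SETTINGS) -> ChainSet:
    """Fit a model by MCMC, dispatching on the response family."""
    if spec.family == "gaussian":
        return fit_gaussian(spec, table, cov, settings)
    return fit_binomial(spec, table, cov, settings)


def _run_chains(n_chains: int, seed: int, runner) -> tuple:
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             np.random.SeedSequence(seed).spawn(n_chains)]
    results = [runner(s) for s in seeds]
    return seeds, results


def fit_gaussian(spec: ModelSpec, table: pd.DataFrame, cov: PhyloCovariance,
                 settings: MCMCSettings = TEST_SETTINGS) -> ChainSet:
    """Gibbs sampler for the Gaussian measurement-error hierarchy."""
    _check_inputs(spec, table, cov)
    design = build_design(table, spec.fixed_terms, spec.reference_levels)
    X, names = design.matrix, design.names
    y = table[spec.response].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(f"response {spec.response!r} contains missing values")
    v = table[spec.mev].to_numpy(float) if spec.mev else None
    n, p = X.shape
    lam, Q = _prepare_phylo(cov)
    XtX = X.T @ X
    shape0, rate0 = settings.prior_nu / 2.0, settings.prior_nu * settings.prior_V / 2.0
    B = settings.prior_fixed_variance
    fix_p, fix_r = settings.fix_sigma2_phylo, settings.fix_sigma2_resid

    if fix_r == 0.0 and v is None:
        raise ValueError("residual variance fixed at zero with no mev leaves a "
                         "degenerate (noise-free) likelihood")

    def run(chain_seed: int):
        rng = np.random.default_rng(chain_seed)
        s2r = float(fix_r) if fix_r is not None else max(np.var(y) / 2.0, 1e-4)
        s2p = float(fix_p) if fix_p is not None else max(np.var(y) / 2.0, 1e-4)
        beta = np.zeros(p)
        at = np.zeros(n)          # phylo effects in the eigenbasis of A
        m = np.zeros(n)
        a = np.zeros(n)
        rows = np.empty((settings.n_draws, p + 2))
        a_accum = np.zeros(n)
        kept = 0
        for it in range(1, settings.iterations + 1):
            # ---- fixed effects -------------------------------------------
            if s2r > 0:
                z = y - m - a
                P = XtX / s2r + np.eye(p) / B
                rhs = X.T @ z / s2r
            else:
                # residual fixed at 0: integrate the mev latents out and
                # weight directly by the known sampling variances
                z = y - a
                Xw = X / v[:, None]
                P = X.T @ Xw + np.eye(p) / B
                rhs = Xw.T @ z
            L = np.linalg.cholesky(P)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            xb = X @ beta
            # ---- phylogenetic effects ------------------------------------
            if s2p > 0:
                if s2r > 0:
                    z = y - m - xb
                    zt = Q.T @ z
                    prec = 1.0 / s2r + 1.0 / (lam * s2p)
                    at = zt / (s2r * prec) + rng.standard_normal(n) / np.sqrt(prec)
                    a = Q @ at
                else:  # mev latents integrated out, heteroscedastic noise
                    z = y - xb
                    Ainv = (Q / lam) @ Q.T
                    P = Ainv / s2p + np.diag(1.0 / v)
                    L = np.linalg.cholesky(P)
                    mu = np.linalg.solve(L.T, np.linalg.solve(L, z / v))
                    a = mu + np.linalg.solve(L.T, rng.standard_normal(n))
                    at = Q.T @ a
            else:
                at = np.zeros(n)
                a = np.zeros(n)
            # ---- measurement-error effects -------------------------------
            if v is not None and s2r > 0:
                s = y - xb - a
                w = v / (v + s2r)
                m = s * w + rng.standard_normal(n) * np.sqrt(v * s2r / (v + s2r))
            # ---- variance components -------------------------------------
            if fix_r is None:
                e = y - m - xb - a
                s2r = _invgamma(rng, shape0 + n / 2.0, rate0 + e @ e / 2.0)
            if fix_p is None:
                quad = float(np.sum(at * at / lam))
                s2p = _invgamma(rng, shape0 + n / 2.0, rate0 + quad / 2.0)
            if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                rows[kept, :p] = beta
                rows[kept, p] = s2p
                rows[kept, p + 1] = s2r
                a_accum += a
                kept += 1
        df = pd.DataFrame(rows, columns=names + ["sigma2_phylo", "sigma2_resid"])
        return df, a_accum / max(kept, 1)

    seeds, results = _run_chains(settings.n_chains, settings.seed, run)
    return ChainSet(
        spec=spec, design=design, settings=settings,
        chains=[r[0] for r in results], seeds=seeds, mev=v, response=y,
        a_means=[r[1] for r in results], taxa=list(cov.taxa),
    )


def fit_binomial(spec: ModelSpec, table: pd.DataFrame, cov: PhyloCovariance,
                 settings: MCMCSettings = TEST_SETTINGS) -> ChainSet:
    """Latent-liability sampler for binomial (logit link) responses."""
    _check_inputs(spec, table, cov)
    design = build_design(table, spec.fixed_terms, spec.reference_levels)
    X, names = design.matrix, design.names
    y = table[spec.response].to_numpy(float)
    ntr = table[spec.trials].to_numpy(float)
    if np.any(ntr <= 0) or np.any(ntr != np.round(ntr)):
        raise ValueError("trials must be positive integers")
    if np.any(y < 0) or np.any(y > ntr):
        raise ValueError("successes must lie in [0, trials]")
    import warnings as _w
    if np.all(y == 0) or np.all(y == ntr):
        _w.warn("all responses at the same boundary: the intercept is only "
                "weakly identified (separation); expect a diffuse posterior")
    n, p = X.shape
    lam, Q = _prepare_phylo(cov)
    XtX = X.T @ X
    shape0, rate0 = settings.prior_nu / 2.0, settings.prior_nu * settings.prior_V / 2.0
    B = settings.prior_fixed_variance
    s2r = settings.binomial_residual_fix
    if s2r <= 0:
        raise ValueError("binomial_residual_fix must be positive")
    fix_p = settings.fix_sigma2_phylo

    emp = np.clip((y + 0.5) / (ntr + 1.0), 1e-4, 1 - 1e-4)
    l_init = np.log(emp / (1 - emp))

    def run(chain_seed: int):
        rng = np.random.default_rng(chain_seed)
        s2p = float(fix_p) if fix_p is not None else 0.5
        beta = np.zeros(p)
        at = np.zeros(n)
        a = np.zeros(n)
        l = l_init.copy()
        scale = np.full(n, 1.0)
        acc_win = np.zeros(n)
        acc_total = np.zeros(n)
        rows = np.empty((settings.n_draws, p + 2))
        a_accum = np.zeros(n)
        l_accum = np.zeros(n)
        kept = 0
        for it in range(1, settings.iterations + 1):
            xb = X @ beta
            mu = xb + a
            # ---- liabilities: vectorized univariate Metropolis -----------
            prop = l + scale * rng.standard_normal(n)
            def loglik(u):
                return y * u - ntr * np.logaddexp(0.0, u) - (u - mu) ** 2 / (2 * s2r)
            log_ratio = loglik(prop) - loglik(l)
            accept = np.log(rng.random(n)) < log_ratio
            l = np.where(accept, prop, l)
            acc_win += accept
            acc_total += accept
            if it <= settings.burn_in and it % 50 == 0:
                scale *= np.exp((acc_win / 50.0 - 0.44))
                scale = np.clip(scale, 1e-3, 50.0)
                acc_win[:] = 0.0
            # ---- fixed effects -------------------------------------------
            z = l - a
            P = XtX / s2r + np.eye(p) / B
            L = np.linalg.cholesky(P)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, X.T @ z / s2r))
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            # ---- phylogenetic effects ------------------------------------
            if s2p > 0:
                zt = Q.T @ (l - X @ beta)
                prec = 1.0 / s2r + 1.0 / (lam * s2p)
                at = zt / (s2r * prec) + rng.standard_normal(n) / np.sqrt(prec)
                a = Q @ at
            if fix_p is None:
                quad = float(np.sum(at * at / lam))
                s2p = _invgamma(rng, shape0 + n / 2.0, rate0 + quad / 2.0)
            if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                rows[kept, :p] = beta
                rows[kept, p] = s2p
                rows[kept, p + 1] = s2r
                a_accum += a
                l_accum += l
                kept += 1
        df = pd.DataFrame(rows, columns=names + ["sigma2_phylo", "sigma2_resid"])
        return df, a_accum / max(kept, 1), l_accum / max(kept, 1), acc_total / settings.iterations

    seeds, results = _run_chains(settings.n_chains, settings.seed, run)
    return ChainSet(
        spec=spec, design=design, settings=settings,
        chains=[r[0] for r in results], seeds=seeds, mev=None, response=y,
        a_means=[r[1] for r in results],
        liability_means=[r[2] for r in results],
        accept_rates=[r[3] for r in results], taxa=list(cov.taxa),
    )


# --------------------------------------------------------------------------
# posterior summaries and diagnostics


def _resolve_draws(chains: ChainSet, quantity, chain: Optional[int]) -> np.ndarray:
    if isinstance(quantity, str):
        if quantity not in chains.param_names:
            raise KeyError(
                f"unknown quantity {quantity!r}; available: {chains.param_names}"
            )
        return chains.draws(quantity, chain=chain)
    return np.asarray(quantity, dtype=float)


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(draws, float)
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    # sum consecutive pairs; stop when a pair sum goes non-positive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / tau))


def summarize(chains: Union[ChainSet, np.ndarray], quantity=None, test_value: float = 0.0,
              chain: Optional[int] = None) -> PosteriorSummary:
    """Summarize one quantity: PM, equal-tail 95% CI, pMCMC, ESS.

    ``quantity`` is a sampled parameter name or an array of draws (for
    contrasts and other linear combinations computed from raw draws).
    pMCMC is twice the smaller tail proportion relative to ``test_value``,
    floored at 2/N so it is never exactly zero.
    """
    if isinstance(chains, ChainSet):
        d = _resolve_draws(chains, quantity, chain)
        psrf = None
        if chain is None and isinstance(quantity, str) and len(chains.chains) >= 2:
            psrf = gelman_rubin(chains)[quantity]
    else:
        d = np.asarray(chains, float)
        psrf = None
    N = d.size
    above = int(np.sum(d > test_value))
    below = int(np.sum(d < test_value))
    pmcmc = min(1.0, 2.0 * max(1, min(above, below)) / N)
    lo, hi = np.percentile(d, [2.5, 97.5])
    return PosteriorSummary(
        pm=float(d.mean()), ci_lower=float(lo), ci_upper=float(hi),
        pmcmc=float(pmcmc), ess=effective_sample_size(d), n_draws=N, psrf=psrf,
    )


def gelman_rubin(chains: ChainSet, params: Optional[Sequence[str]] = None) -> dict:
    """Potential scale reduction factor (PSRF) per parameter.

    Classic Gelman-Rubin: with m chains of n draws, W the mean within-chain
    variance and B/n the variance of the chain means, the PSRF is
    sqrt(((n-1)/n * W + B/n) / W).
    """
    if len(chains.chains) < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    params = list(params) if params is not None else chains.param_names
    out = {}
    for name in params:
        per = np.vstack([c[name].to_numpy() for c in chains.chains])
        m, n = per.shape
        W = per.var(axis=1, ddof=1).mean()
        Bn = per.mean(axis=1).var(ddof=1)  # = B / n
        if W <= 0:
            out[name] = 1.0
            continue
        out[name] = float(math.sqrt(((n - 1) / n * W + Bn) / W))
    return out


def higgins_sigma2_m(v: np.ndarray, method: str = "higgins") -> float:
    """Typical within-study (measurement-error) variance of a meta-analysis.

    The default is the Higgins "typical" sampling variance
    sigma2_m = (k-1) * sum(w) / (sum(w)^2 - sum(w^2)) with weights w = 1/v;
    ``method="mean"`` returns the plain mean of the variances instead.
    """
    v = np.asarray(v, float)
    if method == "mean":
        return float(v.mean())
    if method != "higgins":
        raise ValueError(f"unknown sigma2_m method {method!r}")
    w = 1.0 / v
    k = v.size
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w ** 2).sum()))


def heterogeneity(chains: ChainSet, mev: Optional[np.ndarray] = None,
                  method: str = "higgins", chain: Optional[int] = None) -> HeterogeneityReport:
    """Phylogenetic heritability and total heterogeneity, draw by draw.

    H2 = s2_phylo / (s2_phylo + s2_resid) and
    I2_total = (s2_phylo + s2_resid) / (s2_phylo + s2_resid + s2_m),
    with s2_m the typical measurement-error variance of the mev column.
    """
    if mev is None:
        mev = chains.mev
    if mev is None:
        raise ValueError("heterogeneity requires the measurement-error variances (mev)")
    s2m = higgins_sigma2_m(np.asarray(mev, float), method=method)
    s2p = _resolve_draws(chains, "sigma2_phylo", chain)
    s2r = _resolve_draws(chains, "sigma2_resid", chain)
    h2 = s2p / (s2p + s2r)
    i2 = (s2p + s2r) / (s2p + s2r + s2m)
    return HeterogeneityReport(
        h2=summarize(h2, test_value=0.5), i2_total=summarize(i2, test_value=0.5),
        sigma_m2=s2m,
    )


def r2_marginal(chains: ChainSet, chain: Optional[int] = None) -> PosteriorSummary:
    """Proportion of variance explained by the fixed effects, per draw:
    var(X beta) / (var(X beta) + sigma2_phylo + sigma2_resid)."""
    X = chains.design.matrix
    if X.shape[1] == 1:
        s = summarize(np.zeros(1), test_value=0.5)
        s.pm, s.ci_lower, s.ci_upper = 0.0, 0.0, 0.0
        s.note = "intercept-only model: marginal R2 is 0 by convention"
        return s
    betas = chains.beta_draws(chain=chain)
    s2p = _resolve_draws(chains, "sigma2_phylo", chain)
    s2r = _resolve_draws(chains, "sigma2_resid", chain)
    fitted = betas @ X.T
    vf = fitted.var(axis=1, ddof=1)
    r2 = vf / (vf + s2p + s2r)
    return summarize(r2, test_value=0.0)
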