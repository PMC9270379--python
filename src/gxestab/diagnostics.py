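"""MCMC convergence diagnostics, DIC-based prior comparison, and k-fold
cross-validated predictive correlation.

Geweke's diagnostic compares the mean of an early chain window (default the
first 10%) with a late window (the last 50%) through a z-statistic whose
standard errors come from the spectral density at frequency zero, so
autocorrelation in the chain is accounted for.  |z| < 1.96 passes at the 5%
level.

The Deviance Information Criterion is the standard

    DIC = D(theta_hat) + 2 p_D = D_bar + p_D,

with D(theta) = −2 log L, D_bar the posterior mean deviance, D(theta_hat)
the deviance at the posterior means of (beta0, beta1, beta2, sigma2), and
p_D = D_bar − D(theta_hat) the effective number of parameters.  Two priors
whose DICs differ by less than 2 are treated as equivalent and the vaguer
one kept.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biseg import (
    BayesianBisegmented,
    BayesianBisegmentedResults,
    McmcSettings,
    PosteriorChains,
    PriorSpec,
    log_likelihood,
)
from .env_index import BisegmentedDesign

__all__ = [
    "GewekeResult",
    "DicResult",
    "CvResult",
    "geweke",
    "geweke_table",
    "trace_summary",
    "TraceSummary",
    "dic",
    "total_dic",
    "compare_priors",
    "PriorComparison",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# Geweke
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GewekeResult:
    z: float
    first: float
    last: float
    passed: bool  # |z| < 1.96


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-tapered lag-window
    autocovariance estimator, window length 4·(n/100)^(1/3)."""
    n = x.size
    x = x - x.mean()
    gamma0 = float(x @ x) / n
    L = max(int(4.0 * (n / 100.0) ** (1.0 / 3.0)), 1)
    L = min(L, n - 1)
    s0 = gamma0
    for k in range(1, L + 1):
        gk = float(x[:-k] @ x[k:]) / n
        s0 += 2.0 * (1.0 - k / (L + 1.0)) * gk
    return max(s0, 1e-300)


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> GewekeResult:
    """Geweke convergence z-score for one chain of one parameter.

    z = (mean_first − mean_last) / sqrt(se²_first + se²_last) with the
    standard errors estimated from the spectral density at zero of each
    window.  Windows must not overlap.
    """
    chain = np.asarray(chain, dtype=float).ravel()
    n = chain.size
    if n < 100:
        raise ValueError("Geweke diagnostic needs a chain of length >= 100")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("window fractions must lie in (0,1) and not overlap")
    if np.ptp(chain) == 0:
        raise ValueError("constant chain: Geweke z is undefined")
    n1 = int(np.floor(first * n))
    n2 = int(np.floor(last * n))
    a, b = chain[:n1], chain[n - n2:]
    se2 = _spectrum0(a) / n1 + _spectrum0(b) / n2
    z = float((a.mean() - b.mean()) / np.sqrt(se2))
    return GewekeResult(z=z, first=first, last=last, passed=abs(z) < 1.96)


def geweke_table(chains: PosteriorChains, first: float = 0.1, last: float = 0.5) -> pd.DataFrame:
    """Geweke z per (genotype, parameter, chain) for a whole panel."""
    records = []
    for gi, genotype in enumerate(chains.genotypes):
        for param in ("beta0", "beta1", "beta2", "tau"):
            arr = chains.parameter(param, genotype)
            for ci in range(arr.shape[0]):
                try:
                    res = geweke(arr[ci], first, last)
                    z, passed = res.z, res.passed
                except ValueError:
                    z, passed = np.nan, True  # constant chain (pinned parameter)
                records.append(
                    {
                        "genotype": genotype,
                        "parameter": param,
                        "chain": ci + 1,
                        "z": z,
                        "passed": passed,
                    }
                )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# trace summaries (visual-convergence export)
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TraceSummary:
    """Running posterior means per chain, for visual convergence checks.

    ``running_means`` has shape (genotypes, chains, kept, params);
    ``final_spread`` is the between-chain standard deviation of the final
    running mean, shape (genotypes, params).
    """

    running_means: np.ndarray
    final_spread: np.ndarray
    genotypes: tuple[str, ...]
    parameters: tuple[str, ...] = ("beta0", "beta1", "beta2", "tau")

    def to_frame(self) -> pd.DataFrame:
        g, c, n, p = self.running_means.shape
        gi, ci, ni, pi = np.meshgrid(range(g), range(c), range(n), range(p), indexing="ij")
        return pd.DataFrame(
            {
                "genotype": np.array(self.genotypes)[gi.ravel()],
                "chain": ci.ravel() + 1,
                "iteration": ni.ravel() + 1,
                "parameter": np.array(self.parameters)[pi.ravel()],
                "running_mean": self.running_means.ravel(),
            }
        )


def trace_summary(chains: PosteriorChains) -> TraceSummary:
    """Running-mean series of every chain (burn-in already discarded)."""
    if chains.n_chains < 2:
        raise ValueError("trace summary needs at least 2 chains")
    counts = np.arange(1, chains.n_kept + 1)[None, None, :, None]
    running = np.cumsum(chains.draws, axis=2) / counts
    spread = running[:, :, -1, :].std(axis=1, ddof=1)
    return TraceSummary(running_means=running, final_spread=spread, genotypes=chains.genotypes)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DicResult:
    d_bar: float    # posterior mean deviance
    d_hat: float    # deviance at posterior means
    p_d: float      # effective number of parameters
    dic: float


def _deviance_draws(draws: np.ndarray, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Deviance −2 log L at every draw; draws (K, 4) with tau in column 3."""
    beta = draws[:, :3]
    sigma2 = 1.0 / draws[:, 3]
    resid = y[None, :] - beta @ X.T
    n = y.size
    sse = (resid**2).sum(axis=1)
    return n * np.log(2.0 * np.pi * sigma2) + sse / sigma2


def dic(
    chains: PosteriorChains,
    y: np.ndarray,
    index: np.ndarray,
    t_values: np.ndarray,
    genotype: str | None = None,
) -> DicResult:
    """DIC for one genotype's data under its posterior draws."""
    genotype = genotype if genotype is not None else chains.genotypes[0]
    gi = chains.genotypes.index(genotype)
    flat = chains.draws[gi].reshape(-1, 4)
    y = np.asarray(y, dtype=float)
    X = np.column_stack(
        [np.ones_like(np.asarray(index, dtype=float)), index, t_values]
    )
    dev = _deviance_draws(flat, y, X)
    if not np.isfinite(dev).all():
        bad = np.flatnonzero(~np.isfinite(dev))
        raise ValueError(f"non-finite deviance at draws {bad[:10].tolist()}...")
    d_bar = float(dev.mean())
    post = flat[:, :3].mean(axis=0)
    sigma2_hat = float((1.0 / flat[:, 3]).mean())
    d_hat = -2.0 * log_likelihood(y, index, t_values, (*post, sigma2_hat))
    p_d = d_bar - d_hat
    return DicResult(d_bar=d_bar, d_hat=d_hat, p_d=p_d, dic=d_hat + 2.0 * p_d)


def total_dic(results: BayesianBisegmentedResults) -> DicResult:
    """Panel-level DIC: genotype-wise DICs summed (independent likelihoods)."""
    model = results.model
    parts = [
        dic(results.chains, model.Y[i], model.index, model.t_values, genotype=g)
        for i, g in enumerate(results.chains.genotypes)
    ]
    d_bar = sum(p.d_bar for p in parts)
    d_hat = sum(p.d_hat for p in parts)
    p_d = d_bar - d_hat
    return DicResult(d_bar=d_bar, d_hat=d_hat, p_d=p_d, dic=d_hat + 2.0 * p_d)


@dataclasses.dataclass(frozen=True)
class PriorComparison:
    """Outcome of DIC comparison across candidate priors.

    ``selected`` is the lowest-DIC model, unless contenders lie within
    ``threshold`` of the minimum — then they are ``equivalent`` and the
    earliest-listed (vaguest, by the caller's ordering) is kept.
    """

    dics: dict[str, float]
    selected: str
    equivalent: tuple[str, ...]
    threshold: float

    @property
    def no_increment(self) -> bool:
        return len(self.equivalent) > 1


def compare_priors(
    dic_results: Mapping[str, DicResult | float], threshold: float = 2.0
) -> PriorComparison:
    """Select among prior models by lowest DIC with the |Δ| < threshold
    equivalence rule.  List candidates from vaguest to most informative:
    on a tie the earliest equivalent entry is kept."""
    if len(dic_results) < 1:
        raise ValueError("need at least one model")
    values = {
        k: (v.dic if isinstance(v, DicResult) else float(v)) for k, v in dic_results.items()
    }
    best = min(values.values())
    equivalent = tuple(k for k, v in values.items() if abs(v - best) < threshold)
    selected = equivalent[0]
    return PriorComparison(
        dics=values, selected=selected, equivalent=equivalent, threshold=threshold
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def fold_assignments(n_genotypes: int, n_obs: int, n_folds: int, seed: int) -> np.ndarray:
    """Genotype-stratified fold labels, shape (n_genotypes, n_obs): each
    genotype's observations are shuffled and dealt round-robin from a random
    starting fold, so per-genotype fold sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty((n_genotypes, n_obs), dtype=int)
    for i in range(n_genotypes):
        perm = rng.permutation(n_obs)
        start = int(rng.integers(n_folds))
        fold_of[i, perm] = (start + np.arange(n_obs)) % n_folds
    return fold_of


@dataclasses.dataclass(frozen=True)
class CvResult:
    n_folds: int
    fold_correlations: np.ndarray
    mean_correlation: float


def cross_validate(
    table,
    design: BisegmentedDesign,
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> CvResult:
    """k-fold cross-validated predictive correlation of the Bayesian fit.

    Replicate-level observations are partitioned at random into ``n_folds``
    folds, stratified by genotype (each genotype's observations are dealt
    round-robin after an in-genotype shuffle), so every genotype appears in
    every training set.  Per fold, each genotype is refit on its training
    observations and its held-out observations predicted from the
    posterior-mean coefficients; the per-fold Pearson correlation between
    predictions and held-out yields is reported along with the average.
    """
    settings = settings if settings is not None else McmcSettings()
    Y, layout = table.observation_matrix()
    idx, t = design.expand(layout["environment"])
    g, n = Y.shape
    if n < n_folds:
        raise ValueError("need at least n_folds observations per genotype")
    fold_of = fold_assignments(g, n, n_folds, seed)

    fold_corr = np.full(n_folds, np.nan)
    for fold in range(n_folds):
        preds, obs = [], []
        for i in range(g):
            test = fold_of[i] == fold
            train = ~test
            if not test.any():
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = BayesianBisegmented(
                        Y[i, train], idx[train], t[train], prior=prior
                    )
                res = model.fit(
                    dataclasses.replace(settings, seed=settings.seed + 1000 * fold + i)
                )
            except ValueError:
                warnings.warn(
                    f"fold {fold}: genotype {table.genotypes[i]} unfittable on"
                    " its training observations; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            preds.append(res.predict(idx[test], t[test]))
            obs.append(Y[i, test])
        preds = np.concatenate(preds)
        obs = np.concatenate(obs)
        if preds.size >= 2 and np.ptp(preds) > 0 and np.ptp(obs) > 0:
            fold_corr[fold] = float(np.corrcoef(preds, obs)[0, 1])
    return CvResult(
        n_folds=n_folds,
        fold_correlations=fold_corr,
        mean_correlation=float(np.nanmean(fold_corr)),
    )
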