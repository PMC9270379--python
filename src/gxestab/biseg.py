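"""Bisegmented (two-regime) regression of genotype yield on the coded
environmental index — frequentist and Bayesian.

Model per genotype i:

    y_ij = beta_i0 + beta_i1 * I_j + beta_i2 * T(I_j) + e_ij,
    e_ij ~ N(0, sigma2_ie)

beta_i0 is the genotype's mean response, beta_i1 its slope in unfavorable
environments (I_j <= 0) and beta_i1 + beta_i2 its slope in favorable ones.
The Bayesian fit places independent normal priors on the betas and a Gamma
prior on the precision tau_ie = 1/sigma2_ie; the posterior is then fully
conjugate and is sampled with a component-wise Gibbs sampler whose full
conditionals are available in closed form (normal for each beta by
completing the square, Gamma(alpha + n/2, beta + SSE/2) for tau).  Each
genotype is fit independently with its own residual variance; when all
genotypes share the design the sampler vectorises across them.

The stability statistic is sigma2_di = sigma2_ie − MSR/r (MSR the joint-ANOVA
residual mean square, r the replication count), applied draw-wise so the
posterior of the stability parameter comes for free.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .env_index import BisegmentedDesign

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "PosteriorChains",
    "BisegmentedOLS",
    "BisegmentedOLSResults",
    "BayesianBisegmented",
    "BayesianBisegmentedResults",
    "log_likelihood",
    "stability_draws",
    "r_squared",
]

PARAM_NAMES = ("beta0", "beta1", "beta2", "tau")


# ---------------------------------------------------------------------------
# priors and sampler settings
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the conjugate prior.

    ``beta_mean``/``beta_var`` hold the normal prior mean and variance for
    (beta0, beta1, beta2); ``tau_shape``/``tau_rate`` the Gamma prior on the
    precision (mean shape/rate, variance shape/rate²).  Each entry may be a
    scalar (shared by all genotypes) or an array with one row per genotype.
    """

    beta_mean: np.ndarray
    beta_var: np.ndarray
    tau_shape: float | np.ndarray
    tau_rate: float | np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_mean", np.asarray(self.beta_mean, dtype=float))
        object.__setattr__(self, "beta_var", np.asarray(self.beta_var, dtype=float))
        if self.beta_mean.shape[-1] != 3 or self.beta_var.shape[-1] != 3:
            raise ValueError("beta_mean and beta_var must have 3 entries per genotype")
        if (self.beta_var <= 0).any():
            raise ValueError("prior variances must be positive")
        if np.any(np.asarray(self.tau_shape) <= 0) or np.any(np.asarray(self.tau_rate) <= 0):
            raise ValueError("Gamma shape and rate must be positive")

    @classmethod
    def vague(cls) -> "PriorSpec":
        """The minimally informative prior: N(0, 100000) on every beta and
        Gamma(0.001, 0.001) on the precision (prior mean tau = 1)."""
        return cls(
            beta_mean=np.zeros(3),
            beta_var=np.full(3, 100_000.0),
            tau_shape=0.001,
            tau_rate=0.001,
        )

    @classmethod
    def from_frequentist(
        cls,
        estimates: np.ndarray,
        standard_errors: np.ndarray,
        residual_ms: float | np.ndarray,
        inflation: float = 10.0,
    ) -> "PriorSpec":
        """Elicit a prior from earlier frequentist bisegmented fits.

        Prior means are the earlier point estimates; prior variances are the
        squared standard errors times ``inflation`` (default 10 — centered on
        past data without letting it dominate the likelihood).  The precision
        prior is moment-matched so that its mean is 1/residual_ms and its
        relative variance is widened by the same factor:
        shape = 1/inflation, rate = residual_ms/inflation.
        """
        estimates = np.asarray(estimates, dtype=float)
        standard_errors = np.asarray(standard_errors, dtype=float)
        residual_ms = np.asarray(residual_ms, dtype=float)
        if not (
            np.isfinite(estimates).all()
            and np.isfinite(standard_errors).all()
            and np.isfinite(residual_ms).all()
        ):
            raise ValueError("elicitation inputs must be finite")
        if inflation <= 0:
            raise ValueError("inflation must be positive")
        shape = np.broadcast_to(1.0 / inflation, residual_ms.shape).copy()
        rate = residual_ms / inflation
        return cls(
            beta_mean=estimates,
            beta_var=standard_errors**2 * inflation,
            tau_shape=float(shape) if shape.ndim == 0 else shape,
            tau_rate=float(rate) if rate.ndim == 0 else rate,
        )

    def per_genotype(self, n_genotypes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Broadcast hyperparameters to per-genotype arrays."""
        bm = np.broadcast_to(np.atleast_2d(self.beta_mean), (n_genotypes, 3)).copy()
        bv = np.broadcast_to(np.atleast_2d(self.beta_var), (n_genotypes, 3)).copy()
        ts = np.broadcast_to(np.asarray(self.tau_shape, dtype=float), (n_genotypes,)).copy()
        tr = np.broadcast_to(np.asarray(self.tau_rate, dtype=float), (n_genotypes,)).copy()
        return bm, bv, ts, tr


@dataclasses.dataclass(frozen=True)
class McmcSettings:
    """Gibbs sampling protocol: chains, total iterations, burn-in, thinning.

    Defaults follow the study protocol (4 chains of 100,000 iterations,
    burn-in 10,000, thin 4); tests and quick runs pass smaller values.
    """

    n_chains: int = 4
    n_iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return len(range(self.burn_in, self.n_iterations, self.thin))


# ---------------------------------------------------------------------------
# chain container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PosteriorChains:
    """MCMC draws for (beta0, beta1, beta2, tau) per genotype.

    ``draws`` has shape (n_genotypes, n_chains, n_kept, 4); sigma2 = 1/tau
    is a derived view.
    """

    draws: np.ndarray
    genotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 4 or self.draws.shape[-1] != len(PARAM_NAMES):
            raise ValueError("draws must have shape (genotypes, chains, iterations, 4)")
        if self.draws.shape[0] != len(self.genotypes):
            raise ValueError("genotype labels do not match draws")
        if not np.isfinite(self.draws).all():
            raise ValueError("draws must be finite")
        if (self.draws[..., PARAM_NAMES.index("tau")] <= 0).any():
            raise ValueError("tau draws must be positive")

    @property
    def n_genotypes(self) -> int:
        return self.draws.shape[0]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[1]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[2]

    def parameter(self, name: str, genotype: str | None = None) -> np.ndarray:
        """Draws for one parameter: (chains, kept) for one genotype, or
        (genotypes, chains, kept) for all.  ``sigma2`` is accepted."""
        if name == "sigma2":
            arr = 1.0 / self.draws[..., PARAM_NAMES.index("tau")]
        else:
            arr = self.draws[..., PARAM_NAMES.index(name)]
        if genotype is None:
            return arr
        return arr[self.genotypes.index(genotype)]

    @property
    def sigma2(self) -> np.ndarray:
        return 1.0 / self.draws[..., PARAM_NAMES.index("tau")]

    def to_frame(self) -> pd.DataFrame:
        g, c, n, p = self.draws.shape
        gi, ci, ni, pi = np.meshgrid(range(g), range(c), range(n), range(p), indexing="ij")
        return pd.DataFrame(
            {
                "genotype": np.array(self.genotypes)[gi.ravel()],
                "chain": ci.ravel() + 1,
                "iteration": ni.ravel() + 1,
                "parameter": np.array(PARAM_NAMES)[pi.ravel()],
                "value": self.draws.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorChains":
        genotypes = tuple(pd.unique(df["genotype"]).astype(str))
        g = len(genotypes)
        chains = np.sort(df["chain"].unique())
        iters = np.sort(df["iteration"].unique())
        pivot = df.pivot_table(
            index=["genotype", "chain", "iteration"],
            columns="parameter",
            values="value",
            aggfunc="first",
        )
        pivot = pivot.reindex(
            pd.MultiIndex.from_product([genotypes, chains, iters]), columns=list(PARAM_NAMES)
        )
        draws = pivot.to_numpy(dtype=float).reshape(g, len(chains), len(iters), len(PARAM_NAMES))
        return cls(draws=draws, genotypes=genotypes)


# ---------------------------------------------------------------------------
# likelihood and derived statistics
# ---------------------------------------------------------------------------


def _hinge_identifiable(index: np.ndarray, t_values: np.ndarray) -> bool:
    """beta2 is identified iff the hinge column varies over the favorable
    points and is not collinear with (1, I) — which requires at least two
    distinct favorable design points and at least one unfavorable one."""
    favorable = np.asarray(index) > 0
    return bool(
        np.unique(np.asarray(t_values)[favorable]).size >= 2 and (~favorable).any()
    )


def _design_matrix(index: np.ndarray, t_values: np.ndarray, drop_hinge: bool = False) -> np.ndarray:
    index = np.asarray(index, dtype=float)
    t_values = np.asarray(t_values, dtype=float)
    cols = [np.ones_like(index), index]
    if not drop_hinge:
        cols.append(t_values)
    return np.column_stack(cols)


def log_likelihood(
    y: np.ndarray,
    index: np.ndarray,
    t_values: np.ndarray,
    params: Sequence[float],
) -> float:
    """Gaussian log-likelihood of one genotype's observations.

    ``params`` is (beta0, beta1, beta2, sigma2); the mean is
    beta0 + beta1*I_j for I_j <= 0 and beta0 + beta1*I_j + beta2*T_j above.
    """
    beta0, beta1, beta2, sigma2 = (float(p) for p in params)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    y = np.asarray(y, dtype=float)
    if y.size < 1:
        raise ValueError("need at least one observation")
    index = np.asarray(index, dtype=float)
    t_values = np.asarray(t_values, dtype=float)
    mean = beta0 + beta1 * index + beta2 * t_values
    resid = y - mean
    n = y.size
    return float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * (resid**2).sum() / sigma2)


def predict_mean(index, t_values, beta0, beta1, beta2):
    """Bisegmented regression mean at the given design points."""
    return beta0 + beta1 * np.asarray(index, dtype=float) + beta2 * np.asarray(t_values, dtype=float)


def stability_draws(sigma2_draws: np.ndarray, msr: float, r: int) -> np.ndarray:
    """Draw-wise stability statistic sigma2_di = sigma2_ie − MSR/r.

    Small or negative values mean a stable (predictable) genotype; raw
    negative values are kept as-is.
    """
    if msr < 0:
        raise ValueError("msr must be nonnegative")
    if r < 1:
        raise ValueError("r must be >= 1")
    return np.asarray(sigma2_draws, dtype=float) - msr / r


def r_squared(y: np.ndarray, index: np.ndarray, t_values: np.ndarray, params) -> float:
    """Coefficient of determination 1 − SSE/SST at the given (typically
    posterior-mean) parameters.  Raw value (may be < 0 for a bad model);
    NaN when SST is zero."""
    y = np.asarray(y, dtype=float)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    mean = predict_mean(index, t_values, params[0], params[1], params[2])
    sse = float(((y - mean) ** 2).sum())
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# frequentist fit
# ---------------------------------------------------------------------------


class BisegmentedOLS:
    """Ordinary least squares on the two-column hinge design.

    Used both on its own (the classical adaptability/stability fit) and to
    elicit informative priors for the Bayesian model.  ``y``, ``index`` and
    ``t_values`` are observation-level arrays of equal length.
    """

    def __init__(self, y, index, t_values, name: str = "genotype"):
        self.y = np.asarray(y, dtype=float)
        self.index = np.asarray(index, dtype=float)
        self.t_values = np.asarray(t_values, dtype=float)
        if not (self.y.shape == self.index.shape == self.t_values.shape):
            raise ValueError("y, index and t_values must have equal length")
        if not np.isfinite(self.y).all():
            raise ValueError("y must be finite")
        self.name = name
        self.drop_hinge = not _hinge_identifiable(self.index, self.t_values)
        self.exog = _design_matrix(self.index, self.t_values, self.drop_hinge)

    @classmethod
    def from_design(cls, y, design: BisegmentedDesign, environments, name="genotype"):
        idx, t = design.expand(environments)
        return cls(y, idx, t, name=name)

    def fit(self, confidence: float = 0.95) -> "BisegmentedOLSResults":
        n, p = self.exog.shape
        if n <= p:
            raise ValueError(f"need more than {p} observations to fit")
        if self.drop_hinge:
            warnings.warn(
                f"{self.name}: hinge column is rank-deficient; fitting a"
                " single-slope model (beta2 fixed at 0)",
                UserWarning,
                stacklevel=2,
            )
        res = sm.OLS(self.y, self.exog).fit()
        params = np.zeros(3)
        bse = np.full(3, np.nan)
        ci = np.full((3, 2), np.nan)
        raw_ci = res.conf_int(alpha=1.0 - confidence)
        k = 2 if self.drop_hinge else 3
        params[:k] = res.params
        bse[:k] = res.bse
        ci[:k] = np.asarray(raw_ci)
        return BisegmentedOLSResults(
            model=self,
            params=params,
            bse=bse,
            conf_int=ci,
            confidence=confidence,
            mse_resid=float(res.mse_resid),
            rsquared=float(res.rsquared) if np.isfinite(res.rsquared) else float("nan"),
            df_resid=int(res.df_resid),
        )


@dataclasses.dataclass(frozen=True)
class BisegmentedOLSResults:
    """Point estimates, t-based confidence intervals and residual mean
    square of the frequentist bisegmented fit."""

    model: BisegmentedOLS
    params: np.ndarray      # (beta0, beta1, beta2)
    bse: np.ndarray
    conf_int: np.ndarray    # (3, 2)
    confidence: float
    mse_resid: float
    rsquared: float
    df_resid: int

    def predict(self, index, t_values) -> np.ndarray:
        return predict_mean(index, t_values, *self.params)

    def summary(self) -> pd.DataFrame:
        lo = 100 * (1 - self.confidence) / 2
        return pd.DataFrame(
            {
                "parameter": ["beta0", "beta1", "beta2"],
                "estimate": self.params,
                "se": self.bse,
                f"ci{lo:g}%": self.conf_int[:, 0],
                f"ci{100 - lo:g}%": self.conf_int[:, 1],
            }
        )


# ---------------------------------------------------------------------------
# Gibbs sampler core (vectorised across genotypes sharing a design)
# ---------------------------------------------------------------------------


def _gibbs_chain(
    Y: np.ndarray,             # (m, n)
    X: np.ndarray,             # (n, 3)
    beta_mean: np.ndarray,     # (m, 3)
    beta_var: np.ndarray,      # (m, 3)
    tau_shape: np.ndarray,     # (m,)
    tau_rate: np.ndarray,      # (m,)
    settings: McmcSettings,
    rng: np.random.Generator,
    sample_beta2: bool,
) -> np.ndarray:
    """Run one chain; returns kept draws of shape (m, n_kept, 4)."""
    m, n = Y.shape
    prior_prec = 1.0 / beta_var
    cols = [0, 1, 2] if sample_beta2 else [0, 1]
    xk = [X[:, k] for k in range(3)]
    xk_ss = [float(x @ x) for x in xk]

    # overdispersed init from the priors, truncated to a numerically safe box
    beta = np.clip(
        rng.normal(beta_mean, np.sqrt(beta_var)), -1e6, 1e6
    )
    if not sample_beta2:
        beta[:, 2] = 0.0
    tau = np.clip(rng.gamma(tau_shape, 1.0 / tau_rate), 1e-6, 1e6)

    resid = Y - beta @ X.T
    keep = range(settings.burn_in, settings.n_iterations, settings.thin)
    out = np.empty((m, len(keep), 4))
    keep_set = set(keep)
    pos = 0
    for it in range(settings.n_iterations):
        for k in cols:
            partial = resid + beta[:, k, None] * xk[k][None, :]
            prec = prior_prec[:, k] + tau * xk_ss[k]
            mean = (beta_mean[:, k] * prior_prec[:, k] + tau * (partial @ xk[k])) / prec
            beta[:, k] = mean + rng.standard_normal(m) / np.sqrt(prec)
            resid = partial - beta[:, k, None] * xk[k][None, :]
        sse = (resid**2).sum(axis=1)
        tau = rng.gamma(tau_shape + 0.5 * n, 1.0 / (tau_rate + 0.5 * sse))
        if it in keep_set:
            out[:, pos, :3] = beta
            out[:, pos, 3] = tau
            pos += 1
    return out


def _run_gibbs(
    Y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec,
    settings: McmcSettings,
    genotypes: Sequence[str],
    sample_beta2: bool,
) -> PosteriorChains:
    m = Y.shape[0]
    bm, bv, ts, tr = prior.per_genotype(m)
    root = np.random.SeedSequence(settings.seed)
    chains = []
    for child in root.spawn(settings.n_chains):
        rng = np.random.default_rng(child)
        chains.append(_gibbs_chain(Y, X, bm, bv, ts, tr, settings, rng, sample_beta2))
    draws = np.stack(chains, axis=1)  # (m, chains, kept, 4)
    return PosteriorChains(draws=draws, genotypes=tuple(genotypes))


# ---------------------------------------------------------------------------
# Bayesian model / results
# ---------------------------------------------------------------------------


class BayesianBisegmented:
    """Bayesian bisegmented regression for one genotype or a panel.

    Parameters
    ----------
    y : array
        Observations — 1-D (one genotype) or 2-D with one row per genotype;
        all rows share the same design points.
    index, t_values : arrays
        Observation-level coded index I and hinge value T(I).
    prior : PriorSpec, optional
        Defaults to the minimally informative prior.
    genotypes : labels, optional

    ``fit`` runs the conjugate Gibbs sampler and returns
    :class:`BayesianBisegmentedResults`.
    """

    def __init__(self, y, index, t_values, prior: PriorSpec | None = None, genotypes=None):
        y = np.asarray(y, dtype=float)
        self.single = y.ndim == 1
        self.Y = np.atleast_2d(y)
        self.index = np.asarray(index, dtype=float)
        self.t_values = np.asarray(t_values, dtype=float)
        if self.Y.shape[1] != self.index.size or self.index.size != self.t_values.size:
            raise ValueError("y rows, index and t_values must have equal length")
        if not np.isfinite(self.Y).all():
            raise ValueError("observations must be finite")
        n_min = 4
        if self.Y.shape[1] < n_min:
            raise ValueError(f"need at least {n_min} observations per genotype")
        self.prior = prior if prior is not None else PriorSpec.vague()
        if genotypes is None:
            genotypes = [f"G{i + 1}" for i in range(self.Y.shape[0])]
        self.genotypes = tuple(str(g) for g in genotypes)
        self.sample_beta2 = _hinge_identifiable(self.index, self.t_values)
        if not self.sample_beta2:
            warnings.warn(
                "hinge term unidentified (fewer than two distinct favorable"
                " design points); sampling a single-slope model with beta2"
                " fixed at 0",
                UserWarning,
                stacklevel=2,
            )
        self.X = _design_matrix(self.index, self.t_values)

    @classmethod
    def from_trial(cls, table, design: BisegmentedDesign, prior: PriorSpec | None = None):
        """Build the panel model from a balanced trial table: one row of
        replicate-level observations per genotype, shared design columns."""
        Y, layout = table.observation_matrix()
        idx, t = design.expand(layout["environment"])
        return cls(Y, idx, t, prior=prior, genotypes=table.genotypes)

    def fit(self, settings: McmcSettings | None = None) -> "BayesianBisegmentedResults":
        settings = settings if settings is not None else McmcSettings()
        chains = _run_gibbs(
            self.Y, self.X, self.prior, settings, self.genotypes, self.sample_beta2
        )
        return BayesianBisegmentedResults(model=self, chains=chains, settings=settings)


def _batch_means_mcse(x: np.ndarray) -> float:
    """Monte Carlo standard error of the mean of stacked chains (chains, n)
    by the batch-means method with batch size ~ sqrt(n)."""
    x = np.atleast_2d(x)
    c, n = x.shape
    b = max(int(np.sqrt(n)), 2)
    n_batches = n // b
    if n_batches < 2:
        return float("nan")
    trimmed = x[:, : n_batches * b].reshape(c, n_batches, b)
    bmeans = trimmed.mean(axis=2)
    var_chain_mean = bmeans.var(axis=1, ddof=1) / n_batches
    return float(np.sqrt(var_chain_mean.mean() / c))


class BayesianBisegmentedResults:
    """Posterior draws plus the summaries built on them.

    Summaries are posterior means/sds, equal-tailed 95% credibility intervals
    (HPD behind ``hpd=True``), batch-means MCSEs, the fit R² at posterior
    means, and — given the joint-ANOVA MSR and replication count — the
    stability parameter sigma2_di.
    """

    def __init__(self, model: BayesianBisegmented, chains: PosteriorChains, settings: McmcSettings):
        self.model = model
        self.chains = chains
        self.settings = settings

    # -- basic posterior summaries ---------------------------------------

    def posterior_mean(self, param: str) -> np.ndarray:
        return self.chains.parameter(param).mean(axis=(1, 2))

    def posterior_sd(self, param: str) -> np.ndarray:
        return self.chains.parameter(param).std(axis=(1, 2), ddof=1)

    def credible_interval(self, param: str, level: float = 0.95, hpd: bool = False) -> np.ndarray:
        """(n_genotypes, 2) interval bounds; equal-tailed by default."""
        draws = self.chains.parameter(param).reshape(self.chains.n_genotypes, -1)
        if not hpd:
            lo = (1.0 - level) / 2
            return np.quantile(draws, [lo, 1.0 - lo], axis=1).T
        srt = np.sort(draws, axis=1)
        n = srt.shape[1]
        w = max(int(np.floor(level * n)), 1)
        widths = srt[:, w:] - srt[:, : n - w]
        start = widths.argmin(axis=1)
        rows = np.arange(srt.shape[0])
        return np.column_stack([srt[rows, start], srt[rows, start + w]])

    def mcse(self, param: str) -> np.ndarray:
        arr = self.chains.parameter(param)
        return np.array([_batch_means_mcse(arr[i]) for i in range(arr.shape[0])])

    # -- derived quantities ----------------------------------------------

    def slope_sum_draws(self) -> np.ndarray:
        """Draws of beta1 + beta2, the slope in favorable environments."""
        return self.chains.parameter("beta1") + self.chains.parameter("beta2")

    def stability(self, msr: float, r: int) -> pd.DataFrame:
        """Posterior summary of sigma2_di = sigma2_ie − MSR/r per genotype."""
        draws = stability_draws(self.chains.sigma2, msr, r)
        flat = draws.reshape(self.chains.n_genotypes, -1)
        ci = np.quantile(flat, [0.025, 0.975], axis=1)
        return pd.DataFrame(
            {
                "genotype": self.chains.genotypes,
                "sigma2_di": flat.mean(axis=1),
                "sd": flat.std(axis=1, ddof=1),
                "ci2.5%": ci[0],
                "ci97.5%": ci[1],
                "negative": flat.mean(axis=1) < 0,
            }
        )

    def r_squared(self) -> np.ndarray:
        """R² of each genotype's fit at its posterior-mean coefficients."""
        b0 = self.posterior_mean("beta0")
        b1 = self.posterior_mean("beta1")
        b2 = self.posterior_mean("beta2")
        out = np.empty(self.chains.n_genotypes)
        for i in range(self.chains.n_genotypes):
            out[i] = r_squared(
                self.model.Y[i], self.model.index, self.model.t_values, (b0[i], b1[i], b2[i])
            )
        return out

    def predict(self, index=None, t_values=None) -> np.ndarray:
        """Posterior-mean prediction; defaults to the fitting design."""
        index = self.model.index if index is None else np.asarray(index, dtype=float)
        t_values = self.model.t_values if t_values is None else np.asarray(t_values, dtype=float)
        b0 = self.posterior_mean("beta0")[:, None]
        b1 = self.posterior_mean("beta1")[:, None]
        b2 = self.posterior_mean("beta2")[:, None]
        pred = b0 + b1 * index[None, :] + b2 * t_values[None, :]
        return pred[0] if self.model.single else pred

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Long-format posterior summary table."""
        records = []
        lo = 100 * (1 - level) / 2
        for param in ("beta0", "beta1", "beta2", "sigma2"):
            means = self.posterior_mean(param)
            sds = self.posterior_sd(param)
            ci = self.credible_interval(param, level)
            mcses = self.mcse(param)
            for i, genotype in enumerate(self.chains.genotypes):
                records.append(
                    {
                        "genotype": genotype,
                        "parameter": param,
                        "mean": means[i],
                        "sd": sds[i],
                        f"ci{lo:g}%": ci[i, 0],
                        f"ci{100 - lo:g}%": ci[i, 1],
                        "mcse": mcses[i],
                    }
                )
        return pd.DataFrame(records)
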