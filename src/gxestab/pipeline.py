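"""End-to-end adaptability/stability analysis of a multi-environment trial.

`AdaptabilityStabilityModel` wraps a balanced trial table; `fit()` runs

1. joint ANOVA (with per-environment ANOVAs and Hartley's homogeneity check),
2. the coded environmental index and hinge design,
3. per-genotype Bayesian bisegmented regression by Gibbs sampling
   (vague or frequentist-elicited priors),
4. stability statistics, R², z-scores and classification,

and returns an `AdaptabilityStabilityResults` carrying every intermediate
product plus `summary()`, `classify()` and `report()`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import anova as anova_mod
from .anova import AnovaTable, HomogeneityResult
from .biseg import (
    BayesianBisegmented,
    BayesianBisegmentedResults,
    BisegmentedOLS,
    McmcSettings,
    PriorSpec,
)
from .classify import ClassificationThresholds, classify, report
from .data import TrialTable
from .env_index import BisegmentedDesign, compute_index

__all__ = ["AdaptabilityStabilityModel", "AdaptabilityStabilityResults"]


class AdaptabilityStabilityModel:
    """Bayesian bisegmented adaptability/stability model for a balanced
    genotype × environment × replication trial."""

    def __init__(self, table: TrialTable):
        self.table = table
        self.design = table.require_balanced()
        self._anova: AnovaTable | None = None
        self._index: BisegmentedDesign | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AdaptabilityStabilityModel":
        return cls(TrialTable(df))

    # -- stage 1: ANOVA ---------------------------------------------------

    def joint_anova(self) -> AnovaTable:
        if self._anova is None:
            self._anova = anova_mod.joint_anova(self.table)
        return self._anova

    def per_environment_anova(self):
        return anova_mod.per_environment_anova(self.table)

    def hartley_test(self, alpha: float = 0.05) -> HomogeneityResult:
        per_env = self.per_environment_anova()
        variances = {env: tab.msr for env, tab in per_env.items()}
        df = int(next(iter(per_env.values()))["Residuals"]["df"])
        return anova_mod.hartley_test(variances, df=df, alpha=alpha)

    # -- stage 2: environmental index -------------------------------------

    def environmental_index(self) -> BisegmentedDesign:
        if self._index is None:
            self._index = compute_index(self.table)
        return self._index

    # -- stage 3: per-genotype fits ----------------------------------------

    def frequentist_fits(self, confidence: float = 0.95) -> pd.DataFrame:
        """Per-genotype OLS bisegmented fits (estimates, ses, residual MS) —
        the classical analysis, and the source for prior elicitation."""
        design = self.environmental_index()
        Y, layout = self.table.observation_matrix()
        idx, t = design.expand(layout["environment"])
        records = []
        for i, genotype in enumerate(self.table.genotypes):
            res = BisegmentedOLS(Y[i], idx, t, name=genotype).fit(confidence)
            records.append(
                {
                    "genotype": genotype,
                    "beta0": res.params[0],
                    "beta1": res.params[1],
                    "beta2": res.params[2],
                    "se_beta0": res.bse[0],
                    "se_beta1": res.bse[1],
                    "se_beta2": res.bse[2],
                    "mse_resid": res.mse_resid,
                    "rsquared": res.rsquared,
                }
            )
        return pd.DataFrame(records)

    def elicited_prior(self, inflation: float = 10.0) -> PriorSpec:
        """Prior centered on this panel's own frequentist fits (or, in real
        use, fits from an earlier trial) with variances inflated."""
        fits = self.frequentist_fits()
        est = fits[["beta0", "beta1", "beta2"]].to_numpy()
        ses = fits[["se_beta0", "se_beta1", "se_beta2"]].to_numpy()
        ses = np.where(np.isfinite(ses), ses, np.sqrt(100_000.0))  # pinned params stay vague
        return PriorSpec.from_frequentist(est, ses, fits["mse_resid"].to_numpy(), inflation)

    def fit(
        self,
        prior: PriorSpec | str = "vague",
        settings: McmcSettings | None = None,
        inflation: float = 10.0,
    ) -> "AdaptabilityStabilityResults":
        """Run the full pipeline.  ``prior`` is a PriorSpec, ``"vague"`` for
        the minimally informative prior, or ``"elicited"`` to derive one
        from the frequentist fits with the given inflation factor."""
        if isinstance(prior, str):
            if prior == "vague":
                prior_spec = PriorSpec.vague()
            elif prior == "elicited":
                prior_spec = self.elicited_prior(inflation)
            else:
                raise ValueError("prior must be 'vague', 'elicited' or a PriorSpec")
        else:
            prior_spec = prior
        settings = settings if settings is not None else McmcSettings()
        anova_table = self.joint_anova()
        index = self.environmental_index()
        hartley = self.hartley_test()
        bayes = BayesianBisegmented.from_trial(self.table, index, prior=prior_spec)
        bayes_results = bayes.fit(settings)
        return AdaptabilityStabilityResults(
            model=self,
            anova=anova_table,
            hartley=hartley,
            index=index,
            bayes=bayes_results,
            prior=prior_spec,
            settings=settings,
        )


class AdaptabilityStabilityResults:
    """Everything the fitted pipeline produced."""

    def __init__(self, model, anova, hartley, index, bayes, prior, settings):
        self.model = model
        self.anova: AnovaTable = anova
        self.hartley: HomogeneityResult = hartley
        self.index: BisegmentedDesign = index
        self.bayes: BayesianBisegmentedResults = bayes
        self.prior = prior
        self.settings = settings
        self._summaries: pd.DataFrame | None = None

    @property
    def gxe_significant(self) -> bool:
        return bool(self.anova["GxE"]["p"] < 0.001)

    def genotype_summaries(self) -> pd.DataFrame:
        """One row per genotype: posterior intercept and raw harvest mean,
        stability sigma2_di, R², and both regime slopes."""
        if self._summaries is not None:
            return self._summaries
        bayes = self.bayes
        stability = bayes.stability(self.anova.msr, self.anova.r)
        harvest_mean = (
            self.model.table.data.groupby("genotype")["yield"].mean().sort_index()
        )
        slope_sum = bayes.slope_sum_draws().reshape(bayes.chains.n_genotypes, -1).mean(axis=1)
        self._summaries = pd.DataFrame(
            {
                "genotype": bayes.chains.genotypes,
                "beta0": bayes.posterior_mean("beta0"),
                "harvest_mean": harvest_mean.to_numpy(),
                "sigma2_di": stability["sigma2_di"].to_numpy(),
                "sigma2_di_negative": stability["negative"].to_numpy(),
                "r_squared": bayes.r_squared(),
                "slope_unfavorable": bayes.posterior_mean("beta1"),
                "slope_favorable": slope_sum,
            }
        )
        return self._summaries

    def classify(self, thresholds: ClassificationThresholds | None = None) -> pd.DataFrame:
        return classify(self.genotype_summaries(), thresholds)

    def report(self, outdir, thresholds=None, make_plots: bool = True):
        return report(self.classify(thresholds), self.anova, self.index, outdir, make_plots)

    def summary(self) -> str:
        lines = [
            "Adaptability/stability analysis",
            "=" * 34,
            f"design: {self.model.design.n_genotypes} genotypes x"
            f" {self.model.design.n_environments} environments x"
            f" {self.model.design.n_replications} replications",
            "",
            "Joint ANOVA",
            self.anova.format(),
            "",
            f"GxE interaction significant at 0.001: {self.gxe_significant}",
            f"Hartley Fmax = {self.hartley.fmax:.3f}"
            f" (critical {self.hartley.critical_value:.3f}"
            f" at alpha={self.hartley.alpha}):"
            f" {'homogeneous' if self.hartley.homogeneous else 'heterogeneous'}",
            "",
            "Environmental index",
            self.index.to_frame().to_string(index=False),
            "",
            "Genotype classification",
            self.classify().to_string(index=False),
        ]
        return "\n".join(lines)
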