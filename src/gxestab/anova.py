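"""Per-environment and joint ANOVA for balanced multi-environment trials,
plus Hartley's Fmax test of residual-variance homogeneity.

All factors are treated as fixed and tested against the pooled residual mean
square, matching the classical joint analysis of a randomized-block trial
repeated over environments.  Replication is decomposed into a main effect
with r − 1 df plus a replication-within-environment interaction with
(r − 1)(e − 1) df, so a g = 43, e = 4, r = 3 trial yields the df pattern
3 / 2 / 42 / 6 / 126 / 336.
"""

from __future__ import annotations

import dataclasses
import functools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialTable

__all__ = [
    "AnovaTable",
    "HomogeneityResult",
    "joint_anova",
    "per_environment_anova",
    "hartley_test",
    "hartley_critical_value",
]


@dataclasses.dataclass(frozen=True)
class AnovaTable:
    """Factor decomposition with DF/SS/MS/F/p rows.

    ``msr`` is the residual mean square and ``r`` the replication count —
    the two ingredients of the stability statistic σ̂²_di = σ̂²_ie − MSR/r.
    F and p are NaN for untested rows (the residual) and when the residual
    mean square is zero (noise-free data).
    """

    rows: pd.DataFrame  # columns: factor, df, ss, ms, f, p
    msr: float
    r: int

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def __getitem__(self, factor: str) -> pd.Series:
        match = self.rows[self.rows["factor"] == factor]
        if match.empty:
            raise KeyError(factor)
        return match.iloc[0]

    def format(self, p_floor: float = 1e-16) -> str:
        """Aligned text table; p-values below ``p_floor`` display as '<1e-16'."""
        out = self.rows.copy()
        out["p"] = [
            ""
            if not np.isfinite(p)
            else (f"<{p_floor:g}" if p < p_floor else f"{p:.4g}")
            for p in out["p"]
        ]
        out["f"] = [("" if not np.isfinite(f) else f"{f:.3f}") for f in out["f"]]
        return out.to_string(index=False)


def _rows(entries: list[tuple[str, int, float]], ss_res: float, df_res: int, r: int) -> AnovaTable:
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    recs = []
    for factor, df, ss in entries:
        ms = ss / df if df > 0 else np.nan
        if ms_res > 0 and df > 0 and df_res > 0:
            f = ms / ms_res
            p = float(stats.f.sf(f, df, df_res))
        else:
            f, p = np.nan, np.nan
        recs.append((factor, df, ss, ms, f, p))
    recs.append(("Residuals", df_res, ss_res, ms_res, np.nan, np.nan))
    rows = pd.DataFrame(recs, columns=["factor", "df", "ss", "ms", "f", "p"])
    return AnovaTable(rows=rows, msr=float(ms_res), r=r)


def joint_anova(table: TrialTable) -> AnovaTable:
    """Joint fixed-effects ANOVA of a balanced g × e × r trial.

    Rows: Environment (e−1), Repetition (r−1), Genotypes (g−1),
    R/E (r−1)(e−1), GxE (g−1)(e−1), Residuals by subtraction from N−1.
    Sums of squares use the balanced closed forms over marginal means; every
    tested row is compared against the residual mean square.
    """
    design = table.require_balanced()
    g, e, r = design.n_genotypes, design.n_environments, design.n_replications
    if g < 2 or e < 2 or r < 2:
        raise ValueError("joint ANOVA needs at least 2 genotypes, environments and replications")

    df = table.data
    y = df["yield"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    env_m = df.groupby("environment")["yield"].mean()
    rep_m = df.groupby("replication")["yield"].mean()
    gen_m = df.groupby("genotype")["yield"].mean()
    er_m = df.groupby(["environment", "replication"])["yield"].mean().unstack()
    ge_m = df.groupby(["genotype", "environment"])["yield"].mean().unstack()

    ss_env = g * r * float(((env_m - grand) ** 2).sum())
    ss_rep = g * e * float(((rep_m - grand) ** 2).sum())
    ss_gen = e * r * float(((gen_m - grand) ** 2).sum())
    ss_re = g * float(
        ((er_m.sub(env_m, axis=0).sub(rep_m, axis=1) + grand) ** 2).to_numpy().sum()
    )
    ss_ge = r * float(
        ((ge_m.sub(gen_m, axis=0).sub(env_m, axis=1) + grand) ** 2).to_numpy().sum()
    )
    ss_res = ss_total - (ss_env + ss_rep + ss_gen + ss_re + ss_ge)
    ss_res = max(ss_res, 0.0)  # guard tiny negative round-off

    df_res = (g * e * r - 1) - ((e - 1) + (r - 1) + (g - 1) + (r - 1) * (e - 1) + (g - 1) * (e - 1))
    entries = [
        ("Environment", e - 1, ss_env),
        ("Repetition", r - 1, ss_rep),
        ("Genotypes", g - 1, ss_gen),
        ("R/E", (r - 1) * (e - 1), ss_re),
        ("GxE", (g - 1) * (e - 1), ss_ge),
    ]
    return _rows(entries, ss_res, df_res, r)


def per_environment_anova(table: TrialTable) -> dict[str, AnovaTable]:
    """One randomized-complete-block ANOVA per environment.

    Rows per environment: Genotypes (g−1), Repetition (r−1), Residuals
    (g−1)(r−1).  The residual mean squares feed Hartley's test.
    """
    table.require_balanced()
    out: dict[str, AnovaTable] = {}
    for env, sub in table.data.groupby("environment"):
        g = sub["genotype"].nunique()
        r = sub["replication"].nunique()
        if g < 2 or r < 2:
            raise ValueError(f"environment {env!r} needs >= 2 genotypes and replications")
        y = sub["yield"].to_numpy(dtype=float)
        grand = y.mean()
        gen_m = sub.groupby("genotype")["yield"].mean()
        rep_m = sub.groupby("replication")["yield"].mean()
        ss_total = float(((y - grand) ** 2).sum())
        ss_gen = r * float(((gen_m - grand) ** 2).sum())
        ss_rep = g * float(((rep_m - grand) ** 2).sum())
        ss_res = max(ss_total - ss_gen - ss_rep, 0.0)
        out[env] = _rows(
            [("Genotypes", g - 1, ss_gen), ("Repetition", r - 1, ss_rep)],
            ss_res,
            (g - 1) * (r - 1),
            r,
        )
    return dict(sorted(out.items()))


@dataclasses.dataclass(frozen=True)
class HomogeneityResult:
    """Outcome of Hartley's Fmax test across environments."""

    variances: dict[str, float]
    fmax: float
    critical_value: float
    alpha: float
    df: int
    homogeneous: bool


@functools.lru_cache(maxsize=64)
def hartley_critical_value(
    k: int, df: int, alpha: float = 0.05, n_draws: int = 100_000, seed: int = 20_220_708
) -> float:
    """Upper-alpha quantile of Fmax = max/min of k iid scaled chi-square
    variance estimates with ``df`` degrees of freedom each.

    Computed by Monte Carlo (vectorised, seed-controlled) rather than by
    interpolating printed tables, which supports arbitrary (k, df).
    """
    if k < 2 or df < 1:
        raise ValueError("need k >= 2 groups and df >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.chisquare(df, size=(n_draws, k)) / df
    fmax = draws.max(axis=1) / draws.min(axis=1)
    return float(np.quantile(fmax, 1.0 - alpha))


def hartley_test(
    variances: dict[str, float] | pd.Series,
    df: int,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 20_220_708,
) -> HomogeneityResult:
    """Hartley's Fmax homogeneity test on per-environment residual variances.

    Requires a common residual df (balanced design).  ``homogeneous`` is
    true iff fmax < the Monte Carlo critical value at ``alpha``.
    """
    var = pd.Series(variances, dtype=float)
    if len(var) < 2:
        raise ValueError("Hartley's test needs at least 2 environments")
    if (var <= 0).any():
        raise ValueError("degenerate data: every residual variance must be positive")
    fmax = float(var.max() / var.min())
    crit = hartley_critical_value(len(var), df, alpha, n_draws=n_draws, seed=seed)
    homogeneous = fmax < crit
    if not homogeneous:
        warnings.warn(
            f"residual variances are heterogeneous by Hartley's test"
            f" (Fmax={fmax:.3f} >= {crit:.3f} at alpha={alpha}); the joint"
            " analysis pools them regardless",
            UserWarning,
            stacklevel=2,
        )
    return HomogeneityResult(
        variances=dict(var),
        fmax=fmax,
        critical_value=crit,
        alpha=alpha,
        df=df,
        homogeneous=homogeneous,
    )
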