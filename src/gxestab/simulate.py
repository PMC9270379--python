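"""Synthetic multi-environment trials.

Two generators cover the two data-generating models of the analysis: an
additive ANOVA model (genotype + environment + replication-within-environment
+ GxE effects on a grand mean) and the bisegmented regression model with
known per-genotype coefficients.  Both are fully reproducible from a single
integer seed: each random ingredient draws from its own named substream
(``numpy.random.SeedSequence(seed, spawn_key=(stream_id,))``), so adding a
factor does not reshuffle the others.

Factor effects are drawn from mean-zero normals and then sum-constrained to
zero per factor (the GxE matrix is double-centered, replication effects are
centered within each environment).  With that constraint the simulated
environmental index equals the environment effect up to residual noise,
which keeps index-recovery tests exact in expectation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import TrialDesign, TrialTable
from .env_index import transform_index

__all__ = ["AnovaSimSpec", "BisegSimSpec", "simulate_anova_trial", "simulate_biseg_trial"]

# fixed substream ids; never renumber (reproducibility contract)
_STREAMS = {
    "environment": 1,
    "genotype": 2,
    "gxe": 3,
    "rep_within_env": 4,
    "residual": 5,
    "biseg_residual": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclasses.dataclass(frozen=True)
class AnovaSimSpec:
    """Parameters of the additive-effects trial generator.

    Standard deviations are those of the factor-effect distributions
    (yield units); the defaults emulate a coffee trial of 43 genotypes ×
    4 harvests × 3 blocks with a strong environment signal, a clear genotype
    signal and a GxE interaction detectable at conventional levels.
    """

    design: TrialDesign = TrialDesign(43, 4, 3)
    grand_mean: float = 100.0
    sd_environment: float = 15.0
    sd_genotype: float = 12.0
    sd_gxe: float = 6.0
    sd_rep_within_env: float = 3.0
    sd_residual: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if field.name.startswith("sd_") and getattr(self, field.name) < 0:
                raise ValueError(f"{field.name} must be nonnegative")
        if self.design.n_cells < 1:
            raise ValueError("design has no cells")


def _centered(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    if sd == 0 or size < 2:
        return np.zeros(size)
    x = rng.normal(0.0, sd, size)
    return x - x.mean()


def simulate_anova_trial(spec: AnovaSimSpec) -> TrialTable:
    """Draw a balanced trial from the additive genotype/environment model.

    Yield of genotype i, environment j, replication k is

        mu + e_j + g_i + (ge)_ij + (r/e)_k(j) + eps_ijk

    with each effect drawn once per level from a centered normal at the
    spec's sd and iid residuals.
    """
    g, e, r = (
        spec.design.n_genotypes,
        spec.design.n_environments,
        spec.design.n_replications,
    )
    env_eff = _centered(_rng(spec.seed, "environment"), spec.sd_environment, e)
    gen_eff = _centered(_rng(spec.seed, "genotype"), spec.sd_genotype, g)

    gxe = np.zeros((g, e))
    if spec.sd_gxe > 0 and g > 1 and e > 1:
        raw = _rng(spec.seed, "gxe").normal(0.0, spec.sd_gxe, (g, e))
        gxe = raw - raw.mean(axis=1, keepdims=True) - raw.mean(axis=0, keepdims=True) + raw.mean()

    rep_eff = np.zeros((e, r))
    if spec.sd_rep_within_env > 0 and r > 1:
        raw = _rng(spec.seed, "rep_within_env").normal(0.0, spec.sd_rep_within_env, (e, r))
        rep_eff = raw - raw.mean(axis=1, keepdims=True)

    resid = np.zeros((g, e, r))
    if spec.sd_residual > 0:
        resid = _rng(spec.seed, "residual").normal(0.0, spec.sd_residual, (g, e, r))

    yields = (
        spec.grand_mean
        + env_eff[None, :, None]
        + gen_eff[:, None, None]
        + gxe[:, :, None]
        + rep_eff[None, :, :]
        + resid
    )
    return _assemble(yields, g, e, r)


@dataclasses.dataclass(frozen=True)
class BisegSimSpec:
    """Parameters of the bisegmented-model trial generator.

    ``betas`` holds one (β_i0, β_i1, β_i2) triple per genotype; ``index``
    the coded environmental index I_j per environment (should sum to ~0).
    Replicate yields are the bisegmented cell mean plus iid N(0, σ_ie²)
    noise, with ``sigma`` either a scalar or one value per genotype.
    """

    betas: np.ndarray
    index: np.ndarray
    sigma: float | np.ndarray = 5.0
    n_replications: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", np.atleast_2d(np.asarray(self.betas, dtype=float)))
        object.__setattr__(self, "index", np.asarray(self.index, dtype=float))
        if self.betas.shape[1] != 3:
            raise ValueError("betas must have three columns (beta0, beta1, beta2)")
        sigma = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.betas.shape[0],))
        if (sigma < 0).any():
            raise ValueError("sigma must be nonnegative")
        object.__setattr__(self, "sigma", np.array(sigma))

    @property
    def design(self) -> TrialDesign:
        return TrialDesign(self.betas.shape[0], len(self.index), self.n_replications)

    def cell_means(self) -> np.ndarray:
        """Noise-free genotype × environment means under the hinge model."""
        if not (self.index > 0).any():
            raise ValueError("index has no positive entry; hinge design undefined")
        i_plus_bar = float(self.index[self.index > 0].mean())
        t = transform_index(self.index, i_plus_bar)
        b0, b1, b2 = self.betas.T
        return b0[:, None] + np.outer(b1, self.index) + np.outer(b2, t)


def simulate_biseg_trial(spec: BisegSimSpec) -> TrialTable:
    """Draw replicate-level yields from the bisegmented regression model."""
    g, e, r = spec.betas.shape[0], len(spec.index), spec.n_replications
    means = spec.cell_means()
    noise = _rng(spec.seed, "biseg_residual").normal(0.0, 1.0, (g, e, r))
    yields = means[:, :, None] + spec.sigma[:, None, None] * noise
    return _assemble(yields, g, e, r)


def _assemble(yields: np.ndarray, g: int, e: int, r: int) -> TrialTable:
    gen = _labels("G", g)
    env = _labels("E", e)
    rep = _labels("R", r)
    gi, ei, ri = np.meshgrid(range(g), range(e), range(r), indexing="ij")
    df = pd.DataFrame(
        {
            "genotype": np.array(gen)[gi.ravel()],
            "environment": np.array(env)[ei.ravel()],
            "replication": np.array(rep)[ri.ravel()],
            "yield": yields.ravel(),
        }
    )
    return TrialTable(df)


def default_biseg_spec(
    n_genotypes: int = 43,
    index: Sequence[float] = (-12.0, -4.0, 5.0, 11.0),
    sigma: float = 5.0,
    n_replications: int = 3,
    seed: int = 0,
) -> BisegSimSpec:
    """A study-shaped bisegmented scenario with heterogeneous true genotypes.

    True coefficients are drawn once (from the seed's own substream):
    intercepts around 100 bags/ha with sd 15, unfavorable-regime slopes
    around 1 with sd 0.4, slope changes centered at 0 with sd 0.6 — genotypes
    therefore range from non-responsive to strongly responsive, as in real
    germplasm panels.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    g = n_genotypes
    betas = np.column_stack(
        [
            rng.normal(100.0, 15.0, g),
            rng.normal(1.0, 0.4, g),
            rng.normal(0.0, 0.6, g),
        ]
    )
    return BisegSimSpec(
        betas=betas,
        index=np.asarray(index, dtype=float),
        sigma=sigma,
        n_replications=n_replications,
        seed=seed,
    )
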