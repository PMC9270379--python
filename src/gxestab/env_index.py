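"""Coded environmental index and the hinge transform of bisegmented regression.

The environmental index of environment j is the mean yield of all genotypes
and replications in that environment minus the grand mean, so on balanced
data the indices sum to zero.  Environments with positive index are
"favorable"; the hinge transform T(I_j) activates only there:

    T(I_j) = 0            if I_j <= 0
    T(I_j) = I_j - Ī₊     if I_j > 0

with Ī₊ the mean of the positive indices, which makes the hinge column sum
to zero over the favorable environments.  An index of exactly zero is
grouped with the unfavorable regime.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .data import TrialTable

__all__ = ["BisegmentedDesign", "DegenerateDesignWarning", "compute_index", "transform_index"]


class DegenerateDesignWarning(UserWarning):
    """The index layout cannot identify both regimes of the hinge model."""


@dataclasses.dataclass(frozen=True)
class BisegmentedDesign:
    """Per-environment index I_j, hinge value T(I_j), and Ī₊.

    ``degenerate`` flags layouts with fewer than two favorable or two
    unfavorable environments, where the change in slope (or the slope
    itself) is unidentified and fitting falls back to a single-slope model.
    """

    environments: tuple[str, ...]
    index: np.ndarray          # I_j, one per environment, sums to ~0
    t_values: np.ndarray       # T(I_j)
    i_plus_bar: float          # Ī₊; NaN when no environment is favorable
    degenerate: bool = False

    @classmethod
    def from_index(cls, index, environments=None) -> "BisegmentedDesign":
        """Build a design from known index values (e.g. a simulation's
        truth) instead of deriving them from data."""
        index = np.asarray(index, dtype=float)
        if environments is None:
            width = len(str(len(index)))
            environments = tuple(f"E{i + 1:0{width}d}" for i in range(len(index)))
        positive = index > 0
        if not positive.any():
            raise ValueError("index has no positive entry; hinge design undefined")
        i_plus_bar = float(index[positive].mean())
        return cls(
            environments=tuple(environments),
            index=index,
            t_values=np.asarray(transform_index(index, i_plus_bar), dtype=float),
            i_plus_bar=i_plus_bar,
            degenerate=positive.sum() < 2 or (~positive).sum() < 2,
        )

    @property
    def n_positive(self) -> int:
        return int((self.index > 0).sum())

    @property
    def favorable(self) -> np.ndarray:
        return self.index > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "environment": self.environments,
                "index": self.index,
                "t_value": self.t_values,
                "favorability": np.where(self.index > 0, "favorable", "unfavorable"),
            }
        )

    def expand(self, environments) -> tuple[np.ndarray, np.ndarray]:
        """Map an observation-level environment label vector to (I, T) columns."""
        lookup = {env: i for i, env in enumerate(self.environments)}
        pos = np.array([lookup[e] for e in environments])
        return self.index[pos], self.t_values[pos]


def transform_index(index: float | np.ndarray, i_plus_bar: float) -> float | np.ndarray:
    """Hinge transform: 0 for I_j <= 0, I_j − Ī₊ for I_j > 0."""
    index = np.asarray(index, dtype=float)
    out = np.where(index > 0, index - i_plus_bar, 0.0)
    return float(out) if out.ndim == 0 else out


def compute_index(table: TrialTable) -> BisegmentedDesign:
    """Compute the bisegmented design from a balanced trial table.

    Raises
    ------
    ValueError
        If no environment has a positive index (all environment means equal):
        Ī₊ is undefined and the bisegmented model collapses entirely.
    Warns
    -----
    DegenerateDesignWarning
        If fewer than two favorable or two unfavorable environments remain;
        downstream fits degrade to a single-slope model.
    """
    table.require_balanced()
    env_means = table.environment_means()
    index = env_means.to_numpy(dtype=float) - table.grand_mean
    positive = index > 0
    if not positive.any():
        raise ValueError(
            "no environment has a positive index (all environment means equal"
            " the grand mean); the bisegmented design is undefined"
        )
    i_plus_bar = float(index[positive].mean())
    t_values = transform_index(index, i_plus_bar)
    degenerate = positive.sum() < 2 or (~positive).sum() < 2
    if degenerate:
        warnings.warn(
            "fewer than two favorable or two unfavorable environments: the"
            " hinge term is rank-deficient and fits fall back to a single"
            " slope",
            DegenerateDesignWarning,
            stacklevel=2,
        )
    return BisegmentedDesign(
        environments=tuple(env_means.index),
        index=index,
        t_values=np.asarray(t_values, dtype=float),
        i_plus_bar=i_plus_bar,
        degenerate=degenerate,
    )
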