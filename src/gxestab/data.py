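"""Trial data model and plain-text I/O.

The canonical container is a long ("tidy") table of replicate-level yield
records — one row per (genotype, environment, replication) — because the
joint ANOVA needs replicate-level data; genotype × environment mean matrices
are derived views.  Yields are unitless reals to the engine; the bags·ha⁻¹
label of coffee trials is metadata only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialDesign",
    "TrialTable",
    "read_trial_table",
    "write_trial_table",
    "write_chains",
    "read_chains",
    "write_summaries",
]

REQUIRED_COLUMNS = ("genotype", "environment", "replication", "yield")


class TrialFormatError(ValueError):
    """A file or frame does not have the required trial-table structure."""


class TrialValidationError(ValueError):
    """Structurally well-formed data violating a trial-table invariant."""


@dataclasses.dataclass(frozen=True)
class TrialDesign:
    """Shape of a genotype × environment × replication trial.

    ``balanced`` is true iff every cell of the g·e·r lattice is present
    exactly once.  The full ANOVA decomposition needs g ≥ 2, e ≥ 2, r ≥ 2.
    """

    n_genotypes: int
    n_environments: int
    n_replications: int
    balanced: bool = True

    def __post_init__(self) -> None:
        for field in ("n_genotypes", "n_environments", "n_replications"):
            if getattr(self, field) < 1:
                raise TrialValidationError(f"{field} must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_genotypes * self.n_environments * self.n_replications


class TrialTable:
    """Validated long-format phenotype records of a multi-environment trial.

    Parameters
    ----------
    data : pandas.DataFrame
        Must carry the columns ``genotype``, ``environment``, ``replication``
        (labels, coerced to non-empty strings) and ``yield`` (finite reals).

    Invariants enforced at construction: every (genotype, environment,
    replication) triple appears at most once; yields are finite; labels are
    non-empty.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise TrialFormatError(f"missing required columns: {missing}")
        df = data.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("genotype", "environment", "replication"):
            df[col] = df[col].astype(str)
            if (df[col].str.len() == 0).any() or df[col].isin(("nan", "None")).any():
                raise TrialValidationError(f"empty or missing label in column {col!r}")
        try:
            df["yield"] = pd.to_numeric(df["yield"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise TrialFormatError(f"non-numeric yield value: {exc}") from exc
        if not np.isfinite(df["yield"].to_numpy(dtype=float)).all():
            raise TrialValidationError("yield values must be finite reals")
        dup = df.duplicated(subset=["genotype", "environment", "replication"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["genotype", "environment", "replication"]]
            raise TrialValidationError(
                f"duplicated (genotype, environment, replication) triple: {tuple(first)}"
            )
        self._data = df.reset_index(drop=True)

    # -- basic views ------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The validated long-format records (copy)."""
        return self._data.copy()

    @property
    def genotypes(self) -> list[str]:
        return sorted(self._data["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self._data["environment"].unique())

    @property
    def replications(self) -> list[str]:
        return sorted(self._data["replication"].unique())

    def __len__(self) -> int:
        return len(self._data)

    @property
    def design(self) -> TrialDesign:
        """Inferred design; ``balanced`` compares the observed cell set with
        the full g × e × r lattice."""
        g, e, r = len(self.genotypes), len(self.environments), len(self.replications)
        balanced = len(self._data) == g * e * r
        if balanced:
            # every triple unique (invariant) and count matches the lattice
            # size, but a missing cell could be masked by a stray label; check
            # each (e, r) slice really contains all genotypes.
            counts = self._data.groupby(["environment", "replication"], sort=False)[
                "genotype"
            ].nunique()
            balanced = bool((counts == g).all()) and len(counts) == e * r
        return TrialDesign(g, e, r, balanced)

    # -- derived matrices --------------------------------------------------

    def cell_means(self) -> pd.DataFrame:
        """Genotype × environment mean-yield matrix (rows sorted)."""
        return (
            self._data.pivot_table(
                index="genotype", columns="environment", values="yield", aggfunc="mean"
            )
            .sort_index(axis=0)
            .sort_index(axis=1)
        )

    def environment_means(self) -> pd.Series:
        return self._data.groupby("environment")["yield"].mean().sort_index()

    @property
    def grand_mean(self) -> float:
        return float(self._data["yield"].mean())

    def require_balanced(self) -> TrialDesign:
        design = self.design
        if not design.balanced:
            raise TrialValidationError(
                "this analysis requires a balanced trial (every genotype ×"
                " environment × replication cell present exactly once)"
            )
        return design

    def observation_matrix(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Stack replicate-level yields as a (g, e·r) matrix.

        Rows follow ``self.genotypes``; columns follow a fixed
        (environment, replication) ordering shared by all genotypes, returned
        as the second element.  Requires balance so every genotype shares the
        same column layout.
        """
        self.require_balanced()
        wide = self._data.pivot_table(
            index="genotype",
            columns=["environment", "replication"],
            values="yield",
            aggfunc="first",
        ).sort_index(axis=0).sort_index(axis=1)
        cols = pd.DataFrame(
            {
                "environment": wide.columns.get_level_values(0),
                "replication": wide.columns.get_level_values(1),
            }
        )
        return wide.to_numpy(dtype=float), cols


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {c: c for c in REQUIRED_COLUMNS}
    if dialect:
        for canonical, actual in dialect.items():
            if canonical not in REQUIRED_COLUMNS:
                raise TrialFormatError(
                    f"unknown canonical column {canonical!r}; expected one of {REQUIRED_COLUMNS}"
                )
            mapping[canonical] = actual
    return mapping


def read_trial_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> TrialTable:
    """Read a CSV/TSV phenotype table into a validated :class:`TrialTable`.

    Parameters
    ----------
    dialect : mapping, optional
        Maps canonical column names (``genotype``, ``environment``,
        ``replication``, ``yield``) to the names used in the file.
    sep : str, optional
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.tab`` → tab, otherwise comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    mapping = _resolve_dialect(dialect)
    missing = [actual for actual in mapping.values() if actual not in df.columns]
    if missing:
        raise TrialFormatError(f"file {path} lacks required columns {missing}")
    renamed = df.rename(columns={v: k for k, v in mapping.items()})
    return TrialTable(renamed)


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.12g")


# -- chains and summaries ---------------------------------------------------

_CHAIN_COLUMNS = ["genotype", "chain", "iteration", "parameter", "value"]


def write_chains(chains, path: str | Path) -> None:
    """Write posterior draws as a plain-text long table.

    One row per (genotype, chain, kept-iteration, parameter); values are
    printed with 17 significant digits so ``read_chains`` round-trips draws
    bit-exactly.
    """
    frame = chains.to_frame()
    if frame.empty:
        raise ValueError("cannot write empty chains")
    frame.to_csv(path, index=False, float_format="%.17g")


def read_chains(path: str | Path):
    from .biseg import PosteriorChains  # lazy: avoid cycle

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CHAIN_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"chain file lacks columns {missing}")
    return PosteriorChains.from_frame(df)


def write_summaries(summaries: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write per-genotype posterior summaries as CSV (≥ 12 significant digits)."""
    df = pd.DataFrame(summaries)
    if df.empty:
        raise ValueError("cannot write empty summaries")
    df.to_csv(path, index=False, float_format="%.12g")
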