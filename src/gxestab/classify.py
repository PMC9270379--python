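"""Z-score normalization of genotype summaries, classification into
productive / stable / responsive groups, and report generation.

Classification rules (all configurable):

* productive — posterior-mean intercept z-score > 0; "top tier" when the
  z-score exceeds 1 (more than one standard deviation above the panel mean);
* stable — stability-statistic (sigma2_di) z-score < 0, i.e. below-average
  deviation variance; negative raw sigma2_di is maximally stable;
* responsive — posterior mean favorable-regime slope beta1 + beta2 above a
  threshold (default 1, the classical responsiveness cut of the
  bisegmented-method lineage).

Z-scores use the population standard deviation across the genotype panel,
so classification is invariant to affine rescaling of the yields (the
responsiveness threshold is unit-dependent and documented as such).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["zscore", "classify", "ClassificationThresholds", "report"]


def zscore(values) -> np.ndarray:
    """(x − mean)/sd with the population sd, across the genotype panel.

    Constant input yields all zeros with a warning (no spread to normalise).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-scores need at least 2 genotypes")
    sd = x.std()  # population sd
    if sd == 0:
        warnings.warn("zero spread: all z-scores set to 0", UserWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclasses.dataclass(frozen=True)
class ClassificationThresholds:
    responsiveness: float = 1.0   # favorable-regime slope cut (yield units per index unit)
    top_tier_z: float = 1.0       # intercept z-score for the top production tier


def classify(
    summaries: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Attach z-scores and productive/stable/responsive flags.

    ``summaries`` needs columns ``genotype``, ``beta0``, ``sigma2_di`` and
    ``slope_favorable``; returns a copy with ``beta0_z``, ``sigma2_di_z``,
    ``productive`` (one of below / above-mean / top-tier), ``stable`` and
    ``responsive`` columns added.
    """
    thresholds = thresholds if thresholds is not None else ClassificationThresholds()
    out = summaries.copy()
    out["beta0_z"] = zscore(out["beta0"])
    out["sigma2_di_z"] = zscore(out["sigma2_di"])
    out["productive"] = np.select(
        [out["beta0_z"] > thresholds.top_tier_z, out["beta0_z"] > 0],
        ["top-tier", "above-mean"],
        default="below",
    )
    out["stable"] = out["sigma2_di_z"] < 0
    out["responsive"] = out["slope_favorable"] > thresholds.responsiveness
    return out


def _slope_chart_data(summaries: pd.DataFrame, design) -> pd.DataFrame:
    """Two slope segments per genotype: the unfavorable-regime line up to the
    change-point (index 0) and the favorable-regime line beyond it."""
    i_min = float(design.index.min())
    i_max = float(design.index.max())
    rows = []
    for _, row in summaries.iterrows():
        b0, b1 = row["beta0"], row["slope_unfavorable"]
        bf = row["slope_favorable"]
        # favorable segment passes through the change-point at index 0
        rows.append(
            {
                "genotype": row["genotype"],
                "segment": "unfavorable",
                "x0": i_min,
                "y0": b0 + b1 * i_min,
                "x1": 0.0,
                "y1": b0,
                "responsive": bool(row["responsive"]),
            }
        )
        rows.append(
            {
                "genotype": row["genotype"],
                "segment": "favorable",
                "x0": 0.0,
                "y0": b0,
                "x1": i_max,
                "y1": b0 + bf * i_max,
                "responsive": bool(row["responsive"]),
            }
        )
    return pd.DataFrame(rows)


def report(
    summaries: pd.DataFrame,
    anova_table,
    design,
    outdir: str | Path,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write the report bundle: genotype summary CSV, ANOVA CSV, slope-chart
    data CSV (two segments per genotype) and optional PNG charts.

    The file set is deterministic for a given input; chart underlying data
    are always emitted as CSV so the charts are testable without pixels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["summaries"] = outdir / "genotype_summaries.csv"
    summaries.to_csv(paths["summaries"], index=False, float_format="%.12g")

    paths["anova"] = outdir / "joint_anova.csv"
    anova_table.to_frame().to_csv(paths["anova"], index=False, float_format="%.12g")

    paths["index"] = outdir / "environmental_index.csv"
    design.to_frame().to_csv(paths["index"], index=False, float_format="%.12g")

    slope_data = _slope_chart_data(summaries, design)
    paths["slopes"] = outdir / "slope_segments.csv"
    slope_data.to_csv(paths["slopes"], index=False, float_format="%.12g")

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = summaries.sort_values("beta0_z")
        fig, axes = plt.subplots(1, 2, figsize=(11, 0.25 * len(order) + 2), sharey=True)
        colors0 = np.where(order["beta0_z"] > 0, "forestgreen", "firebrick")
        axes[0].barh(order["genotype"], order["beta0_z"], color=colors0)
        axes[0].set_xlabel("production (beta0) z-score")
        colors1 = np.where(order["sigma2_di_z"] < 0, "forestgreen", "firebrick")
        axes[1].barh(order["genotype"], order["sigma2_di_z"], color=colors1)
        for y, (_, row) in enumerate(order.iterrows()):
            axes[1].annotate(
                f"{row['r_squared']:.2f}", (row["sigma2_di_z"], y), fontsize=6, va="center"
            )
        axes[1].set_xlabel("stability (sigma2_di) z-score (label: R²)")
        fig.tight_layout()
        paths["zscore_chart"] = outdir / "zscore_chart.png"
        fig.savefig(paths["zscore_chart"], dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(7, 6))
        for _, seg in slope_data.iterrows():
            ax.plot(
                [seg["x0"], seg["x1"]],
                [seg["y0"], seg["y1"]],
                color="forestgreen" if seg["responsive"] else "firebrick",
                lw=0.8,
                alpha=0.7,
            )
        ax.axvline(0.0, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("environmental index")
        ax.set_ylabel("expected yield")
        ax.set_title("adaptability: slope before/after the change-point")
        fig.tight_layout()
        paths["slope_chart"] = outdir / "slope_chart.png"
        fig.savefig(paths["slope_chart"], dpi=120)
        plt.close(fig)

    return paths
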