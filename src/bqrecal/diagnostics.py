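"""Calibration and discrimination diagnostics for quality scores.

The *empirical quality* of a reported score q is the Phred transform of the
observed error rate among all bases assigned q. Perfectly calibrated scores
place every (reported, empirical) point on the 45-degree line; the
frequency-weighted squared error (FWSE)

    FWSE = sum_q f(q) * (q - e(q))^2

summarizes the vertical miss, weighted by the relative frequency f(q) of
each score. Discrimination — how well scores separate true variants from
sequencing errors among non-reference bases — is summarized by the area
under the ROC curve (rank-sum/Mann-Whitney estimator, ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .training import FilterParams

__all__ = [
    "CalibrationTable",
    "DiscriminationSet",
    "build_calibration_table",
    "fwse",
    "build_discrimination_set",
    "auc",
    "plot_diagnostics",
    "error_counts_by_read_position",
]


@dataclass(frozen=True)
class CalibrationTable:
    """Per-quality-score error tallies.

    ``table`` has one row per observed quality with columns ``quality``,
    ``count``, ``errors``, ``frequency`` (counts normalized to sum 1),
    ``empirical_quality`` and ``capped`` (True where a zero-error bin's
    undefined empirical quality was capped at ``q_max``).
    """

    table: pd.DataFrame
    q_max: int = 60

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy()


@dataclass(frozen=True)
class DiscriminationSet:
    """Quality scores of non-reference bases split into the two truth classes."""

    variant_scores: np.ndarray
    error_scores: np.ndarray


def build_calibration_table(
    quals: Iterable[int], errors: Iterable[int], q_max: int = 60
) -> CalibrationTable:
    """Group bases by assigned quality and compute empirical qualities.

    Bins with zero observed errors have no defined empirical quality; they
    are capped at ``q_max`` and marked ``capped`` so they still contribute
    to FWSE and appear in plots.
    """
    quals = np.asarray(quals)
    errors = np.asarray(errors)
    if quals.size == 0:
        raise ValueError("cannot build a calibration table from no bases")
    if quals.shape != errors.shape:
        raise ValueError("quals and errors must have equal length")
    df = pd.DataFrame({"quality": quals, "errors": errors})
    g = df.groupby("quality", sort=True)["errors"].agg(count="size", errors="sum")
    g = g.reset_index()
    g["frequency"] = g["count"] / g["count"].sum()
    rate = g["errors"] / g["count"]
    capped = g["errors"] == 0
    with np.errstate(divide="ignore"):
        emp = -10.0 * np.log10(rate.to_numpy())
    emp[capped.to_numpy()] = float(q_max)
    g["empirical_quality"] = np.minimum(emp, float(q_max))
    g["capped"] = capped
    return CalibrationTable(table=g, q_max=q_max)


def fwse(table: CalibrationTable) -> float:
    """Frequency-weighted squared error: sum_q f(q) * (q - e(q))^2.

    Empirical qualities enter unrounded; zero is perfect calibration.
    """
    t = table.table
    dev = t["quality"].to_numpy(np.float64) - t["empirical_quality"].to_numpy()
    return float(np.sum(t["frequency"].to_numpy() * dev**2))


def build_discrimination_set(
    bases: pd.DataFrame,
    snp_positions: Iterable[tuple[str, int]],
    params: FilterParams | None = None,
    min_variant_bases: int = 3,
) -> DiscriminationSet:
    """Split filtered non-reference bases into variant and error classes.

    ``bases`` is a labeled table (columns ``chrom``, ``pos``, ``qual``,
    ``is_error`` where is_error marks a reference mismatch). Positions listed
    in ``snp_positions`` form the variant class, all others the error class.
    Position-level filters mirror the training filter: an error-class
    position is kept only if its mismatch count does not exceed
    ``max(nerr, nraf * coverage)`` (more likely a novel variant or systematic
    artifact otherwise); a variant-class position is kept only if its
    mismatch count reaches ``max(min_variant_bases, nraf * coverage)``
    (otherwise the "variant" support may itself be sequencing error).
    Failing positions are dropped entirely. Only the non-reference bases'
    qualities are returned.
    """
    params = params or FilterParams()
    snp = set(snp_positions)
    if bases.empty:
        return DiscriminationSet(np.empty(0, int), np.empty(0, int))
    g = bases.groupby(["chrom", "pos"], sort=False)["is_error"].agg(
        coverage="size", n_nonref="sum"
    )
    is_snp = g.index.isin(snp)
    err_thresh = np.maximum(float(params.nerr), params.nraf * g["coverage"])
    var_thresh = np.maximum(float(min_variant_bases), params.nraf * g["coverage"])
    keep_err = ~is_snp & (g["n_nonref"] <= err_thresh)
    keep_var = is_snp & (g["n_nonref"] >= var_thresh)

    key = pd.MultiIndex.from_arrays([bases["chrom"], bases["pos"]])
    nonref = bases["is_error"].to_numpy() == 1
    err_scores = bases.loc[nonref & key.isin(g.index[keep_err]), "qual"].to_numpy()
    var_scores = bases.loc[nonref & key.isin(g.index[keep_var]), "qual"].to_numpy()
    return DiscriminationSet(variant_scores=var_scores, error_scores=err_scores)


def auc(variant_scores: np.ndarray, error_scores: np.ndarray) -> float:
    """P(random variant base outscores a random error base), ties counted 1/2.

    Computed with the rank-sum (Mann-Whitney U) estimator; variants are the
    positive class, so higher quality is more variant-like.
    """
    variant_scores = np.asarray(variant_scores, dtype=np.float64)
    error_scores = np.asarray(error_scores, dtype=np.float64)
    if variant_scores.size == 0 or error_scores.size == 0:
        raise ValueError("both score classes must be non-empty to compute AUC")
    u = mannwhitneyu(variant_scores, error_scores, alternative="two-sided").statistic
    return float(u / (variant_scores.size * error_scores.size))


def error_counts_by_read_position(training: pd.DataFrame) -> pd.Series:
    """Error count per read position over the full read length (zeros included)."""
    read_length = int(training["read_pos"].max())
    counts = (
        training.loc[training["is_error"] == 1, "read_pos"]
        .value_counts()
        .reindex(range(1, read_length + 1), fill_value=0)
        .sort_index()
    )
    counts.index.name = "read_pos"
    return counts


def _calibration_panel(ax, table: CalibrationTable, label: str, cmap: str) -> None:
    t = table.table
    lim = max(table.q_max, int(t["quality"].max()) + 2)
    ax.plot([0, lim], [0, lim], color="gray", lw=1, zorder=1)
    sc = ax.scatter(
        t["quality"],
        t["empirical_quality"],
        c=t["frequency"],
        cmap=cmap,
        edgecolors="k",
        linewidths=0.4,
        zorder=2,
    )
    ax.set_xlabel("reported quality")
    ax.set_ylabel("empirical quality")
    ax.set_title(f"{label}: FWSE = {fwse(table):.2f}")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.figure.colorbar(sc, ax=ax, label="frequency")


def plot_diagnostics(
    error_counts: pd.Series,
    flag_threshold: float,
    table_before: CalibrationTable,
    table_after: CalibrationTable,
    out_path: str | Path,
):
    """Render the four-panel diagnostic figure; returns the matplotlib Figure.

    (A) training-set error counts by read position with the flagging
    threshold as a dashed line; (B) quality-score frequency distributions
    before and after recalibration; (C)/(D) reported vs empirical quality
    before/after, points shaded by frequency, FWSE annotated in the title.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(11, 9))
    (ax_a, ax_b), (ax_c, ax_d) = axes

    ax_a.bar(error_counts.index, error_counts.to_numpy(), color="steelblue")
    ax_a.axhline(flag_threshold, color="c", linestyle="--", label="flag threshold")
    ax_a.set_xlabel("read position")
    ax_a.set_ylabel("errors")
    ax_a.set_title("A: errors by read position")
    ax_a.legend()

    tb, ta = table_before.table, table_after.table
    ax_b.plot(tb["quality"], tb["frequency"], "b-", label="before")
    ax_b.plot(ta["quality"], ta["frequency"], "r--", label="after")
    ax_b.set_xlabel("quality score")
    ax_b.set_ylabel("relative frequency")
    ax_b.set_title("B: quality-score distributions")
    ax_b.legend()

    _calibration_panel(ax_c, table_before, "C: before recalibration", "Blues")
    _calibration_panel(ax_d, table_after, "D: after recalibration", "Reds")

    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return fig
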