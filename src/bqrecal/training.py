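"""Training-set construction: error labeling and position-level filtering.

A base is called a sequencing error when it disagrees with the reference.
Some such mismatches are not errors at all — novel variants, or systematic
alignment artifacts where every read disagrees with the reference — and
would poison the labels. Two defenses are applied before fitting:

* positions listed in a known-variant file are removed wholesale, and
* any position whose mismatch count exceeds ``thresh = max(nerr, nraf * coverage)``
  is removed wholesale (all bases at the position, not just the mismatches).

Defaults ``nerr=2`` and ``nraf=0.05`` tolerate up to 2 mismatches at
low-coverage positions and a 5% non-reference allele frequency at
high-coverage ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "FilterParams",
    "PositionSummary",
    "label_errors",
    "read_known_variants",
    "exclude_known_variants",
    "compute_thresh",
    "apply_position_filter",
    "build_training_set",
    "TrainingStats",
]


@dataclass(frozen=True)
class FilterParams:
    """Position-filter parameters.

    nerr : maximum number of called errors tolerated at a position.
    nraf : maximum non-reference allele frequency tolerated at a position.
    """

    nerr: int = 2
    nraf: float = 0.05

    def __post_init__(self) -> None:
        if self.nerr < 0:
            raise ValueError(f"nerr must be >= 0, got {self.nerr}")
        if not 0.0 <= self.nraf <= 1.0:
            raise ValueError(f"nraf must lie in [0, 1], got {self.nraf}")


class PositionSummary(NamedTuple):
    """Per-position tally used by the filter (one row of the removed table)."""

    chrom: str
    pos: int
    coverage: int
    n_nonref: int


class TrainingStats(NamedTuple):
    n_input: int
    n_after_n_drop: int
    n_after_snp: int
    n_final: int
    n_removed_positions: int
    n_removed_bases: int


def label_errors(bases: pd.DataFrame) -> pd.DataFrame:
    """Add the binary ``is_error`` label (base != ref_base); drop N calls.

    Bases called N, or aligned against an N/unknown reference base, cannot be
    labeled meaningfully and are excluded.
    """
    ok = bases["base"].isin(["A", "C", "G", "T"]) & bases["ref_base"].isin(
        ["A", "C", "G", "T"]
    )
    out = bases.loc[ok].copy()
    out["is_error"] = (out["base"].to_numpy() != out["ref_base"].to_numpy()).astype(
        "int8"
    )
    return out


def read_known_variants(path: str | Path) -> set[tuple[str, int]]:
    """Read known-variant positions from a two-column TSV or a VCF.

    Only the first two whitespace-delimited columns (chromosome, 1-based
    position) are used, so a plain ``chrom<TAB>pos`` list and an uncompressed
    VCF are both accepted; ``#`` header lines are ignored.
    """
    positions: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"malformed variant line: {line!r}")
            positions.add((fields[0], int(fields[1])))
    return positions


def exclude_known_variants(
    bases: pd.DataFrame, snp_positions: Iterable[tuple[str, int]]
) -> pd.DataFrame:
    """Remove every base at a listed (chrom, pos); removal is position-wise."""
    snp = set(snp_positions)
    if not snp:
        return bases
    key = pd.MultiIndex.from_arrays([bases["chrom"], bases["pos"]])
    return bases.loc[~key.isin(snp)]


def compute_thresh(coverage: int, params: FilterParams) -> float:
    """Maximum tolerated mismatch count at a position: max(nerr, nraf * coverage).

    Returned as a real number — no rounding; the comparison against it is strict.
    """
    if coverage < 0:
        raise ValueError(f"coverage must be >= 0, got {coverage}")
    return max(float(params.nerr), params.nraf * coverage)


def apply_position_filter(
    bases: pd.DataFrame, params: FilterParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove all bases at positions with more mismatches than ``thresh``.

    Coverage is counted over the labeled, training-eligible bases handed in
    (post N-drop, post known-variant exclusion): the filter protects the
    training labels, which only those bases carry. Positions with
    ``n_nonref`` exactly equal to thresh are kept (the removal criterion is
    strict). Returns ``(kept_bases, removed_positions)`` where the second
    element is a per-position table with columns chrom, pos, coverage,
    n_nonref.
    """
    if bases.empty:
        removed = pd.DataFrame(columns=["chrom", "pos", "coverage", "n_nonref"])
        return bases, removed
    grouped = bases.groupby(["chrom", "pos"], sort=False)["is_error"].agg(
        coverage="size", n_nonref="sum"
    )
    thresh = grouped["coverage"].mul(params.nraf).clip(lower=float(params.nerr))
    bad = grouped.index[grouped["n_nonref"] > thresh]
    removed = grouped.loc[bad].reset_index()
    if len(bad) == 0:
        return bases, removed
    key = pd.MultiIndex.from_arrays([bases["chrom"], bases["pos"]])
    kept = bases.loc[~key.isin(bad)]
    return kept, removed


def build_training_set(
    bases: pd.DataFrame,
    params: FilterParams | None = None,
    snp_positions: Iterable[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, TrainingStats]:
    """Full labeling + filtering pipeline; returns the training table and tallies."""
    params = params or FilterParams()
    n_input = len(bases)
    labeled = label_errors(bases)
    n_after_n = len(labeled)
    if snp_positions:
        labeled = exclude_known_variants(labeled, snp_positions)
    n_after_snp = len(labeled)
    kept, removed = apply_position_filter(labeled, params)
    stats = TrainingStats(
        n_input=n_input,
        n_after_n_drop=n_after_n,
        n_after_snp=n_after_snp,
        n_final=len(kept),
        n_removed_positions=len(removed),
        n_removed_bases=n_after_snp - len(kept),
    )
    return kept, stats
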