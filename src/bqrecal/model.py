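"""The logistic-regression error model and Phred transform.

The probability that a base call is a sequencing error is modeled as

    logit P(error) = b0 + b1*X1 + b2*X2 + ... + b_{7+k}*X_{7+k}

with covariates X1 = reported quality, X2 = I{X1 = 0} (quality zero marks
bad/random calls and is treated separately), X3 = mean reported quality of
the containing read, X4 = read position, X5..X7 = indicators for called base
A/C/G (T is the reference category), and one indicator per *flagged* read
position — a sequencing cycle whose error count exceeds 1.5x the mean
errors per cycle, capturing the error pile-up at read ends.

Fitting follows a median-of-subsets scheme: the training table is split, in
input order, into contiguous subsets of at most ``subset_size`` bases
(default 10 million, a memory guard for genome-scale training sets); a
maximum-likelihood logistic fit is run per subset and the final coefficient
vector is the element-wise median across subsets. Predicted probabilities
are mapped to quality scores by Q = floor(-10 * log10(p)), clamped to
[0, q_max].

The public surface follows the Model/Results convention:
:class:`BaseQualityModel` holds the training design and ``.fit()`` returns a
:class:`BaseQualityResults` carrying coefficients, per-subset spread, a
``summary()`` table, prediction and BAM-rewriting methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .io_bam import RegionSpec, read_aligned_bases, write_recalibrated_bam
from .training import FilterParams, TrainingStats, build_training_set, read_known_variants

__all__ = [
    "FlaggedPositions",
    "flag_read_positions",
    "build_design_matrix",
    "fit_subsets",
    "median_coefficients",
    "predict_error_probability",
    "probability_to_phred",
    "BaseQualityModel",
    "BaseQualityResults",
]

#: Design-matrix column names preceding the flagged-position indicators.
BASE_EXOG_NAMES = [
    "intercept",
    "qual",
    "qual_is_zero",
    "read_mean_qual",
    "read_pos",
    "base_A",
    "base_C",
    "base_G",
]

DEFAULT_Q_MAX = 60
DEFAULT_SUBSET_SIZE = 10_000_000


@dataclass(frozen=True)
class FlaggedPositions:
    """Read positions whose error count exceeds ``threshold`` (ascending order)."""

    positions: tuple[int, ...]
    threshold: float

    @property
    def k(self) -> int:
        return len(self.positions)


def flag_read_positions(
    training: pd.DataFrame, multiplier: float = 1.5
) -> FlaggedPositions:
    """Flag read positions with more errors than ``multiplier`` x the per-cycle mean.

    The mean is total errors divided by read length (taken as the largest
    observed read position), so cycles with zero errors pull it down.
    """
    if training.empty:
        raise ValueError("cannot flag read positions on an empty training set")
    read_length = int(training["read_pos"].max())
    errors = training.loc[training["is_error"] == 1, "read_pos"]
    threshold = multiplier * len(errors) / read_length
    counts = errors.value_counts()
    flagged = tuple(sorted(int(p) for p in counts.index[counts > threshold]))
    return FlaggedPositions(positions=flagged, threshold=threshold)


def _design_from_arrays(
    quals: np.ndarray,
    read_mean_qual: np.ndarray,
    read_pos: np.ndarray,
    bases: np.ndarray,
    flagged: FlaggedPositions,
) -> np.ndarray:
    n = len(quals)
    X = np.empty((n, 8 + flagged.k), dtype=np.float64)
    X[:, 0] = 1.0
    X[:, 1] = quals
    X[:, 2] = quals == 0
    X[:, 3] = read_mean_qual
    X[:, 4] = read_pos
    X[:, 5] = bases == b"A"
    X[:, 6] = bases == b"C"
    X[:, 7] = bases == b"G"
    for m, fp in enumerate(flagged.positions):
        X[:, 8 + m] = read_pos == fp
    return X


def build_design_matrix(
    training: pd.DataFrame, flagged: FlaggedPositions
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One design row per training base, plus the error-label vector.

    Returns ``(X, y, names)``; columns are ordered intercept, qual,
    qual_is_zero, read_mean_qual, read_pos, base_A/C/G, then one indicator
    per flagged read position.
    """
    bases = training["base"].to_numpy(dtype="S1")
    X = _design_from_arrays(
        training["qual"].to_numpy(np.float64),
        training["read_mean_qual"].to_numpy(np.float64),
        training["read_pos"].to_numpy(np.float64),
        bases,
        flagged,
    )
    y = training["is_error"].to_numpy(np.float64)
    names = BASE_EXOG_NAMES + [f"read_pos_{fp}" for fp in flagged.positions]
    return X, y, names


def fit_subsets(
    X: np.ndarray,
    y: np.ndarray,
    subset_size: int = DEFAULT_SUBSET_SIZE,
    maxiter: int = 25,
    tol: float = 1e-8,
) -> np.ndarray:
    """Fit one logistic regression per contiguous subset of at most ``subset_size`` rows.

    Subsets are slices in input order. A subset containing a single response
    class is skipped with a warning; within a subset, a constant non-intercept
    column is dropped and its coefficient recorded as NaN (absent from that
    subset's vector). Returns an (n_converged_subsets, n_columns) matrix.
    """
    n, p = X.shape
    if n == 0:
        raise ValueError("empty design matrix")
    n_subsets = -(-n // subset_size)
    rows: list[np.ndarray] = []
    for s in range(n_subsets):
        sl = slice(s * subset_size, min((s + 1) * subset_size, n))
        Xs, ys = X[sl], y[sl]
        if ys.min() == ys.max():
            warnings.warn(
                f"subset {s + 1}/{n_subsets} contains a single response class; skipped"
            )
            continue
        keep = np.ones(p, dtype=bool)
        keep[1:] = (Xs[1:, 1:] != Xs[0, 1:]).any(axis=0) if len(Xs) > 1 else True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(ys, Xs[:, keep], family=sm.families.Binomial()).fit(
                    maxiter=maxiter, tol=tol
                )
            if not getattr(res, "converged", True):
                warnings.warn(f"subset {s + 1}/{n_subsets} did not converge; skipped")
                continue
        except Exception as exc:  # degenerate subset (e.g. perfect separation)
            warnings.warn(f"subset {s + 1}/{n_subsets} failed to fit ({exc}); skipped")
            continue
        coefs = np.full(p, np.nan)
        coefs[keep] = res.params
        rows.append(coefs)
    if not rows:
        raise ValueError("no subset produced a converged logistic fit")
    return np.vstack(rows)


def median_coefficients(subset_coefficients: np.ndarray) -> np.ndarray:
    """Element-wise median across subset fits; NaN entries are absent, not zero."""
    subset_coefficients = np.asarray(subset_coefficients, dtype=np.float64)
    if subset_coefficients.size == 0:
        raise ValueError("no subset coefficients to combine")
    if subset_coefficients.ndim == 1:
        subset_coefficients = subset_coefficients[None, :]
    all_nan = np.isnan(subset_coefficients).all(axis=0)
    if all_nan.any():
        warnings.warn(
            "some covariates were constant in every subset; their coefficients are set to 0"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(subset_coefficients, axis=0)
    med[all_nan] = 0.0
    return med


def predict_error_probability(coefficients: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Inverse-logit of the linear predictor; values lie strictly inside (0, 1)."""
    p = expit(np.asarray(X, dtype=np.float64) @ np.asarray(coefficients, np.float64))
    # expit underflows to exactly 0/1 for |eta| > ~37; keep the open interval
    return np.clip(p, 1e-300, 1.0 - 1e-16)


def probability_to_phred(p, q_max: int = DEFAULT_Q_MAX):
    """Phred transform floor(-10 * log10(p)), clamped to [0, q_max].

    Accepts a scalar or array; raises for p <= 0 or p > 1.
    """
    arr = np.asarray(p, dtype=np.float64)
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("probabilities must lie in (0, 1]")
    q = np.clip(np.floor(-10.0 * np.log10(arr)), 0, q_max).astype(np.int64)
    return int(q) if np.isscalar(p) or arr.ndim == 0 else q


class BaseQualityModel:
    """Logistic error model over a labeled training table of aligned bases.

    Parameters
    ----------
    training : DataFrame
        Labeled training bases (columns ``qual``, ``read_mean_qual``,
        ``read_pos``, ``base``, ``is_error``), typically produced by
        :func:`bqrecal.training.build_training_set`.
    flag_multiplier : float
        Multiplier on the mean per-cycle error count above which a read
        position receives its own indicator covariate.
    subset_size : int
        Maximum rows per logistic fit; the full fit is the per-coefficient
        median across subsets.
    q_max : int
        Cap on output quality scores (the Phred transform of very small
        predicted probabilities is clamped here).
    """

    def __init__(
        self,
        training: pd.DataFrame,
        flag_multiplier: float = 1.5,
        subset_size: int = DEFAULT_SUBSET_SIZE,
        q_max: int = DEFAULT_Q_MAX,
        filter_params: FilterParams | None = None,
        region: RegionSpec | None = None,
    ) -> None:
        if training.empty:
            raise ValueError("training set is empty")
        self.training = training
        self.flag_multiplier = flag_multiplier
        self.subset_size = subset_size
        self.q_max = q_max
        self.filter_params = filter_params or FilterParams()
        self.region = region
        self.training_stats: TrainingStats | None = None
        self.flagged = flag_read_positions(training, flag_multiplier)
        self.exog, self.endog, self.exog_names = build_design_matrix(
            training, self.flagged
        )

    @classmethod
    def from_bam(
        cls,
        bam_path: str | Path,
        ref_path: str | Path,
        region: RegionSpec | str,
        snp: str | Path | set | None = None,
        filter_params: FilterParams | None = None,
        max_train: int | None = None,
        **kwargs,
    ) -> "BaseQualityModel":
        """Build the model from a training region of a sorted, indexed BAM.

        ``region`` may be a :class:`RegionSpec` or a ``"chrom:start-end"``
        string; ``snp`` a known-variant file path (TSV or VCF) or a set of
        ``(chrom, pos)`` tuples.
        """
        import pysam

        if isinstance(region, str):
            with pysam.FastaFile(str(ref_path)) as fa:
                lengths = dict(zip(fa.references, fa.lengths))
            region = RegionSpec.parse(region, lengths, max_train=max_train)
        elif max_train is not None and region.max_train is None:
            region = RegionSpec(region.chrom, region.start, region.end, max_train)
        filter_params = filter_params or FilterParams()
        snp_positions = None
        if snp is not None:
            snp_positions = snp if isinstance(snp, set) else read_known_variants(snp)
        bases = read_aligned_bases(bam_path, region, ref_path)
        training, stats = build_training_set(bases, filter_params, snp_positions)
        if training.empty:
            raise ValueError("no training bases survive labeling and filtering")
        model = cls(training, filter_params=filter_params, region=region, **kwargs)
        model.training_stats = stats
        return model

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def fit(self, maxiter: int = 25, tol: float = 1e-8) -> "BaseQualityResults":
        """Fit per-subset logistic regressions and combine by coefficient medians."""
        subset_coefs = fit_subsets(
            self.exog, self.endog, self.subset_size, maxiter=maxiter, tol=tol
        )
        params = median_coefficients(subset_coefs)
        return BaseQualityResults(
            params=pd.Series(params, index=self.exog_names),
            subset_params=pd.DataFrame(subset_coefs, columns=self.exog_names),
            flagged=self.flagged,
            q_max=self.q_max,
            model=self,
        )


@dataclass
class BaseQualityResults:
    """Fitted recalibration model: median coefficients plus per-subset fits.

    Self-contained for prediction — a results object loaded from JSON (no
    attached model, no subset matrix) can still rewrite BAMs.
    """

    params: pd.Series
    flagged: FlaggedPositions
    q_max: int = DEFAULT_Q_MAX
    subset_params: pd.DataFrame | None = None
    model: BaseQualityModel | None = field(default=None, repr=False)

    @property
    def coefficients(self) -> np.ndarray:
        return self.params.to_numpy()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Predicted error probability for design-matrix rows."""
        return predict_error_probability(self.coefficients, X)

    def predict_quality(self, X: np.ndarray) -> np.ndarray:
        """Recalibrated integer quality for design-matrix rows."""
        return probability_to_phred(self.predict_proba(X), self.q_max)

    def recalibrate_read(self, quals: np.ndarray, seq: str) -> np.ndarray:
        """Recalibrated qualities for one read's full QUAL string.

        Requires only read-level covariates (no reference), so every base of
        every read — aligned, clipped or unmapped — can be rescored.
        """
        quals = np.asarray(quals, dtype=np.float64)
        n = len(quals)
        X = _design_from_arrays(
            quals,
            np.full(n, quals.mean() if n else 0.0),
            np.arange(1, n + 1, dtype=np.float64),
            np.frombuffer(seq.encode("ascii"), dtype="S1"),
            self.flagged,
        )
        return self.predict_quality(X)

    def recalibrate_table(self, bases: pd.DataFrame) -> np.ndarray:
        """Recalibrated qualities for a table of aligned bases."""
        X = _design_from_arrays(
            bases["qual"].to_numpy(np.float64),
            bases["read_mean_qual"].to_numpy(np.float64),
            bases["read_pos"].to_numpy(np.float64),
            bases["base"].to_numpy(dtype="S1"),
            self.flagged,
        )
        return self.predict_quality(X)

    def write_bam(self, bam_in: str | Path, bam_out: str | Path, index: bool = False):
        """Write a copy of ``bam_in`` with every QUAL string recalibrated."""
        return write_recalibrated_bam(bam_in, bam_out, self, index=index)

    def summary(self) -> str:
        """Human-readable fit summary: coefficients and their across-subset spread."""
        lines = ["Base-quality recalibration model (logistic regression)"]
        if self.model is not None:
            lines.append(f"  training bases: {self.model.nobs}")
            if self.model.region is not None:
                r = self.model.region
                lines.append(f"  training region: {r.chrom}:{r.start}-{r.end}")
        lines.append(
            f"  flagged read positions (> {self.flagged.threshold:.2f} errors): "
            f"{list(self.flagged.positions) or 'none'}"
        )
        tbl = pd.DataFrame({"coef": self.params})
        if self.subset_params is not None and len(self.subset_params) > 1:
            tbl["subset_min"] = self.subset_params.min()
            tbl["subset_max"] = self.subset_params.max()
            lines.append(f"  subsets combined: {len(self.subset_params)}")
        lines.append("")
        lines.append(tbl.to_string(float_format=lambda v: f"{v: .6g}"))
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize to a small JSON document (train once, apply to many BAMs)."""
        doc = {
            "format": "bqrecal-model",
            "version": 1,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "flagged_positions": list(self.flagged.positions),
            "flag_threshold": self.flagged.threshold,
            "q_max": self.q_max,
        }
        if self.model is not None:
            doc["n_training"] = self.model.nobs
            fp = self.model.filter_params
            doc["filter_params"] = {"nerr": fp.nerr, "nraf": fp.nraf}
            if self.model.region is not None:
                r = self.model.region
                doc["region"] = f"{r.chrom}:{r.start}-{r.end}"
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BaseQualityResults":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "bqrecal-model":
            raise ValueError(f"{path} is not a bqrecal model file")
        return cls(
            params=pd.Series(doc["coefficients"]),
            flagged=FlaggedPositions(
                positions=tuple(doc["flagged_positions"]),
                threshold=float(doc["flag_threshold"]),
            ),
            q_max=int(doc["q_max"]),
        )
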