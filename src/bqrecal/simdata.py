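"""Synthetic references and aligned reads with controlled miscalibration.

The simulator emulates the features of short-read data that drive
recalibration: fixed-length single-end reads, error rates elevated at read
ends, reported qualities systematically off from the true error probability
(by default the true probability is ``distortion_factor`` times the
probability the reported Phred score implies), planted heterozygous/true
variants, and fully non-reference "systematic" positions where every
overlapping read disagrees with the reference (mapping-artifact mimics).
Alongside each BAM a per-base truth table records which bases really are
sequencing errors and which carry a planted variant allele, so calibration
can be judged against actual errors rather than reference mismatches.

Reads are ungapped (CIGAR ``<L>M``), forward strand, MAPQ 60: enough to
exercise every algorithmic path without modeling indels or pairing.
"""

from __future__ import annotations

from array import array
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ErrorModelSpec",
    "SimulationTruth",
    "generate_reference",
    "simulate_bam",
    "default_position_multiplier",
    "default_quality_distribution",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


def default_position_multiplier(read_length: int) -> np.ndarray:
    """Error-rate multipliers by cycle: mild elevation at the start, strong ramp at the end."""
    mult = np.ones(read_length)
    mult[: min(3, read_length)] = 1.5
    tail = min(15, read_length)
    mult[read_length - tail :] = np.linspace(1.2, 4.0, tail)
    return mult


def default_quality_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Reported-quality distribution: half the bases near Q40, a low-quality tail."""
    values = np.concatenate(
        [[0, 2, 5, 10, 15], np.arange(20, 30), np.arange(30, 40), [40]]
    )
    weights = np.concatenate(
        [np.full(5, 0.01), np.full(10, 0.015), np.full(10, 0.03), [0.5]]
    )
    return values, weights / weights.sum()


@dataclass
class ErrorModelSpec:
    """Parameters of the simulated sequencing-error process.

    True per-base error probability is
    ``min(distortion_factor * 10**(-q/10) * position_multiplier, max_error_prob)``
    where q is the reported quality — i.e. reported scores are miscalibrated
    by a constant factor on the probability scale, on top of a
    position-dependent profile. ``variant_sites`` maps a 1-based reference
    position to ``(alt_base, allele_frequency)``; ``systematic_sites`` maps a
    position to an alt base carried by *every* overlapping read (and is not
    counted as a variant site in the truth table).
    """

    read_length: int = 76
    distortion_factor: float = 10.0
    position_multiplier: np.ndarray | None = None
    quality_values: np.ndarray | None = None
    quality_weights: np.ndarray | None = None
    variant_sites: dict[int, tuple[str, float]] = field(default_factory=dict)
    systematic_sites: dict[int, str] = field(default_factory=dict)
    max_error_prob: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.position_multiplier is None:
            self.position_multiplier = default_position_multiplier(self.read_length)
        self.position_multiplier = np.asarray(self.position_multiplier, np.float64)
        if len(self.position_multiplier) != self.read_length:
            raise ValueError("position_multiplier length must equal read_length")
        if self.quality_values is None or self.quality_weights is None:
            self.quality_values, self.quality_weights = default_quality_distribution()
        self.quality_values = np.asarray(self.quality_values)
        self.quality_weights = np.asarray(self.quality_weights, np.float64)
        self.quality_weights = self.quality_weights / self.quality_weights.sum()
        if not 0.0 <= self.max_error_prob <= 1.0:
            raise ValueError("max_error_prob must lie in [0, 1]")
        for pos, (alt, freq) in self.variant_sites.items():
            if alt not in _BASE_CODE or not 0.0 <= freq <= 1.0:
                raise ValueError(f"bad variant site {pos}: ({alt}, {freq})")

    def true_error_probability(self, quals: np.ndarray) -> np.ndarray:
        """Per-base true error probability for an (n_reads, read_length) quality array."""
        p = self.distortion_factor * np.power(10.0, -np.asarray(quals, float) / 10.0)
        return np.clip(p * self.position_multiplier[None, :], 0.0, self.max_error_prob)


@dataclass
class SimulationTruth:
    """Per-base ground truth for a simulated BAM (row i = read ``sim_{i}``)."""

    chrom: str
    starts: np.ndarray  # 0-based leftmost reference position per read
    quals: np.ndarray  # (n_reads, read_length) reported qualities
    seq_codes: np.ndarray  # (n_reads, read_length) base codes 0..3 = ACGT
    is_error: np.ndarray  # (n_reads, read_length) true sequencing-error flag
    is_variant: np.ndarray  # (n_reads, read_length) base carries a planted variant allele

    @property
    def n_reads(self) -> int:
        return len(self.starts)

    @property
    def read_length(self) -> int:
        return self.quals.shape[1]

    def read_name(self, i: int) -> str:
        return f"sim_{i:07d}"

    def read_sequence(self, i: int) -> str:
        return _BASES[self.seq_codes[i]].tobytes().decode()

    def to_frame(self) -> pd.DataFrame:
        n, L = self.quals.shape
        return pd.DataFrame(
            {
                "read": np.repeat([self.read_name(i) for i in range(n)], L),
                "read_pos": np.tile(np.arange(1, L + 1), n),
                "pos": (self.starts[:, None] + np.arange(L)[None, :]).ravel() + 1,
                "is_error": self.is_error.ravel().astype(int),
                "is_variant_site": self.is_variant.ravel().astype(int),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def generate_reference(
    length: int,
    seed: int,
    out_path: str | Path | None = None,
    name: str = "simchr",
) -> str:
    """Uniform-random A/C/G/T sequence; written (and faidx-indexed) if a path is given."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, length, 70):
                fh.write(seq[i : i + 70] + "\n")
        pysam.faidx(str(out_path))
    return seq


def simulate_bam(
    ref: str | Path,
    spec: ErrorModelSpec,
    n_reads: int,
    out_bam: str | Path,
    truth_tsv: str | Path | None = None,
) -> SimulationTruth:
    """Simulate ``n_reads`` reads from a reference FASTA; write a sorted, indexed BAM.

    Read start positions are uniform over the reference; the output is
    coordinate sorted and indexed, and the returned truth object (also
    written as TSV when ``truth_tsv`` is given) flags every base as
    error / variant-carrier / clean. Deterministic under ``spec.seed``.
    """
    with pysam.FastaFile(str(ref)) as fa:
        chrom = fa.references[0]
        ref_seq = fa.fetch(chrom).upper()
    L = spec.read_length
    if L > len(ref_seq):
        raise ValueError("read_length exceeds reference length")
    rng = np.random.default_rng(spec.seed)

    ref_codes = np.frombuffer(ref_seq.encode("ascii"), dtype="S1")
    ref_codes = np.searchsorted(_BASES, ref_codes)  # ACGT -> 0..3 (ref is ACGT-only)

    starts = np.sort(rng.integers(0, len(ref_seq) - L + 1, size=n_reads))
    offsets = np.arange(L)
    seq_codes = ref_codes[starts[:, None] + offsets[None, :]].astype(np.uint8)
    quals = rng.choice(spec.quality_values, size=(n_reads, L), p=spec.quality_weights)
    quals = quals.astype(np.uint8)

    is_variant = np.zeros((n_reads, L), dtype=bool)
    planted = [(p, a, f, True) for p, (a, f) in spec.variant_sites.items()]
    planted += [(p, a, 1.0, False) for p, a in spec.systematic_sites.items()]
    for pos1, alt, freq, count_as_variant in planted:
        pos0 = pos1 - 1
        rows = np.nonzero((starts <= pos0) & (pos0 < starts + L))[0]
        if rows.size == 0:
            continue
        carrier = rng.random(rows.size) < freq
        rows = rows[carrier]
        cols = pos0 - starts[rows]
        seq_codes[rows, cols] = _BASE_CODE[alt]
        if count_as_variant:
            is_variant[rows, cols] = True

    p_true = spec.true_error_probability(quals)
    is_error = (rng.random((n_reads, L)) < p_true) & ~is_variant
    shift = rng.integers(1, 4, size=(n_reads, L), dtype=np.uint8)
    seq_codes[is_error] = (seq_codes[is_error] + shift[is_error]) % 4

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(ref_seq)}],
    }
    truth = SimulationTruth(
        chrom=chrom,
        starts=starts,
        quals=quals,
        seq_codes=seq_codes,
        is_error=is_error,
        is_variant=is_variant,
    )
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for i in range(n_reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = truth.read_name(i)
            a.flag = 0
            a.reference_id = 0
            a.reference_start = int(starts[i])
            a.mapping_quality = 60
            a.cigartuples = [(0, L)]
            a.query_sequence = truth.read_sequence(i)
            a.query_qualities = array("B", quals[i])
            bam.write(a)
    pysam.index(str(out_bam))
    if truth_tsv is not None:
        truth.to_tsv(truth_tsv)
    return truth
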