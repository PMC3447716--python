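"""BAM input/output: extract aligned bases from a training region, rewrite QUAL.

Aligned bases are returned as a :class:`pandas.DataFrame` (one row per base,
columns :data:`BASE_COLUMNS`) rather than a list of per-base objects: training
regions routinely hold millions of bases and every downstream step is
vectorised. :class:`AlignedBase` is provided as the record-level view of a
single row.

Coordinate conventions: user-facing regions are 1-based inclusive (samtools
``chrom:start-end`` style); all internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import re
from array import array
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "RegionSpec",
    "AlignedBase",
    "BASE_COLUMNS",
    "RecalibrationSummary",
    "read_aligned_bases",
    "write_recalibrated_bam",
]

#: Columns of the aligned-base table, in order.
BASE_COLUMNS = ["chrom", "pos", "read_pos", "base", "qual", "read_mean_qual", "ref_base"]

# CIGAR operation codes (BAM spec): M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_CONSUMES_BOTH = (0, 7, 8)
_CONSUMES_QUERY = (1, 4)
_CONSUMES_REF = (2, 3)

_REGION_RE = re.compile(r"^([^:]+)(?::([\d,]+)-([\d,]+))?$")


class AlignedBase(NamedTuple):
    """A single aligned base with the read-level context the error model uses.

    ``read_pos`` is the 1-based offset of the base within the read as stored
    in the BAM record (reference orientation); ``read_mean_qual`` is the mean
    over the read's full QUAL string, clipping included.
    """

    chrom: str
    pos: int
    read_pos: int
    base: str
    qual: int
    read_mean_qual: float
    ref_base: str


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive genomic interval, optionally capped at ``max_train`` bases."""

    chrom: str
    start: int
    end: int
    max_train: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) must be >= start ({self.start})")
        if self.max_train is not None and self.max_train <= 0:
            raise ValueError(f"max_train must be positive, got {self.max_train}")

    @classmethod
    def parse(
        cls,
        region: str,
        chrom_lengths: dict[str, int] | None = None,
        max_train: int | None = None,
    ) -> "RegionSpec":
        """Parse ``"chrom:start-end"`` or bare ``"chrom"`` (needs ``chrom_lengths``)."""
        m = _REGION_RE.match(region.strip())
        if not m:
            raise ValueError(f"cannot parse region string {region!r}")
        chrom, start, end = m.groups()
        if start is None:
            if chrom_lengths is None or chrom not in chrom_lengths:
                raise ValueError(
                    f"bare chromosome region {chrom!r} requires a known chromosome length"
                )
            return cls(chrom, 1, chrom_lengths[chrom], max_train)
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")), max_train)

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        """Exclusive 0-based end."""
        return self.end


class RecalibrationSummary(NamedTuple):
    reads_written: int
    bases_recalibrated: int


def _aligned_index_arrays(read: pysam.AlignedSegment) -> tuple[np.ndarray, np.ndarray]:
    """Query and reference index arrays for CIGAR match/mismatch bases only."""
    q_blocks: list[np.ndarray] = []
    r_blocks: list[np.ndarray] = []
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples:
        if op in _CONSUMES_BOTH:
            q_blocks.append(np.arange(qpos, qpos + length))
            r_blocks.append(np.arange(rpos, rpos + length))
            qpos += length
            rpos += length
        elif op in _CONSUMES_QUERY:
            qpos += length
        elif op in _CONSUMES_REF:
            rpos += length
    if not q_blocks:
        empty = np.empty(0, dtype=int)
        return empty, empty
    return np.concatenate(q_blocks), np.concatenate(r_blocks)


def read_aligned_bases(
    bam_path: str | Path,
    region: RegionSpec,
    ref: str | Path | pysam.FastaFile,
) -> pd.DataFrame:
    """Collect aligned (CIGAR match/mismatch) bases inside ``region``.

    Insertions, deletions and soft clips contribute no rows; reads flagged
    unmapped, secondary or duplicate are skipped. When ``region.max_train``
    is set, collection stops after that many bases (counted before any
    downstream filtering). Returns a DataFrame with :data:`BASE_COLUMNS`.
    """
    own_ref = isinstance(ref, (str, Path))
    fasta = pysam.FastaFile(str(ref)) if own_ref else ref
    try:
        if region.chrom not in fasta.references:
            raise ValueError(f"chromosome {region.chrom!r} not present in reference")
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            if not bam.has_index():
                raise FileNotFoundError(f"BAM index not found for {bam_path}")
            if region.chrom not in bam.references:
                raise ValueError(f"chromosome {region.chrom!r} not present in BAM header")
            # Reference slice can exceed the chromosome; fetch what exists.
            ref_seq = fasta.fetch(region.chrom, region.start0, region.end0).upper()
            ref_arr = np.frombuffer(ref_seq.encode("ascii"), dtype="S1")

            pos_chunks: list[np.ndarray] = []
            rpos_chunks: list[np.ndarray] = []
            base_chunks: list[np.ndarray] = []
            qual_chunks: list[np.ndarray] = []
            meanq_chunks: list[np.ndarray] = []
            collected = 0
            cap = region.max_train
            for read in bam.fetch(region.chrom, region.start0, region.end0):
                if read.is_unmapped or read.is_secondary or read.is_duplicate:
                    continue
                if read.query_qualities is None or read.cigartuples is None:
                    continue
                q_idx, r_idx = _aligned_index_arrays(read)
                inside = (r_idx >= region.start0) & (r_idx < region.end0)
                # guard against reference slice shorter than the region
                inside &= r_idx < region.start0 + len(ref_arr)
                if not inside.any():
                    continue
                q_idx = q_idx[inside]
                r_idx = r_idx[inside]
                quals = np.asarray(read.query_qualities, dtype=np.int64)
                seq = np.frombuffer(read.query_sequence.encode("ascii"), dtype="S1")
                if cap is not None and collected + len(q_idx) > cap:
                    take = cap - collected
                    q_idx, r_idx = q_idx[:take], r_idx[:take]
                pos_chunks.append(r_idx + 1)
                rpos_chunks.append(q_idx + 1)
                base_chunks.append(seq[q_idx])
                qual_chunks.append(quals[q_idx])
                meanq_chunks.append(np.full(len(q_idx), quals.mean()))
                collected += len(q_idx)
                if cap is not None and collected >= cap:
                    break
    finally:
        if own_ref:
            fasta.close()
    if not pos_chunks:
        return pd.DataFrame(columns=BASE_COLUMNS)
    pos = np.concatenate(pos_chunks)
    return pd.DataFrame(
        {
            "chrom": region.chrom,
            "pos": pos,
            "read_pos": np.concatenate(rpos_chunks),
            "base": np.concatenate(base_chunks).astype("U1"),
            "qual": np.concatenate(qual_chunks),
            "read_mean_qual": np.concatenate(meanq_chunks),
            "ref_base": ref_arr[pos - 1 - region.start0].astype("U1"),
        }
    )[BASE_COLUMNS]


def write_recalibrated_bam(
    bam_in: str | Path,
    bam_out: str | Path,
    model,
    index: bool = False,
) -> RecalibrationSummary:
    """Copy ``bam_in`` to ``bam_out`` replacing every QUAL string.

    All other fields (FLAG, POS, CIGAR, SEQ, tags, record order) are
    preserved bitwise. Every record — aligned or not — is recalibrated,
    since prediction needs only read-level covariates, no reference.

    ``model`` is a fitted results object exposing
    ``recalibrate_read(quals, seq) -> ndarray`` (see
    :class:`bqrecal.model.BaseQualityResults`).
    """
    if getattr(model, "params", None) is None:
        raise ValueError("model is not fitted; call .fit() first")
    reads = 0
    bases = 0
    with pysam.AlignmentFile(str(bam_in), "rb") as src:
        with pysam.AlignmentFile(str(bam_out), "wb", template=src) as dst:
            for read in src.fetch(until_eof=True):
                quals = read.query_qualities
                if quals is not None and read.query_sequence is not None:
                    new_quals = model.recalibrate_read(
                        np.asarray(quals, dtype=np.int64), read.query_sequence
                    )
                    read.query_qualities = array("B", new_quals.astype(np.uint8))
                    bases += len(new_quals)
                dst.write(read)
                reads += 1
    if index:
        pysam.index(str(bam_out))
    return RecalibrationSummary(reads_written=reads, bases_recalibrated=bases)
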