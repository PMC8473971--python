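"""Classifier predictors from read alignments.

The three predictors of TE presence are the read support over the 10 bp
window internal to each TE edge, plus the TE order. Window support is the
number of MQ-filtered reads overlapping the window by at least one base
(the semantics of ``bedtools multicov``); a per-base mean-depth variant is
available behind ``mode="mean_depth"``.

Alignments may be given as a pysam :class:`~pysam.AlignmentFile` (BAM/SAM),
a path to one, or a read-interval :class:`~pandas.DataFrame` with columns
``chrom, start, end, mq`` (1-based inclusive aligned reference span).
Secondary, supplementary and duplicate records are always excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotations import TEAnnotation

READ_COLUMNS = ["chrom", "start", "end", "mq"]


@dataclass(frozen=True)
class EdgeWindows:
    """The two 10 bp windows internal to a TE's start and end."""

    start_window: tuple[int, int]
    end_window: tuple[int, int]


@dataclass(frozen=True)
class SampleCoverage:
    """Realized (observed, MQ-filtered) fold coverage of one sample."""

    sample_id: str
    realized_depth: float


def edge_windows(te: TEAnnotation) -> EdgeWindows:
    """Windows of length min(10, TE length) at each internal TE edge.

    Short TEs degrade gracefully: below 20 bp the windows overlap, below
    10 bp both equal the whole TE interval.
    """
    w = min(10, te.length)
    return EdgeWindows(
        start_window=(te.start, te.start + w - 1),
        end_window=(te.end - w + 1, te.end),
    )


def edge_windows_table(tes: Sequence[TEAnnotation]) -> pd.DataFrame:
    """Both edge windows per TE as a 1-based interval table (BED-exportable
    via :func:`tepav.annotations.write_bed`)."""
    rows = []
    for te in tes:
        ew = edge_windows(te)
        rows.append((te.chrom, ew.start_window[0], ew.start_window[1], f"{te.te_id}:start"))
        rows.append((te.chrom, ew.end_window[0], ew.end_window[1], f"{te.te_id}:end"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Alignment access


def load_read_table(path: str | Path | pysam.AlignmentFile) -> pd.DataFrame:
    """Flatten primary alignments to a (chrom, start, end, mq) table.

    Coordinates are the 1-based inclusive reference span of each aligned
    record. Unmapped, secondary, supplementary and duplicate records are
    dropped.
    """
    if isinstance(path, pysam.AlignmentFile):
        aln = path
        close = False
    else:
        aln = pysam.AlignmentFile(str(path))
        close = True
    rows = []
    try:
        for read in aln.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            rows.append(
                (read.reference_name, read.reference_start + 1, read.reference_end, read.mapping_quality)
            )
    finally:
        if close:
            aln.close()
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def _as_read_table(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        missing = set(READ_COLUMNS) - set(alignments.columns)
        if missing:
            raise ValueError(f"read table missing columns {sorted(missing)}")
        return alignments
    return load_read_table(alignments)


def window_read_count(
    alignments,
    chrom: str,
    window: tuple[int, int],
    min_mq: int = 20,
    mode: str = "count",
) -> float:
    """Read support for one window.

    ``mode="count"`` (default, multicov semantics): number of MQ-passing
    reads whose aligned span overlaps the window by >= 1 base.
    ``mode="mean_depth"``: mean per-base depth over the window.
    """
    reads = _as_read_table(alignments)
    s, e = window
    sub = reads[
        (reads["chrom"] == chrom)
        & (reads["mq"] >= min_mq)
        & (reads["start"] <= e)
        & (reads["end"] >= s)
    ]
    if mode == "count":
        return float(len(sub))
    if mode == "mean_depth":
        overlap = np.minimum(sub["end"].to_numpy(), e) - np.maximum(
            sub["start"].to_numpy(), s
        ) + 1
        return float(overlap.sum()) / (e - s + 1)
    raise ValueError(f"unknown mode {mode!r}")


def feature_table(
    tes: Sequence[TEAnnotation],
    alignments,
    sample_id: str,
    min_mq: int = 20,
    mode: str = "count",
    reference_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-TE predictor rows (te_id, sample_id, start_cov, end_cov, order).

    A TE on a chromosome absent from the alignment header (when one is
    available) gets NaN coverage and a warning rather than a silent zero.
    """
    if reference_names is None and isinstance(alignments, (str, Path, pysam.AlignmentFile)):
        aln = (
            alignments
            if isinstance(alignments, pysam.AlignmentFile)
            else pysam.AlignmentFile(str(alignments))
        )
        reference_names = list(aln.references)
    reads = _as_read_table(alignments)
    reads = reads[reads["mq"] >= min_mq]

    # per-chromosome sorted arrays: count = #(start <= e) - #(end < s)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in reads.groupby("chrom"):
        by_chrom[chrom] = (
            np.sort(sub["start"].to_numpy()),
            np.sort(sub["end"].to_numpy()),
        )

    missing_chroms = set()
    rows = []
    for te in tes:
        if reference_names is not None and te.chrom not in reference_names:
            missing_chroms.add(te.chrom)
            rows.append((te.te_id, sample_id, np.nan, np.nan, te.order))
            continue
        ew = edge_windows(te)
        covs = []
        for s, e in (ew.start_window, ew.end_window):
            if te.chrom not in by_chrom:
                covs.append(0.0)
            elif mode == "count":
                starts, ends = by_chrom[te.chrom]
                covs.append(
                    float(
                        np.searchsorted(starts, e, side="right")
                        - np.searchsorted(ends, s - 1, side="right")
                    )
                )
            else:
                covs.append(
                    window_read_count(
                        reads[reads["chrom"] == te.chrom], te.chrom, (s, e), min_mq=0, mode=mode
                    )
                )
        rows.append((te.te_id, sample_id, covs[0], covs[1], te.order))
    if missing_chroms:
        warnings.warn(
            f"sample {sample_id}: chromosomes absent from alignment header: "
            f"{sorted(missing_chroms)}; coverage recorded as missing"
        )
    return pd.DataFrame(
        rows, columns=["te_id", "sample_id", "start_cov", "end_cov", "order"]
    )


def realized_coverage(
    alignments,
    assembly_length: int,
    sample_id: str = "",
    min_mq: int = 20,
) -> SampleCoverage:
    """Observed fold coverage: MQ-filtered aligned bases / assembly length.

    This is the realized (post-alignment, post-filter) depth, distinct from
    the theoretical depth implied by raw read counts.
    """
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    reads = _as_read_table(alignments)
    sub = reads[reads["mq"] >= min_mq]
    aligned = int((sub["end"] - sub["start"] + 1).sum())
    if aligned == 0:
        warnings.warn(f"sample {sample_id!r}: zero aligned bases; depth 0")
    return SampleCoverage(sample_id=sample_id, realized_depth=aligned / assembly_length)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"te_id": str, "sample_id": str})
    return df
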