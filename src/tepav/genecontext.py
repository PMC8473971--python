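"""Gene-proximity categories, bootstrap backgrounds, region membership.

Each TE gets exactly one of 13 gene-proximity categories, assigned by a
fixed hierarchy: the first category in :data:`CATEGORY_ORDER` that
applies to any gene wins. "Completely within" means the TE interval is a
subset of the feature interval (closed coordinates); partial overlaps
fall through to the flank rules with distance zero. Flank distances run
from the gene's strand-aware boundary to the nearest TE edge, with bins
(0,1kb], (1kb,5kb] and (5kb,10kb]; anything farther than 10 kb from
every gene is intergenic.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel, TEAnnotation, merge_intervals
from .popfreq import FREQUENCY_CLASSES, frequency_class

CATEGORY_ORDER = (
    "gene_within_te",
    "in_5utr",
    "in_3utr",
    "in_exon",
    "in_intron",
    "within_gene",
    "up_0_1kb",
    "up_1_5kb",
    "up_5_10kb",
    "down_0_1kb",
    "down_1_5kb",
    "down_5_10kb",
    "intergenic",
)

_FLANK_BINS = ((0, 1000, "0_1kb"), (1000, 5000, "1_5kb"), (5000, 10000, "5_10kb"))


def _within(te: TEAnnotation, interval: tuple[int, int]) -> bool:
    return interval[0] <= te.start and te.end <= interval[1]


def _flank(te: TEAnnotation, gene: GeneModel) -> tuple[str | None, int]:
    """(side, distance) of the TE relative to one gene.

    side is "up"/"down" by gene strand; distance is gene boundary to the
    nearest TE edge, 0 for any overlap.
    """
    if te.end < gene.start:
        d = gene.start - te.end
        left = True
    elif te.start > gene.end:
        d = te.start - gene.end
        left = False
    else:  # partial overlap (full containment handled before flank rules)
        d = 0
        mid = (te.start + te.end) / 2
        left = mid < (gene.start + gene.end) / 2
    side = ("up" if left else "down") if gene.strand == "+" else ("down" if left else "up")
    return side, d


def categorize_te(
    te: TEAnnotation, genes: Sequence[GeneModel]
) -> tuple[str, str | None, int | None]:
    """Assign a TE its gene-proximity category.

    Returns (category, nearest gene id, distance to that gene); the
    nearest gene is by edge-to-edge distance (0 when overlapping) and is
    None for TEs with no gene on their chromosome.
    """
    near = [g for g in genes if g.chrom == te.chrom]
    applicable: set[str] = set()
    nearest_gene: str | None = None
    nearest_d: int | None = None
    for gene in near:
        overlap = te.start <= gene.end and te.end >= gene.start
        contains_gene = te.start <= gene.start and gene.end <= te.end
        te_within = _within(te, (gene.start, gene.end))
        if contains_gene:
            applicable.add("gene_within_te")
        if te_within:
            if any(_within(te, iv) for iv in gene.utr5):
                applicable.add("in_5utr")
            if any(_within(te, iv) for iv in gene.utr3):
                applicable.add("in_3utr")
            if any(_within(te, iv) for iv in gene.exons):
                applicable.add("in_exon")
            if any(_within(te, iv) for iv in gene.introns):
                applicable.add("in_intron")
            applicable.add("within_gene")
        if not contains_gene and not te_within:
            side, d = _flank(te, gene)
            for lo, hi, name in _FLANK_BINS:
                if lo < d <= hi or (d == 0 and lo == 0):
                    applicable.add(f"{side}_{name}")
                    break
        d_edge = 0 if overlap else (gene.start - te.end if te.end < gene.start else te.start - gene.end)
        if nearest_d is None or d_edge < nearest_d:
            nearest_d, nearest_gene = d_edge, gene.gene_id
    for cat in CATEGORY_ORDER:
        if cat in applicable:
            return cat, nearest_gene, nearest_d
    return "intergenic", nearest_gene, nearest_d


def categorize_all(
    tes: Sequence[TEAnnotation], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Category table (te_id, category, nearest_gene, distance) for all TEs."""
    rows = []
    for te in tes:
        cat, gene_id, d = categorize_te(te, genes)
        rows.append({"te_id": te.te_id, "category": cat, "nearest_gene": gene_id, "distance": d})
    return pd.DataFrame(rows).set_index("te_id")


def bootstrap_background(
    records: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Genome-wide background frequency-class proportions per category.

    ``records`` needs columns ``order``, ``frequency`` and ``category``.
    For each (order, category) cell with k members, every bootstrap
    iteration draws k TEs with replacement from all TEs of that order
    genome-wide and records the low/moderate/high class proportions, so
    each category is compared against an order-matched background of the
    same sample size. Empty cells are skipped.

    Child RNG streams are keyed per (order, category) so enlarging
    ``n_boot`` extends, rather than reshuffles, the iteration sequence.
    """
    required = {"order", "frequency", "category"}
    if not required.issubset(records.columns):
        raise ValueError(f"records missing columns {sorted(required - set(records.columns))}")
    pools = {
        order: sub["frequency"].to_numpy(dtype=float)
        for order, sub in records.groupby("order")
    }
    rows = []
    keys = sorted(
        records.groupby(["order", "category"]).size().items(), key=lambda kv: kv[0]
    )
    for gidx, ((order, category), k) in enumerate(keys):
        if k == 0:
            continue
        pool = pools[order]
        rng = np.random.default_rng([seed, gidx])
        draws = rng.choice(pool, size=(n_boot, int(k)), replace=True)
        classes = frequency_class(draws)
        for it in range(n_boot):
            row = {"order": order, "category": category, "iteration": it}
            for cls in FREQUENCY_CLASSES:
                row[f"p_{cls}"] = float((classes[it] == cls).sum()) / k
            rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_summary(background: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of each class proportion per (order, category)."""
    cols = [c for c in background.columns if c.startswith("p_")]
    grouped = background.groupby(["order", "category"])[cols]
    mean = grouped.mean().add_suffix("_mean")
    n = grouped.size()
    se = (grouped.std(ddof=1).divide(np.sqrt(n), axis=0)).add_suffix("_se")
    return mean.join(se)


def region_membership(
    tes: Sequence[TEAnnotation], regions: pd.DataFrame
) -> pd.Series:
    """Whether each TE's midpoint falls inside a region set.

    ``regions`` is a 1-based inclusive interval table (e.g. from
    :func:`tepav.annotations.read_bed`); overlapping regions are merged
    first. Indexed by te_id.
    """
    merged = merge_intervals(regions)
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in merged.groupby("chrom")
    }
    out = {}
    for te in tes:
        mid = te.midpoint
        inside = False
        if te.chrom in by_chrom:
            starts, ends = by_chrom[te.chrom]
            i = np.searchsorted(starts, mid, side="right") - 1
            inside = i >= 0 and mid <= ends[i]
        out[te.te_id] = inside
    return pd.Series(out, name="in_region")
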