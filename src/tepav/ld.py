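"""Linkage disequilibrium between TE presence/absence markers and SNPs.

Lines in an inbred panel are effectively haploid, so both marker types
are coded 0/1 per sample (heterozygous SNP calls are set missing with a
count report). For a TE the marker position is its midpoint and
ambiguous calls map to missing. LD on the pairwise-complete subset:

    D  = p_AB - p_A * p_B
    r2 = D^2 / (p_A (1-p_A) p_B (1-p_B))
    D' = |D| / Dmax,  Dmax = min(p_A (1-p_B), (1-p_A) p_B)      if D > 0
                      Dmax = min(p_A p_B, (1-p_A)(1-p_B))       otherwise

Tagging strength of the best SNP within +/- 1 Mb of the TE midpoint is
binned as high (r2 > 0.9), moderate (0.5-0.9, closed) or low (< 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import ABSENT, PRESENT, CallMatrix, TEAnnotation

WINDOW_BP = 1_000_000


@dataclass
class MarkerVector:
    """A biallelic marker: 0/1 allele codes with NaN for missing."""

    marker_id: str
    chrom: str
    position: int
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=float)
        ok = np.isnan(self.alleles) | np.isin(self.alleles, (0.0, 1.0))
        if not ok.all():
            raise ValueError(f"marker {self.marker_id}: allele codes must be 0/1/NaN")
        if (~np.isnan(self.alleles)).sum() < 2:
            raise ValueError(f"marker {self.marker_id}: fewer than 2 non-missing codes")


@dataclass(frozen=True)
class LDResult:
    a_id: str
    b_id: str
    D: float
    d_prime: float
    r2: float
    distance_bp: int
    n: int
    defined: bool


@dataclass(frozen=True)
class TagSummary:
    te_id: str
    best_snp_id: str | None
    best_value: float
    metric: str
    ld_class: str | None
    distance_bp: int | None
    n_snps: int


def te_marker(
    te: TEAnnotation, calls: CallMatrix, sample_ids: Sequence[str] | None = None
) -> MarkerVector:
    """TE presence/absence as a marker at the TE midpoint."""
    row = calls.labels.loc[te.te_id]
    if sample_ids is not None:
        row = row.reindex(sample_ids)
    alleles = np.where(
        row.values == PRESENT, 1.0, np.where(row.values == ABSENT, 0.0, np.nan)
    )
    return MarkerVector(te.te_id, te.chrom, te.midpoint, alleles)


def _ld_core(pA: float, pB: float, pAB: float) -> tuple[float, float, float]:
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D > 0 else min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    return D, d_prime, r2


def ld_pair(a: MarkerVector, b: MarkerVector) -> LDResult:
    """LD statistics for one marker pair on pairwise-complete samples.

    A pair where either marker is monomorphic on the complete subset is
    returned with ``defined=False`` and NaN statistics; callers exclude
    such pairs from summaries.
    """
    x, y = a.alleles, b.alleles
    keep = ~np.isnan(x) & ~np.isnan(y)
    n = int(keep.sum())
    distance = abs(int(a.position) - int(b.position))
    if n < 2:
        return LDResult(a.marker_id, b.marker_id, np.nan, np.nan, np.nan, distance, n, False)
    xv, yv = x[keep], y[keep]
    pA, pB = float(xv.mean()), float(yv.mean())
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDResult(a.marker_id, b.marker_id, np.nan, np.nan, np.nan, distance, n, False)
    pAB = float((xv * yv).mean())
    D, d_prime, r2 = _ld_core(pA, pB, pAB)
    return LDResult(a.marker_id, b.marker_id, D, d_prime, r2, distance, n, True)


def ld_class(value: float, metric: str = "r2") -> str:
    """high > 0.9, moderate 0.5-0.9 inclusive, low < 0.5."""
    if not 0.0 <= value <= 1.0 + 1e-12:
        raise ValueError(f"{metric} value {value} outside [0, 1]")
    if value > 0.9:
        return "high"
    if value >= 0.5:
        return "moderate"
    return "low"


def best_tag_snp(
    te_vec: MarkerVector,
    snps: Sequence[MarkerVector],
    window_bp: int = WINDOW_BP,
    metric: str = "r2",
) -> TagSummary:
    """Best tag SNP within +/- window of the TE midpoint.

    The SNP maximizing the chosen metric wins; exact ties break by
    smallest physical distance, then by lowest coordinate for
    determinism. A TE with no eligible (same-chromosome, in-window,
    polymorphic) SNP is returned untagged.
    """
    if metric not in ("r2", "d_prime"):
        raise ValueError(f"unknown metric {metric!r}")
    best = None  # (-value, distance, position, snp_id)
    n_considered = 0
    for snp in snps:
        if snp.chrom != te_vec.chrom:
            continue
        if abs(int(snp.position) - int(te_vec.position)) > window_bp:
            continue
        res = ld_pair(te_vec, snp)
        if not res.defined:
            continue
        n_considered += 1
        value = getattr(res, metric)
        key = (-value, res.distance_bp, snp.position, snp.marker_id)
        if best is None or key < best:
            best = key
    if best is None:
        return TagSummary(te_vec.marker_id, None, np.nan, metric, None, None, 0)
    neg_value, distance, _, snp_id = best
    value = -neg_value
    return TagSummary(
        te_id=te_vec.marker_id,
        best_snp_id=snp_id,
        best_value=value,
        metric=metric,
        ld_class=ld_class(value, metric),
        distance_bp=distance,
        n_snps=n_considered,
    )


def exclude_snps_in_tes(
    snps: Sequence[MarkerVector], tes: Sequence[TEAnnotation]
) -> tuple[list[MarkerVector], int]:
    """Drop SNPs positioned inside any TE interval (closed coordinates).

    Returns (kept SNPs, number removed).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    kept = []
    removed = 0
    for snp in snps:
        inside = False
        if snp.chrom in merged:
            starts, ends = merged[snp.chrom]
            i = np.searchsorted(starts, snp.position, side="right") - 1
            inside = i >= 0 and snp.position <= ends[i]
        if inside:
            removed += 1
        else:
            kept.append(snp)
    return kept, removed


# ---------------------------------------------------------------------------
# SNP matrix input


def read_snp_matrix_vcf(path: str | Path) -> tuple[list[MarkerVector], list[str], int]:
    """Biallelic SNP markers from a VCF, haploid-coded for inbred lines.

    Homozygous reference -> 0, homozygous alternate -> 1; heterozygous
    and uncalled genotypes -> missing. Returns (markers, sample ids,
    count of heterozygous calls set missing). Multi-allelic and non-SNP
    records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[MarkerVector] = []
    n_het = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        het = gt == 1
        n_het += int(het.sum())
        alleles = np.where(gt == 0, 0.0, np.where(gt == 3, 1.0, np.nan))
        snp_id = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        try:
            markers.append(MarkerVector(snp_id, var.CHROM, var.POS, alleles))
        except ValueError:
            continue  # fewer than 2 called genotypes
    vcf.close()
    if n_het:
        warnings.warn(f"{path}: {n_het} heterozygous genotype calls set to missing")
    return markers, samples, n_het


def read_snp_matrix_tsv(path: str | Path) -> tuple[list[MarkerVector], list[str]]:
    """SNP markers from a TSV with columns snp_id, chrom, position, then
    one 0/1/NA column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    samples = [c for c in df.columns if c not in ("snp_id", "chrom", "position")]
    markers = []
    for _, row in df.iterrows():
        alleles = row[samples].to_numpy(dtype=float)
        markers.append(
            MarkerVector(str(row["snp_id"]), str(row["chrom"]), int(row["position"]), alleles)
        )
    return markers, samples


def ld_results_table(results: Sequence[LDResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_id": r.a_id,
                "snp_id": r.b_id,
                "D": r.D,
                "d_prime": r.d_prime,
                "r2": r.r2,
                "distance_bp": r.distance_bp,
                "n": r.n,
                "defined": r.defined,
            }
            for r in results
        ]
    )


def tag_summary_table(summaries: Sequence[TagSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_id": s.te_id,
                "best_snp_id": s.best_snp_id,
                "best_value": s.best_value,
                "metric": s.metric,
                "ld_class": s.ld_class,
                "distance_bp": s.distance_bp,
                "n_snps": s.n_snps,
            }
            for s in summaries
        ]
    )
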