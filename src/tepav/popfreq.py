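"""Population frequencies, nonredundant merging, class bins and tests.

The population frequency of a TE is presents / (presents + absents):
ambiguous calls are no-calls and are excluded from the denominator, as
are missing cells. Homologous TEs annotated in several assemblies are
collapsed by averaging their per-assembly frequencies; metadata comes
from the designated source assembly.

Frequency bins: low < 20%, moderate 20-80% (closed), high > 80%.
LTR-similarity bins: low < 95%, moderate 95-99% (closed), high > 99%.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import ABSENT, AMBIGUOUS, MISSING, PRESENT, CallMatrix, HomologGroup

FREQUENCY_CLASSES = ("low", "moderate", "high")


def te_frequency(labels: Sequence[str] | pd.Series) -> tuple[float, dict[str, int]]:
    """Frequency and call counts for one TE's row of calls."""
    arr = np.asarray(labels, dtype=object)
    n_present = int((arr == PRESENT).sum())
    n_absent = int((arr == ABSENT).sum())
    n_ambiguous = int((arr == AMBIGUOUS).sum())
    if n_present + n_absent == 0:
        raise ValueError("no present/absent calls: row should have been filtered")
    counts = {
        "n_present": n_present,
        "n_absent": n_absent,
        "n_ambiguous": n_ambiguous,
    }
    return n_present / (n_present + n_absent), counts


def call_frequencies(calls: CallMatrix) -> pd.DataFrame:
    """Per-TE frequency table from a call matrix.

    Columns: n_present, n_absent, n_ambiguous, frequency, frequency_class.
    TEs with no present/absent calls are dropped with a warning.
    """
    lab = calls.labels.to_numpy()
    n_present = (lab == PRESENT).sum(axis=1)
    n_absent = (lab == ABSENT).sum(axis=1)
    n_ambiguous = (lab == AMBIGUOUS).sum(axis=1)
    denom = n_present + n_absent
    df = pd.DataFrame(
        {
            "n_present": n_present,
            "n_absent": n_absent,
            "n_ambiguous": n_ambiguous,
        },
        index=calls.te_ids,
    )
    empty = denom == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} TEs have no present/absent calls; dropped"
        )
        df = df[~empty]
        denom = denom[~empty]
    df["frequency"] = df["n_present"] / denom
    df["frequency_class"] = frequency_class(df["frequency"].to_numpy())
    return df


def frequency_class(frequency):
    """low < 0.20, moderate 0.20-0.80 inclusive, high > 0.80."""
    f = np.asarray(frequency, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequency outside [0, 1]")
    out = np.where(f < 0.20, "low", np.where(f <= 0.80, "moderate", "high"))
    return out.item() if np.isscalar(frequency) else out


def similarity_class(ltr_similarity):
    """low < 95, moderate 95-99 inclusive, high > 99 (percent identity)."""
    s = np.asarray(ltr_similarity, dtype=float)
    if np.any(np.isnan(s)) or np.any((s < 0) | (s > 100)):
        raise ValueError("LTR similarity must be within [0, 100] and non-missing")
    out = np.where(s < 95.0, "low", np.where(s <= 99.0, "moderate", "high"))
    return out.item() if np.isscalar(ltr_similarity) else out


def merge_homolog_frequencies(
    per_assembly: Mapping[str, pd.DataFrame],
    groups: Iterable[HomologGroup],
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse homologous TEs to a nonredundant frequency table.

    ``per_assembly`` maps assembly -> frequency table indexed by te_id
    (TEs filtered out upstream are simply absent from their table). The
    nonredundant frequency is the mean over members with retained
    frequencies; non-frequency metadata columns are taken from the
    group's source-assembly member. Groups whose members were all
    filtered are dropped and reported.
    """
    rows = []
    dropped: list[str] = []
    for group in groups:
        freqs = []
        meta_row = None
        for asm, te_id in group.members:
            table = per_assembly.get(asm)
            if table is None or te_id not in table.index:
                continue
            freqs.append(float(table.loc[te_id, "frequency"]))
            if asm == group.source_assembly and meta_row is None:
                meta_row = table.loc[te_id]
        if not freqs:
            dropped.append(group.nonredundant_id)
            continue
        if meta_row is None:
            # source-assembly member filtered: fall back to first retained
            for asm, te_id in group.members:
                table = per_assembly.get(asm)
                if table is not None and te_id in table.index:
                    meta_row = table.loc[te_id]
                    break
        row = {} if meta_row is None else meta_row.to_dict()
        row["nonredundant_id"] = group.nonredundant_id
        row["frequency"] = float(np.mean(freqs))
        row["n_assemblies"] = len(freqs)
        rows.append(row)
    if dropped:
        warnings.warn(f"{len(dropped)} homolog groups dropped (all members filtered)")
    out = pd.DataFrame(rows).set_index("nonredundant_id")
    if len(out):
        out["frequency_class"] = frequency_class(out["frequency"].to_numpy())
    return out, dropped


# ---------------------------------------------------------------------------
# Statistics


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    D is the supremum of the absolute difference between the two ECDFs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    p sums hypergeometric probabilities (margins fixed) of all tables no
    more probable than the observed one; the odds ratio is the sample
    cross-product ratio ad/bc.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins in 2x2 table")
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def family_enrichment(
    records: pd.DataFrame,
    flag: pd.Series,
    min_family_size: int = 20,
) -> pd.DataFrame:
    """Per-family Fisher enrichment of a boolean TE property.

    For each family with at least ``min_family_size`` elements, tests the
    2x2 table of (in family vs not) x (flagged vs not) over all records.
    Returns size, flagged count, odds ratio and two-sided p per family.
    """
    flag = flag.reindex(records.index).astype(bool)
    total = len(records)
    total_flagged = int(flag.sum())
    rows = []
    for family, sub in records.groupby("family", sort=True):
        size = len(sub)
        if size < min_family_size:
            continue
        in_flag = int(flag.loc[sub.index].sum())
        table = [
            [in_flag, size - in_flag],
            [total_flagged - in_flag, (total - size) - (total_flagged - in_flag)],
        ]
        try:
            odds, p = fisher_exact(table)
        except ValueError:
            odds, p = float("nan"), float("nan")
        rows.append(
            {
                "family": family,
                "size": size,
                "flagged": in_flag,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def ibs_distance_matrix(calls: CallMatrix) -> pd.DataFrame:
    """Pairwise 1 - identity-by-state distances between samples.

    Only cells where both samples have a present/absent call are
    compared; pairs with zero comparable sites get NaN with a warning.
    """
    if len(calls.sample_ids) < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    lab = calls.labels.to_numpy()
    x = np.where(lab == PRESENT, 1.0, np.where(lab == ABSENT, 0.0, np.nan))
    valid = ~np.isnan(x)  # tes x samples
    v = np.nan_to_num(x)  # calls with 0 where invalid
    m = valid.astype(float)
    comparable = m.T @ m
    # mismatches(i,j) = sum over comparable cells of |x_i - x_j|
    #                 = sum x_i*(valid_j) + x_j*(valid_i) - 2*x_i*x_j
    cross = v.T @ v
    mismatch = (v.T @ m) + (m.T @ v) - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = mismatch / comparable
    if np.isnan(dist[comparable == 0]).size and (comparable == 0).any():
        warnings.warn("some sample pairs share zero comparable calls")
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=calls.sample_ids, columns=calls.sample_ids)
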