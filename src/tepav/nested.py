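"""Nested-TE pairing and insertion-timing comparisons.

A nested TE sits fully inside its outer element, so it cannot exist in a
genotype without the outer copy: its population frequency must be at or
below the outer element's, and (being the later insertion) its LTR
similarity should be at or above the outer's when both are LTR
retrotransposons. These two orderings, and the correlation between
nested and outer frequencies, are what this module measures.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import TEAnnotation
from .popfreq import frequency_class


def build_nested_pairs(
    tes: Sequence[TEAnnotation],
    frequencies: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """One row per (nested TE, immediate outer TE) relation.

    Multi-level nests contribute one pair per parent-child edge only
    (C nested in B nested in A yields (C,B) and (B,A), never (C,A)).
    Pairs whose outer element has no frequency are dropped with a warning.

    ``freq_delta`` is outer minus nested frequency; ``sim_delta`` is
    nested minus outer LTR similarity, present only when both elements
    are LTRs with similarity values.
    """
    freqs = dict(frequencies)
    by_id = {te.te_id: te for te in tes}
    rows = []
    dropped = 0
    for te in tes:
        if te.nested_in is None:
            continue
        outer = by_id.get(te.nested_in)
        if outer is None:
            raise ValueError(f"TE {te.te_id}: outer {te.nested_in!r} not in annotation")
        if te.te_id not in freqs or outer.te_id not in freqs:
            dropped += 1
            continue
        nested_freq = float(freqs[te.te_id])
        outer_freq = float(freqs[outer.te_id])
        both_ltr = (
            te.ltr_similarity is not None and outer.ltr_similarity is not None
        )
        rows.append(
            {
                "nested_id": te.te_id,
                "outer_id": outer.te_id,
                "nested_freq": nested_freq,
                "outer_freq": outer_freq,
                "freq_delta": outer_freq - nested_freq,
                "nested_sim": te.ltr_similarity,
                "outer_sim": outer.ltr_similarity,
                "sim_delta": (te.ltr_similarity - outer.ltr_similarity)
                if both_ltr
                else np.nan,
                "nested_order": te.order,
                "outer_order": outer.order,
            }
        )
    if dropped:
        warnings.warn(f"{dropped} nested pairs dropped for missing frequencies")
    return pd.DataFrame(
        rows,
        columns=[
            "nested_id",
            "outer_id",
            "nested_freq",
            "outer_freq",
            "freq_delta",
            "nested_sim",
            "outer_sim",
            "sim_delta",
            "nested_order",
            "outer_order",
        ],
    )


def pair_consistency(
    pairs: pd.DataFrame, tolerance: float = 0.05
) -> tuple[float, float, float]:
    """Proportions of pairs by frequency-ordering consistency.

    With delta = outer frequency - nested frequency, returns the
    proportions of (delta >= 0, -tolerance <= delta < 0, delta < -tolerance).
    The first bin is the biologically required ordering; the second allows
    the nested element to appear up to ``tolerance`` higher from call
    noise. The three proportions sum to 1.
    """
    if len(pairs) == 0:
        raise ValueError("no nested pairs")
    delta = pairs["freq_delta"].to_numpy(dtype=float)
    n = len(delta)
    p_ok = float((delta >= 0).sum()) / n
    p_slight = float(((delta < 0) & (delta >= -tolerance)).sum()) / n
    p_bad = float((delta < -tolerance).sum()) / n
    return p_ok, p_slight, p_bad


def pearson_r2(x, y) -> float:
    """Squared sample Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def nested_similarity_given_fixed_outer(
    pairs: pd.DataFrame, outer_min_freq: float = 0.95
) -> pd.DataFrame:
    """Nested-LTR similarity stratified by nested frequency class, for
    pairs whose outer element is fixed or nearly fixed (frequency >
    ``outer_min_freq``).

    Restricting to (nearly) fixed outer elements removes the outer
    element's own frequency signal, so the nested elements' similarity
    spectrum reflects the timing of the nested insertions alone.
    """
    sub = pairs[
        (pairs["outer_freq"] > outer_min_freq) & pairs["nested_sim"].notna()
    ].copy()
    if len(sub):
        sub["nested_freq_class"] = frequency_class(sub["nested_freq"].to_numpy())
    else:
        sub["nested_freq_class"] = pd.Series(dtype=object)
    return sub[
        ["nested_id", "outer_id", "nested_freq", "nested_freq_class", "nested_sim"]
    ]


def similarity_ordering(pairs: pd.DataFrame) -> float:
    """Proportion of LTR-in-LTR pairs where the nested element has the
    higher LTR similarity (i.e. looks younger). Ties count as not higher."""
    sub = pairs[pairs["nested_sim"].notna() & pairs["outer_sim"].notna()]
    if len(sub) == 0:
        raise ValueError("no LTR-in-LTR pairs with similarity on both sides")
    return float((sub["nested_sim"] > sub["outer_sim"]).sum()) / len(sub)
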