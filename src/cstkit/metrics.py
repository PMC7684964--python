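"""Community descriptors and clinical-variable binning.

Shannon diversity is reported in bits (log base 2), matching how the
sub-CST characterizations are usually summarised. Vaginal pH and Nugent
scores are binned into the categorical schemes used to relate CSTs to
clinical state: pH into four bins with 5.0 and 5.5 both claimed by the
inclusive middle bin, Nugent 0-10 into low/intermediate/high.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateCompositionError, ValidationError

PH_CATEGORIES = ("≤4.5", "(4.5,5.0)", "[5.0,5.5]", "≥5.5")
NUGENT_CATEGORIES = ("low", "intermediate", "high")


def shannon_diversity(p) -> float:
    """Shannon diversity H = -sum(p_i * log2 p_i), in bits.

    Zero-proportion taxa contribute 0 (the 0*log 0 convention). H is 0 for
    a single-taxon community and log2(S) for a uniform community over S
    taxa.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("composition must be one-dimensional")
    if (arr < 0).any():
        raise DegenerateCompositionError("composition has negative proportions")
    total = arr.sum()
    if total <= 0:
        raise DegenerateCompositionError("composition is all-zero")
    if abs(total - 1.0) > 1e-9:
        raise DegenerateCompositionError(f"composition sums to {total!r}, not 1")
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def bin_ph(ph: float, lo: float = 3.0, hi: float = 9.0) -> str:
    """Bin a vaginal pH measurement.

    Bins: <=4.5 | strictly between 4.5 and 5.0 | 5.0 to 5.5 inclusive |
    >5.5 (reported as ">=5.5"; 5.5 itself belongs to the inclusive middle
    bin). Values outside [lo, hi] are rejected as implausible.
    """
    if not lo <= ph <= hi:
        raise ValidationError(f"pH {ph} outside plausible range [{lo}, {hi}]")
    if ph <= 4.5:
        return PH_CATEGORIES[0]
    if ph < 5.0:
        return PH_CATEGORIES[1]
    if ph <= 5.5:
        return PH_CATEGORIES[2]
    return PH_CATEGORIES[3]


def bin_nugent(score: int) -> str:
    """Bin a Nugent score: 0-3 low, 4-7 intermediate, 8-10 high."""
    if not float(score).is_integer():
        raise ValidationError(f"Nugent score must be an integer, got {score!r}")
    score = int(score)
    if not 0 <= score <= 10:
        raise ValidationError(f"Nugent score {score} outside 0-10")
    if score <= 3:
        return NUGENT_CATEGORIES[0]
    if score <= 7:
        return NUGENT_CATEGORIES[1]
    return NUGENT_CATEGORIES[2]


def cst_category_crosstab(
    assignments: pd.Series,
    categories: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Cross-tabulate sub-CST assignments against a clinical category.

    Both inputs are indexed by sample id; unmatched ids are reported and
    excluded.

    Returns
    -------
    (counts, proportions, unmatched)
        ``counts`` rows = sub-CSTs, columns = categories; the grand total
        equals the number of paired samples. ``proportions`` are
        within-sub-CST (rows sum to 1). ``unmatched`` lists ids present in
        only one input.
    """
    shared = assignments.index.intersection(categories.index)
    unmatched = sorted(
        set(assignments.index).symmetric_difference(categories.index)
    )
    if len(shared) == 0:
        import warnings

        warnings.warn("no overlapping sample ids; empty crosstab", UserWarning, stacklevel=2)
        empty = pd.DataFrame()
        return empty, empty, [str(u) for u in unmatched]
    counts = pd.crosstab(assignments.loc[shared], categories.loc[shared])
    counts.index.name = "subCST"
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return counts, proportions, [str(u) for u in unmatched]


def ph_odds_table(counts: pd.DataFrame) -> pd.Series:
    """Per-sub-CST odds of pH > 4.5 from a pH-bin crosstab.

    Computed as a simple 2x2 odds within each sub-CST row: (samples above
    4.5) / (samples at or below 4.5). Rows with no samples at or below
    4.5 yield inf.
    """
    if PH_CATEGORIES[0] not in counts.columns:
        low = pd.Series(0, index=counts.index)
    else:
        low = counts[PH_CATEGORIES[0]]
    high = counts.sum(axis=1) - low
    with np.errstate(divide="ignore"):
        odds = high.astype(float) / low.replace(0, np.nan)
    return odds.fillna(np.inf).rename("odds_ph_gt_4.5")
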