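"""Effect-size interaction analysis between baseline and pain tolerance.

For every feature, the baseline (B) and pain-tolerance (T4) trial values are
first residualized against subject identity (fixed per-subject intercepts —
per-subject centering, which for balanced data removes additive inter-subject
variation exactly).  Normality of the pooled residuals is gated with a
Lilliefors-style Kolmogorov-Smirnov test; non-normal features are compared
with the Wilcoxon rank-sum test, normal ones with a two-sample t-test.
Substantive significance is quantified by Cohen's d (pooled SD, sign positive
when T4 exceeds B) and summarized into arrow categories at the conventional
small / medium / large bands 0.2 / 0.5 / 0.8:

    p >= 0.05 or |d| < 0.2  →  "-"
    0.2 <= |d| < 0.5        →  "↑" / "↓"
    0.5 <= |d| < 0.8        →  "↑↑" / "↓↓"
    |d| >= 0.8              →  "↑↑↑" / "↓↓↓"

No multiple-testing correction is applied by default (per-feature reporting);
Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .featurebank import (
    FEATURE_TABLE,
    MODALITY_NUMBERS,
    MODALITY_PREFIX,
    FeatureMatrix,
)
from .synthgen import PainLevel

UP = {1: "↑", 2: "↑↑", 3: "↑↑↑"}
DOWN = {1: "↓", 2: "↓↓", 3: "↓↓↓"}


@dataclass
class InteractionSummary:
    feature: str
    p_value: float
    d: float
    direction: str          # "T4_greater" | "B_greater" | "none"
    category: str
    test_used: str          # "t" | "wilcoxon"


def residualize_subject(values: np.ndarray, subject_ids: np.ndarray) -> np.ndarray:
    """Remove per-subject means (fixed-effect subject model)."""
    values = np.asarray(values, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if len(values) < 2 or len(np.unique(subject_ids)) < 2:
        raise ValueError("need at least 2 subjects to residualize")
    out = values.copy()
    for s in np.unique(subject_ids):
        m = subject_ids == s
        out[m] -= out[m].mean()
    return out


def compare_conditions(
    resid_b: np.ndarray, resid_t4: np.ndarray, alpha_ks: float = 0.05
) -> tuple[float, str]:
    """Two-sided p-value for a B vs T4 location difference, with the test
    chosen by a normality gate on the pooled residuals."""
    resid_b = np.asarray(resid_b, dtype=float)
    resid_t4 = np.asarray(resid_t4, dtype=float)
    if len(resid_b) < 5 or len(resid_t4) < 5:
        raise ValueError("need at least 5 values per condition")
    pooled = np.concatenate([resid_b, resid_t4])
    if np.std(pooled) == 0:
        return 1.0, "t"
    _, p_norm = lilliefors(pooled, dist="norm")
    if p_norm < alpha_ks:
        p = float(stats.ranksums(resid_b, resid_t4).pvalue)
        return p, "wilcoxon"
    p = float(stats.ttest_ind(resid_b, resid_t4).pvalue)
    return p, "t"


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean(b) − mean(a)) / pooled SD; positive when the second sample (T4)
    exceeds the first (B).  Zero pooled SD → 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return 0.0
    return float((b.mean() - a.mean()) / np.sqrt(pooled_var))


def categorize(p: float, d: float) -> str:
    """Arrow symbol from (p, d) under the 0.2 / 0.5 / 0.8 effect-size bands."""
    if p >= 0.05 or abs(d) < 0.2:
        return "-"
    arrows = 1 if abs(d) < 0.5 else (2 if abs(d) < 0.8 else 3)
    return UP[arrows] if d > 0 else DOWN[arrows]


def interaction_table(
    matrix: FeatureMatrix,
    alpha_ks: float = 0.05,
    fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature B vs T4 interaction analysis.

    Returns ``(wide, long)``: a base-feature × modality table of category
    symbols ("na" where a feature is not defined for a modality), and a
    long-format frame with numeric p, d, direction, and test per feature.
    """
    levels = matrix.meta["level"].to_numpy()
    has_b = (levels == PainLevel.B.name).any()
    has_t4 = (levels == PainLevel.T4.name).any()
    if not (has_b and has_t4):
        raise ValueError("matrix must contain both B and T4 trials")
    keep = np.isin(levels, [PainLevel.B.name, PainLevel.T4.name])
    sub_levels = levels[keep]
    subjects = matrix.meta["subject"].to_numpy()[keep]
    is_t4 = sub_levels == PainLevel.T4.name

    records = []
    for name in matrix.values.columns:
        vals = matrix.values[name].to_numpy()[keep]
        resid = residualize_subject(vals, subjects)
        rb, rt = resid[~is_t4], resid[is_t4]
        if np.std(np.concatenate([rb, rt])) == 0:
            p, test, d = 1.0, "t", 0.0
        else:
            p, test = compare_conditions(rb, rt, alpha_ks)
            d = cohens_d(rb, rt)
        records.append((name, p, d, test))
    long = pd.DataFrame(records, columns=["feature", "p_value", "d", "test_used"])
    if fdr:
        long["p_value"] = multipletests(long["p_value"], method="fdr_bh")[1]
    long["category"] = [categorize(p, d) for p, d in zip(long["p_value"], long["d"])]
    long["direction"] = np.where(
        long["category"] == "-", "none", np.where(long["d"] > 0, "T4_greater", "B_greater")
    )

    cat = dict(zip(long["feature"], long["category"]))
    modalities = ["zEMG", "cEMG", "tEMG", "SCL", "ECG"]
    rows = []
    for num, base, _grp in FEATURE_TABLE:
        row = {"feature": base}
        for mod in modalities:
            name = MODALITY_PREFIX[mod] + base
            row[mod] = cat.get(name, "na") if num in MODALITY_NUMBERS[mod] else "na"
        rows.append(row)
    wide = pd.DataFrame(rows).set_index("feature")
    return wide, long
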