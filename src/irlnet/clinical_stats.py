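"""Clinical derivations and qPCR statistics.

Implements the standard insulin-resistance work-up for a two-group cohort:
HOMA-IR = fasting insulin (mIU/L) x fasting glucose (mmol/L) / 22.5, with
insulin resistance defined as the upper HOMA-IR tertile; WHO Asian BMI
categories (normal 18.5-23.9, overweight >= 24, obese >= 29 kg/m^2);
hyperinsulinemia as fasting insulin strictly above 23 mIU/L; relative qPCR
quantification by 2^-ddCt against a reference-group calibrator; and
normality-gated two-group comparisons (Lilliefors-corrected
Kolmogorov-Smirnov, then Student t or Mann-Whitney U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

log = logging.getLogger(__name__)

HOMA_IR_DENOMINATOR = 22.5
HYPERINSULINEMIA_CUTOFF = 23.0      # mIU/L, strict
BMI_NORMAL_LOW, BMI_OVERWEIGHT, BMI_OBESE = 18.5, 24.0, 29.0


def homa_ir(fasting_insulin: float, fasting_glucose: float) -> float:
    """HOMA-IR index: insulin (mIU/L) * glucose (mmol/L) / 22.5."""
    if fasting_insulin <= 0 or fasting_glucose <= 0:
        raise ValueError("fasting insulin and glucose must be positive")
    return fasting_insulin * fasting_glucose / HOMA_IR_DENOMINATOR


def tertile_assignment(values) -> tuple[pd.Series, pd.DataFrame]:
    """Tertile labels I/II/III cut at the 1/3 and 2/3 empirical quantiles.

    Linear-interpolation quantiles; values exactly on a boundary go to the
    lower tertile.  Tertile III is the insulin-resistant flag.  Returns
    (labels, tertile range table).
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 3:
        raise ValueError("tertile assignment needs at least 3 values")
    q1, q2 = np.quantile(values.to_numpy(), [1 / 3, 2 / 3])
    labels = pd.Series("I", index=values.index)
    labels[values > q1] = "II"
    labels[values > q2] = "III"
    ranges = pd.DataFrame({
        "tertile": ["I", "II", "III"],
        "low": [float(values.min()), float(q1), float(q2)],
        "high": [float(q1), float(q2), float(values.max())],
    })
    return labels, ranges


def bmi_category(bmi: float) -> str:
    """WHO Asian-population BMI category."""
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    if bmi < BMI_NORMAL_LOW:
        return "underweight"
    if bmi < BMI_OVERWEIGHT:
        return "normal"
    if bmi < BMI_OBESE:
        return "overweight"
    return "obese"


def hyperinsulinemia_flag(fasting_insulin: float) -> bool:
    """Fasting insulin strictly greater than 23 mIU/L."""
    return fasting_insulin > HYPERINSULINEMIA_CUTOFF


def derive_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Append HOMA-IR, tertiles, BMI category and hyperinsulinemia flags."""
    out = clinical.copy()
    out["homa_ir"] = [
        homa_ir(i, g)
        for i, g in zip(out["fasting_insulin"], out["fasting_glucose"])
    ]
    labels, _ = tertile_assignment(out["homa_ir"])
    out["homa_tertile"] = labels.values
    out["insulin_resistant"] = out["homa_tertile"] == "III"
    out["bmi_category"] = out["bmi"].map(bmi_category)
    out["hyperinsulinemia"] = out["fasting_insulin"].map(hyperinsulinemia_flag)
    return out


def ddct_fold_change(
    qpcr: pd.DataFrame, reference_group: str = "control"
) -> pd.Series:
    """Per-subject relative expression 2^-ddCt.

    dCt = ct_target - ct_reference; ddCt = dCt - mean dCt of the reference
    group (Livak group-mean calibrator); fold = 2^-ddCt.  Subjects with a
    missing Ct are dropped with a warning.
    """
    required = {"subject_id", "group", "ct_target", "ct_reference"}
    if not required <= set(qpcr.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    ok = qpcr.dropna(subset=["ct_target", "ct_reference"])
    if len(ok) < len(qpcr):
        log.warning("dropped %d subjects with missing Ct values", len(qpcr) - len(ok))
    ref = ok[ok["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    dct = ok["ct_target"] - ok["ct_reference"]
    ref_mean = float((ref["ct_target"] - ref["ct_reference"]).mean())
    fold = np.power(2.0, -(dct - ref_mean))
    return pd.Series(fold.values, index=ok["subject_id"].values, name="fold_change")


@dataclass
class ComparisonResult:
    test: str               # "t" or "mannwhitney"
    statistic: float
    p: float
    normal_a: bool
    normal_b: bool


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    # Lilliefors-corrected KS test against a normal with estimated moments
    if np.std(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p >= alpha


def group_compare(values_a, values_b, alpha_normality: float = 0.05) -> ComparisonResult:
    """Two-group comparison gated on normality.

    Both groups pass the Lilliefors-corrected KS normality check at
    ``alpha_normality`` -> two-sided equal-variance Student t-test;
    otherwise (or on zero-variance groups) -> two-sided Mann-Whitney U.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    na, nb = _is_normal(a, alpha_normality), _is_normal(b, alpha_normality)
    if na and nb and a.std(ddof=1) > 0 and b.std(ddof=1) > 0:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return ComparisonResult("t", float(stat), float(p), na, nb)
    if na and nb:
        log.info("zero-variance group: falling back to Mann-Whitney")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult("mannwhitney", float(stat), float(p), na, nb)


def compare_groups_table(
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Run group_compare per clinical variable; report which test ran."""
    groups = list(pd.unique(clinical[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    if variables is None:
        variables = [
            c for c in clinical.columns
            if c != group_col and pd.api.types.is_numeric_dtype(clinical[c])
        ]
    rows = []
    for var in variables:
        res = group_compare(
            clinical.loc[clinical[group_col] == g1, var],
            clinical.loc[clinical[group_col] == g2, var],
        )
        rows.append({
            "variable": var,
            f"mean_{g1}": float(clinical.loc[clinical[group_col] == g1, var].mean()),
            f"mean_{g2}": float(clinical.loc[clinical[group_col] == g2, var].mean()),
            "test": res.test, "statistic": res.statistic, "p": res.p,
        })
    return pd.DataFrame(rows)
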