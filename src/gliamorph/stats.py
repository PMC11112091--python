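"""Quantification formulas and group-comparison procedure.

Implements the statistical pipeline used throughout the study's
quantifications: single-pass 1.5×IQR outlier removal applied per group
before testing, unpaired two-sample t-tests, 2×2 two-way ANOVA with
Tukey's HSD post-hoc comparisons, ΔΔCt relative qPCR expression, and the
simple ratio measures (sucrose preference, CD68⁺ microglia percentage,
dendritic spine density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "iqr_outlier_filter",
    "unpaired_t",
    "TTestResult",
    "two_way_anova_tukey",
    "AnovaResult",
    "QpcrRecord",
    "qpcr_relative",
    "QpcrResult",
    "sucrose_preference",
    "cd68_positive_percentage",
    "spine_density",
]


def iqr_outlier_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 1.5×IQR outlier removal.

    A value is an outlier when it lies above ``Q3 + 1.5·IQR`` or below
    ``Q1 − 1.5·IQR``; quartiles use linear interpolation between order
    statistics (the numpy default).  The rule is applied once — fences
    are not recomputed after removal — and is invariant to affine
    transforms of the data.

    Returns ``(kept, removed)`` as arrays.  Requires at least 4 values;
    raises ``ValueError("degenerate sample")`` if nothing survives.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need at least 4 values for quartile-based filtering")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (x >= lo) & (x <= hi)
    if not keep.any():
        raise ValueError("degenerate sample")
    return x[keep], x[~keep]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def unpaired_t(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Two-sample unpaired t-test, two-sided.

    Pooled-variance (Student) by default to match mainstream use of the
    named test; ``equal_var=False`` gives Welch's correction.  Raises on
    groups smaller than 2 or zero pooled variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else (
        len(a) + len(b) - 2 if equal_var else np.nan)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Tukey-adjusted pairwise comparisons."""

    table: pd.DataFrame           # effect -> F, p (Type II SS)
    tukey: pd.DataFrame           # pairwise cell comparisons, adjusted p

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def two_way_anova_tukey(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "gene",
    factor_b: str = "drug",
) -> AnovaResult:
    """2×2 two-way ANOVA followed by Tukey's multiple-comparison test.

    Type II sums of squares are used for (possibly unbalanced) designs;
    the Tukey HSD compares all four factor-level cells with
    studentized-range adjustment.  Each cell needs at least 2
    observations.  A table of identical constants returns F = 0, p = 1
    (the 0/0 ratio is defined to zero for this degenerate input).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(table)[[value, factor_a, factor_b]].copy()
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("2x2 design requires >= 2 observations per cell")

    effects = [f"C({factor_a})", f"C({factor_b})",
               f"C({factor_a}):C({factor_b})"]
    nice = {effects[0]: factor_a, effects[1]: factor_b,
            effects[2]: "interaction"}

    if np.ptp(df[value].to_numpy()) == 0:
        out = pd.DataFrame({"F": 0.0, "p": 1.0},
                           index=[factor_a, factor_b, "interaction"])
        cell = df[factor_a].astype(str) + "_" + df[factor_b].astype(str)
        pairs = pd.DataFrame(
            [(a, b, 0.0, 1.0) for i, a in enumerate(sorted(cell.unique()))
             for b in sorted(cell.unique())[i + 1:]],
            columns=["group1", "group2", "meandiff", "p_adj"])
        return AnovaResult(table=out, tukey=pairs)

    model = smf.ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out = pd.DataFrame({
        "F": [anova.loc[e, "F"] for e in effects],
        "p": [anova.loc[e, "PR(>F)"] for e in effects],
    }, index=[nice[e] for e in effects])

    cell = (df[factor_a].astype(str) + "_" + df[factor_b].astype(str)).to_numpy()
    hsd = pairwise_tukeyhsd(df[value].to_numpy(), cell)
    pairs = pd.DataFrame(
        hsd.summary().data[1:], columns=[c for c in hsd.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    return AnovaResult(table=out, tukey=pairs)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR sample: threshold cycles for target and reference gene."""

    sample_id: str
    target_ct: float
    reference_ct: float

    def __post_init__(self):
        if not (self.target_ct > 0):
            raise ValueError("target Ct must be positive")
        if not (self.reference_ct > 0):
            raise ValueError("missing or invalid reference-gene Ct")

    @property
    def delta_ct(self) -> float:
        """ΔCt = Ct(target) − Ct(reference); lower means more transcript."""
        return self.target_ct - self.reference_ct


@dataclass
class QpcrResult:
    neg_dct_control: np.ndarray
    neg_dct_treated: np.ndarray
    ddct: float
    fold_change: float
    p: float


def qpcr_relative(
    control: list[QpcrRecord], treated: list[QpcrRecord]
) -> QpcrResult:
    """ΔΔCt relative expression between two sample groups.

    Each sample's target Ct is normalized to its own reference gene
    (ΔCt); ΔΔCt is the treated-minus-control difference of group mean
    ΔCt, and the group fold change is ``2**(−ΔΔCt)``.  Per-sample −ΔCt
    values are returned for plotting (mean ± SEM convention), along with
    an unpaired t-test p on the ΔCt values.
    """
    if not control or not treated:
        raise ValueError("both groups need samples")
    dct_c = np.array([r.delta_ct for r in control])
    dct_t = np.array([r.delta_ct for r in treated])
    ddct = float(dct_t.mean() - dct_c.mean())
    fold = float(2.0 ** (-ddct))
    try:
        p = unpaired_t(dct_c, dct_t).p
    except ValueError:  # singleton or zero-variance groups: fold is still defined
        p = float("nan")
    return QpcrResult(neg_dct_control=-dct_c, neg_dct_treated=-dct_t,
                      ddct=ddct, fold_change=fold, p=p)


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Sucrose preference %: consumed sucrose / total consumed × 100."""
    total = sucrose_g + water_g
    if total <= 0:
        raise ValueError("total consumption must be positive")
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("consumption cannot be negative")
    return sucrose_g / total * 100.0


def cd68_positive_percentage(n_double_positive: int, n_iba1_positive: int) -> float:
    """CD68⁺ microglia %: Iba1⁺CD68⁺ cells / all Iba1⁺ cells × 100."""
    if n_iba1_positive <= 0:
        raise ValueError("total microglia count must be positive")
    if not 0 <= n_double_positive <= n_iba1_positive:
        raise ValueError("double-positive count out of range")
    return n_double_positive / n_iba1_positive * 100.0


def spine_density(n_spines: int, dendrite_length_um: float) -> float:
    """Dendritic spine density in spines/µm."""
    if dendrite_length_um <= 0:
        raise ValueError("dendrite length must be positive")
    if n_spines < 0:
        raise ValueError("spine count cannot be negative")
    return n_spines / dendrite_length_um
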