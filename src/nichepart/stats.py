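"""Inference on overlap fields: ANCOVA, Tukey HSD and the partitioning test.

Regional and temporal structure in an overlap index is assessed with an
analysis of covariance treating area as the fixed factor and survey year as a
continuous covariate (sequential, type-I sums of squares; area entered before
year).  Stage one tests the area x year interaction; if it is absent, stage
two reports the main effects.  Post hoc area contrasts use Tukey's honest
significant differences.  The resource-partitioning hypothesis predicts a
negative Pearson correlation between spatial overlap S and dietary overlap D
over the (year, cell) combinations where both are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AncovaResult",
    "CorrelationResult",
    "ancova",
    "tukey_hsd",
    "pearson_partitioning",
    "annual_summary",
    "pair_overlap",
]


@dataclass
class AncovaResult:
    """Sequential-SS ANCOVA: interaction stage and main-effects stage."""

    interaction: pd.DataFrame
    main_effects: pd.DataFrame
    alpha: float
    interaction_significant: bool
    significant_terms: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class CorrelationResult:
    """Pearson correlation with its t statistic on df = n - 2."""

    r: float
    df: int
    t: float
    p: float
    n: int
    defined: bool = True

    def __post_init__(self):
        if self.defined and abs(self.r) < 1:
            expected = self.r * np.sqrt(self.df / (1 - self.r**2))
            if abs(self.t - expected) > 1e-9 * max(1.0, abs(self.t)):
                raise ValueError("t statistic inconsistent with r and df")


def _anova_table(fit) -> pd.DataFrame:
    tab = anova_lm(fit, typ=1)
    tab = tab.rename(
        columns={"sum_sq": "ss", "F": "f", "PR(>F)": "p", "df": "df"}
    )
    return tab


def ancova(
    data: pd.DataFrame,
    value: str = "value",
    area: str = "area",
    year: str = "year",
    alpha: float = 0.1,
) -> AncovaResult:
    """Two-stage ANCOVA of an overlap index on area (factor) and year.

    Year enters as a continuous covariate.  Sequential sums of squares with
    area before year (the entry order is part of the contract and logged in
    the returned tables' row order).  Rank-deficient designs raise.
    """
    df = data[[value, area, year]].dropna().copy()
    df.columns = ["value", "area", "year"]
    if df["area"].nunique() < 2:
        raise ValueError("need at least two areas")
    if df["year"].nunique() < 2:
        raise ValueError("need at least two years")
    inter_fit = smf.ols("value ~ C(area) + year + C(area):year", data=df).fit()
    if np.linalg.matrix_rank(inter_fit.model.exog) < inter_fit.model.exog.shape[1]:
        raise ValueError("rank-deficient interaction design")
    inter_tab = _anova_table(inter_fit)
    inter_p = float(inter_tab.loc["C(area):year", "p"])
    main_fit = smf.ols("value ~ C(area) + year", data=df).fit()
    main_tab = _anova_table(main_fit)
    sig = tuple(
        str(ix) for ix in main_tab.index
        if ix != "Residual" and float(main_tab.loc[ix, "p"]) < alpha
    )
    return AncovaResult(
        interaction=inter_tab,
        main_effects=main_tab,
        alpha=alpha,
        interaction_significant=bool(inter_p < alpha),
        significant_terms=sig,
    )


def tukey_hsd(values, groups, alpha: float = 0.1) -> pd.DataFrame:
    """All pairwise group contrasts with studentized-range adjusted p-values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq))
             for j in range(i + 1, len(uniq))]
    tab = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "mean_diff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "ci_lo": np.asarray(res.confint[:, 0], dtype=float),
            "ci_hi": np.asarray(res.confint[:, 1], dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )
    return tab


def _pearson(s: np.ndarray, d: np.ndarray) -> CorrelationResult:
    n = len(s)
    if n < 3:
        return CorrelationResult(np.nan, max(n - 2, 0), np.nan, np.nan, n,
                                 defined=False)
    if np.std(s) == 0 or np.std(d) == 0:
        return CorrelationResult(np.nan, n - 2, np.nan, np.nan, n,
                                 defined=False)
    r, p = sps.pearsonr(s, d)
    df = n - 2
    if abs(r) < 1:
        t = r * np.sqrt(df / (1 - r**2))
    else:
        t = np.inf * np.sign(r)
    return CorrelationResult(float(r), df, float(t), float(p), n)


def pair_overlap(
    spatial: pd.DataFrame, dietary: pd.DataFrame
) -> pd.DataFrame:
    """Join S and D on (year, cell); cells lacking D are excluded."""
    merged = spatial.merge(dietary, on=["year", "cell_id"], how="inner")
    return merged[["year", "cell_id", "s", "d"]]


def pearson_partitioning(
    pairs: pd.DataFrame,
    grouping: str = "basin",
    area: pd.Series | None = None,
) -> CorrelationResult | dict[str, CorrelationResult]:
    """Pearson test of S against D: the resource-partitioning measure.

    ``grouping='basin'`` pools all pairs; ``grouping='per-area'`` requires an
    ``area`` label per pair and returns one result per label.  Degenerate
    groups (fewer than 3 pairs or zero variance) are flagged as undefined
    rather than raising.
    """
    s = pairs["s"].to_numpy(dtype=float)
    d = pairs["d"].to_numpy(dtype=float)
    if grouping == "basin":
        return _pearson(s, d)
    if grouping == "per-area":
        if area is None:
            raise ValueError("per-area grouping requires area labels")
        area = np.asarray(area)
        return {
            lab: _pearson(s[area == lab], d[area == lab])
            for lab in pd.unique(area)
        }
    raise ValueError(f"unknown grouping {grouping!r}")


def annual_summary(field: pd.DataFrame, value: str) -> pd.DataFrame:
    """Per-year mean, SD and normal-approximation 95% CI of an overlap index.

    A year with a single value has SD 0 by convention (degenerate CI).
    """
    def _one(grp: pd.Series):
        n = len(grp)
        mean = grp.mean()
        sd = grp.std(ddof=1) if n > 1 else 0.0
        half = 1.959963984540054 * sd / np.sqrt(n) if n > 0 else np.nan
        return pd.Series(
            dict(mean=mean, sd=sd, n=n, ci_lo=mean - half, ci_hi=mean + half)
        )

    out = field.groupby("year")[value].apply(_one).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()
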