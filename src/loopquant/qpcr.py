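"""Relative expression from qPCR Ct values and condition testing.

Target Ct values are normalized to a housekeeping gene (delta-Ct), fold
changes are expressed relative to the geometric mean of a reference
condition (2^-ddCt), and per-condition differences are tested on delta-Ct
values with a linear mixed model (replicate as random intercept) via a
likelihood-ratio test, followed by Benjamini-Hochberg correction across
targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample", "replicate", "condition", "target", "ct")


@dataclass(frozen=True)
class ConditionTestResult:
    target: str
    statistic: float
    df: int
    p_value: float
    method: str  # 'mixed' or 'ols'


def delta_ct(ct_target: float, ct_housekeeping: float) -> float:
    """Cycle-threshold difference of target relative to housekeeping."""
    return ct_target - ct_housekeeping


def fold_change(delta_ct_sample: float, delta_ct_reference_set: Iterable[float]) -> float:
    """2^-(dCt - mean(reference dCts)).

    Identical to 2^-dCt divided by the geometric mean of the reference
    2^-dCt values: the arithmetic mean of reference dCt in exponent space
    IS the geometric mean on the linear scale.
    """
    ref = np.asarray(list(delta_ct_reference_set), dtype=float)
    if ref.size == 0:
        raise ValueError("reference set must be non-empty")
    return float(2.0 ** (-(delta_ct_sample - ref.mean())))


def delta_ct_table(ct_table: pd.DataFrame, housekeeping: str) -> pd.DataFrame:
    """Per-sample dCt for each non-housekeeping target.

    ``ct_table`` has columns (sample, replicate, condition, target, ct);
    each (sample, target) appears at most once and every sample must carry
    the housekeeping target.
    """
    missing = set(CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    dup = ct_table.duplicated(subset=["sample", "target"])
    if dup.any():
        raise ValueError("duplicate (sample, target) rows in Ct table")
    hk = ct_table[ct_table["target"] == housekeeping].set_index("sample")["ct"]
    rows = []
    for r in ct_table[ct_table["target"] != housekeeping].itertuples():
        if r.sample not in hk.index:
            raise ValueError(f"sample {r.sample!r} lacks housekeeping target {housekeeping!r}")
        rows.append(
            {
                "sample": r.sample,
                "replicate": r.replicate,
                "condition": r.condition,
                "target": r.target,
                "delta_ct": delta_ct(r.ct, float(hk.loc[r.sample])),
            }
        )
    return pd.DataFrame(rows)


def fold_change_table(dct: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Fold change per row relative to the reference-condition geometric mean, per target."""
    out = dct.reset_index(drop=True).copy()
    fcs = np.empty(len(out), dtype=float)
    for target, sub in out.groupby("target"):
        ref = sub.loc[sub["condition"] == reference_condition, "delta_ct"]
        if ref.empty:
            raise ValueError(f"no reference condition {reference_condition!r} for target {target!r}")
        fcs[sub.index.to_numpy()] = [fold_change(v, ref) for v in sub["delta_ct"]]
    out["fold_change"] = fcs
    return out


def _lrt_mixed(dct: np.ndarray, condition: np.ndarray, replicate: np.ndarray) -> tuple[float, int, str]:
    """LRT of the condition term in a random-intercept model (ML fits)."""
    conditions = pd.unique(condition)
    df = len(conditions) - 1
    if np.ptp(dct) == 0:  # degenerate: no variance at all, trivially null
        return 0.0, df, "mixed"
    exog_full = pd.get_dummies(pd.Categorical(condition), drop_first=True, dtype=float).to_numpy()
    exog_full = np.column_stack([np.ones(len(dct)), exog_full])
    exog_null = np.ones((len(dct), 1))
    n_replicates = len(pd.unique(replicate))
    if n_replicates < 2:
        logger.warning("single replicate: falling back to ordinary linear model")
        full = sm.OLS(dct, exog_full).fit()
        null = sm.OLS(dct, exog_null).fit()
        return max(0.0, 2.0 * (full.llf - null.llf)), df, "ols"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(dct, exog_full, groups=replicate).fit(reml=False)
        null = sm.MixedLM(dct, exog_null, groups=replicate).fit(reml=False)
    return max(0.0, 2.0 * (full.llf - null.llf)), df, "mixed"


def _balanced_block_f(dct: np.ndarray, condition: np.ndarray, replicate: np.ndarray):
    """Exact F for the condition effect in a balanced replicate-block design.

    With one observation per (replicate, condition) cell this is the exact
    finite-sample test of the fixed condition effect in the random-intercept
    model; the asymptotic chi-squared LRT reference is anti-conservative at
    these sample sizes.  Returns None when the design is not balanced.
    """
    df = pd.DataFrame({"y": dct, "c": condition, "r": replicate})
    cells = df.groupby(["r", "c"]).size()
    g, m = df["r"].nunique(), df["c"].nunique()
    if len(cells) != g * m or (cells != 1).any() or g < 2:
        return None
    grand = df["y"].mean()
    cm = df.groupby("c")["y"].mean()
    rm = df.groupby("r")["y"].mean()
    ss_cond = g * ((cm - grand) ** 2).sum()
    resid = df["y"] - df["c"].map(cm) - df["r"].map(rm) + grand
    ss_res = (resid**2).sum()
    df1, df2 = m - 1, (m - 1) * (g - 1)
    if ss_res <= 0:
        return (np.inf if ss_cond > 0 else 0.0), df1, df2
    return float((ss_cond / df1) / (ss_res / df2)), df1, df2


def condition_test_single(dct: pd.DataFrame) -> ConditionTestResult:
    """Condition-effect test on delta-Ct for one target.

    The mixed model (condition fixed, replicate random intercept) is fitted
    by ML and the LRT statistic for the condition term is reported.  The
    p-value comes from the exact balanced-block F reference when the design
    is balanced (one observation per replicate x condition), and from the
    asymptotic chi-squared distribution of the LRT otherwise.
    """
    if dct["condition"].nunique() < 2:
        raise ValueError("condition test requires >= 2 conditions")
    y = dct["delta_ct"].to_numpy(dtype=float)
    condition = dct["condition"].to_numpy()
    replicate = dct["replicate"].to_numpy()
    stat, df, method = _lrt_mixed(y, condition, replicate)
    exact = _balanced_block_f(y, condition, replicate) if method == "mixed" else None
    if exact is not None:
        f_stat, df1, df2 = exact
        p = 1.0 if f_stat == 0.0 else float(stats.f.sf(f_stat, df1, df2))
        method = "mixed+exactF"
    else:
        p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, df))
    target = str(dct["target"].iloc[0]) if "target" in dct.columns else ""
    return ConditionTestResult(target=target, statistic=stat, df=df, p_value=p, method=method)


def condition_test(dct: pd.DataFrame, group_key: str = "target") -> pd.DataFrame:
    """Per-target condition LRT with BH adjustment across targets."""
    results = [condition_test_single(sub) for _, sub in dct.groupby(group_key, sort=True)]
    out = pd.DataFrame(
        {
            group_key: [r.target for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "method": [r.method for r in results],
        }
    )
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = q
    return out


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any() or ~np.isfinite(df["ct"]).all():
        raise ValueError("Ct values must be finite and > 0")
    return df
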