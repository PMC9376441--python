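"""Pooling of site-stratified results.

Random-effects pooling uses the DerSimonian-Laird method-of-moments
estimator of the between-site variance tau^2 (REML available behind a
flag); beta-diversity p-values are combined with Fisher's method; and
multiplicity is controlled with Benjamini-Hochberg FDR applied
independently within each (site, analysis type) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MetaResult:
    """Pooled random-effects estimate across site-stratified fits."""

    term: str
    k: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    q: float
    tau2: float
    i2: float
    study_labels: list = field(default_factory=list)
    study_estimates: list = field(default_factory=list)
    study_ses: list = field(default_factory=list)


def dersimonian_laird(
    estimates,
    ses,
    term: str = "",
    labels=None,
    method: str = "dl",
) -> MetaResult:
    """Random-effects meta-analysis of per-site estimates.

    ``method='dl'`` (default) is the DerSimonian-Laird moment estimator:
    with fixed weights w_i = 1/se_i^2, Q = sum w_i (y_i - ybar_w)^2 and
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random
    weights 1/(se_i^2 + tau^2) then give the pooled mean and its
    standard error.  ``method='reml'`` iterates the restricted
    likelihood for tau^2 instead.
    """
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("meta-analysis needs at least one study")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    k = y.size
    w = 1.0 / s**2
    ybar = (w * y).sum() / w.sum()
    q = float((w * (y - ybar) ** 2).sum())
    if k == 1:
        tau2 = 0.0
    elif method == "dl":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    elif method == "reml":
        tau2 = _reml_tau2(y, s)
    else:
        raise ValueError(f"unknown method {method!r}")
    wr = 1.0 / (s**2 + tau2)
    est = float((wr * y).sum() / wr.sum())
    se = float(wr.sum() ** -0.5)
    z = est / se
    p = float(2 * stats.norm.sf(abs(z)))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 and k > 1 else 0.0
    return MetaResult(
        term=term,
        k=k,
        estimate=est,
        se=se,
        ci_low=est - 1.959963984540054 * se,
        ci_high=est + 1.959963984540054 * se,
        z=z,
        p_value=p,
        q=q,
        tau2=tau2,
        i2=i2,
        study_labels=list(labels) if labels is not None else [f"study_{i}" for i in range(k)],
        study_estimates=list(y),
        study_ses=list(s),
    )


def _reml_tau2(y: np.ndarray, s: np.ndarray, n_iter: int = 100, tol: float = 1e-10) -> float:
    tau2 = max(0.0, np.var(y, ddof=1) - np.mean(s**2)) if len(y) > 1 else 0.0
    for _ in range(n_iter):
        w = 1.0 / (s**2 + tau2)
        mu = (w * y).sum() / w.sum()
        num = (w**2 * ((y - mu) ** 2 - s**2)).sum() + tau2 * (w**2).sum() / w.sum()
        new = max(0.0, num / (w**2).sum())
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


@dataclass
class CombinedP:
    """Fisher-combined evidence across independent p-values."""

    statistic: float
    df: int
    p_value: float


def fishers_method(pvals) -> CombinedP:
    """Fisher's combination: X^2 = -2 sum ln p ~ chi^2 with 2k df."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedP(x2, df, float(stats.chi2.sf(x2, df)))


def benjamini_hochberg(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR adjustment; rejection at adjusted p <= q (inclusive)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def grouped_adjust(
    results: pd.DataFrame,
    group_cols=("site", "analysis_type"),
    p_col: str = "p_value",
    q: float = 0.05,
) -> pd.DataFrame:
    """BH adjustment applied independently within each group.

    ``results`` must carry the grouping columns and a raw p-value column;
    the returned copy adds ``fdr_p`` and ``significant``.  Rows with a
    missing p-value (for example non-converged fits) are left unadjusted.
    """
    group_cols = list(group_cols)
    for col in group_cols + [p_col]:
        if col not in results.columns:
            raise ValueError(f"results lack required column {col!r}")
    if results[group_cols].isna().any().any():
        raise ValueError("every result must be labeled with site and analysis type")
    out = results.copy()
    out["fdr_p"] = np.nan
    out["significant"] = False
    for _, idx in out.groupby(group_cols, dropna=False).groups.items():
        ok = out.loc[idx, p_col].notna()
        rows = pd.Index(idx)[ok.to_numpy()]
        if len(rows) == 0:
            continue
        adj, rej = benjamini_hochberg(out.loc[rows, p_col].to_numpy(), q=q)
        out.loc[rows, "fdr_p"] = adj
        out.loc[rows, "significant"] = rej
    return out


def eligible_for_supplement_meta(frame: pd.DataFrame) -> bool:
    """A site enters the supplement-term meta-analysis only if supplement
    status varies at every timepoint.  An India-style design — no
    never-supplemented arm, so every woman is on the supplement at 34
    weeks — has a timepoint with no contrast and is excluded."""
    return all(
        sub["supplement_status"].nunique() > 1 for _, sub in frame.groupby("time")
    )


def forest_table(meta: MetaResult, excluded: dict | None = None) -> pd.DataFrame:
    """Plot-ready forest rows: one per study plus a pooled diamond row.

    ``excluded`` maps study label -> reason for studies shown but not
    pooled (for example a site with no supplement contrast).
    """
    z = 1.959963984540054
    rows = []
    for label, est, se in zip(meta.study_labels, meta.study_estimates, meta.study_ses):
        rows.append(
            {
                "row": label,
                "kind": "study",
                "estimate": est,
                "se": se,
                "ci_low": est - z * se,
                "ci_high": est + z * se,
                "excluded": "",
            }
        )
    for label, reason in (excluded or {}).items():
        rows.append(
            {
                "row": label,
                "kind": "excluded",
                "estimate": np.nan,
                "se": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "excluded": reason,
            }
        )
    rows.append(
        {
            "row": "pooled",
            "kind": "pooled",
            "estimate": meta.estimate,
            "se": meta.se,
            "ci_low": meta.ci_low,
            "ci_high": meta.ci_high,
            "excluded": "",
        }
    )
    return pd.DataFrame(rows)
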