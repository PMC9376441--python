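"""Per-site longitudinal models.

The analysis is stratified by site and pooled afterwards
(:mod:`gravidbiome.meta_analysis`).  Within a site:

* alpha-diversity outcomes are modeled with Gaussian generalized
  estimating equations (exchangeable working correlation over subjects,
  robust sandwich standard errors);
* beta-diversity uses repeated-measures PERMANOVA — the McArdle-Anderson
  pseudo-F with sequential sums of squares and restricted permutations
  (within-subject visit swaps for the time term, whole-subject block
  permutation for between-subject terms);
* individual taxa are modeled with a negative-binomial GLM (log link,
  ML dispersion) whose significance comes from a cluster bootstrap that
  resamples subjects with replacement;
* phylum-level relative abundances use linear mixed models with a
  subject random intercept, interaction-first ANOVA, and Tukey-adjusted
  pairwise contrasts.

Time is coded 12 weeks -> 0, 34 weeks -> 1, so every coefficient is the
12-to-34-week contrast.  All models include standardized read depth and
batch as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from gravidbiome.diversity import DistanceMatrix, gower_center


@dataclass
class DesignSpec:
    """Fixed-effect structure of one site-stratified model."""

    outcome: str
    site: str | None = None
    include_interaction: bool = False
    covariates: tuple = ()
    include_batch: bool = True
    include_depth: bool = True
    cluster: str = "subject_id"

    def rhs_terms(self) -> list[str]:
        terms = ["time", "supplement_status"]
        if self.include_interaction:
            terms.append("time:supplement_status")
        terms.extend(self.covariates)
        if self.include_batch:
            terms.append("C(batch)")
        if self.include_depth:
            terms.append("standardized_depth")
        return terms

    def formula(self, outcome: str | None = None) -> str:
        lhs = outcome or self.outcome
        return f"Q('{lhs}') ~ " + " + ".join(self.rhs_terms())


@dataclass
class FitResult:
    """One model term's estimate with robust inference."""

    term: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    n_samples: int
    n_clusters: int
    converged: bool
    family: str
    fdr_p: float | None = None
    site: str | None = None
    outcome: str | None = None


def fit_results_frame(results: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _select_site(frame: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    if spec.site is None:
        return frame
    sub = frame[frame["site"] == spec.site]
    if len(sub) == 0:
        raise ValueError(f"no samples for site {spec.site!r}")
    return sub


def fit_gee_alpha(
    alpha: pd.DataFrame, frame: pd.DataFrame, spec: DesignSpec
) -> list[FitResult]:
    """Gaussian GEE of one alpha-diversity outcome on the trial design.

    Exchangeable working correlation over subjects, robust (sandwich)
    covariance, Wald z p-values per term.  Non-convergence is flagged on
    every returned term, never silently downgraded.
    """
    data = _select_site(frame, spec).copy()
    if spec.outcome in data.columns:
        data = data.drop(columns=[spec.outcome])
    data = data.merge(
        alpha.reset_index()[["sample_id", spec.outcome]], on="sample_id", how="inner"
    )
    return _fit_gee(data, spec, outcome=spec.outcome, family_tag="gaussian_gee")


def _fit_gee_raw(data: pd.DataFrame, formula: str, cluster: str):
    """Fit a Gaussian exchangeable GEE, returning (result, converged)."""
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.gee(
            formula,
            groups=cluster,
            data=data,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        try:
            res = model.fit(maxiter=200)
        except Exception:
            converged = False
            res = None
        if res is not None and any("onverge" in str(w.message) for w in caught):
            converged = False
    if res is None or not np.isfinite(res.params).all():
        converged = False
    return res, converged


def _fit_gee(
    data: pd.DataFrame, spec: DesignSpec, outcome: str, family_tag: str
) -> list[FitResult]:
    if data[spec.cluster].nunique() < 2:
        raise ValueError("GEE requires at least two clusters")
    res, converged = _fit_gee_raw(data, spec.formula(outcome), spec.cluster)
    results = []
    if res is None:
        return [
            FitResult(
                term="(model)", estimate=np.nan, se=np.nan, statistic=np.nan,
                p_value=np.nan, n_samples=len(data),
                n_clusters=data[spec.cluster].nunique(), converged=False,
                family=family_tag, site=spec.site, outcome=outcome,
            )
        ]
    bse = res.bse
    for term in res.params.index:
        se = float(bse[term])
        z = float(res.params[term]) / se if se > 0 else np.nan
        results.append(
            FitResult(
                term=term,
                estimate=float(res.params[term]),
                se=se,
                statistic=z,
                p_value=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                n_samples=len(data),
                n_clusters=data[spec.cluster].nunique(),
                converged=converged,
                family=family_tag,
                site=spec.site,
                outcome=outcome,
            )
        )
    return results


# ---------------------------------------------------------------------------
# PERMANOVA with repeated-measures permutation schemes
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    term: str
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    scheme: str
    seed: int | None
    n_samples: int


def _design_matrix(frame: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept + dummy-coded design columns for the given terms."""
    cols = [np.ones(len(frame))]
    for term in terms:
        if term.startswith("C(") and term.endswith(")"):
            col = term[2:-1]
            dummies = pd.get_dummies(frame[col].astype(str), drop_first=True)
            cols.extend(dummies[c].to_numpy(float) for c in dummies.columns)
        elif ":" in term:
            a, b = term.split(":")
            cols.append(frame[a].to_numpy(float) * frame[b].to_numpy(float))
        else:
            vals = frame[term]
            if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(vals.astype(str), drop_first=True)
                cols.extend(dummies[c].to_numpy(float) for c in dummies.columns)
            else:
                cols.append(vals.to_numpy(float))
    return np.column_stack(cols)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0]))))
    q = q[:, :rank]
    return q @ q.T, rank


class _PermScheme:
    """Restricted-permutation generator over a fixed sample frame.

    Subject visit positions are precomputed once; each call to
    :meth:`draw` returns a row-index permutation honoring the scheme.
    """

    def __init__(self, frame: pd.DataFrame, scheme: str):
        self.scheme = scheme
        self.n = len(frame)
        week = frame["week"].to_numpy()
        self.pairs = []  # subjects with both visits, as (pos12, pos34)
        self.patterns: dict[tuple, list[np.ndarray]] = {}
        for _, rows in frame.groupby("subject_id").groups.items():
            pos = np.asarray(rows)
            pos = pos[np.argsort(week[pos])]
            if len(pos) == 2:
                self.pairs.append(pos)
            self.patterns.setdefault(tuple(week[pos]), []).append(pos)

    def draw(self, rng) -> np.ndarray:
        idx = np.arange(self.n)
        if self.scheme == "free":
            return rng.permutation(self.n)
        if self.scheme == "within_subject":
            flips = rng.random(len(self.pairs)) < 0.5
            for pos, flip in zip(self.pairs, flips):
                if flip:
                    idx[pos[0]], idx[pos[1]] = idx[pos[1]], idx[pos[0]]
            return idx
        if self.scheme == "between_subject":
            for blocks in self.patterns.values():
                perm = rng.permutation(len(blocks))
                for i, dst in enumerate(blocks):
                    idx[dst] = blocks[perm[i]]
            return idx
        raise ValueError(f"unknown permutation scheme {self.scheme!r}")


def permanova(
    dm: DistanceMatrix,
    frame: pd.DataFrame,
    spec: DesignSpec,
    term: str,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str | None = None,
) -> PermanovaResult:
    """Repeated-measures PERMANOVA for one term of a site model.

    The McArdle-Anderson pseudo-F is computed from the Gower-centered
    -D^2/2 matrix with sequential sums of squares, the tested term
    entered last.  The permutation scheme defaults to within-subject
    visit swaps when testing ``time`` and whole-subject block
    permutation otherwise; ``scheme='free'`` gives unrestricted
    permutations for cross-sectional screens.  p = (1 + #{F* >= F}) /
    (1 + n_perm).
    """
    frame = frame.reset_index(drop=True)
    if list(dm.ids) != list(frame["sample_id"]):
        dm = dm.subset(list(frame["sample_id"]))
    adjust = [t for t in spec.rhs_terms() if t != term]
    if term not in spec.rhs_terms():
        adjust = spec.rhs_terms()
    x_red = _design_matrix(frame, adjust)
    x_full = _design_matrix(frame, adjust + [term])
    h_red, rank_red = _hat(x_red)
    h_full, rank_full = _hat(x_full)
    df_term = rank_full - rank_red
    if df_term == 0:
        raise ValueError(f"term {term!r} is collinear with the adjustment set")
    n = len(frame)
    df_res = n - rank_full
    g = gower_center(dm.values)

    def pseudo_f(gmat: np.ndarray) -> tuple[float, float, float]:
        ss_term = float(np.sum((h_full - h_red) * gmat.T))
        ss_res = float(np.sum((np.eye(n) - h_full) * gmat.T))
        ss_total = float(np.trace(gmat))
        tol = 1e-12 * max(1.0, abs(ss_total))
        if ss_res <= tol:  # saturated fit: the design explains all variation
            f = np.inf if ss_term > tol else 0.0
        else:
            f = (ss_term / df_term) / (ss_res / df_res)
        r2 = ss_term / ss_total if ss_total > 0 else np.nan
        return f, r2, ss_term

    f_obs, r2, _ = pseudo_f(g)
    if scheme is None:
        scheme = "within_subject" if term == "time" else "between_subject"
    generator = _PermScheme(frame, scheme)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = generator.draw(rng)
        g_perm = g[np.ix_(idx, idx)]
        f_star, _, _ = pseudo_f(g_perm)
        if f_star >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        term=term, pseudo_f=f_obs, r2=r2, p_value=p,
        n_permutations=n_perm, scheme=scheme, seed=seed, n_samples=n,
    )


# ---------------------------------------------------------------------------
# Negative-binomial differential abundance with cluster bootstrap
# ---------------------------------------------------------------------------

def _nb_design(counts, frame: pd.DataFrame, spec: DesignSpec):
    data = frame.copy()
    data["_count"] = np.asarray(counts)
    if spec.site is not None:
        data = data[data["site"] == spec.site]
    return data


def nb_glm(
    counts, frame: pd.DataFrame, spec: DesignSpec, start_params=None
):
    """Negative-binomial (NB2, log link) regression of one taxon's counts.

    Dispersion is estimated by maximum likelihood.  Read depth enters as
    the standardized covariate rather than an offset (``offset`` mode is
    available through the spec by dropping the depth term and passing an
    exposure downstream).  Returns a fitted statsmodels result plus a
    convergence flag via :func:`nb_glm_terms`.
    """
    data = _nb_design(counts, frame, spec)
    formula = "_count ~ " + " + ".join(spec.rhs_terms())
    model = smf.negativebinomial(formula, data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(
            disp=0, maxiter=200, start_params=start_params, method="bfgs", gtol=1e-6
        )
    return res


def nb_glm_terms(counts, frame: pd.DataFrame, spec: DesignSpec) -> list[FitResult]:
    """Tidy per-term results for one taxon's negative-binomial fit."""
    data = _nb_design(counts, frame, spec)
    res = nb_glm(counts, frame, spec)
    converged = bool(res.mle_retvals.get("converged", False)) and bool(
        np.isfinite(res.params).all()
    )
    out = []
    for term in res.params.index:
        if term == "alpha":
            continue
        se = float(res.bse[term])
        z = float(res.params[term]) / se if se > 0 else np.nan
        out.append(
            FitResult(
                term=term,
                estimate=float(res.params[term]),
                se=se,
                statistic=z,
                p_value=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                n_samples=len(data),
                n_clusters=data[spec.cluster].nunique(),
                converged=converged,
                family="negative_binomial",
                site=spec.site,
            )
        )
    return out


@dataclass
class BootstrapTest:
    """Cluster-bootstrap significance test for one NB-GLM term."""

    taxon: str
    term: str
    estimate: float
    boot_mean: float
    boot_sd: float
    p_value: float
    n_replicates: int
    n_failed: int
    seed: int | None
    unreliable: bool
    samples: np.ndarray = field(repr=False, default=None)


def nb_bootstrap_test(
    counts,
    frame: pd.DataFrame,
    spec: DesignSpec,
    terms=("time",),
    B: int = 1000,
    seed: int | None = None,
    taxon: str = "",
    max_failed_frac: float = 0.2,
    pvalue_method: str = "normal",
) -> dict[str, BootstrapTest]:
    """Subject-level bootstrap of the NB-GLM coefficients.

    Subjects (clusters) are resampled with replacement, each keeping all
    of its samples, and the model is refit per replicate.  The default
    p-value is the two-sided normal approximation
    ``2 (1 - Phi(|mean* / sd*|))`` on the bootstrap distribution;
    ``pvalue_method='percentile'`` instead doubles the smaller tail of
    the replicate distribution around zero.  Replicates that fail to
    refit are dropped and counted; more than ``max_failed_frac`` of them
    flags the test unreliable.
    """
    if B < 10:
        raise ValueError("bootstrap needs at least 10 replicates")
    data = _nb_design(counts, frame, spec).reset_index(drop=True)
    inner_spec = DesignSpec(
        outcome="_count", site=None, include_interaction=spec.include_interaction,
        covariates=spec.covariates, include_batch=spec.include_batch,
        include_depth=spec.include_depth, cluster=spec.cluster,
    )
    full = nb_glm(data["_count"].to_numpy(), data, inner_spec)
    start = np.asarray(full.params)
    # the design matrix is built once; replicates only reindex its rows
    endog = np.asarray(full.model.endog)
    exog = np.asarray(full.model.exog)
    names = list(full.model.exog_names)
    term_idx = {t: names.index(t) for t in terms}
    subj_rows = [np.asarray(rows) for _, rows in data.groupby(spec.cluster).groups.items()]
    n_subjects = len(subj_rows)
    width = max(len(r) for r in subj_rows)
    padded = np.full((n_subjects, width), -1, dtype=np.int64)
    for i, r in enumerate(subj_rows):
        padded[i, : len(r)] = r
    rng = np.random.default_rng(seed)
    draws = {t: [] for t in terms}
    n_failed = 0
    for _ in range(B):
        pick = rng.integers(0, n_subjects, n_subjects)
        sel = padded[pick].ravel()
        rows = sel[sel >= 0]
        try:
            model = sm.NegativeBinomial(endog[rows], exog[rows])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=100, start_params=start,
                                method="bfgs", gtol=1e-6)
            if not np.isfinite(res.params).all():
                raise RuntimeError("non-finite refit")
            for t in terms:
                draws[t].append(float(res.params[term_idx[t]]))
        except Exception:
            n_failed += 1
    out = {}
    for t in terms:
        arr = np.asarray(draws[t])
        if len(arr) < 2:
            raise RuntimeError(f"all bootstrap refits failed for term {t!r}")
        mean, sd = arr.mean(), arr.std(ddof=1)
        if pvalue_method == "normal":
            p = float(2 * stats.norm.sf(abs(mean) / sd)) if sd > 0 else 0.0
        elif pvalue_method == "percentile":
            tail = min((arr <= 0).mean(), (arr >= 0).mean())
            p = float(min(1.0, 2 * max(tail, 1.0 / len(arr))))
        else:
            raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
        p = max(p, np.finfo(float).tiny)
        out[t] = BootstrapTest(
            taxon=taxon, term=t, estimate=float(full.params[t]),
            boot_mean=float(mean), boot_sd=float(sd), p_value=p,
            n_replicates=B, n_failed=n_failed, seed=seed,
            unreliable=n_failed > max_failed_frac * B, samples=arr,
        )
    return out


# ---------------------------------------------------------------------------
# Outlier sensitivity analysis
# ---------------------------------------------------------------------------

def residual_outlier_mask(residuals, k: float = 3.0) -> np.ndarray:
    """Flag residuals outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics; the
    mask is monotone in ``k`` (larger fences flag fewer points).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 4:
        raise ValueError("need >= 4 residuals for quartile fences")
    q1, q3 = np.quantile(r, [0.25, 0.75])
    iqr = q3 - q1
    return (r < q1 - k * iqr) | (r > q3 + k * iqr)


@dataclass
class SensitivityResult:
    full: list[FitResult]
    reduced: list[FitResult]
    removed_sample_ids: list
    degenerate: bool


def sensitivity_refit(
    alpha: pd.DataFrame, frame: pd.DataFrame, spec: DesignSpec, k: float = 3.0,
    min_clusters: int = 10,
) -> SensitivityResult:
    """Outlier sensitivity analysis for one alpha-diversity GEE.

    Residuals from the full fit define the Q1-3*IQR / Q3+3*IQR fences;
    the model is refit once on the reduced set and both fits are
    returned side by side.  The refit is flagged degenerate when too few
    clusters remain or a design level disappears."""
    data = _select_site(frame, spec).copy()
    if spec.outcome in data.columns:
        data = data.drop(columns=[spec.outcome])
    data = data.merge(
        alpha.reset_index()[["sample_id", spec.outcome]], on="sample_id", how="inner"
    ).reset_index(drop=True)
    res, converged = _fit_gee_raw(data, spec.formula(), spec.cluster)
    if not converged:
        raise RuntimeError("full fit did not converge; sensitivity undefined")
    full = _fit_gee(data, spec, spec.outcome, "gaussian_gee")
    resid = np.asarray(res.resid)
    mask = residual_outlier_mask(resid, k=k)
    removed = list(data.loc[mask, "sample_id"])
    reduced_data = data.loc[~mask].reset_index(drop=True)
    degenerate = (
        reduced_data[spec.cluster].nunique() < min_clusters
        or reduced_data["batch"].nunique() < data["batch"].nunique()
        or reduced_data["time"].nunique() < data["time"].nunique()
    )
    if degenerate:
        reduced = full
    else:
        reduced = _fit_gee(reduced_data, spec, spec.outcome, "gaussian_gee")
    return SensitivityResult(full, reduced, removed, degenerate)


# ---------------------------------------------------------------------------
# Phylum-level linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class PhylumResult:
    phylum: str
    interaction_p: float
    model_used: str
    contrasts: pd.DataFrame
    main_effect_p: dict
    fallback_fixed_effects: bool


def phylum_lmm(
    rel_abund: pd.Series, frame: pd.DataFrame, phylum: str = "",
    interaction_alpha: float = 0.05,
) -> PhylumResult:
    """All-site mixed model for one phylum's relative abundance.

    Fits ``rel_abund ~ time * site + batch`` with a subject random
    intercept and tests the interaction by Wald ANOVA.  When the
    interaction is significant, Tukey-adjusted pairwise comparisons are
    made between the time x site cells; otherwise the additive model is
    refit and pairwise contrasts are reported for whichever main
    effects are significant.  A singular random-effects fit falls back
    to a fixed-effects model with cluster-robust errors (flagged).
    """
    data = frame.copy().reset_index(drop=True)
    data["_y"] = np.asarray(rel_abund)
    data["cell"] = data["site"].astype(str) + ":" + data["time"].astype(str)

    def _fit(formula):
        fallback = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(formula, data, groups=data["subject_id"])
                res = md.fit(reml=False)
                if not np.isfinite(res.params).all() or not res.converged:
                    raise RuntimeError("singular mixed fit")
            except Exception:
                fallback = True
                res = smf.ols(formula, data).fit(
                    cov_type="cluster", cov_kwds={"groups": data["subject_id"]}
                )
        return res, fallback

    res_int, fb1 = _fit("_y ~ C(time) * C(site) + C(batch)")
    inter_names = [n for n in res_int.params.index if "C(time)" in n and "C(site)" in n]
    interaction_p = float(_wald_joint(res_int, inter_names))
    if interaction_p < interaction_alpha:
        res_cells, fb2 = _fit("_y ~ C(cell, Treatment) + C(batch)")
        contrasts = _pairwise_cells(res_cells, data, "cell")
        return PhylumResult(phylum, interaction_p, "interaction", contrasts, {}, fb1 or fb2)
    res_add, fb2 = _fit("_y ~ C(time) + C(site) + C(batch)")
    main_p = {
        "time": float(_wald_joint(res_add, [n for n in res_add.params.index if n.startswith("C(time)")])),
        "site": float(_wald_joint(res_add, [n for n in res_add.params.index if n.startswith("C(site)")])),
    }
    pieces = []
    if main_p["site"] < interaction_alpha:
        res_site, _ = _fit("_y ~ C(site, Treatment) + C(time) + C(batch)")
        pieces.append(_pairwise_cells(res_site, data, "site", term_prefix="C(site, Treatment)"))
    if main_p["time"] < interaction_alpha:
        res_time, _ = _fit("_y ~ C(time, Treatment) + C(site) + C(batch)")
        pieces.append(_pairwise_cells(res_time, data, "time", term_prefix="C(time, Treatment)"))
    contrasts = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["level_a", "level_b", "estimate", "se", "statistic", "p_tukey"]
    )
    return PhylumResult(phylum, interaction_p, "additive", contrasts, main_p, fb1 or fb2)


def _wald_joint(res, names: list[str]) -> float:
    if not names:
        return 1.0
    k = len(res.params)
    contrast = np.zeros((len(names), k))
    index = list(res.params.index)
    for i, nm in enumerate(names):
        contrast[i, index.index(nm)] = 1.0
    wt = res.wald_test(contrast, scalar=True)
    return float(wt.pvalue)


def _pairwise_cells(res, data, factor: str, term_prefix: str | None = None) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts between the levels of a factor,
    read off a treatment-coded fit."""
    prefix = term_prefix or f"C({factor}, Treatment)"
    levels = sorted(data[factor].astype(str).unique())
    index = list(res.params.index)
    cov = np.asarray(res.cov_params())
    if cov.shape[0] != len(index):  # mixedlm appends the variance component
        cov = cov[: len(index), : len(index)]
    coef = {levels[0]: np.zeros(len(index))}
    for lev in levels[1:]:
        vec = np.zeros(len(index))
        name = f"{prefix}[T.{lev}]"
        if name not in index:
            continue
        vec[index.index(name)] = 1.0
        coef[lev] = vec
    k = len(coef)
    df_resid = max(int(getattr(res, "df_resid", len(data) - len(index))), 2)
    rows = []
    levs = list(coef)
    for i in range(len(levs)):
        for j in range(i + 1, len(levs)):
            vec = coef[levs[j]] - coef[levs[i]]
            est = float(vec @ np.asarray(res.params)[: len(index)])
            se = float(np.sqrt(vec @ cov @ vec))
            tstat = est / se if se > 0 else np.nan
            p = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2), k, df_resid)) if np.isfinite(tstat) else np.nan
            rows.append(
                {"level_a": levs[i], "level_b": levs[j], "estimate": est,
                 "se": se, "statistic": tstat, "p_tukey": p}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-comparison and biomarker tests
# ---------------------------------------------------------------------------

def cochran_armitage(table, scores=None) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2 x k contingency table.

    Rows are the two groups, columns the k ordered categories; scores
    default to equally spaced integers.  Returns (Z, two-sided p).
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("need a 2 x k table with k >= 2")
    if (tab.sum(axis=1) == 0).any() or tab.sum() == 0:
        raise ValueError("a zero margin makes the trend test undefined")
    k = tab.shape[1]
    s = np.asarray(scores, dtype=float) if scores is not None else np.arange(k, dtype=float)
    n_col = tab.sum(axis=0)
    n = tab.sum()
    a = tab[0]  # group-1 counts per category
    r = tab[0].sum() / n
    num = float((s * (a - n_col * r)).sum())
    var = r * (1 - r) * float((n_col * s**2).sum() - (n_col * s).sum() ** 2 / n)
    if var <= 0:
        raise ValueError("degenerate score distribution")
    z = num / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mean_difference_test(x, y) -> tuple[float, float]:
    """Welch two-sample t-test for a difference in means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


BIOMARKERS = ("agp", "crp", "mpo", "calprotectin")


def biomarker_models(
    alpha: pd.DataFrame, frame: pd.DataFrame, biomarkers=BIOMARKERS,
    alpha_measures=("sobs", "chao1", "shannon_h", "evenness"),
) -> tuple[pd.DataFrame, list[str]]:
    """Inflammatory-biomarker models across the sites that measured them.

    (a) change over pregnancy: Gaussian GEE of the log biomarker on
    time + supplement + site, clustered by subject; (b) association
    with diversity: GEE of each alpha measure on the biomarker plus
    time, batch, and standardized depth.  Sites with no biomarker data
    (e.g. a site without cold-chain access) are skipped and logged.
    """
    log: list[str] = []
    rows: list[FitResult] = []
    for marker in biomarkers:
        if marker not in frame.columns:
            log.append(f"biomarker {marker!r} absent from metadata; skipped")
            continue
        have = frame[frame[marker].notna()].copy()
        skipped_sites = sorted(set(frame["site"]) - set(have["site"]))
        for s in skipped_sites:
            log.append(f"site {s!r} has no {marker!r} measurements; skipped")
        if have["site"].nunique() < 2 or len(have) < 8:
            log.append(f"biomarker {marker!r}: fewer than 2 sites with data; skipped")
            continue
        have[f"log_{marker}"] = np.log(have[marker].astype(float))
        spec = DesignSpec(outcome=f"log_{marker}", include_batch=False, include_depth=False)
        data = have.copy()
        data["_site_dummy"] = data["site"].astype(str)
        time_fits = _fit_gee_formula(
            data, f"Q('log_{marker}') ~ time + supplement_status + C(site)",
            cluster="subject_id", family_tag="gaussian_gee",
        )
        for f in time_fits:
            f.outcome = f"log_{marker}"
            f.site = "all"
            rows.append(f)
        merged = have.merge(alpha.reset_index(), on="sample_id", how="inner")
        for measure in alpha_measures:
            fits = _fit_gee_formula(
                merged,
                f"Q('{measure}') ~ Q('log_{marker}') + time + C(batch) + standardized_depth",
                cluster="subject_id", family_tag="gaussian_gee",
            )
            for f in fits:
                if marker in f.term:
                    f.outcome = measure
                    f.site = "all"
                    rows.append(f)
    return fit_results_frame(rows) if rows else pd.DataFrame(), log


def _fit_gee_formula(data, formula, cluster, family_tag) -> list[FitResult]:
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.gee(
            formula, groups=cluster, data=data,
            family=sm.families.Gaussian(), cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit(maxiter=200)
        if any("onverge" in str(w.message) for w in caught):
            converged = False
    out = []
    for term in res.params.index:
        se = float(res.bse[term])
        z = float(res.params[term]) / se if se > 0 else np.nan
        out.append(
            FitResult(
                term=term, estimate=float(res.params[term]), se=se, statistic=z,
                p_value=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                n_samples=len(data), n_clusters=data[cluster].nunique(),
                converged=converged, family=family_tag,
            )
        )
    return out
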