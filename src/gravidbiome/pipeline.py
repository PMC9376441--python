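"""End-to-end orchestration: simulate/ingest -> filter -> diversity ->
covariate selection -> per-site models -> meta-analysis -> report.

Every stage writes a plain TSV or JSON artifact into the run directory
so any stage can be re-run or audited in isolation, and every random
stage records its seed.  The run is deterministic given its config.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from gravidbiome import covariate_selection as covsel
from gravidbiome import diversity as dv
from gravidbiome import feature_tables as ft
from gravidbiome import longitudinal_models as lm
from gravidbiome import meta_analysis as ma
from gravidbiome import synthetic_cohort as sc

logger = logging.getLogger("gravidbiome")


@dataclass
class RunConfig:
    """All thresholds, sizes, and seeds of one pipeline run."""

    out_dir: str = "gravidbiome_run"
    scenario: sc.ScenarioConfig | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    seed: int = 7
    min_reads: int = 3700
    prevalence: float = 0.05
    max_rel_abund: float = 0.001
    fdr_q: float = 0.05
    screening_alpha: float = 0.1
    r_threshold: float = 0.7
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    screen_covariates: tuple = ("overall_ses", "ses_factor_1", "improved_water_source",
                               "maternal_schooling", "cooking_fuel")
    screen_permutations: int = 200
    n_pcoa_axes: int = 2
    max_bootstrap_taxa: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.prevalence <= 1 and 0 <= self.max_rel_abund <= 1):
            raise ValueError("thresholds out of range")
        if self.scenario is None and (self.table_path is None or self.metadata_path is None):
            self.scenario = sc.default_scenario()


@dataclass
class RunReport:
    """Machine-readable outputs of one run, mirroring the study's tables."""

    filter_reports: list
    alpha_fits: pd.DataFrame
    beta_results: pd.DataFrame
    taxon_fits: pd.DataFrame
    covariate_table: pd.DataFrame
    meta_table: pd.DataFrame
    forest_table: pd.DataFrame
    beta_meta: pd.DataFrame
    adjusted_means: pd.DataFrame
    pcoa_coords: pd.DataFrame
    pcoa_explained: list
    manifest: dict = field(default_factory=dict)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}

    # ------------------------------------------------------------ ingest
    if config.scenario is not None:
        bundle = sc.generate_cohort(config.scenario, config.seed)
        table, frame = bundle.table, bundle.frame
        (out / "truth.json").write_text(sc.truth_json(bundle))
    else:
        table = ft.read_feature_table(config.table_path)
        table = ft.aggregate_rank(table, "genus")
        frame = ft.read_metadata(config.metadata_path)
        frame = ft.attach_design(frame, table.depths())

    # ------------------------------------------------------------ filter
    table, frame, depth_report = ft.filter_min_depth(table, frame, config.min_reads)
    frame = frame.copy()
    frame["standardized_depth"] = ft.standardized_depth(frame["read_depth"].to_numpy())
    table, taxon_report = ft.filter_taxa(table, config.prevalence, config.max_rel_abund)
    (out / "filter_report.json").write_text(
        json.dumps([depth_report.__dict__, taxon_report.__dict__], indent=2, default=str)
    )
    ft.write_feature_table(table, out / "table.filtered.tsv")
    ft.write_metadata(frame, out / "meta.filtered.tsv")

    # ---------------------------------------------------------- diversity
    alpha = dv.alpha_table(table)
    alpha.to_csv(out / "alpha.tsv", sep="\t")
    dm = dv.bray_curtis(table)
    dm.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
    ordination = dv.pcoa(dm, n_axes=config.n_pcoa_axes)
    pcoa_coords = pd.DataFrame(
        ordination.coordinates,
        index=ordination.ids,
        columns=[f"PCo{i + 1}" for i in range(ordination.coordinates.shape[1])],
    )
    pcoa_coords.to_csv(out / "pcoa.tsv", sep="\t")

    # -------------------------------------------------- covariate selection
    trace = covsel.SelectionTrace()
    screens = []
    for cov in config.screen_covariates:
        if cov in frame.columns:
            screens.append(
                covsel.screen_covariate(
                    dm, frame, cov, n_perm=config.screen_permutations,
                    seed=_stage_seed(config.seed, f"screen:{cov}"), trace=trace,
                )
            )
    if screens:
        screens_df = pd.concat(screens, ignore_index=True)
        candidates = covsel.select_candidates(screens_df, alpha=config.screening_alpha)
        final, trace = covsel.prune_correlated(
            candidates, frame, r_threshold=config.r_threshold, trace=trace
        )
    else:
        final = {site: [] for site in frame["site"].unique()}
    covariate_table = covsel.final_covariate_table(final)
    covariate_table.to_csv(out / "covariates.tsv", sep="\t")
    trace.to_frame().to_csv(out / "covariate_trace.tsv", sep="\t", index=False)

    # ------------------------------------------------------ per-site models
    sites = sorted(frame["site"].unique())
    alpha_rows, beta_rows, taxon_rows = [], [], []
    for site in sites:
        site_covs = tuple(c for c in final.get(site, ()) if c in frame.columns)
        spec_base = dict(site=site, covariates=site_covs)
        for measure in sc.ALPHA_MEASURES:
            spec = lm.DesignSpec(outcome=measure, **spec_base)
            for fit in lm.fit_gee_alpha(alpha, frame, spec):
                row = fit.__dict__ | {"analysis_type": "alpha"}
                alpha_rows.append(row)
        sub = frame[frame["site"] == site].reset_index(drop=True)
        dm_site = dm.subset(list(sub["sample_id"]))
        spec = lm.DesignSpec(outcome="", **spec_base)
        for term in ("time", "supplement_status"):
            try:
                res = lm.permanova(
                    dm_site, sub, spec, term, n_perm=config.n_permutations,
                    seed=_stage_seed(config.seed, f"permanova:{site}:{term}"),
                )
            except ValueError as exc:
                logger.warning("PERMANOVA %s/%s skipped: %s", site, term, exc)
                continue
            beta_rows.append(
                {"site": site, "term": term, "pseudo_f": res.pseudo_f, "r2": res.r2,
                 "p_value": res.p_value, "scheme": res.scheme,
                 "n_permutations": res.n_permutations, "analysis_type": "beta"}
            )
        counts_site = table.data[list(sub["sample_id"])]
        boot_budget = config.max_bootstrap_taxa
        for taxon in table.taxa:
            counts = counts_site.loc[taxon].to_numpy()
            if (counts > 0).sum() < max(8, 0.05 * len(counts)):
                continue
            try:
                fits = lm.nb_glm_terms(counts, sub, lm.DesignSpec(outcome="_count", **spec_base))
            except Exception as exc:
                logger.warning("NB fit failed for %s at %s: %s", taxon, site, exc)
                continue
            boot = None
            if boot_budget > 0:
                boot = lm.nb_bootstrap_test(
                    counts, sub, lm.DesignSpec(outcome="_count", **spec_base),
                    terms=("time", "supplement_status"), B=config.n_bootstrap,
                    seed=_stage_seed(config.seed, f"boot:{site}:{taxon}"), taxon=taxon,
                )
                boot_budget -= 1
            for fit in fits:
                if fit.term not in ("time", "supplement_status"):
                    continue
                row = fit.__dict__ | {"taxon": taxon, "analysis_type": "taxon"}
                if boot is not None and fit.term in boot:
                    row["p_value"] = boot[fit.term].p_value
                    row["bootstrap"] = True
                else:
                    row["bootstrap"] = False
                taxon_rows.append(row)

    alpha_fits = pd.DataFrame(alpha_rows)
    beta_results = pd.DataFrame(beta_rows)
    taxon_fits = pd.DataFrame(taxon_rows)

    # --------------------------------------------------------- grouped FDR
    alpha_core = alpha_fits[alpha_fits["term"].isin(["time", "supplement_status"])].copy()
    alpha_core = ma.grouped_adjust(alpha_core, ("site", "analysis_type"), q=config.fdr_q)
    beta_adj = ma.grouped_adjust(beta_results, ("site", "analysis_type"), q=config.fdr_q) \
        if len(beta_results) else beta_results
    taxon_adj = ma.grouped_adjust(taxon_fits, ("site", "analysis_type"), q=config.fdr_q) \
        if len(taxon_fits) else taxon_fits
    alpha_core.to_csv(out / "alpha_fits.tsv", sep="\t", index=False)
    beta_adj.to_csv(out / "beta_results.tsv", sep="\t", index=False)
    taxon_adj.to_csv(out / "taxon_fits.tsv", sep="\t", index=False)

    # ------------------------------------------------------- meta-analysis
    meta_rows = []
    forest_rows: list[pd.DataFrame] = []
    eligible = {
        site: ma.eligible_for_supplement_meta(frame[frame["site"] == site])
        for site in sites
    }
    for measure in sc.ALPHA_MEASURES:
        for term in ("time", "supplement_status"):
            sub = alpha_core[
                (alpha_core["outcome"] == measure)
                & (alpha_core["term"] == term)
                & alpha_core["converged"]
            ]
            sub = sub[[eligible[s] for s in sub["site"]]]
            if len(sub) == 0:
                continue
            meta = ma.dersimonian_laird(
                sub["estimate"], sub["se"], term=term, labels=sub["site"]
            )
            meta_rows.append(
                {"outcome": measure, "term": term, "analysis_type": "alpha",
                 "k": meta.k, "estimate": meta.estimate, "se": meta.se,
                 "p_value": meta.p_value, "tau2": meta.tau2, "i2": meta.i2}
            )
            excluded = {
                s: "no supplement contrast at a timepoint"
                for s in sites if not eligible[s]
            } if term == "supplement_status" else {}
            forest = ma.forest_table(meta, excluded=excluded)
            forest.insert(0, "term", term)
            forest.insert(0, "outcome", measure)
            forest_rows.append(forest)
    if len(taxon_adj):
        for (taxon, term), sub in taxon_adj.groupby(["taxon", "term"]):
            sub = sub[sub["converged"]]
            sub = sub[[eligible[s] for s in sub["site"]]]
            if len(sub) < 2:
                continue
            meta = ma.dersimonian_laird(
                sub["estimate"], sub["se"], term=term, labels=sub["site"]
            )
            meta_rows.append(
                {"outcome": taxon, "term": term, "analysis_type": "taxon",
                 "k": meta.k, "estimate": meta.estimate, "se": meta.se,
                 "p_value": meta.p_value, "tau2": meta.tau2, "i2": meta.i2}
            )
    meta_table = pd.DataFrame(meta_rows)
    if len(meta_table):
        meta_table = ma.grouped_adjust(
            meta_table, ("analysis_type",), q=config.fdr_q
        )
    meta_table.to_csv(out / "meta.tsv", sep="\t", index=False)
    forest_table = (
        pd.concat(forest_rows, ignore_index=True) if forest_rows else pd.DataFrame()
    )
    forest_table.to_csv(out / "forest.tsv", sep="\t", index=False)

    beta_meta_rows = []
    if len(beta_adj):
        for term, sub in beta_adj.groupby("term"):
            use = sub if term == "time" else sub[[eligible[s] for s in sub["site"]]]
            if len(use) == 0:
                continue
            combined = ma.fishers_method(use["p_value"])
            beta_meta_rows.append(
                {"term": term, "x2": combined.statistic, "df": combined.df,
                 "p_value": combined.p_value, "k": len(use)}
            )
    beta_meta = pd.DataFrame(beta_meta_rows)
    beta_meta.to_csv(out / "beta_meta.tsv", sep="\t", index=False)

    # -------------------------------------------------------------- report
    adjusted = adjusted_means(alpha, frame, covariates_by_site={
        s: tuple(c for c in final.get(s, ()) if c in frame.columns) for s in sites
    })
    adjusted.to_csv(out / "adjusted_means.tsv", sep="\t", index=False)
    manifest["stages"] = {
        "filter": {"min_reads": config.min_reads, "prevalence": config.prevalence,
                   "max_rel_abund": config.max_rel_abund},
        "permanova": {"n_permutations": config.n_permutations},
        "bootstrap": {"n_bootstrap": config.n_bootstrap,
                      "max_bootstrap_taxa": config.max_bootstrap_taxa},
        "fdr_q": config.fdr_q,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return RunReport(
        filter_reports=[depth_report, taxon_report],
        alpha_fits=alpha_core,
        beta_results=beta_adj,
        taxon_fits=taxon_adj,
        covariate_table=covariate_table,
        meta_table=meta_table,
        forest_table=forest_table,
        beta_meta=beta_meta,
        adjusted_means=adjusted,
        pcoa_coords=pcoa_coords,
        pcoa_explained=list(ordination.proportion_explained),
        manifest=manifest,
    )


def adjusted_means(
    alpha: pd.DataFrame, frame: pd.DataFrame, covariates_by_site: dict | None = None,
) -> pd.DataFrame:
    """Adjusted mean alpha diversity by (site, time, supplement) cell.

    Means come from an OLS fit with cell-means coding plus the site's
    covariates, batch, and standardized depth, evaluated at the average
    covariate value; with no covariates this reduces exactly to the raw
    cell means.  Confidence intervals use cluster-robust (subject)
    standard errors.
    """
    rows = []
    for site, sub in frame.groupby("site"):
        sub = sub.drop(columns=[c for c in alpha.columns if c in sub.columns])
        sub = sub.merge(alpha.reset_index(), on="sample_id", how="inner").reset_index(drop=True)
        covs = tuple((covariates_by_site or {}).get(site, ()))
        sub["cell"] = sub["time"].astype(str) + "_" + sub["supplement_status"].astype(str)
        for measure in sc.ALPHA_MEASURES:
            terms = ["C(cell) - 1"] + [str(c) for c in covs]
            extra = []
            if sub["batch"].nunique() > 1:
                extra.append("C(batch)")
            extra.append("standardized_depth")
            formula = f"Q('{measure}') ~ " + " + ".join(terms + extra)
            res = smf.ols(formula, sub).fit(
                cov_type="cluster", cov_kwds={"groups": sub["subject_id"]}
            )
            for cell in sorted(sub["cell"].unique()):
                name = f"C(cell)[{cell}]"
                if name not in res.params.index:
                    continue
                vec = pd.Series(0.0, index=res.params.index)
                vec[name] = 1.0
                # evaluate covariates and nuisance terms at their means
                for col in res.params.index:
                    if col == name or col.startswith("C(cell)"):
                        continue
                    if col.startswith("C(batch)"):
                        level = col.split("[T.")[-1].rstrip("]")
                        vec[col] = (sub["batch"].astype(str) == level).mean()
                    elif col == "standardized_depth":
                        vec[col] = sub["standardized_depth"].mean()
                    elif col in sub.columns:
                        vec[col] = pd.to_numeric(sub[col], errors="coerce").mean()
                est = float(vec @ res.params)
                se = float(np.sqrt(vec @ res.cov_params() @ vec))
                t, s = cell.split("_")
                rows.append(
                    {"site": site, "measure": measure, "time": int(t),
                     "supplement_status": int(s), "adjusted_mean": est, "se": se,
                     "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
                     "n": int((sub["cell"] == cell).sum())}
                )
    return pd.DataFrame(rows)
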