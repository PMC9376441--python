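"""Site-specific covariate screening and correlation pruning.

Candidate covariates are screened per site and timepoint with a
PERMANOVA of beta-diversity on the covariate, adjusted for batch,
regional cluster, and supplement status.  A covariate survives for a
site when any of its timepoint p-values falls strictly below 0.1.
Survivors are then pruned for collinearity: within a site, covariate
pairs with |Pearson r| > 0.7 keep only one member — the one associated
in more sites, ties broken by a configured generality ranking (the
composite indicator outranks its components).  Batch and read depth are
always carried into the final models regardless of screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gravidbiome.diversity import DistanceMatrix
from gravidbiome.longitudinal_models import permanova

ALWAYS_INCLUDED = ("batch", "read_depth")

#: Default generality ranking: earlier = more general, kept on ties.
DEFAULT_GENERALITY = (
    "overall_ses",
    "improved_water_source",
    "delivery_date",
    "maternal_schooling",
    "supplement_compliance",
    "cooking_fuel",
)


@dataclass
class SelectionTrace:
    """Ordered audit log of screening and pruning decisions."""

    entries: list = field(default_factory=list)

    def log(self, **kwargs) -> None:
        self.entries.append(dict(kwargs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def _numeric_codes(values: pd.Series) -> np.ndarray:
    """Integer-code categorical covariates by level order for Pearson r."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(float)
    levels = sorted(values.dropna().astype(str).unique())
    mapping = {lev: i for i, lev in enumerate(levels)}
    return values.astype(str).map(mapping).to_numpy(float)


def screen_covariate(
    dm: DistanceMatrix,
    frame: pd.DataFrame,
    covariate: str,
    n_perm: int = 200,
    seed: int | None = None,
    trace: SelectionTrace | None = None,
) -> pd.DataFrame:
    """PERMANOVA screen of one covariate per (site, timepoint).

    Each stratum is cross-sectional, so free permutations are used; the
    adjustment set is {batch, regional cluster, supplement status}.
    Strata where the covariate (or an adjustment variable) is constant
    are logged as undefined and reported with a missing p-value.
    """
    if covariate not in frame.columns:
        raise ValueError(f"covariate {covariate!r} missing from metadata")
    rows = []
    rng = np.random.default_rng(seed)
    for (site, time), sub in frame.groupby(["site", "time"], sort=True):
        sub = sub.reset_index(drop=True)
        entry = {"covariate": covariate, "site": site, "time": int(time)}
        if sub[covariate].dropna().nunique() < 2:
            entry["p_value"] = np.nan
            entry["note"] = "constant covariate; p undefined"
            if trace is not None:
                trace.log(**entry)
            rows.append(entry)
            continue
        sub = sub[sub[covariate].notna()].reset_index(drop=True)
        adjust = []
        if sub["batch"].nunique() > 1:
            adjust.append("C(batch)")
        if "regional_cluster" in sub.columns and sub["regional_cluster"].nunique() > 1:
            adjust.append("C(regional_cluster)")
        if sub["supplement_status"].nunique() > 1:
            adjust.append("supplement_status")
        sub["_cov"] = _numeric_codes(sub[covariate])
        # cross-sectional stratum: only the adjustment set plus the
        # tested covariate enter the design, not the full trial terms
        spec = _BareSpec(adjust + ["_cov"])
        try:
            res = permanova(
                dm.subset(list(sub["sample_id"])), sub, spec, "_cov",
                n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), scheme="free",
            )
            entry["p_value"] = res.p_value
            entry["note"] = ""
        except ValueError as exc:
            entry["p_value"] = np.nan
            entry["note"] = f"undefined: {exc}"
        if trace is not None:
            trace.log(**entry)
        rows.append(entry)
    return pd.DataFrame(rows)


class _BareSpec:
    """Minimal stand-in exposing only rhs_terms(), for screening models."""

    def __init__(self, terms: list[str]):
        self._terms = list(terms)
        self.cluster = "subject_id"

    def rhs_terms(self) -> list[str]:
        return list(self._terms)


def select_candidates(screens: pd.DataFrame, alpha: float = 0.1) -> dict[str, list[str]]:
    """Per-site candidate lists: keep a covariate for a site iff the
    minimum p over that site's timepoints is strictly below ``alpha``."""
    out: dict[str, list[str]] = {}
    for site, sub in screens.groupby("site"):
        kept = []
        for cov, rows in sub.groupby("covariate"):
            pmin = rows["p_value"].min()
            if pd.notna(pmin) and pmin < alpha:
                kept.append(cov)
        out[site] = sorted(kept)
    return out


def prune_correlated(
    candidates: dict[str, list[str]],
    frame: pd.DataFrame,
    r_threshold: float = 0.7,
    generality: tuple = DEFAULT_GENERALITY,
    trace: SelectionTrace | None = None,
) -> tuple[dict[str, list[str]], SelectionTrace]:
    """Collinearity pruning of screened candidates, per site.

    Pairwise |Pearson r| is computed within each site on integer-coded
    values.  Pairs with |r| > ``r_threshold`` are processed in
    descending |r| order; the member associated in more sites wins,
    ties go to the covariate appearing earlier in the generality
    ranking.  A tie between covariates absent from the ranking is an
    error demanding configuration.
    """
    if trace is None:
        trace = SelectionTrace()
    n_sites = {
        cov: sum(cov in lst for lst in candidates.values())
        for lst in candidates.values() for cov in lst
    }
    final: dict[str, list[str]] = {}
    for site in sorted(candidates):
        covs = sorted(candidates[site])
        sub = frame[frame["site"] == site]
        dropped: set[str] = set()
        pairs = []
        for i in range(len(covs)):
            for j in range(i + 1, len(covs)):
                a = _numeric_codes(sub[covs[i]])
                b = _numeric_codes(sub[covs[j]])
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                    continue
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
                if abs(r) > r_threshold:
                    pairs.append((abs(r), covs[i], covs[j], r))
        for absr, a, b, r in sorted(pairs, reverse=True):
            if a in dropped or b in dropped:
                continue
            if n_sites.get(a, 0) != n_sites.get(b, 0):
                winner = a if n_sites.get(a, 0) > n_sites.get(b, 0) else b
                rule = "associated in more sites"
            else:
                ranks = {c: generality.index(c) for c in (a, b) if c in generality}
                if len(ranks) == 0:
                    raise ValueError(
                        f"tie between {a!r} and {b!r}: add them to the generality ranking"
                    )
                winner = min(ranks, key=ranks.get) if len(ranks) == 2 else next(iter(ranks))
                rule = "more general (ranking)"
            loser = b if winner == a else a
            dropped.add(loser)
            trace.log(site=site, action="prune", kept=winner, dropped=loser,
                      r=round(r, 6), rule=rule)
        final[site] = [c for c in covs if c not in dropped]
        trace.log(site=site, action="final", kept=",".join(final[site]), dropped="",
                  r=np.nan, rule="")
    return final, trace


def final_covariate_table(final: dict[str, list[str]]) -> pd.DataFrame:
    """Site x covariate indicator table; batch and read depth rows are
    always present since every model includes them."""
    sites = sorted(final)
    rows = list(ALWAYS_INCLUDED)
    extra = sorted({c for lst in final.values() for c in lst})
    rows += [c for c in extra if c not in rows]
    table = pd.DataFrame("", index=rows, columns=sites)
    for site in sites:
        for cov in list(ALWAYS_INCLUDED) + list(final[site]):
            table.loc[cov, site] = "X"
    table.index.name = "covariate"
    return table
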