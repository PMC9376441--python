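"""Synthetic multi-site longitudinal cohorts.

Generates cohorts with the statistical structure the analysis pipeline
assumes: four sites with distinct baseline compositions, three trial
arms with the study's missingness design (the never-supplemented Arm 3
is sampled only at 34 weeks, and not at all at the India-like site),
two visits per subject, batch and read-depth nuisance variation, and
planted effects on diversity and on named genera.

Two simulators are provided:

* :func:`generate_alpha_outcomes` draws alpha-diversity outcomes
  directly from the Gaussian design model, so GEE/meta recovery tests
  are not confounded by the composition layer;
* :func:`generate_cohort` draws genus-level count tables through a
  softmax composition model with a Dirichlet overdispersion layer and
  multinomial sampling at a log-normal read depth.  Planted genus
  effects are pinned exactly on the relative-abundance scale, and a
  temperature calibration of the untargeted genera makes the expected
  Shannon-H contrasts match the configured diversity effects.

Default planted parameters are the effect sizes the pipeline is
expected to recover (a Shannon-H time contrast of -0.22 pooled across
the three meta-eligible sites, a supplement contrast of -0.08,
site-specific genus log-fold changes, Table-style phylum profiles and
biomarker levels).  Subject- and batch-level variance components are
simulator assumptions, recorded in the truth record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from gravidbiome.feature_tables import CountTable, standardized_depth, supplement_status

ALPHA_MEASURES = ("sobs", "chao1", "shannon_h", "evenness")


def _default_sites() -> dict:
    return {"DRC": 250, "Guatemala": 250, "India": 250, "Pakistan": 250}


def _default_arm_proportions() -> dict:
    return {
        "DRC": (1 / 3, 1 / 3, 1 / 3),
        "Guatemala": (1 / 3, 1 / 3, 1 / 3),
        "India": (0.5, 0.5, 0.0),  # no Arm 3 at the India-like site
        "Pakistan": (1 / 3, 1 / 3, 1 / 3),
    }


#: Average phylum relative abundances at the first trimester, per site.
def _default_phylum_profiles() -> dict:
    return {
        "DRC": {"Firmicutes": 0.56, "Bacteroidetes": 0.27, "Actinobacteria": 0.02,
                "Proteobacteria": 0.09, "Other": 0.06},
        "Guatemala": {"Firmicutes": 0.56, "Bacteroidetes": 0.32, "Actinobacteria": 0.01,
                      "Proteobacteria": 0.06, "Other": 0.05},
        "India": {"Firmicutes": 0.53, "Bacteroidetes": 0.28, "Actinobacteria": 0.06,
                  "Proteobacteria": 0.09, "Other": 0.04},
        "Pakistan": {"Firmicutes": 0.54, "Bacteroidetes": 0.29, "Actinobacteria": 0.07,
                     "Proteobacteria": 0.07, "Other": 0.03},
    }


#: Genus panel: name -> (phylum, within-phylum baseline weight, lineage).
def _default_genus_panel() -> dict:
    fam = {
        "Firmicutes": "Bacteria;Firmicutes;Clostridia;Clostridiales",
        "Bacteroidetes": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales",
        "Actinobacteria": "Bacteria;Actinobacteria;Actinobacteria;Bifidobacteriales",
        "Proteobacteria": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacteriales",
        "Other": "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales",
    }
    panel = {
        "Prevotella": ("Bacteroidetes", 18.0, f"{fam['Bacteroidetes']};Prevotellaceae;Prevotella"),
        "unclassified Ruminococcaceae": ("Firmicutes", 8.0, f"{fam['Firmicutes']};Ruminococcaceae"),
        "unclassified Lachnospiraceae": ("Firmicutes", 7.0, f"{fam['Firmicutes']};Lachnospiraceae"),
        "Blautia": ("Firmicutes", 5.0, f"{fam['Firmicutes']};Lachnospiraceae;Blautia"),
        "Christensenellaceae": ("Firmicutes", 0.45, f"{fam['Firmicutes']};Christensenellaceae;Christensenellaceae"),
        "Faecalibacterium": ("Firmicutes", 6.0, f"{fam['Firmicutes']};Ruminococcaceae;Faecalibacterium"),
        "Ruminococcus": ("Firmicutes", 4.0, f"{fam['Firmicutes']};Ruminococcaceae;Ruminococcus"),
        "Clostridium": ("Firmicutes", 3.0, f"{fam['Firmicutes']};Clostridiaceae;Clostridium"),
        "Roseburia": ("Firmicutes", 2.5, f"{fam['Firmicutes']};Lachnospiraceae;Roseburia"),
        "Dorea": ("Firmicutes", 1.5, f"{fam['Firmicutes']};Lachnospiraceae;Dorea"),
        "Coprococcus": ("Firmicutes", 1.5, f"{fam['Firmicutes']};Lachnospiraceae;Coprococcus"),
        "Oscillospira": ("Firmicutes", 1.2, f"{fam['Firmicutes']};Ruminococcaceae;Oscillospira"),
        "Eubacterium": ("Firmicutes", 1.2, f"{fam['Firmicutes']};Eubacteriaceae;Eubacterium"),
        "Lactobacillus": ("Firmicutes", 0.8, "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus"),
        "Streptococcus": ("Firmicutes", 0.8, "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus"),
        "Dialister": ("Firmicutes", 0.6, "Bacteria;Firmicutes;Negativicutes;Selenomonadales;Veillonellaceae;Dialister"),
        "Catenibacterium": ("Firmicutes", 0.5, "Bacteria;Firmicutes;Erysipelotrichia;Erysipelotrichales;Erysipelotrichaceae;Catenibacterium"),
        "Bacteroides": ("Bacteroidetes", 6.0, f"{fam['Bacteroidetes']};Bacteroidaceae;Bacteroides"),
        "Alloprevotella": ("Bacteroidetes", 2.0, f"{fam['Bacteroidetes']};Prevotellaceae;Alloprevotella"),
        "Parabacteroides": ("Bacteroidetes", 1.2, f"{fam['Bacteroidetes']};Tannerellaceae;Parabacteroides"),
        "unclassified Bacteroidales": ("Bacteroidetes", 1.0, fam["Bacteroidetes"]),
        "Bifidobacterium": ("Actinobacteria", 3.0, f"{fam['Actinobacteria']};Bifidobacteriaceae;Bifidobacterium"),
        "Collinsella": ("Actinobacteria", 1.5, "Bacteria;Actinobacteria;Coriobacteriia;Coriobacteriales;Coriobacteriaceae;Collinsella"),
        "Escherichia": ("Proteobacteria", 3.0, f"{fam['Proteobacteria']};Enterobacteriaceae;Escherichia"),
        "Klebsiella": ("Proteobacteria", 1.5, f"{fam['Proteobacteria']};Enterobacteriaceae;Klebsiella"),
        "Succinivibrio": ("Proteobacteria", 1.5, "Bacteria;Proteobacteria;Gammaproteobacteria;Aeromonadales;Succinivibrionaceae;Succinivibrio"),
        "Sutterella": ("Proteobacteria", 0.8, "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Sutterellaceae;Sutterella"),
        "Akkermansia": ("Other", 2.0, f"{fam['Other']};Akkermansiaceae;Akkermansia"),
        "Methanobrevibacter": ("Other", 0.8, "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobrevibacter"),
        "Treponema": ("Other", 1.2, "Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;Treponema"),
    }
    return panel


#: Planted genus log-fold 12->34-week effects, per site.
def _default_taxon_effects() -> dict:
    return {
        "Prevotella": {"Guatemala": 0.326},
        "unclassified Ruminococcaceae": {"DRC": -0.442, "Guatemala": -0.389},
        "unclassified Lachnospiraceae": {"Guatemala": -0.236},
        "Blautia": {"Guatemala": -0.2},
        "Christensenellaceae": {"DRC": -0.7, "Guatemala": -0.7, "India": -0.7,
                                "Pakistan": -0.7},
    }


#: Per-site Shannon-H time effects whose DRC/Guatemala/Pakistan mean is the
#: pooled -0.22; the Guatemala stratum carries the reported -0.25.
def _default_alpha_time_effects() -> dict:
    return {
        "shannon_h": {"DRC": -0.20, "Guatemala": -0.25, "India": -0.20,
                      "Pakistan": -0.21},
        "chao1": {"DRC": -1.0, "Guatemala": -2.13, "India": -1.0, "Pakistan": -1.0},
        "sobs": {"DRC": -1.0, "Guatemala": -2.0, "India": -1.0, "Pakistan": -1.0},
        "evenness": {"DRC": -0.01, "Guatemala": -0.04, "India": -0.01,
                     "Pakistan": -0.01},
    }


def _default_alpha_supplement_effects() -> dict:
    return {
        "shannon_h": -0.08,
        "chao1": -0.5,
        "sobs": -0.5,
        "evenness": -0.005,
    }


def _default_alpha_baselines() -> dict:
    return {
        "sobs": {"DRC": 95.0, "Guatemala": 105.0, "India": 90.0, "Pakistan": 100.0},
        "chao1": {"DRC": 115.0, "Guatemala": 128.0, "India": 110.0, "Pakistan": 122.0},
        "shannon_h": {"DRC": 4.3, "Guatemala": 4.6, "India": 4.2, "Pakistan": 4.4},
        "evenness": {"DRC": 0.62, "Guatemala": 0.66, "India": 0.61, "Pakistan": 0.63},
    }


def _default_alpha_noise() -> dict:
    # (subject-intercept sd, residual sd) per measure; the residual sds
    # are sized so a 250-subject site estimates its time contrast with a
    # standard error ~3x below the recovery tolerances the suite asserts
    return {
        "sobs": (10.0, 6.0),
        "chao1": (12.0, 7.0),
        "shannon_h": (0.40, 0.25),
        "evenness": (0.04, 0.025),
    }


#: Biomarker (mean, sd) per site and week, on the original scale.
def _default_biomarkers() -> dict:
    return {
        "agp": {
            "Pakistan": {12: (871, 305), 34: (565, 198)},
            "India": {12: (990, 371), 34: (597, 243)},
            "Guatemala": {12: (915, 362), 34: (643, 220)},
        },
        "crp": {
            "Pakistan": {12: (7.2, 24), 34: (5.0, 6)},
            "India": {12: (6.2, 13), 34: (5.6, 8)},
            "Guatemala": {12: (9.8, 11), 34: (11.1, 16)},
        },
        "mpo": {
            "Pakistan": {12: (1020, 2607), 34: (1306, 5073)},
            "India": {12: (1112, 1608), 34: (754, 1789)},
            "Guatemala": {12: (2615, 4481), 34: (2091, 3838)},
        },
        "calprotectin": {
            "Pakistan": {12: (27, 57), 34: (34, 59)},
            "India": {12: (45, 57), 34: (40, 78)},
            "Guatemala": {12: (81, 116), 34: (60, 67)},
        },
    }


def _default_covariates() -> list[str]:
    return [
        "overall_ses", "ses_factor_1", "ses_factor_2", "improved_water_source",
        "delivery_date", "maternal_schooling", "supplement_compliance",
        "cooking_fuel", "maternal_age", "maternal_bmi",
    ] + [f"household_factor_{i}" for i in range(1, 11)]


@dataclass
class ScenarioConfig:
    """Every parameter of the synthetic cohort."""

    sites: dict = field(default_factory=_default_sites)
    arm_proportions: dict = field(default_factory=_default_arm_proportions)
    phylum_profiles: dict = field(default_factory=_default_phylum_profiles)
    genus_panel: dict = field(default_factory=_default_genus_panel)
    taxon_time_effects: dict = field(default_factory=_default_taxon_effects)
    alpha_time_effects: dict = field(default_factory=_default_alpha_time_effects)
    alpha_supplement_effects: dict = field(default_factory=_default_alpha_supplement_effects)
    alpha_baselines: dict = field(default_factory=_default_alpha_baselines)
    alpha_noise: dict = field(default_factory=_default_alpha_noise)
    alpha_batch_sd_frac: float = 0.15   # batch sd as a fraction of residual sd
    alpha_depth_effect: dict = field(
        default_factory=lambda: {"sobs": 2.0, "chao1": 2.5, "shannon_h": 0.02,
                                 "evenness": 0.0}
    )
    shannon_time_effect: float = -0.22      # pooled target across eligible sites
    shannon_supplement_effect: float = -0.08
    n_batches: int = 4
    depth_median: float = 10_000.0          # desk scale; study scale is 96,064
    depth_sdlog: float = 0.6
    subject_taxon_sd: float = 0.30          # per-subject per-genus log effect
    batch_taxon_sd: float = 0.10
    dirichlet_concentration: float = 300.0
    covariate_names: list = field(default_factory=_default_covariates)
    composition_confounders: dict = field(
        default_factory=lambda: {"DRC": {"overall_ses": 0.25}}
    )
    biomarkers: dict = field(default_factory=_default_biomarkers)
    biomarker_subject_sdlog: float = 0.15
    study_scale: bool = False

    def __post_init__(self) -> None:
        for site, props in self.arm_proportions.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"arm proportions for {site} must sum to 1")
        if self.study_scale:
            self.depth_median = 96_064.0

    def meta_sites(self) -> list[str]:
        """Sites eligible for the supplement/time meta (India-like sites,
        with every 34-week woman supplemented, are excluded)."""
        return [s for s in self.sites if self.arm_proportions[s][2] > 0]


def default_scenario(study_scale: bool = False) -> ScenarioConfig:
    """The shipped scenario with all planted defaults."""
    return ScenarioConfig(study_scale=study_scale)


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """n independent child seeds (< 2**31) derived from one base seed."""
    return [int(s % (2**31)) for s in np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)]


def null_scenario(n_subjects: int = 40, sites: tuple = ("DRC",)) -> ScenarioConfig:
    """Scenario with every planted effect set to zero.

    Used for type-I-error calibration: outcomes and compositions differ
    between design cells only through noise, so any test of time or
    supplement terms should reject at its nominal rate.
    """
    config = ScenarioConfig()
    config.sites = {s: n_subjects for s in sites}
    config.arm_proportions = {s: config.arm_proportions[s] for s in sites}
    config.phylum_profiles = {s: config.phylum_profiles[s] for s in sites}
    config.taxon_time_effects = {}
    config.composition_confounders = {}
    for measure in ALPHA_MEASURES:
        config.alpha_time_effects[measure] = {s: 0.0 for s in sites}
        config.alpha_supplement_effects[measure] = 0.0
        config.alpha_depth_effect[measure] = 0.0
    return config


# ---------------------------------------------------------------------------
# Design and nuisance generation shared by both simulators
# ---------------------------------------------------------------------------

def _arm_counts(n: int, props) -> list[int]:
    counts = [int(round(p * n)) for p in props]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    return counts


def _design_frame(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for site in config.sites:
        n = config.sites[site]
        counts = _arm_counts(n, config.arm_proportions[site])
        arms = np.repeat([1, 2, 3], counts)
        rng.shuffle(arms)
        for i, arm in enumerate(arms):
            subject = f"{site[:3].upper()}{i:04d}"
            weeks = (34,) if arm == 3 else (12, 34)
            for week in weeks:
                rows.append(
                    {
                        "sample_id": f"{subject}_w{week}",
                        "subject_id": subject,
                        "site": site,
                        "arm": int(arm),
                        "week": int(week),
                    }
                )
    frame = pd.DataFrame(rows)
    frame["time"] = (frame["week"] == 34).astype(int)
    frame["supplement_status"] = [
        supplement_status(a, w) for a, w in zip(frame["arm"], frame["week"])
    ]
    frame["batch"] = rng.choice(
        [f"B{i + 1}" for i in range(config.n_batches)], size=len(frame)
    )
    depth = rng.lognormal(np.log(config.depth_median), config.depth_sdlog, len(frame))
    frame["read_depth"] = np.maximum(3700, depth).astype(int)
    frame["standardized_depth"] = standardized_depth(frame["read_depth"].to_numpy())
    return frame


def _subject_covariates(
    frame: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    subjects = frame[["subject_id", "site", "arm"]].drop_duplicates("subject_id")
    n = len(subjects)
    cov = pd.DataFrame({"subject_id": subjects["subject_id"].to_numpy()})
    ses = rng.integers(0, 7, n).astype(float)
    cov["overall_ses"] = ses
    # components correlated with the composite well above the 0.7 fence
    cov["ses_factor_1"] = ses + rng.normal(0, 0.8, n)
    cov["ses_factor_2"] = ses + rng.normal(0, 0.9, n)
    cov["improved_water_source"] = rng.binomial(1, 0.6, n).astype(float)
    cov["delivery_date"] = rng.uniform(0, 365, n)
    cov["maternal_schooling"] = rng.integers(0, 3, n).astype(float)
    cov["supplement_compliance"] = np.clip(rng.beta(5, 2, n), 0, 1)
    cov["cooking_fuel"] = rng.choice(["wood", "gas", "charcoal"], n)
    cov["maternal_age"] = rng.normal(23, 4, n).round(0)
    cov["maternal_bmi"] = rng.normal(21, 3, n).round(1)
    for name in config.covariate_names:
        if name not in cov.columns:
            cov[name] = rng.normal(0, 1, n)
    return frame.merge(cov, on="subject_id", how="left")


def _biomarker_columns(
    frame: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    out = frame.copy()
    subjects = out["subject_id"].unique()
    for marker, per_site in config.biomarkers.items():
        subj_mult = dict(
            zip(subjects, rng.lognormal(0, config.biomarker_subject_sdlog, len(subjects)))
        )
        vals = np.full(len(out), np.nan)
        for i, row in enumerate(out.itertuples(index=False)):
            site_cfg = per_site.get(row.site)
            if site_cfg is None:
                continue  # e.g. the DRC-like site has no biomarker sampling
            mean, sd = site_cfg[int(row.week)]
            sdlog2 = np.log(1 + (sd / mean) ** 2)
            mu = np.log(mean) - sdlog2 / 2
            vals[i] = np.exp(rng.normal(mu, np.sqrt(sdlog2))) * subj_mult[row.subject_id]
        out[marker] = vals
    return out


# ---------------------------------------------------------------------------
# Direct-outcome simulator (alpha-diversity recovery path)
# ---------------------------------------------------------------------------

def generate_alpha_outcomes(
    config: ScenarioConfig, seed: int
) -> pd.DataFrame:
    """Sample frame with alpha-diversity outcomes drawn from the design model.

    Outcomes follow ``y = b0_site + bt*time + bs*supplement + batch +
    depth*z + subject + noise`` per measure, honoring the arm and
    missingness design.  This path bypasses the composition layer so
    model-recovery checks see exactly the planted Gaussian structure.
    """
    rng = np.random.default_rng(seed)
    frame = _design_frame(config, rng)
    frame = _subject_covariates(frame, config, rng)
    frame = _biomarker_columns(frame, config, rng)
    subjects = frame["subject_id"].unique()
    batches = sorted(frame["batch"].unique())
    for measure in ALPHA_MEASURES:
        subj_sd, resid_sd = config.alpha_noise[measure]
        subj_eff = dict(zip(subjects, rng.normal(0, subj_sd, len(subjects))))
        batch_eff = dict(
            zip(batches, rng.normal(0, config.alpha_batch_sd_frac * resid_sd, len(batches)))
        )
        base = frame["site"].map(config.alpha_baselines[measure]).to_numpy(float)
        bt = frame["site"].map(config.alpha_time_effects[measure]).to_numpy(float)
        bs = config.alpha_supplement_effects[measure]
        y = (
            base
            + bt * frame["time"].to_numpy()
            + bs * frame["supplement_status"].to_numpy()
            + frame["batch"].map(batch_eff).to_numpy(float)
            + config.alpha_depth_effect[measure] * frame["standardized_depth"].to_numpy()
            + frame["subject_id"].map(subj_eff).to_numpy(float)
            + rng.normal(0, resid_sd, len(frame))
        )
        frame[measure] = y
    return frame


# ---------------------------------------------------------------------------
# Evenness calibration and the count-level simulator
# ---------------------------------------------------------------------------

def _shannon_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def calibrate_evenness(target_h: float, n_taxa: int, base_profile) -> float:
    """Temperature tau such that Shannon H of softmax(log_profile / tau)
    equals ``target_h`` bits, to 1e-6.

    H is monotone increasing in tau (tau -> inf flattens the profile to
    uniform, tau -> 0 concentrates on the arg-max taxon).  Targets
    outside [0, log2(n_taxa)] are rejected.
    """
    hmax = np.log2(n_taxa)
    if not (0.0 <= target_h <= hmax):
        raise ValueError(f"target H must lie in [0, {hmax:.6f}] bits")
    logits = np.log(np.asarray(base_profile, dtype=float))
    if np.allclose(logits, logits[0]):
        if abs(target_h - hmax) < 1e-9:
            return 1.0
        raise ValueError("uniform profile only achieves H = log2(n_taxa)")

    def h_of(log_tau: float) -> float:
        return _shannon_bits(_softmax(logits / np.exp(log_tau)))

    lo, hi = -20.0, 20.0
    h_lo, h_hi = h_of(lo), h_of(hi)
    if not (h_lo - 1e-9 <= target_h <= h_hi + 1e-9):
        raise ValueError(
            f"target H {target_h:.4f} outside achievable range "
            f"[{h_lo:.4f}, {h_hi:.4f}] for this profile"
        )
    target = min(max(target_h, h_lo), h_hi)
    log_tau = brentq(lambda lt: h_of(lt) - target, lo, hi, xtol=1e-12)
    return float(np.exp(log_tau))


def _calibrate_cell(
    pinned: np.ndarray, pinned_mask: np.ndarray, base_logits: np.ndarray,
    target_h: float,
) -> np.ndarray:
    """Cell composition with pinned genus abundances and the untargeted
    remainder temperature-scaled to hit ``target_h`` bits.

    ``pinned`` holds exact relative abundances for the targeted genera;
    the untargeted genera share mass 1 - sum(pinned) in proportions
    softmax(base_logits / tau), tau solved by monotone root search.
    """
    a = pinned[pinned_mask]
    rest = 1.0 - a.sum()
    if rest <= 0:
        raise ValueError("pinned abundances exceed total mass")
    logits = base_logits[~pinned_mask]
    h_pinned = float(-(a * np.log2(a)).sum())

    def h_total(log_tau: float) -> float:
        q = _softmax(logits / np.exp(log_tau))
        return h_pinned + rest * (_shannon_bits(q) - np.log2(rest))

    lo, hi = -20.0, 20.0
    h_lo, h_hi = h_total(lo), h_total(hi)
    if not (min(h_lo, h_hi) - 1e-9 <= target_h <= max(h_lo, h_hi) + 1e-9):
        raise ValueError(
            f"target H {target_h:.4f} outside achievable range "
            f"[{min(h_lo, h_hi):.4f}, {max(h_lo, h_hi):.4f}] for this cell"
        )
    target = min(max(target_h, min(h_lo, h_hi)), max(h_lo, h_hi))
    log_tau = brentq(lambda lt: h_total(lt) - target, lo, hi, xtol=1e-12)
    q = _softmax(logits / np.exp(log_tau))
    out = np.empty_like(base_logits)
    out[pinned_mask] = a
    out[~pinned_mask] = rest * q
    return out


@dataclass
class CohortBundle:
    """A generated cohort with its ground truth."""

    table: CountTable
    frame: pd.DataFrame
    truth: dict
    seed: int


def _site_baseline(config: ScenarioConfig, site: str) -> np.ndarray:
    genera = list(config.genus_panel)
    profile = np.empty(len(genera))
    phylum_of = {g: config.genus_panel[g][0] for g in genera}
    weight_of = {g: config.genus_panel[g][1] for g in genera}
    for phylum, share in config.phylum_profiles[site].items():
        members = [g for g in genera if phylum_of[g] == phylum]
        total_w = sum(weight_of[g] for g in members)
        for g in members:
            profile[genera.index(g)] = share * weight_of[g] / total_w
    return profile / profile.sum()


def expected_compositions(config: ScenarioConfig) -> dict:
    """Expected genus composition per (site, time, supplement) cell.

    Targeted genera change exactly by their planted log-fold effect on
    the relative-abundance scale; untargeted genera are recalibrated so
    the cell's Shannon H matches the planted diversity contrasts."""
    genera = list(config.genus_panel)
    cells: dict = {}
    for site in config.sites:
        base = _site_baseline(config, site)
        base_logits = np.log(base)
        effects = {
            g: config.taxon_time_effects.get(g, {}).get(site, 0.0) for g in genera
        }
        pinned_mask = np.array([effects[g] != 0.0 for g in genera])
        h_base = _shannon_bits(base)
        bt = config.alpha_time_effects["shannon_h"][site]
        bs = config.alpha_supplement_effects["shannon_h"]
        for t in (0, 1):
            pinned = np.zeros(len(genera))
            pinned[pinned_mask] = base[pinned_mask] * np.exp(
                np.array([effects[g] for g in genera])[pinned_mask] * t
            )
            for s in (0, 1):
                target_h = h_base + bt * t + bs * s
                cells[(site, t, s)] = _calibrate_cell(
                    pinned, pinned_mask, base_logits, target_h
                )
    return cells


def generate_cohort(config: ScenarioConfig, seed: int) -> CohortBundle:
    """Genus-level count table plus metadata with planted effects.

    Per sample, genus probabilities are the cell composition perturbed
    by subject- and batch-level log effects (and any configured
    composition confounder), passed through a Dirichlet overdispersion
    layer, and counted by a multinomial draw at the sample's read depth.
    """
    rng = np.random.default_rng(seed)
    frame = _design_frame(config, rng)
    frame = _subject_covariates(frame, config, rng)
    frame = _biomarker_columns(frame, config, rng)
    genera = list(config.genus_panel)
    g = len(genera)
    cells = expected_compositions(config)
    subjects = frame["subject_id"].unique()
    batches = sorted(frame["batch"].unique())
    subj_eff = {s: rng.normal(0, config.subject_taxon_sd, g) for s in subjects}
    batch_eff = {b: rng.normal(0, config.batch_taxon_sd, g) for b in batches}
    conf_dirs = {
        site: {cov: rng.normal(0, 1.0, g) for cov in covs}
        for site, covs in config.composition_confounders.items()
    }
    counts = np.zeros((g, len(frame)), dtype=np.int64)
    for i, row in enumerate(frame.itertuples(index=False)):
        logp = np.log(cells[(row.site, row.time, row.supplement_status)])
        logp = logp + subj_eff[row.subject_id] + batch_eff[row.batch]
        site_conf = config.composition_confounders.get(row.site, {})
        for cov, strength in site_conf.items():
            z = (getattr(row, cov) - 3.0) / 2.0  # centered SES-scale value
            logp = logp + strength * z * conf_dirs[row.site][cov]
        p = _softmax(logp)
        if config.dirichlet_concentration > 0:
            p = rng.dirichlet(config.dirichlet_concentration * p)
            p = np.maximum(p, 1e-12)
            p = p / p.sum()
        counts[:, i] = rng.multinomial(int(row.read_depth), p)
    data = pd.DataFrame(counts, index=genera, columns=frame["sample_id"])
    # generated depth = drawn multinomial total, equal to read_depth by design
    lineages = pd.Series({gname: config.genus_panel[gname][2] for gname in genera})
    table = CountTable(data, lineages.reindex(genera))
    truth = {
        "seed": seed,
        "taxon_time_effects": config.taxon_time_effects,
        "shannon_time_effects": config.alpha_time_effects["shannon_h"],
        "shannon_supplement_effect": config.alpha_supplement_effects["shannon_h"],
        "subject_taxon_sd": config.subject_taxon_sd,
        "batch_taxon_sd": config.batch_taxon_sd,
        "dirichlet_concentration": config.dirichlet_concentration,
        "composition_confounders": config.composition_confounders,
    }
    return CohortBundle(table=table, frame=frame, truth=truth, seed=seed)


def truth_json(bundle: CohortBundle) -> str:
    return json.dumps(bundle.truth, indent=2, default=str)
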