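# gravidbiome

Site-stratified longitudinal analysis of gut-microbiota 16S profiles
during pregnancy, built for multi-site maternal-nutrition trials in
which women are sampled in the first (12 weeks) and third (34 weeks)
trimester under a staggered lipid-based nutrient-supplement design.

The package implements the full stratify-then-pool workflow:

1. **Feature-table handling** — genus-level count tables with
   Silva-style lineages; library filtering at a minimum read depth of
   3,700; taxon filtering at ≥5% prevalence and >0.001 relative
   abundance in at least one sample; rank aggregation with
   `unclassified <parent>` buckets; the supplement-status design
   encoding (Arm 1 supplemented at both visits, Arm 2 from the second
   visit, Arm 3 never — and absent at 12 weeks by design).
2. **Diversity** — Sobs, bias-corrected Chao1
   (S + F₁(F₁−1)/(2(F₂+1))), Shannon H (base 2) with evenness H/H_max,
   Good's coverage 1 − F₁/N, Bray-Curtis dissimilarities on relative
   abundances, and classical PCoA.
3. **Per-site models** — Gaussian GEE (exchangeable working
   correlation, sandwich SEs) for the four alpha measures;
   repeated-measures PERMANOVA (McArdle–Anderson pseudo-F, sequential
   SS, restricted permutations: within-subject visit swaps for the
   time term, whole-subject blocks otherwise); negative-binomial GLM
   per genus with significance from a subject-level cluster bootstrap
   (B = 1,000, z = mean*/sd*); phylum-level linear mixed models with
   interaction-first ANOVA and Tukey-adjusted contrasts; Welch t and
   Cochran–Armitage cohort comparisons; a Q₁/Q₃ ± 3·IQR residual-outlier
   sensitivity refit.
4. **Covariate screening** — per-site, per-timepoint PERMANOVA screens
   (keep at p < 0.1), Pearson |r| > 0.7 correlation pruning with
   most-sites-wins and a generality ranking for ties.
5. **Meta-analysis** — DerSimonian–Laird random-effects pooling across
   sites (sites with no supplement contrast at a timepoint are excluded
   from the supplement-term meta), Fisher's combination for
   beta-diversity p-values, and Benjamini–Hochberg FDR applied within
   (site, analysis type) groups at q = 0.05.
6. **Synthetic cohorts** — a two-layer simulator (direct Gaussian
   alpha outcomes, and Dirichlet-multinomial genus counts through a
   softmax composition model) that reproduces the trial's design,
   missingness, batch/depth nuisance structure, and planted effects,
   so every stage is testable without access to cohort data.

## Worked example

```python
import gravidbiome as gb
from gravidbiome import longitudinal_models as lm
from gravidbiome import meta_analysis as ma

config = gb.default_scenario()          # 4 sites, 250 subjects each
frame = gb.generate_alpha_outcomes(config, seed=1)
alpha = frame.set_index("sample_id")[["shannon_h"]]

estimates, ses = [], []
for site in ("DRC", "Guatemala", "Pakistan"):
    spec = lm.DesignSpec(outcome="shannon_h", site=site)
    fits = {r.term: r for r in lm.fit_gee_alpha(alpha, frame, spec)}
    estimates.append(fits["time"].estimate)
    ses.append(fits["time"].se)
    print(f"{site:10s} time effect {fits['time'].estimate:+.3f} "
          f"(se {fits['time'].se:.3f})")

pooled = ma.dersimonian_laird(estimates, ses, term="time")
print(f"pooled     time effect {pooled.estimate:+.3f} "
      f"(se {pooled.se:.3f}, p {pooled.p_value:.2e})")
```

Output from this exact script:

```
DRC        time effect -0.266 (se 0.031)
Guatemala  time effect -0.192 (se 0.032)
Pakistan   time effect -0.253 (se 0.030)
pooled     time effect -0.238 (se 0.022, p 2.89e-26)
```

Each per-site coefficient is the adjusted 12→34-week change in Shannon
H for that stratum; the pooled row is the DerSimonian–Laird
random-effects combination. The scenario plants a cross-site mean
decline of −0.22 bits (DRC −0.20, Guatemala −0.25, Pakistan −0.21);
a single seed lands within one to two standard errors of each planted
value, and averaging over ten seeds recovers the pooled contrast to
within ±0.02 (see `scripts/acceptance.py`).

The same pipeline runs end to end from the command line:

```bash
gravidbiome simulate --seed 7 --out-dir sim/
gravidbiome filter --in sim/table.tsv --meta sim/meta.tsv --out-dir filt/
gravidbiome run-all --seed 7 --out-dir run/
```

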