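# tauspread

Connectivity-mediated tau spreading analysis for longitudinal tau-PET
cohorts.

Misfolded tau is thought to propagate along functional connections, from
a subject-specific set of *epicentres* — the regions with the most
abnormal baseline signal — outward through the connectome, and this
spreading appears to disrupt the functional connectivity between the
epicentres and the rest of the brain.  `tauspread` turns that analysis
into a reusable, tested pipeline for neuroimaging researchers working
with regional tau-PET SUVR tables and fMRI connectomes:

1. **Connectome template** — subject Fisher-Z FC matrices are averaged,
   thresholded at 30% density, and converted to a shortest-path distance
   matrix in which strongly connected regions are close
   (edge length = 1/weight, Dijkstra).
2. **Epicentres** — per region, a two-component Gaussian mixture over
   baseline SUVR gives each subject a tau-positivity probability; the 10
   regions with the greatest probability-weighted (*cleaned*) SUVR are
   that subject's epicentres.
3. **Spreading statistic** — regional accumulation rates (SUVR/year,
   from linear mixed models or per-subject slopes) are regressed on the
   distance to the epicentres across the 190 non-epicentre regions.
   With both sides z-scored the standardized coefficient β equals the
   Pearson correlation; β < 0 means faster accumulation in regions
   functionally closer to the epicentres — connectivity-mediated
   spreading.
4. **FC to epicentres and mediation** — the mean FC of non-epicentre
   regions to the epicentre set (globally and per network) is related to
   β with covariate-adjusted linear models, and the mediating role of
   epicentre amyloid is tested with product-of-coefficients mediation
   (ACME = a·b, 1000 bootstrap CIs).
5. **Susceptibility subtyping** — per network, bisquare robust
   regression of FC-to-epicentres on β yields mismatch residuals,
   discretized at ±0.7 SD into {−1, 0, +1} profiles; Ward clustering
   with silhouette/elbow model selection groups subjects into
   *canonical*, *resilient*, *susceptible* and *DMN-susceptible*
   clusters, which are then compared on biomarkers, genotype frequencies
   and longitudinal cognition (ANCOVA + BH/Bonferroni, χ², mixed-effects
   models).

Because the cohorts this analysis targets are access-restricted, the
package includes a first-class synthetic-cohort generator
(`tauspread.synthetic`) that plants every piece of structure the
pipeline estimates — the bimodal regional SUVR, the rate–distance
correlation, the amyloid mediation path, and the four residual-pattern
groups — so the whole chain is testable end to end from one seed.

## Worked example

```python
import numpy as np
import tauspread as ts
from tauspread import tau as td

# a synthetic cohort at the default study conditions
cfg = ts.CohortConfig(n_subjects=211, seed=3)
cohort = ts.generate_cohort(cfg)

# epicentres from mixture-cleaned baseline SUVR
baseline = cohort.baseline_suvr()
mixtures = td.fit_cohort_gmms(baseline)
cleaned = td.cleaned_suvr(baseline, td.posterior_probabilities(baseline, mixtures))
rates = td.estimate_rates(cohort.tau_scans, mode="subject-slope")

betas = []
for sid in cleaned.index:
    epi = td.select_epicentres(cleaned.loc[sid], k=10, subject_id=sid)
    dist = ts.distance_to_epicentres(cohort.distance, epi.region_ids)
    betas.append(ts.spreading_beta(rates.rates.loc[sid], dist).beta)
print(f"mean spreading beta: {np.mean(betas):.3f}")
```

```
mean spreading beta: -0.279
```

The cohort was generated with a planted rate–distance correlation of
−0.3 (subject SD 0.3), and the estimated per-subject β values average
−0.279: the pipeline recovers the planted spreading strength, slightly
attenuated by scan measurement noise.  A negative β of this size says
that, for a typical subject, regions one SD functionally closer to their
epicentres accumulate tau about 0.28 SD faster per year.

The full pipeline — template, tau, spreading, mediation, clustering,
group statistics, with every intermediate written to disk and a run
manifest — runs from one config:

```bash
tauspread run -o results/demo --seed 3        # synthetic defaults
tauspread synth -o data/cohort --seed 3       # just the data
tauspread validate data/cohort                # schema checks
```

or `ts.run_pipeline(ts.PipelineConfig(cohort=cfg, out_dir="results/demo"))`
from Python.

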