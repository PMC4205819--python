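# fetalconn

Developmental analysis of the fetal functional connectome, from regional
BOLD time series to growth trajectories — with a seeded synthetic cohort
generator standing in for fetal resting-state fMRI data, which is rarely
shareable.

## Who this is for

Researchers studying how intrinsic functional connectivity emerges in the
human brain between gestational weeks (GW) 21 and 37, and anyone who needs
a fully testable reference implementation of the analysis chain used in
fetal resting-state studies: motion scrubbing, CompCor-style nuisance
regression, weighted connectome construction, permutation-based network
inference, and nonlinear growth-curve modelling.

## The model

Connectivity between regions *i* and *j* is the Fisher-Z-transformed
Pearson correlation *S*<sub>i,j</sub> = atanh(*r*<sub>i,j</sub>) of their
cleaned BOLD series; the 70-region network has 70·69/2 = 2415 edges. Each
edge (and each sub-network mean) is modelled against gestational age *x*
either linearly or with a four-parameter logistic

  *f*(*x*) = *d* + *c* / (1 + exp(−(*x* − *a*)/*b*))

whose inflection *a* is the age of fastest strengthening; the *expansion
period* is where *f*′(*x*) ≥ 0.9·*f*′(*a*), i.e. *a* ± 2*b*·acosh(1/√0.9).
Edge-wise age effects are tested with an F-test (gestational days, motion
covariate) and family-wise error is controlled with the network-based
statistic (NBS): permute ages, compare connected-component extents above
F > 5 with the permutation distribution of the maximum extent.

The synthetic cohort generator emulates the study conditions: 50-frame
scans at TR = 1 s, a 0.01–0.08 Hz neural component whose inter-regional
correlation follows edge-class-specific growth (sigmoid within lobes with
occipital < temporal < frontal < parietal inflections, linear for
long-range connections), an aliased ~2.4 Hz cardiac component, drift,
motion spikes, and CompCor noise channels.

## Worked example

```python
import numpy as np
from fetalconn import (
    GrowthTruth, make_default_atlas, simulate_cohort, preprocess_subject,
    build_graph, fit_sigmoid, expansion_interval,
)

atlas = make_default_atlas(70, seed=0)
truth = GrowthTruth.default(atlas)          # within-lobe sigmoid growth
cohort = simulate_cohort(atlas, truth, n_subjects=32, seed=7)

ga, strength = [], []
lobes = np.asarray(atlas.lobe)
i, j = np.triu_indices(70, 1)
within = lobes[i] == lobes[j]
for rec in cohort:
    clean = preprocess_subject(rec)         # censor > 2 mm, 6 motion + 5 PCs, band-pass
    z = build_graph(clean).Z
    ga.append(rec.ga_weeks)
    strength.append(z[i, j][within].mean())

fit = fit_sigmoid(ga, strength)
print(f"inflection {fit.a_:.2f} GW, amplitude {fit.c_:.3f} Z")
print("expansion period [%.2f, %.2f] GW" % expansion_interval(fit, 0.9))
```

Output:

```
inflection 26.12 GW, amplitude 0.346 Z
expansion period [25.71, 26.53] GW
```

The generator's amplitude-weighted mean inflection here is 26.33 GW, so
this cohort recovers the inflection to ~0.2 weeks; the amplitude estimate
(0.346 Z against an imposed 0.45) reflects attenuation and the residual
noise of 50-frame correlation estimates.

The same analysis runs end to end from the command line:

```bash
fetalconn run --workdir out --seed 7 --n-perm 1000
fetalconn report --workdir out
```

which writes per-subject TSVs, `edges_stats.tsv`, `nbs_components.json`,
`growth_fits.tsv`, `stage_table.json`, `coherence.tsv` and a `report.json`
carrying the configuration hash and every seed.

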