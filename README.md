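# statedyn

Temporal dynamics of large-scale brain networks from resting-state fMRI
component time courses.

Neurodegenerative disease alters not only which brain networks are engaged
but *how the brain moves between them*. `statedyn` implements a complete,
tested pipeline for quantifying that movement and relating it to clinical
course — the kind of analysis used to study presymptomatic and symptomatic
carriers of frontotemporal-dementia mutations across multi-site cohorts,
where changes in salience-network occupancy herald symptom onset and
predict cognitive decline. It is written for imaging researchers who have
per-scan ICA component time courses (the pipeline's input; preprocessing and
the group ICA itself are out of scope) plus subject metadata and
longitudinal cognitive scores.

## The model

Scan data are treated as emissions of a **K-state hidden Markov model with a
shared covariance**: a latent state sequence `s_t` follows a Markov chain
with initial distribution π and row-stochastic transition matrix A, and the
observed C-vector of component amplitudes is

```
x_t | s_t = k  ~  N(μ_k, Σ)          (one Σ shared by all states)
```

fit by maximum-likelihood EM (Baum–Welch) on temporally concatenated,
per-scan standardized time courses, with forward–backward restarted at every
scan boundary. From each scan's soft posteriors (γ, ξ) the pipeline derives:

* **fractional occupancy** FO_k = (1/T) Σ_t γ_tk — the proportion of time a
  state is active;
* **switching rate** SR = Σ_{i≠j} ξ_ij / ((T−1)·TR) — between-state
  transitions per second, adjusted for the site's repetition time;
* the per-subject **transition/persistence matrix** (rows of ξ normalized).

Downstream statistics follow the study design end to end: occupancy
compositions are reduced by **α-transformation PCA** (α = 1, orthonormal
Helmert contrasts) with MacArthur's **broken-stick** component selection and
**varimax** rotation; group contrasts use linear **mixed models** (site
random intercept, Satterthwaite degrees of freedom) or ANCOVA, with BH-FDR
correction; the interdependent K×K transition probabilities are tested with
a **max-statistic permutation test** (age/sex as nuisance covariates,
family-wise error control over all cells and both directions); and cognitive
decline is predicted by a **two-step model** — per-subject slopes from
`score ~ time + (time | subject)`, then slopes regressed on baseline
component scores with age/sex/site covariates and optional age and group
interactions.

A synthetic-cohort generator produces the whole input bundle (time courses,
metadata, motion-QC indices, longitudinal visits) with *planted* effects —
a persistence-probability increment on a target state for symptomatic
subjects, a fractional dose of it for presymptomatic converters, and an
occupancy-linked decline rate — so every claim the pipeline makes can be
checked against known ground truth.

## Worked example

```python
import numpy as np
import statedyn as sd

# a 4-state ground truth on 8 channels, 30 scans of 300 volumes
truth = sd.sample_ground_truth(K=4, C=8, persistence=0.85, seed=77)
scans, occ = [], []
for i in range(30):
    path, X = sd.simulate_timecourse(truth, 300, seed=7000 + i)
    scans.append(sd.standardize_timecourse(X))
    occ.append([(path == k + 1).mean() for k in range(4)])

stacked, bounds = sd.concatenate_scans(scans)
model = sd.fit_hmm(stacked, bounds, K=4, seed=0)

from statedyn.hmm import match_states
from statedyn.metrics import fractional_occupancy

perm = match_states(truth.state_means, model.state_means)
A_err = np.abs(model.transition_matrix[np.ix_(perm, perm)]
               - truth.transition_matrix).max()
fo = np.array([fractional_occupancy(sd.forward_backward(model, s))[perm]
               for s in scans])
r = np.corrcoef(fo.ravel(), np.array(occ).ravel())[0, 1]
print(f"transition-matrix max abs error: {A_err:.3f}")
print(f"per-scan FO vs true-path occupancy: r = {r:.3f}")
```

which prints

```
transition-matrix max abs error: 0.017
per-scan FO vs true-path occupancy: r = 0.998
```

i.e. the EM fit recovers the generating transition structure to about one
percentage point per cell, and per-scan occupancy estimates track the true
state paths almost perfectly.

The full pipeline is also available as a CLI over plain-text inputs
(per-scan TSVs, cohort CSV, visits CSV):

```bash
statedyn all --config config.json --workdir study/   # simulate -> qc -> fit
                                                     # -> metrics -> pca
                                                     # -> stats -> longitudinal
```

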