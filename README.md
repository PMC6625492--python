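# solvoptim

Descriptor-based multi-objective Bayesian optimisation for reaction solvent
selection.

Choosing a solvent is a discrete decision over hundreds of candidates, yet
most design-of-experiments machinery wants continuous variables.
`solvoptim` closes that gap the way practitioners in asymmetric catalysis
do: every solvent is embedded in a continuous space of 17 molecular
descriptors — tabulated physical properties plus segment areas of its COSMO
screening-charge-density profile ("σ-profile") — and two Gaussian-process
surrogates learn conversion and diastereomeric excess (d.e.) from a handful
of experiments.  New experiments are proposed by Thompson sampling: draw one
random function from each GP posterior, evaluate both at every untested
solvent, and vote for the candidate that most increases the dominated
hypervolume of the observed Pareto front.  The same machinery optimises
solvent *mixtures* and temperature under the simplex constraint Σ₁³xᵢ ≤ 1
with a constrained NSGA-II, and an amplify-and-classify loop stretches ten
measurements into a hundred GP-predicted rows to train a classification
pipeline that screens the whole library.

The core quantities, in the field's notation:

- features: σ-segment areas (σ₁–σ₅ or σ̄₁–σ̄₃, cuts at ±0.005, ±0.010,
  ±0.015 e Å⁻²) and principal components t₁–t₄ of the autoscaled
  17-descriptor block;
- surrogate: GP with Matérn-5/2 ARD kernel, hyperparameters by maximum
  marginal likelihood; per-input length scales ℓ_d read as relevance
  (smaller ⇒ more influential);
- selection: hypervolume improvement HVI(x) = HV(front ∪ {f̃(x)}) − HV(front)
  for posterior samples f̃, aggregated by vote counting over repeats;
- validation: leave-one-out q² = 1 − PRESS/TSS with per-fold re-fitting;
- selectivity scale: ΔΔG‡ = R·T·ln((1+de)/(1−de)).

Everything is exercisable end-to-end without laboratory data: a synthetic
module generates correlated descriptor libraries with a prescribed PCA
spectrum, plausible σ-profiles, and noisy ground-truth reaction landscapes.

## Worked example

```python
import numpy as np, pandas as pd
import solvoptim as sv

lib, _ = sv.gen_library(60, seed=7)            # synthetic 60-solvent library
oracle = sv.make_oracle(lib, seed=8)           # ground-truth reaction stand-in
pca = sv.fit_pca(lib, sv.PCA_DESCRIPTORS, k=4)
print(np.round(np.cumsum(pca.explained_variance_ratio), 3))

rng = np.random.default_rng(9)
init = [str(s) for s in rng.choice(lib.ids, size=8, replace=False)]
rows = [{"solvent_id": s, **dict(zip(("conversion", "de"), oracle.query(s)))}
        for s in init]
state = sv.CampaignState(
    library=lib,
    conv_spec=sv.feature_spec(3, pca),         # conversion on t1–t4
    de_spec=sv.feature_spec(1),                # d.e. on σ1–σ5
    experiments=pd.DataFrame(rows),
    gp_config=sv.GPConfig(n_restarts=5),
)
state.refit(seed=10)
print(sv.suggest_discrete(state, n_repeats=50, seed=11).head(3).to_string(index=False))

sv.run_campaign(state, lambda sid: oracle.query(sid), iterations=6,
                per_iteration=1, n_repeats=50, seed=12)
print(np.round(sv.pareto_front(state.observed_points()).points, 1))
print(sorted(set(oracle.true_pareto_ids()) & set(state.tested_ids)))
```

prints

```
[0.32  0.488 0.618 0.698]
solvent_id  votes    mean_hvi
     S0002     23 7456.596270
     S0024      6 6107.989672
     S0052      6 5977.180542
[[92.6 74.8]
 [88.6 84.6]]
['S0002', 'S0015']
```

Reading the output: the first four principal components carry 70% of the
descriptor variance; after eight initial experiments the Thompson-sampling
vote goes overwhelmingly to solvent `S0002` (23 of 50 repeats, and the
largest mean hypervolume improvement); six closed-loop iterations later the
observed Pareto front holds two solvents at ~93%/75% and ~89%/85%
(conversion/d.e.), and the campaign has in fact found both members of the
landscape's true Pareto set — `S0002` among them, vindicating the vote.

A command-line layer wraps the same functions
(`solvoptim featurize | sigma-segment | fit | suggest | mix-suggest |
amplify-loop | simulate`); every run writes a JSON manifest with its
configuration, seed and input digests.

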