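# clonodyn

Clonal deconvolution for **longitudinally** sequenced tumours. Given somatic
mutation read counts from a sequence of bulk samples collected over months or
years, `clonodyn` clusters mutations by their cancer-cell fraction (CCF),
corrects for sample purity and local copy number, and — unlike cross-sectional
tools — models each cluster's CCF as a **continuous function of time**, so the
abundance of every clone can be reconstructed both at and between the sampled
time points. It is aimed at bioinformaticians studying clonal evolution in
settings where long sample series are feasible: liquid cancers (e.g. CLL) and
liquid biopsies.

## Model

For mutation *i* in sample *j* the expected variant allele fraction is linear
in the CCF φ̃<sub>ij</sub> once purity ρ<sub>j</sub>, local total copy number
D<sub>ij</sub> and mutation multiplicity d<sub>ij</sub> are known:

```
θ_ij = ζ_ij · φ̃_ij,        ζ_ij = d_ij ρ_j / (2(1−ρ_j) + D_ij ρ_j)
```

Alt-read counts are binomial or beta-binomial around θ (sample-specific
precision v<sub>j</sub>, prior 1/(1+v<sub>j</sub>) ~ U(0,1)) to absorb
sequencing over-dispersion. Mutations share CCFs through a Dirichlet-process
mixture in stick-breaking form, truncated at K = 20 components, with
u<sub>k</sub> ~ Beta(1, α) and the heavy-tailed prior p(α) ∝ (1+α)⁻².

Cluster trajectories live on the logit scale, ψ<sub>k</sub>(t) =
logit φ<sub>k</sub>(t), and carry one of five priors:

| family | prior on trajectories | extra parameters |
|--------|----------------------|------------------|
| `Flat` | φ<sub>jk</sub> iid U(0,1); time ordering ignored | — |
| `GP0`  | one shared GP(0, h²·g<sub>τ</sub>) for all clusters | h², τ |
| `GP1`  | separable multi-output GP, Σ = diag(h²<sub>k</sub>) | h²<sub>k</sub>, τ |
| `GP2`  | separable, Σ = D·C·D with C ~ LKJ(η=2) | + K(K−1)/2 correlations |
| `GP3`  | block-diagonal, per-cluster (h²<sub>k</sub>, τ<sub>k</sub>) | 2K |

with four stationary kernels (`Exp`, `Mat32`, `Mat52`, `ExpQ` — the Matérn
family ordered by smoothness), h², τ ~ Gamma(1, 1), giving **17 model
configurations** in total. All models are fit by stochastic-gradient
variational inference (mean-field Gaussian on unconstrained transforms)
maximizing the ELBO, which doubles as the model-comparison score: being a
lower bound on the log evidence, it automatically penalizes the
parameter-heavy variants on data too thin to support them.

## Worked example

```python
import numpy as np
from clonodyn import (SimConfig, simulate_dataset, model_by_name, VIConfig,
                      fit, make_report, compare_models, adjusted_rand_index)

cfg = SimConfig(n_samples=6, n_mutations=60, n_clusters=3, depth_mean=500,
                min_separation=0.2, seed=7)
table, truth = simulate_dataset(cfg)

fits = {name: fit(table, model_by_name(name), VIConfig(seed=7, max_iters=3000))
        for name in ("Flat", "GP0-Mat32")}
for row in compare_models(list(fits.values())):
    print(f"{row['rank']}. {row['model']:10s} ELBO {row['elbo']:9.1f} +/- {row['elbo_se']:.2f}")

report = make_report(fits["GP0-Mat32"], predictive=False)
print("kept clusters:", report.kept_clusters)
print("posterior weights:", np.round(report.weights_posterior, 3))
print("ARI vs truth:", adjusted_rand_index(truth.labels, report.hard_labels))
```

prints

```
1. Flat       ELBO   -1593.5 +/- 0.13
2. GP0-Mat32  ELBO   -1602.5 +/- 0.18
kept clusters: [1, 3, 4]
posterior weights: [0.318 0.293 0.389]
ARI vs truth: 1.0
```

Three of the twenty mixture components survive pruning and carry all the
weight; the hard assignment reproduces the simulated partition exactly
(ARI = 1). The two ELBOs are a model-evidence comparison on this dataset:
here the Flat baseline edges out GP0-Mat32 by a few nats — six time points of
a smooth simulation are easy for both — while only the GP fit also returns
continuous CCF trajectories with 95% credible bands between the sample times
(`report.trajectories`).

## Command line

```bash
clonodyn list-models                   # the 17 configuration names
clonodyn simulate --samples 6 --mutations 60 --clusters 3 --seed 7 --out sim
clonodyn fit --input sim.tsv --model GP0-Mat32 --seed 7 --out results/
clonodyn metrics labels_a.txt labels_b.txt
clonodyn benchmark --samples 3,6 --mutations 25,50 --clusters 2,4 \
    --models Flat,GP0-Mat32 --out bench.csv
```

`fit` expects a long-format TSV/CSV with columns `mutationID, sampleID,
altCounts, totalCounts` (or `refCounts`), `purity, time` and optional
`cnTotal` (default 2) and `cnMultiplicity` (estimated from the pooled VAF by
the closest-integer rule when absent). Every mutation must appear in every
sample. Outputs are an assignment CSV, a dense trajectory CSV and a metadata
JSON embedding the model name, seed and package version.

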