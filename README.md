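# metarecon

Reconstruction of biochemical Jacobians from the covariance of replicate
metabolite profiles, and ranking of the reaction elasticities that differ
between two biological conditions.

## The problem

Targeted metabolomics gives a handful of replicate intensity measurements per
condition for a panel of metabolites. Around a metabolic steady state, the
biological replicate-to-replicate fluctuations behave like an
Ornstein–Uhlenbeck process: their stationary covariance **C** is tied to the
local dynamics — the Jacobian **J** of the reaction network — and the
fluctuation intensity **F** by the stochastic Lyapunov equation

```
J·C + C·Jᵀ = −2·F .
```

`metarecon` inverts this relationship. Given a sample covariance and a
metabolic network, it recovers the Jacobian restricted to the network's
structural sparsity, parameterized through the stoichiometric matrix **N**
and the elasticity matrix **∂r/∂C**:

```
J = N · ∂r/∂C ,
```

so the unknowns are the reaction elasticities allowed by the network (which
metabolites each reaction consumes or is modulated by). The symmetric upper
triangle of the Lyapunov residual supplies n(n+1)/2 independent linear
equations in those elasticities, solved by (ridge-regularized) least squares.
Because the true fluctuation magnitudes are unknown, the inversion is
repeated over a Monte-Carlo ensemble of sampled diagonal fluctuation matrices
(default 1000 draws); the per-entry **median** is the reported Jacobian and
the **interquartile range** its uncertainty.

To compare two conditions (e.g. control vs. a tissue-specific knockout), each
structurally allowed entry is scored as

```
score(i,j) = |median_B(i,j) − median_A(i,j)| / pooled_IQR(i,j)² ,
```

and the top-ranked entries localize the perturbed reaction couplings. The
package also implements the standard discriminant-metabolite companion
workflow: Pareto scaling, PCA, PLS-DA / OPLS-DA with R²X/R²Y and
cross-validated Q², VIP scores (Σ VIP² = number of metabolites), label
permutation validation, fold change, and the `VIP > 1 and p < 0.05` selection
rule with a two-tailed Welch t-test.

A synthetic-data module generates everything with known ground truth — a
built-in D-serine synthesis network (PHGDH → PSAT1 → PSPH → SRR with NAD/NADH
and Glu/KGA cofactor coupling), stable sampled elasticities, analytic
covariances, and Euler–Maruyama OU simulation — so every stage is testable
without external data.

## Worked example

Simulate a control and a knockout-like condition in which the elasticity of
the α-ketoglutarate → NADH coupling (reaction KGDH) is scaled to 0.3×, then
reconstruct both Jacobians and rank the differential entries:

```python
import numpy as np
import metarecon as mr

net = mr.build_serine_network()
truth = mr.make_ground_truth(net, seed=0)
cfg = mr.SimulationConfig(n_samples=1000, seed=0)
ctl, ko, _ = mr.generate_two_condition_dataset(truth, ("KGDH", "KGA", 0.3), cfg)

cov_c, cov_k = mr.sample_covariance(ctl), mr.sample_covariance(ko)
base = 0.1 * (np.diag(cov_c.values) + np.diag(cov_k.values)) / 2  # shared FLU base
ens = {}
for i, (cov, lab) in enumerate([(cov_c, "control"), (cov_k, "knockout")]):
    flu = mr.FluctuationModel(base, spread=0.2, seed=i)
    ens[lab] = mr.ensemble_invert(
        mr.InverseProblem(cov=cov, network=net, fluctuation=flu, n_draws=1000),
        condition_label=lab,
    )
diff = mr.differential_jacobian(ens["control"], ens["knockout"])
print(mr.rank_perturbations(diff, top_k=5)[["rank", "entry", "score", "signed_difference"]])
```

Output:

```
 rank          entry      score  signed_difference
    1  ∂f_NAD/∂f_KGA 158.257987           0.313272
    2 ∂f_NADH/∂f_KGA 158.257987          -0.313272
    3  ∂f_KGA/∂f_KGA 158.257987           0.313272
    4  ∂f_KGA/∂f_NAD  49.336832           0.054038
    5 ∂f_NADH/∂f_NAD  23.047885          -0.051007
```

The three top entries are exactly the Jacobian coordinates fed by the
perturbed KGDH elasticity (KGDH changes NAD, NADH and KGA, and its rate
depends on KGA): the weakened coupling is recovered as a large median shift
relative to the ensembles' interquartile spread, with `∂f_NADH/∂f_KGA` — the
sensitivity of NADH's net rate to α-ketoglutarate — dropping (negative signed
difference) by the injected factor. Entries further down are an order of
magnitude smaller: sampling noise, not structure.

The same analysis from the shell:

```
metarecon simulate --out data/ --n-samples 1000 --perturb KGDH:KGA:0.3 --seed 0
metarecon reconstruct --profiles data/profiles.tsv --network data/network.txt \
    --conditions control,knockout --out run/ --seed 0
metarecon discriminant --profiles data/profiles.tsv --conditions control,knockout \
    --out disc/ --seed 0
```

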