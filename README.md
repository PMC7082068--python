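# ptlasso

Parallel tempering with Lasso regularization for **simultaneous calibration
and reduction** of mass-action reaction-network models.

Signaling-network models accumulate reactions faster than any single data
set can constrain them.  `ptlasso` poses reaction elimination as Bayesian
parameter estimation: every reaction's rate constant gets a Laplace (Lasso)
prior centred at a dynamically inert value (μ = −10 in log10 space, i.e.
10⁻¹⁰), the posterior is sampled with replica-exchange (parallel tempering)
MCMC over the energy

    E(θ) = −log L(θ) − log p(θ),      log L = −Σ (Y_sim − Y_expt)²/2σ²,

and a parameter whose marginal posterior stays confined within the prior
boundaries is called *extraneous* — its reaction is not needed to fit the
data — while one that escapes is *necessary*.  Because the approach is
fully Bayesian it can return **several** minimal reaction sets when the
data support alternatives.  A grouped variant ties all reactions of a
module to one shared penalty parameter (θ′_i = k′_i + λ′_m), so whole
modules (e.g. a feedback loop) can be tested for dispensability under
different stimulation protocols.

The package provides the network/ODE layer (stiff-capable, with an exact
matrix-exponential path for conversion-only networks), the tempered
sampler with burn-in adaptation targeting the 0.234 acceptance optimum,
Gelman-Rubin PSRF / Brooks-Gelman MPSRF convergence diagnostics with the
M-run combining gate, seeded synthetic-data generators (noise on
trajectories or on log parameters), the reduction calls (confinement
classification, support census, elbow-rule selection of the Lasso width),
and a CLI tying it together.  See `docs/methods.md` for the science and
all defaults.

## Worked example

Recover the pulse-generator motif A→B→C from a fully connected 3-node
network, given only noisy observations of species B (truth k_AB = 0.1 s⁻¹,
k_BC = 1 s⁻¹, all other rates zero; 8 time points, 10 replicates, 30%
noise):

```python
from ptlasso.studies import k3_dataset, run_k3
from ptlasso.reduction import marginal_mode

data = k3_dataset(data_seed=1)          # seeded synthetic observations
result = run_k3(seed=101, dataset=data) # 6 tempered chains, 1000 swaps

for name in ("k_AB", "k_BC"):
    print(name, round(10 ** marginal_mode(result.store.marginal(name)), 3))
report = result.classify()
print("extraneous:", sorted(report.extraneous))
print("necessary: ", sorted(report.necessary))
```

prints

```
k_AB 0.1
k_BC 1.007
extraneous: ['k_AC', 'k_BA', 'k_CA', 'k_CB']
necessary:  ['k_AB', 'k_BC']
```

i.e. both generative rate constants are recovered at their true values and
the four reactions that played no part in generating the data are flagged
removable.  The same pipeline from the shell:

```bash
ptlasso gen-data --fixture k3 --seed 1 --out examples/        # writes examples/k3.tsv
ptlasso fit --config examples/k3.yaml --mode ptlasso --seed 1 --out run1/
ptlasso fit --config examples/k3.yaml --mode ptlasso --seed 2 --out run2/
ptlasso diagnose run1/samples.tsv run2/samples.tsv   # PSRF / MPSRF report
ptlasso reduce --store run1/samples.tsv              # classification + supports
```

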