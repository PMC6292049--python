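# nbmbclust

Negative binomial model-based (NBMB) clustering of **samples** from
over-dispersed RNA-seq count matrices.

## The problem

Unsupervised clustering of subjects/samples is a standard step in
transcriptomic studies (latent disease subtypes, molecular subgroups).
Gaussian mixture models (GMM) — with or without log or rank-based
inverse-normal (Blom) transforms — are the usual model-based tool, but
RNA-seq counts are over-dispersed (variance ≫ mean), which Gaussian
models capture poorly, especially in small cohorts (N ≲ 100–200). This
package clusters samples with a mixture of negative binomial (NB)
distributions fitted directly on normalized, untransformed counts.

## The model

The data are an N × G matrix of non-negative normalized counts
`x_ig`. Sample `i` belongs to one of K latent clusters; within cluster
`k`, genes are independent NB:

    x_ig | k  ~  NB(mu_kg, theta_kg),    Var = mu + mu²/theta

    L = Σ_i log( Σ_k p_k Π_g f(x_ig | mu_kg, theta_kg) )

Fitting is EM with three modifications that make it robust at high G:

1. **Deterministic initialization** — priors 1/K, and component k starts
   at the all-sample per-gene MLE scaled by `1 + 0.01·(k−1)` (the small
   shift breaks the symmetry that would pin all posteriors at 1/K).
2. **Fixed dispersions** — `theta_kg` stays at its initialization (exact
   per-gene MLE) for all iterations, giving a closed-form M-step
   (posterior-weighted means; priors = posterior column means).
3. **Density rescaling + deterministic annealing** — per-sample log
   joint densities are offset by their mean over components and genes,
   and the E-step raises the (offset) density to the power `1/τ` with a
   cooling ladder `τ_{s+1} = max(1, 0.9·τ_s)`, `τ₀ = 10` (or 2), to
   avoid poor local optima. Convergence is monitored once τ = 1.

K is chosen by BIC (`−2L + ν·log N`, `ν = (K−1) + K·G`); ties go to the
smaller K. The package also contains the simulation engine used to
benchmark the method (per-gene NB baselines with multiplicative cluster
shifts `mu_k = mu_1·e^{(k−1)Δμ}`, `theta_k = theta_1·e^{(k−1)Δθ}`, a DE
gene fraction, uniform cluster membership) and an evaluation harness
that scores NBMB and GMM comparators by the adjusted Rand index (ARI).

## Worked example

```python
from nbmbclust import (Scenario, sample_baseline, simulate_dataset,
                       select_k, adjusted_rand_index)

scenario = Scenario(n_samples=100, n_genes=200, n_clusters=3,
                    delta_mu=1.0, delta_theta=0.0, de_fraction=1.0, seed=42)
base = sample_baseline(200, seed=43)
X, truth = simulate_dataset(scenario, base)

result = select_k(X, range(2, 7))
print("BIC trace:", {k: round(v, 1) for k, v in result.bic_trace.items()})
print("selected K:", result.selected_k)
print("ARI vs truth:", round(adjusted_rand_index(truth, result.labels), 3))
```

prints

```
BIC trace: {2: 232455.2, 3: 230569.7, 4: 231311.9, 5: 232066.5, 6: 232808.4}
selected K: 3
ARI vs truth: 1.0
```

i.e. on a 100-sample, 200-gene dataset with three clusters one
log-fold-change apart, BIC is minimized at K = 3 and the recovered
partition matches the truth exactly (ARI = 1). Weak-signal regimes
behave very differently — see `scripts/acceptance.py` below.

A console script exposes the same pipeline from the shell:

```sh
nbmb cluster --counts counts.tsv --uq-cpm --top-mad 1000 \
     --k-min 2 --k-max 6 --out-dir out/
nbmb simulate --n-samples 50 --n-genes 1000 --k 3 --replicates 5 --out-dir sim/
nbmb benchmark --n-samples 50 --k 2 --methods NBMB,GMM-log --replicates 10 \
     --out-dir bench/
```

`nbmb cluster` optionally applies upper-quartile CPM normalization and
top-N MAD gene filtering before clustering, and writes labels, the
fitted model (JSON), the BIC trace and a replayable resolved config.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the mean ARI of NBMB with BIC-selected
K ∈ 2..6 over 20 simulated replicates of the hardest small-sample
scenario family (true K = 5 at N = 50, G = 1000, 5% DE genes,
Δμ = 0.5, Δθ = 1) — the regime where no model-based method can resolve
the clusters from so few samples. Runs in well under a minute on one
CPU.

## Layout

| module                    | contents                                                |
|---------------------------|---------------------------------------------------------|
| `nbmbclust.nb_core`       | stable NB log-density, exact per-gene MLE of (mu, theta) |
| `nbmbclust.mixture`       | DA-EM mixture fit, BIC, model selection                 |
| `nbmbclust.preprocessing` | count I/O, UQ-CPM, MAD filter, log/Blom transforms      |
| `nbmbclust.simulate`      | scenario grid and clustered NB data generator           |
| `nbmbclust.evaluation`    | ARI, GMM comparators, simulation-study driver           |
| `nbmbclust.cli`           | `nbmb` console script                                   |

See `docs/methods.md` for the modeling details, numerical choices and
limitations.
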