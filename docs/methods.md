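# Methods

## Model

Samples are rows of an N × G matrix of non-negative normalized RNA-seq
counts. Conditional on membership in cluster k, genes are independent
negative binomial variables with mean `mu_kg` and size/dispersion
`theta_kg` (variance `mu + mu²/theta`; `theta → ∞` is the Poisson
limit). The mixture log-likelihood is

    L = Σ_{i=1..N} log( Σ_{k=1..K} p_k Π_{g=1..G} f(x_ig | mu_kg, theta_kg) )

Independence across genes and samples is assumed; library-size and
batch effects must be removed *before* clustering (the model is applied
to normalized counts without any transformation). Normalized counts are
continuous, so the factorial in the NB pmf is generalized to
`Γ(x + 1)`; the density is evaluated entirely in log space with
log-gamma functions and is finite for every valid input. A gene whose
mean is exactly zero is treated as a point mass at zero.

## Estimation

**Initialization (deterministic).** Priors start at 1/K. Per-gene
all-sample MLEs `(mu_hat, theta_hat)` are computed once: `mu_hat` is the
sample mean; `theta_hat` maximizes the profile log-likelihood over
`log theta` with a bounded scalar optimizer (Brent, tolerance 1e-8 on
`log theta`) on `theta ∈ [1e-3, 1e5]`. When the sample variance does
not exceed the mean the gene is not over-dispersed and `theta_hat` is
pinned at the cap (Poisson-like). Component k starts at
`(mu_hat, theta_hat) · (1 + s·(k−1))` with shift step `s = 0.01`; the
shift breaks the exact symmetry that would otherwise fix every
posterior at 1/K forever. Dispersions are clipped back into bounds if
the shift leaves them (warned only when the baseline value was strictly
inside the bounds).

**Fixed dispersions.** `theta_k` is never re-estimated inside EM.
Fixing the dispersion at a pre-estimated value is known not to impair
clustering power while removing the expensive, failure-prone inner
optimization; with `theta` fixed the M-step is closed-form:

    p_k   <- (1/N) Σ_i p_ik
    mu_k  <- Σ_i p_ik x_i / Σ_i p_ik

**E-step with rescaling and deterministic annealing.** With G in the
thousands the joint density underflows. Each per-sample log joint
density is offset by `M_i`, the mean per-gene log density over all
components and genes (`M_i = row sum of the N × K log-density matrix /
(K·G)`), and responsibilities are computed as

    p_ik ∝ p_k · exp( (logdens_ik − M_i) / τ )

normalized per row via log-sum-exp, so no intermediate can overflow or
underflow even at G = 5000. The posteriors are algebraically invariant
to `M_i` (it cancels in the normalization); the offset plus log-sum-exp
is purely a conditioning device, and the invariance is asserted to
1e-12 in the test suite. The prior is *not* raised to `1/τ`. The
temperature follows `τ_{s+1} = max(1, r·τ_s)` with defaults `τ₀ = 10`,
`r = 0.9` (`τ₀ = 2` available as a preset). The ladder always runs to
τ = 1; convergence — relative change `|ΔL|/(|L|+1) < 1e-6`, cap 1000
iterations — is only tested in the τ = 1 phase, because testing during
annealing can freeze the fit at high temperature. Once τ = 1 the
iteration is classical EM, and L is non-decreasing (asserted within
1e-8 relative slack on every test fit). Final posteriors, labels
(row-argmax, ties to the lowest component index), L and BIC are
evaluated at τ = 1 with the final parameters. The whole algorithm is
deterministic given its inputs; the config seed exists only for
optional multi-start extensions, off by default.

**Degenerate components.** A posterior column collapsing to ~0 mass is
floored at `prior_floor = 1e-10`, priors renormalized and a warning
recorded; this avoids NaN cascades at small N.

**Model selection.** `BIC = −2L + ν·log N` with `ν = (K−1) + K·G`:
mixing proportions and component means are free; dispersions are fixed
after initialization and therefore not counted (`count_dispersions=True`
adds `K·G` for sensitivity checks). The candidate with the smallest BIC
wins; exact ties go to the smaller K. Candidate fits share one per-gene
MLE computation. The K range is entirely user-set (no hidden minimum
of 2); benchmark defaults use 2..6.

## Preprocessing

* **Upper-quartile CPM** — per-sample factor = 75th percentile of the
  sample's nonzero counts divided by its total count; factors rescaled
  to geometric mean 1; effective library size = total × factor; output
  = `1e6·x / effective library size`. Defined this way (quantile of the
  library-size-normalized counts) the output is invariant to rescaling
  any sample's raw counts by a positive constant.
* **MAD filter** — keep the top-n genes by `median_i |x_ig −
  median_i x_ig|` (no 1.4826 constant; ranking is scale-invariant),
  ties broken by original gene order. Typical use: top 1000 genes.
* **Log transform** — `log(x + 1)` by default (pseudocount
  configurable); **Blom transform** — per gene,
  `Φ⁻¹((r_i − 3/8)/(N + 1/4))` with average ranks for ties. Both exist
  for the Gaussian-mixture comparators only; the NB mixture runs on
  untransformed normalized counts.

## Simulator

The generator states a world mirroring benchmark designs for NB
clustering: per-gene baselines `(mu_1g, theta_1g)`; a seeded DE subset
of `⌈de_fraction·G⌉` genes; cluster k multiplies DE-gene parameters by
`e^{(k−1)Δμ}` (means) and `e^{(k−1)Δθ}` (dispersions); non-DE genes are
identical in every cluster and cluster 1 is the baseline everywhere.
Labels are i.i.d. uniform over K (an exact-split mode exists); counts
are independent NB draws; everything is reproducible from the scenario
seed. The full benchmark grid is K ∈ {2..6} × Δμ ∈ {0.1, 0.5, 1} ×
Δθ ∈ {0, 1} × DE ∈ {5%, 10%} × N ∈ {50, 100, 150, 200} ×
G ∈ {1000, 5000} — 480 scenarios, any axis overridable.

Because the real tumor-derived baseline MLE vectors behind the original
benchmark are unpublished, the default baseline is an explicit
synthetic stand-in: `log mu_1 ~ Normal(log 50, 1.5)` truncated to
`[1, 1e4]` and `theta_1 ~ Gamma(2, 1)` truncated to `[0.1, 50]`
(rejection sampling) — i.e. genes spanning ~1–10⁴ mean counts, mostly
strongly over-dispersed, as after MAD filtering of bulk tumor data.
User-supplied baseline vectors can be loaded from CSV. The simulator
emulates clean, batch-free, normalized data with independent genes; it
does not emulate gene-gene correlation, library-size or batch effects,
zero-inflation beyond NB, or unbalanced designs — a green simulation
test therefore establishes algorithmic correctness under the stated
model, not robustness to those real-data features.

## Evaluation

The adjusted Rand index (Hubert–Arabie) is computed from the pairwise
contingency table; it is invariant to relabeling, 1 for identical
partitions, ~0 under independence. Degenerate conventions: both
partitions trivial → 1 (the denominator vanishes); one trivial → the
formula value (0 against any non-trivial partition). The implementation
is cross-checked against an exhaustive pair-counting oracle and an
independent library routine.

GMM comparators fit Gaussian mixtures (EM, diagonal per-component
covariances — full covariances are singular when G ≫ N; configurable)
for each K, select K by BIC, on untransformed, log- or Blom-transformed
data; the mixture fit is delegated to an established implementation and
seeded per replicate, single start. The study driver simulates
replicate datasets per scenario from seeds derived deterministically
from a master seed, scores every requested method by ARI against the
truth, records per-replicate selected K, and aggregates
mean/sd/median/min/max and the modal K into a long-format table.
Results are independent of execution order; per-replicate failures are
recorded, excluded from summaries and counted.

## Known limitations

* Genes are modeled as independent; correlated expression modules
  violate this and can inflate apparent cluster separation.
* Dispersions fixed at the pooled all-sample MLE are biased when
  clusters differ strongly in dispersion (the pooled estimate straddles
  them); the simulation axis Δθ = 1 probes exactly this regime.
* The BIC parameter count charges every component mean, so with many
  uninformative genes the penalty is conservative and BIC tends to
  merge clusters at weak signal (visibly: small-Δμ scenarios select
  K below truth — consistent with low benchmark ARIs there).
* At N = 50 and true K ≥ 5 no method in the benchmark family resolves
  the partition (mean ARI < 0.5); K ranges beyond 4 are not advisable
  for cohorts that small.
* No covariates, no zero-inflation, no infinite/Dirichlet-process
  mixtures; per-iteration dispersion re-estimation and simulated
  annealing are deliberately out of scope.
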