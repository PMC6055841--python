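# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `divtime`, in the spirit of a model reference rather
than an API reference. Ages are in units of 100 Myr throughout the library;
table I/O converts to and from Ma.

## Calibration densities

Two soft-bound families turn fossil evidence into node-age priors.

**Soft-bound uniform** `B(t_L, t_U, p_L, p_U)`. The plateau height is
`h = (1 − p_L − p_U)/(t_U − t_L)`. Below the minimum the density is the
power branch `p_L a t^{a−1}/t_L^a` with `a = h t_L / p_L`, which holds mass
exactly `p_L` and meets the plateau continuously at `t_L`; above the maximum
it is `p_U b e^{−b(t−t_U)}` with `b = h/p_U`, mass exactly `p_U` and
continuous at `t_U`. Defaults `p_L = 0.01`, `p_U = 0.05` give the
94 / 1 / 5 split. All tail-matching constants are closed-form, so the CDF
and quantile function are exact (no quadrature inside the library; the test
suite uses adaptive quadrature as an independent oracle).

**Truncated Cauchy** `L(t_L, p, c, p_L)` for minimum-only fossils. Above
`t_L` the density is Cauchy with location `t_L(1 + p)` and scale `c t_L`,
truncated to `t > t_L` (truncation constant `A = 1/2 + arctan(p/c)/π`) and
carrying mass `1 − p_L`; `p` offsets the mode past the bound, `c` controls
how slowly mass extends toward older ages. Below `t_L` a power branch holds
mass `p_L`, with its exponent chosen so the two branches meet continuously.
The same continuity-matched power decay is used for both families; the
library makes no attempt to equate the decay exponents across families —
each is fixed by its own continuity condition.

Narrow bands (e.g. a root pinned by `B(0.99, 1.01)`) give very large power
exponents, so `logpdf` is evaluated in log space; the linear-space `pdf`
may legitimately underflow far below such a bound.

Point calibrations are represented as narrow soft-uniform bands,
`t_0 (1 ∓ 0.01)` by default.

**Strategies.** `SA` maps minimum-only records to `L(t_L, 0.1, 0.1, 0.01)`
and min+max records to `B(t_L, t_U, 0.01, 0.05)`. `SB` gives every
minimum-only node the maximum of its nearest maximum-bearing calibrated
ancestor (the nearest such ancestor is necessarily the youngest). `SC` and
`SD` shorten the Cauchy tail (`c = 0.01`, `c = 0.005`) on two configurable
focal nodes (defaults `crown_angiosperms`, `crown_mesangiosperms` — labels,
not hard-coded indices, since node numbers are tree-specific). `SE` instead
gives those nodes a soft maximum at 1.394 (139.4 Ma).

## Time prior

Uncalibrated node ages follow the birth–death-sampling kernel conditioned
on the root age, with per-lineage birth rate λ, death rate μ and sampling
fraction ρ. The kernel CDF has the closed form `v(t)/v(t₁)` with
`v(t) = 1 − P(0,t) e^{(μ−λ)t}/ρ`; normalisation is verified by quadrature
for the parameter grid used in the analyses, {(1,1,0), (1,4,0.1),
(4,1,10⁻⁴)}. ρ = 0 is treated as the limit ρ → 0: below 10⁻¹⁰ the code
switches to the limiting form, which for λ = μ is the uniform density on
(0, root age). Ages are drawn from the kernel by bisection inversion of the
CDF.

The joint prior over all internal-node ages is the product of calibration
densities (calibrated nodes) and BD kernels (uncalibrated nodes), with
log-density −∞ whenever any parent is not strictly older than its children.
Truncation is enforced by evaluation, never by renormalising marginals;
this is deliberate, because the gap between the *specified* density and the
*effective* marginal prior induced by joint truncation is itself an object
of study. The root must carry a calibration; the library refuses to build a
time prior without one.

## Clock models

* **strict** — all branches share `μ`; only the hyperprior contributes.
* **independent (IR)** — `log r ~ N(log μ − σ²/2, σ²)` iid per branch, so
  `E[r] = μ` (`μ` is the mean of the rate; the alternative reading of `μ`
  as log-scale median would contradict that definition and is not used).
* **autocorrelated (AR)** — geometric Brownian motion over the tree. A
  branch's rate lives at the branch midpoint; its log-rate is normal around
  the parent branch's log-rate with variance `σ²·Δt` (Δt between midpoints)
  and drift `−σ²Δt/2`, so the rate process is a martingale. Branches off
  the root start from `log μ` at the root age.

Hyperpriors are gamma: defaults G(2, 50) on μ (mean 0.04 substitutions/
site/100 Myr) and G(2, 4) on σ² (mean 0.5); G(2, 60) (mean 0.033, quoted
0.03) for outgroup-free configurations and G(2, 10) (mean 0.2) for
model-selection runs where the root is rescaled to 1. Whether partitions
share σ² is an open choice; here every partition carries its own (μ, σ²)
and its own branch rates.

## Likelihood

**Exact.** Felsenstein pruning under HKY85 with discrete-gamma site rates:
5 equal-probability categories, each represented by its conditional mean
(computed via the incomplete gamma function; the category means average
exactly 1). HKY transition probabilities use the closed-form spectral
solution (cross-checked in tests against a matrix-exponential oracle).
Site patterns are compressed; gaps and ambiguity codes are missing data
(partial likelihood 1 in every state). No per-node rescaling is applied —
at the ≤ 54-taxon scale exercised here, float64 partials do not underflow.

**Approximate.** Branch lengths are estimated by L-BFGS-B on the
transformed scale `z = √b`, followed by Newton polishing with a
finite-difference Hessian until the interior gradient is below 10⁻⁶. The
stored summary is the gradient and Hessian at the optimum (central
differences, step 10⁻⁴ on the transformed scale, configurable) plus the
log-likelihood value; the approximate log-likelihood of arbitrary lengths
is `g·Δz + ½ΔzᵀHΔz`, exactly 0 at the MLE and finite at zero-length
branches (the √ transform removes the boundary singularity). A
`zero_gradient` flag forces `g = 0` for users who prefer to treat the MLE
as exactly stationary. Branch lengths estimated at the zero boundary get a
zeroed gradient component and a regularised Hessian row/column. Under a
reversible model the two root-adjacent branch lengths are identifiable only
through their sum (pulley principle); the quadratic summary inherits this
flat direction, which is harmless because the time prior breaks the tie.
Per-partition summaries round-trip through a documented plain-text file
(`write_inbv`/`read_inbv`).

## MCMC

A Metropolis–Hastings sampler over node ages, per-branch log-rates (for
non-strict clocks), and per-partition (μ, σ²). One sweep comprises:

* a per-node age slide, reflected at the admissible bounds (oldest child,
  parent) so order constraints are never violated by construction; the
  prior update is incremental (only the moved node's term, plus all BD
  terms when the root moves);
* a per-node *compensated* age slide that rescales the log-rates of the
  three adjacent branches to keep all branch lengths — and hence the
  likelihood — exactly unchanged (the Jacobian of the rate map enters the
  acceptance ratio). This move decorrelates ages from rates and is what
  gives young, data-constrained nodes usable effective sample sizes;
* per-branch log-rate slides (iid-lognormal updates are incremental), or
  optionally a joint all-branch proposal (`block_rate_updates`) costing one
  likelihood evaluation — used for power-posterior chains where the exact
  likelihood is the bottleneck; in that regime the likelihood-coupled age
  sweep runs every third iteration, with the compensated moves carrying age
  mixing in between;
* multiplicative slides on μ and σ²;
* a whole-tree mixing move scaling all ages by `c` and all rates (and μ)
  by `1/c`, which leaves every branch length invariant.

Windows are tuned every 50 burn-in sweeps toward ~30% acceptance, then
frozen. All randomness flows from one seeded generator; chains are exactly
reproducible per seed. Prior-only mode sets the likelihood term to zero and
is how effective priors are sampled. A move class that is never accepted
after tuning raises, as does an initial state with zero prior density.
Initial ages start from calibration medians with a postorder repair pass.

Summaries report, per parameter: posterior mean, 95% equal-tail interval
(numpy linear-interpolation percentiles), 95% HPD interval and ESS (both
via arviz). Equal-tail intervals are the primary summary; HPD is always
emitted alongside. Convergence is assessed the pragmatic way: two chains
with different seeds must agree within 3 combined Monte-Carlo standard
errors (`consistency_check`); disagreement warns rather than errors.

## Model selection

`log m = ∫₀¹ E_β[log L] dβ` is evaluated with Gauss–Legendre nodes and
weights mapped to (0, 1) (`numpy.polynomial.legendre.leggauss`); one chain
per node samples the power posterior `prior · L^β` and contributes its mean
retained log-likelihood. Thermodynamic integration uses the exact pruning
likelihood — a quadratic approximation would bias the path integral. Each
β-chain passes a stationarity check (first- vs second-half means within 10
autocorrelation-adjusted standard errors, ESS-based). Bayes factors are
taken against the best model and posterior model probabilities assume equal
prior model weights, mirroring the selection-table convention (root fixed
by a `B(0.99, 1.01)`-style band, μ ~ G(2, 10), σ² ~ G(2, 4)). Defaults are
desk-scale (the quadrature order and chain lengths are configuration, not
contract); stepping-stone sampling is intentionally not implemented.

## Synthetic data

The generator produces every input with known truth: time trees from the
conditioned BD process (iid kernel ages attached by uniformly splitting an
extant lineage, which respects the exchangeability of the conditioned
process); branch rates from any of the three clock models; alignments by
state evolution under HKY85+Γ (per-site category fixed at a category mean,
no indels); and calibration tables with minima `true age × U(0.6, 0.95)`
and maxima `true age × U(1.05, 1.6)` — an informative-minimum regime in
which fossil minima sit close below the true ages. The root is always
calibrated and always carries a maximum, which guarantees the
maximum-inheritance strategy is well defined on generated tables.

Two packaged fixtures: a synthetic 52-calibration table (41 minimum-only,
11 with maxima, labelled crown nodes, crown-angiosperm minimum at the
published 125.9 Ma bound — the numbers are generated, not transcribed from
any fossil compendium) and a synthetic ten-taxon tracheophyte bundle
(outgroups basal, ladder ingroup, root scaled to 1, three partitions plus
concatenation, IR rates with σ² = 0.5) used for clock-model selection.

What the simulations do *not* emulate: missing data and alignment raggedness,
indels, codon structure, amino-acid partitions (the mixed-partition scheme is
supported at the approximate-likelihood level, consuming externally supplied
quadratic summaries), among-partition topology conflict, and the sheer scale
of real supermatrices. Passing tests therefore demonstrate correctness of
the machinery and directional behaviour of the priors, not real-data
performance.

## Problem sizes in the test suite

The end-to-end checks run at sizes chosen to keep the full suite under ten
minutes on a single core while leaving each check statistically meaningful:
effective-prior fidelity uses 10⁵ prior draws (KS < 0.02); coverage uses 20
replicates of 8 taxa × 2 kb (140 true ages, ≥ 90% must fall in their 95%
intervals); model selection uses the ten-taxon bundle at 3 × 500 bp with a
3-point quadrature and short block-update chains; the sensitivity grid uses
8 taxa × 3 × 2 kb partitions. The partition fixtures deliberately give the
three partitions different mean rates (0.08 / 0.15 / 0.3), both because
real partitions differ and because the extra independent rate realisations
are exactly why a three-partition analysis dates more precisely than the
same data concatenated.

## Known limitations

* Binary rooted trees only; no fossilised-birth–death or tip-dating priors.
* HKY85+Γ is the only exact substitution model; GTR, codon and amino-acid
  models enter only through externally computed quadratic summaries.
* The sampler is a single-chain MH scheme; no parallel tempering or
  adaptive covariance proposals. Very short desk-scale chains can leave
  young nodes with modest ESS — the compensated age move mitigates but does
  not abolish this.
* Thermodynamic integration at desk scale carries Monte-Carlo noise of
  order 1 log-unit; Bayes factors between models that fit nearly equally
  well (IR vs AR on small trees) are resolved only in sign frequency across
  replicates, not per dataset.
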