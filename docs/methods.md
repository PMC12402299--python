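# Methods

## The model

The package models androgen-induced negative feedback on AR output with
mass-action ordinary differential equations over nine species: AR transcript
(`mRNA_AR`), free unmodified AR (`AR_free`), free ADP-ribosylated AR
(`AR_adp_free`), unoccupied promoters (`P_free`), the unmodified and
modified AR–promoter complexes (`C_AR`, `C_ADP`), PARP7 transcript
(`mRNA_P7`), PARP7 protein (`P7`), and the target transcript (`T`, the
composite readout the fits are scored on).

Shared assumptions across all three architectures:

1. All AR is ligand-bound and nuclear; ligand-binding kinetics are not
   modeled.
2. Unmodified AR is not degraded on the simulated time scale; only the
   ADP-ribosylated free form is cleared (`k_deg_adp`). Modified AR bound to
   a promoter must dissociate before it can be degraded, which keeps
   promoter bookkeeping exact.
3. AR represses its own transcript by mass action
   (`k_rep_ar · AR_free · mRNA_AR`), with basal production `k_tx_ar` and
   first-order decay `k_deg_arm`.
4. PARP7 protein decays at a fast rate that AR shifts toward a slow rate:
   `δ(u) = k_deg_p7_fast − (k_deg_p7_fast − k_deg_p7_slow) · u/(K_stab + u)`
   with `u` the unmodified AR pool (`AR_free + C_AR`). The saturating form
   implements the stabilization with a single half-point parameter while
   staying smooth; a pure mass-action protective-complex variant was
   considered and not adopted (it adds a species and a rate without
   changing the qualitative behavior).
5. Both promoter complexes transcribe at the same rate (`k_tx_target`,
   `k_tx_p7` per transcribing unit); the modified complex differs from the
   unmodified one only in binding kinetics, not output.

The architectures differ in where transcription and modification happen:

- **simple** — no promoter species; `AR_free` drives transcription directly
  and is modified wherever it is (`k_cat_adp · P7 · AR_free`). The four
  promoter binding rates are inactive (14 active parameters).
- **chromatin** — transcription requires the promoter complex and PARP7
  modifies only promoter-bound AR (`k_cat_adp · P7 · C_AR`, converting
  `C_AR → C_ADP` in place). 18 active parameters.
- **nucleoplasm** — transcription requires the promoter complex but PARP7
  modifies only free AR (`k_cat_adp · P7 · AR_free`). 18 active parameters.

The inhibitor condition is the identical system with `k_cat_adp = 0`,
matching a purely catalytic PARP7 inhibitor.

Initial conditions: 660 AR molecules and 100 promoters (ratio 6.6, a scaled
version of roughly 20,000 receptors over 3,050 responsive promoters); every
other species starts at zero. The default reporting grid is 2,200 intervals
of 0.01 h (22 simulated hours, 100 report points per hour).

## Numerics

The integrator is an adaptive Rosenbrock(2,3) pair (the linearly implicit
family suited to stiff kinetics) with an analytic Jacobian, compiled with
numba. Error control uses `rtol = 1e-6`, `atol = 1e-9` for trajectory-grade
simulation; dense output between accepted steps uses the method's quadratic
continuous extension. Because stage values come from solves against
`W = I − hdJ`, which can be severely ill-conditioned on large stiff steps,
each stage solve gets one pass of iterative refinement; this keeps linear
invariants (promoter conservation, AR mass bookkeeping in closed
configurations) at the 1e-12 level over a full trajectory. The implementation
was cross-checked against an independent LSODA integration at tight
tolerance.

States within `[−1e-8, 0)` at report points are clamped to zero; anything
below `−1e-8`, a non-finite state, or an exhausted step budget marks the
simulation invalid. During fitting, invalid simulations score `+inf` and
simply rank last, which makes the random screen robust to pathological
parameter draws.

Fitting-time solves use looser control (`rtol = 1e-3`, `atol = 1e-6`, step
budget 10,000, no refinement pass): SSE scores on values of order 100 are
insensitive at that level, and the two-stage search performs hundreds of
thousands of paired solves. Normalized targets are interpolated linearly to
the observed times; the fitting report grid is hourly by default, dense
relative to nothing finer than hourly data.

## Parameter estimation

Stage one draws `n_mc` parameter vectors log-uniformly within bounds and
keeps the `top_k` lowest summed SSE. Default bounds are per-parameter, set
by dimensional analysis rather than one global range: second-order rates
(per molecule per hour: `k_on_*`, `k_cat_adp`, `k_rep_ar`) span 1e-4..1,
so characteristic fluxes `k·N` with `N ≈ 660` molecules span 0.07..660 per
hour; first-order and zeroth-order rates span 1e-2..1e2 per hour against
the 22-hour observation window; `K_stab` spans 1..1000 molecules. A single
global `(low, high)` pair and linear-uniform sampling remain available in
`SearchConfig`. The fast/slow PARP7 decay pair is ordered after sampling
(fast = max), i.e. the pair is distributed as the order statistics of two
independent draws.

Stage two refines each retained set with a Metropolis–Hastings chain:
proposals perturb each active parameter by a Gaussian of standard deviation
`proposal_cv` (default 5%) times its current value, negative draws are
re-drawn, and the fast/slow pair is re-ordered. Acceptance is
`min(1, exp((SSE_cur − SSE_prop)/T))`. The default temperature is the
greedy limit `T = 0` (accept only improvements): at the chain lengths used
here a temperature of, say, 10% of the starting SSE accepts worsening moves
so often that the chain random-walks instead of descending — measured on
synthetic data, the greedy default roughly halves the best refined SSE at
500 steps. `temperature=None` selects the 10%-of-start rule for users who
want an exploring chain; the best-visited state is returned either way, so
refinement never worsens the screened score.

All randomness is explicitly seeded; per-chain seeds derive from the config
seed and the chain index through numpy's `SeedSequence`, so full runs are
bit-reproducible. The default full-scale protocol performs
`100,000 + 100 × 5,000 = 600,000` paired simulations; the desk-scale
`SearchConfig.reduced()` (5,000 draws, top 20, 500 steps) performs 15,000.

## Model selection

Architectures are compared on the single best refined SSE via the
Gaussian-residual BIC, `n ln(SSE/n) + k ln(n)`, where `n` counts fitted data
points across both conditions and `k` is the architecture's active parameter
count; the best SSE is the proxy for the maximized likelihood, which is why
the top-k mean is not used. Bayes weights renormalize `exp(−ΔBIC/2)`. A
perfect fit (SSE = 0) maps to a `−inf` BIC sentinel that takes the whole
weight. Top-k SSE distributions can additionally be compared with a paired
t test or the two-tailed Wilcoxon signed-rank test; Wilcoxon is the default
as the rank-based choice for skewed SSE distributions.

## Synthetic data

`make_observed` emulates the structure of a composite qPCR time course:
simulate the truth architecture noise-free; read the raw target at the
sample times; create `n_genes` (default 3) noisy replicates with
multiplicative Gaussian noise (`noise_cv`, default 5% — replicate error in
expression measurements scales with signal); average them into a composite;
interpolate linearly to an hourly grid; normalize each condition to a
maximum of 100. The latent (noise-free) profile is returned alongside for
oracle comparisons.

The packaged reference parameter set (`REFERENCE_PARAMS`, a repository
fixture) was chosen so the chromatin-model control readout shows the
signature kinetics of the feedback: steep induction, a peak near 8 h
(7.79 h on the default grid), and a collapse to ~10% of maximum by 22 h,
with the inhibitor condition rising monotonically; modified AR binds the
promoter ~100-fold more weakly than unmodified AR; and the feedback delay
grows with the initial AR:promoter ratio. The sharp, occupancy-capped
plateau is deliberate: promoters stay saturated while the excess AR pool
drains, and the collapse is abrupt once the buffer is exhausted. That
plateau-and-collapse shape is exactly what distinguishes the chromatin
architecture from a promoter-free cascade; a smoother pulse is fittable by
all three architectures and carries no architectural information.

What the generator does **not** emulate: RNA-seq count noise, library-size
or batch effects, per-gene kinetic heterogeneity, or correlated noise across
time points. Passing recovery tests therefore demonstrate that the
estimation machinery identifies the generating architecture under the
stated noise model — not that it would do so under every real-data noise
structure.

## Rank overlap and enrichment

`rank_overlap_curve` computes O(k) = |top-k(A) ∩ top-k(B)| for two ranked
gene lists (the `bottom` direction reverses both lists first). The
empirical null permutes one list's ranks uniformly over the shared N-gene
universe (default 1,000 subsamples) and reports the mean and 2.5/97.5
percentiles per k; the null mean converges to the hypergeometric
expectation k²/N. Permuting one list rather than both is sufficient — the
overlap distribution depends only on the relative ranking. Ties in input
statistics keep input order (stable sort).

Overrepresentation uses `expected = module_size/background_size ×
study_size`, `fold = overlap/expected`, a one-tailed hypergeometric
p-value P(X ≥ overlap), and Benjamini–Hochberg adjustment across tested
modules; modules with adjusted p below 0.001 are flagged. Degenerate cases
are errors rather than silent zeros (empty lists, duplicate identifiers,
`expected = 0`, extrapolation in interpolation).

## Problem sizes and defaults used in the shipped experiments

The shipped recovery experiment (tests and `scripts/acceptance.py`) uses
hourly sampling over 0–22 h, 5% noise, ten seeds, and the reduced search
(5,000 + 20 × 500 paired simulations per architecture) — 450,000 paired
solves across ten replicates and three architectures, a few minutes on one
CPU. The full-scale defaults (600,000 per architecture) are the protocol a
real fitting campaign would run and are exercised arithmetically rather
than end-to-end.

## Known limitations

- The equations are a canonical reconstruction constrained by the stated
  biological assumptions; alternative forms for AR self-repression and
  PARP7 stabilization (e.g. Hill instead of saturating-linear) are not
  implemented.
- The Metropolis–Hastings stage is a refinement device, not a calibrated
  posterior sampler: no likelihood model, no credible intervals.
- BIC from SSE assumes i.i.d. Gaussian residuals; interpolated points
  violate independence, so weights should be read as a ranking heuristic,
  consistent with their use here.
- The simple architecture shares the AR self-repression machinery with the
  promoter architectures; treating AR transcript as an exogenous input
  trace is not supported.
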