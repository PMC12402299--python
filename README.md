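# arfeedback

Modeling and inference tools for the negative feedback loop in androgen
signaling: the androgen receptor (AR) induces the mono-ADP-ribosyltransferase
PARP7, PARP7 ADP-ribosylates AR, and the modified receptor is degraded by the
proteasome — limiting AR transcriptional output after a multi-hour delay.
Catalytic PARP7 inhibition (e.g. RBN2397) removes the brake.

The package is for systems biologists who want to ask *where* in the nucleus
the modification happens. It provides:

- **Three competing mass-action ODE architectures** for the loop:
  *simple* (no explicit promoter; free AR transcribes), *chromatin* (AR must
  bind a promoter to transcribe, and PARP7 modifies only promoter-bound AR),
  and *nucleoplasm* (promoter binding required, but PARP7 modifies only free
  AR). Control and inhibitor conditions are simulated as the same system with
  the catalytic rate `k_cat_adp` set to zero under inhibitor.
- **Two-stage stochastic parameter estimation**: a log-uniform Monte Carlo
  screen (default 100,000 draws, top 100 retained) followed by
  Metropolis–Hastings refinement of each survivor (default 5,000 steps:
  600,000 paired simulations in total). Fits are scored by the summed
  control + inhibitor SSE against a composite transcript profile normalized
  to max = 100.
- **Model selection** by the Gaussian-residual Bayesian Information
  Criterion, `BIC = n ln(SSE/n) + k ln(n)`, and Bayes weights
  `w_i = exp(-ΔBIC_i/2) / Σ_j exp(-ΔBIC_j/2)`, plus paired t / Wilcoxon
  comparisons of top-k SSE distributions.
- **A synthetic-data generator** that emulates the composite qPCR time course
  the models are fitted to (latent trajectory → noisy gene replicates →
  composite average → hourly interpolation → per-condition normalization).
- **Rank-overlap and enrichment statistics**: the step function
  O(k) = |top-k(A) ∩ top-k(B)| for two ranked gene lists with a
  rank-permutation null band, and module overrepresentation
  (fold enrichment = overlap / expected with
  expected = module_size/background_size × study_size, one-tailed
  hypergeometric test, Benjamini–Hochberg adjustment).

Simulation uses an adaptive stiff Rosenbrock(2,3) integrator with analytic
Jacobian, compiled with numba, so the full two-stage search runs in minutes
on one CPU.

## Worked example

```python
import numpy as np

from arfeedback import ratio_scan, simulate_paired
from arfeedback.fitting import SearchConfig, estimate_parameters
from arfeedback.selection import score_models
from arfeedback.synthetic import REFERENCE_PARAMS, SynthConfig, make_observed

# paired simulation of the reference chromatin model (+/- PARP7 inhibitor)
control, inhibitor = simulate_paired("chromatin", REFERENCE_PARAMS)
print(f"control peak: {control.peak_time:.2f} h "
      f"(final level {control.target_norm[-1]:.0f}/100)")
print(f"inhibitor peak: {inhibitor.peak_time:.2f} h "
      f"(final level {inhibitor.target_norm[-1]:.0f}/100)")

# the AR excess sets the feedback delay
scan = ratio_scan("chromatin", REFERENCE_PARAMS, [1.65, 3.3, 6.6, 13.2])
print("ratio scan peak times:",
      {r: round(p, 2) for r, (_, p) in scan.items()})

# fit all three architectures to synthetic data and select the best
obs, _ = make_observed(SynthConfig(seed=4, sample_times=np.arange(23.0)))
config = SearchConfig.reduced(seed=4)
fits = {arch: estimate_parameters(arch, obs, config=config)
        for arch in ("simple", "chromatin", "nucleoplasm")}
scores = score_models({a: [f.sse_total for f in r.fits]
                       for a, r in fits.items()}, n_points=obs.n_points)
for s in scores:
    print(f"{s.arch.value:>11}: best SSE {min(s.sse_top):8.1f}  "
          f"BIC {s.bic:7.1f}  Bayes weight {s.bayes_weight:.3f}")
```

Output:

```
control peak: 7.79 h (final level 10/100)
inhibitor peak: 22.00 h (final level 100/100)
ratio scan peak times: {1.65: 4.22, 3.3: 5.84, 6.6: 7.79, 13.2: 9.75}
     simple: best SSE   1306.0  BIC   207.5  Bayes weight 0.000
  chromatin: best SSE    605.3  BIC   187.5  Bayes weight 1.000
nucleoplasm: best SSE    867.5  BIC   204.0  Bayes weight 0.000
```

Reading the numbers: under control the composite transcript peaks near 8 h
and then collapses to 10% of maximum as the feedback drains the AR pool,
while under PARP7 inhibition it keeps rising — the inhibitor condition lacks
the decline. Raising the initial AR:promoter ratio (default 660 AR over 100
promoters, i.e. 6.6) lengthens the delay before the decline, because excess
AR buffers promoter occupancy while modified AR is cleared. When the
synthetic data are generated from the chromatin architecture, the
reduced-scale fit recovers the chromatin model as the most probable one
(Bayes weight 1.000 here), with the promoter-free simple model far behind.

A command-line interface mirrors the library (`arfeedback simulate`,
`ratio-scan`, `synth`, `fit`, `select`, `enrich overlap`, `enrich ora`);
see `arfeedback --help`.

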