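# superstat

Superstatistical analysis of environmental sensor time series.

High-frequency water-quality records — dissolved oxygen (mg/L) or electrical
conductivity (µS/cm) logged every 15 minutes in a river — are strongly
non-Gaussian once the daily and seasonal cycles are removed: their
fluctuations have heavy tails with far more extreme events than any Gaussian
process allows. `superstat` implements the superstatistical description of
such records for freshwater scientists and time-series analysts: the
fluctuations are locally Gaussian inside windows of some long timescale *T*,
while their inverse variance β wanders on that scale, and the aggregated
distribution is the β-mixture of those local Gaussians.

The pipeline:

1. **Detrend** `F(t) = Trend(t) + Fluctuations(t)`, either by a centered
   moving average with filtering window *f* (default 6 h) or by empirical
   mode decomposition, assigning the *m* fastest modes (default 2) to the
   fluctuations.
2. **Long timescale** *T* from the average moment kurtosis of sliding
   windows, κ̄(Δt) = ⟨(u−ū)⁴⟩/⟨(u−ū)²⟩², as the window size where κ̄ first
   reaches the Gaussian value 3. If κ̄ never reaches 3 the fluctuations are
   platykurtic and no *T* exists (the analysis reports this instead of a
   number).
3. **Short timescale** τ from the 1/e decay of the autocorrelation
   c(t) ~ exp(−t/τ), with a filter-aware correction for the bias the
   detrending step imprints on the ACF; superstatistics requires τ ≪ T.
4. **β-extraction**: β = 1/s² on consecutive non-overlapping windows of
   length *T*.
5. **β-distribution fitting** by maximum likelihood: χ² (gamma with mean
   β0), inverse-χ², log-normal, and a two-component χ² mixture
   `f(β) = W f_χ²(β; n₁, β0) + (1−W) f_χ²(β; n₂, β0)` sharing one β0 —
   fitted by EM — ranked by AIC. The aggregated fluctuations themselves are
   fitted with the q-Gaussian
   `p(x) ∝ (1 + (q−1) b (x−μ)²)^(1/(1−q))`, which is the exact marginal of
   χ² superstatistics (q = 1 + 2/(n+1)).

A synthetic-data generator with exact ground truth (epoch-wise AR(1)
fluctuations whose stationary variance is redrawn from a configurable β-law
every *T*ₜᵣᵤₑ) makes every stage testable by parameter recovery.

## Worked example

```python
import superstat as ss

cfg = ss.SyntheticConfig(seed=0, duration_days=365)   # DO-like record, 15-min
series, truth = ss.generate_superstat_series(cfg)      # T_true=16 h, tau=1 h
report = ss.run_pipeline(series, ss.PipelineConfig(seed=0))
print(report["timescales"]["T_hours"], report["timescales"]["tau_hours"])
print(report["best_family"], report["separation"])
```

prints

```
11.487039012904527 0.8980722554779846
lognormal {'applicable': True, 'ratio': 0.07818135330341364, 'passed': True, 'threshold': 0.1}
```

i.e. the long timescale is recovered at 11.5 h (same order as the generating
16 h; the κ̄ = 3 crossing is systematically at or below the β-redraw period),
the relaxation time at 0.90 h for a true 1 h, the log-normal β-law that
generated the data is the AIC-best family, and the separation check
τ/T ≈ 0.08 < 0.1 passes.

The same analysis from the shell:

```bash
superstat simulate --out fixture.csv --seed 0
superstat run --input fixture.csv --seed 0 --out report.json
superstat sweep --input fixture.csv --values 2,4,6,8 --out sweep.csv
```

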