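# suturelax

Three-phase relaxation analysis of knotted-suture tension traces.

Every surgical suture compresses the tissue enclosed in its loop, and that
tension is far from constant: within the first hour it relaxes in three
phases — a one-minute **rapid cutting phase** (RCP) in which the suture
cuts into the tissue (peak tension P₀ drops to P₁), a **constant declining
phase** (CDP) of slower plastic deformation, and a residual **plateau**
(P_plat) reflecting the tissue's remaining structural stability. How much
tension is lost, and how fast, is tissue specific and tracks the tissue's
collagen/protein content. `suturelax` is for biomechanics researchers who
work with in-loop force-sensor recordings of this kind: it simulates
realistic 60-minute, 250 Hz tension traces for liver, skin, stomach,
muscle and small intestine; segments traces into the three phases; fits
the relaxation model; and aggregates cohorts into a tissue-level report
with nonparametric statistics.

The declining phase is modelled as a stretched exponential with offset,

```
y(t) = a · exp(−b · tᶜ) + d
```

with `t` in minutes from the CDP start, `a ≈ P₁ − P_plat`, `b` the decay
rate per minute, `c` the time exponent (fixed at 1 by default: a constant
per-minute relative decline), and `d ≈ P_plat`. With `c = 1` the tension
gap above the plateau loses the constant fraction `1 − exp(−b)` per
minute. Landmarks (P₀, P₁, P_plat), the percentage RCP loss, the
plateau-to-peak ratio and the (possibly censored) time to half of peak
tension are measured directly from the trace; the fit contributes the
per-minute CDP decline and a model-based half-tension time.

## Worked example

```python
import numpy as np
from suturelax import (
    SensorConfig, builtin_profiles, sample_suture_params, synthesize_trace,
    segment_phases, fit_relaxation, decline_per_minute, half_time_from_fit,
)

profile = builtin_profiles()["liver"].with_zero_sds()   # deterministic draws
rng = np.random.default_rng(0)
params = sample_suture_params(profile, mode="relative", rng=rng)
trace = synthesize_trace(params, SensorConfig(noise_sd_n=0.0), rng)

m = segment_phases(trace)
fit = fit_relaxation(trace, free_c=False)
print(f"P0 = {m.p0:.3f} N, RCP loss = {m.rcp_loss_pct:.1f} %")
print(f"b = {fit.b:.4f}/min, d = {fit.d:.3f} N, r = {fit.r_fit:.4f}")
print(f"CDP decline = {decline_per_minute(fit):.2f} %/min")
print(f"half-tension time = {half_time_from_fit(fit, m.p0).time_min:.1f} min")
```

prints

```
P0 = 2.600 N, RCP loss = 34.0 %
b = 0.0834/min, d = 1.040 N, r = 1.0000
CDP decline = 8.00 %/min
half-tension time = 12.5 min
```

A noiseless liver suture in relative mode starts at the profile's 2.6 N
peak and loses 34% of it during the first minute. The fitted plateau
(1.04 N) is 40% of the peak, and the gap above it decays at 8% per minute
(`b = −ln 0.92`), so the trace falls to half its peak 12.5 minutes after
knotting. With sensor noise enabled, `r_fit` stays above 0.95 for every
tissue profile.

The same pipeline runs from the shell:

```
suturelax simulate --tissue all --n 6 --seed 1 --out traces/
suturelax analyze traces/*_0*.csv --out metrics.csv
suturelax fit traces/*_0*.csv --out fits.csv
suturelax report --metrics metrics.csv --fits fits.csv \
    --collagen traces/collagen.csv --out report.json --markdown report.md
suturelax run --seed 1 --out run_out/      # all four stages + MANIFEST
```

`report.md` renders one row per tissue (mean ± SD of P₀, P₁, P_plat, RCP
loss, CDP decline, plateau ratio, collagen) with censored half-tension
times shown as `> 60`; `report.json` adds the Kruskal–Wallis /
Mann–Whitney comparisons and the collagen correlations.

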