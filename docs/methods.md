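# Methods

## The measurement setting

A knotted surgical suture compresses the tissue enclosed in its loop. With
an in-loop force sensor, that tension can be recorded continuously from the
moment the final knot is completed. In the rodent setting this package
emulates, single monofilament polypropylene (3/0) sutures were placed in
five tissue types — liver, skin, stomach, muscle and small intestine — with
six 60-minute recordings per tissue, digitised at 250 Hz with a force
resolution of 0.077 g (7.551 × 10⁻⁴ N; forces are newtons everywhere in
this package, grams-force appears only in this one constant).

Because the suture is effectively inelastic, tension loss is attributed to
the tissue, and it proceeds in three phases:

1. **Rapid cutting phase (RCP)** — the first minute, interpreted as the
   suture cutting into the tissue. Peak tension P0 falls to P1.
2. **Constant declining phase (CDP)** — slower relaxation interpreted as
   plastic tissue deformation, with an approximately constant *relative*
   decline of the tension gap above the final plateau.
3. **Plateau phase (PP)** — the residual tension Pplat after about an hour,
   reflecting the remaining structural stability of the tissue.

## The relaxation model

The declining phase is modelled as a stretched exponential with offset,

    y(t) = a · exp(−b · t^c) + d,        t in minutes from the CDP start,

where `a ≈ P1 − Pplat` (the model equals `a + d` at `t = 0`), `b` is the
decay rate per minute, `c` the time exponent, and `d ≈ Pplat`. A constant
per-minute relative decline of the gap corresponds to `c = 1`, in which
case the gap above the plateau loses the fraction `1 − exp(−b)` every
minute; `decline_per_minute` reports that as a percentage. By default the
fitter holds `c = 1` and frees it only on request (`free_c`), reporting the
geometric-mean per-minute gap decline over the window when `c ≠ 1`.

Fitting is bounded nonlinear least squares (scipy `least_squares`, trust
region reflective) on the trace decimated to 1 Hz, over the window
[60 s, record end]. Bounds: `a ∈ (0, 2·P0]`, `b ∈ [10⁻⁴, 10]/min`,
`d ∈ [0, P1]`, and `c ∈ [0.2, 3]` when freed. The starting point is
data-driven: `d₀` from the last decile of window forces, `a₀` from the
first window point above `d₀`, `b₀` from the log-gap slope to mid-window
(floored at 10⁻³/min), `c₀ = 1`. Convergence requires a relative cost
change below 10⁻¹⁰ within the iteration budget; a non-converged fit returns
its best iterate flagged `converged=False`. Fit quality is the plain
Pearson correlation `r_fit` between fitted and measured forces on the
window. The loss is unweighted squared error, matching the additive
Gaussian sensor-noise model; no robust loss is used.

## Phase segmentation

Landmarks are measured, not fitted: P0 is the maximum force over the first
5 s at full acquisition rate (wide enough to catch the post-knot peak,
short enough that even a 15%/min decline contributes < 1% error); P1 is the
mean force over [55 s, 65 s] — the RCP is *defined* as exactly one minute,
so no transition detector is used on the primary path; Pplat is the mean
over the trailing 60 s of the full record (a measurement deliberately
distinct from the fitted `d`). The phase-2/phase-3 boundary is never
defined numerically in descriptions of this setting; the package therefore
treats the CDP window as [1 min, record end] and reads the plateau from the
trailing minute, which is the interpretation used everywhere here.

The half-tension time is the first crossing of P0/2, linearly interpolated
between bracketing samples, earliest crossing winning. A trace that never
crosses within the record is *censored*: the record length (60 min) is
reported as a lower bound, matching the "> 60" convention of per-tissue
summary tables, and censored values are excluded from tissue means rather
than imputed (no Kaplan–Meier estimate is attempted, keeping the summary
directly comparable to the printed table).

## The synthetic-data generator

No raw recordings of this setting are publicly deposited, so the generator
is the package's data source, parameterized by the published per-tissue
table. The noiseless mean curve is piecewise: an exponential RCP transient
`P1 + (P0 − P1)·exp(−t/τ)` with τ = 10 s (the rapid phase has no published
internal shape; τ = 10 s makes it 99.75% complete at one minute, and a
residual ≥ 2% of P0 at the joint is rejected), then the CDP/plateau curve
`d + a·exp(−b·(t−60 s)/60)` with `b = −ln(1 − decline_per_min)` and `c = 1`
(a constant per-minute relative decline is exactly `c = 1`; the fitter may
still free `c`). Per-sample Gaussian noise (default SD 0.02 N) is added,
then forces are quantized to the 0.077 g sensor step and clipped at zero.

Two parameterization modes exist because the published absolute rows (P0,
P1, Pplat) and ratio rows (RCP loss %, plateau/P0 %) are means of
per-suture quantities and are *not* mutually consistent when combined
(liver: 0.9/2.6 = 34.6% vs a printed plateau ratio of 40%). `absolute`
draws the three tension levels and derives the ratios; `relative` draws P0
plus the two ratios. Each consumer states its mode.

Per-suture parameters are drawn from normals with the profile's mean/SD,
truncated **symmetrically about the mean** (half-width = distance to the
nearer invariant bound) by inverse-CDF sampling. Symmetric truncation cuts
equal mass from both tails, so parameter means are exactly unbiased — a
one-sided cut at zero would bias the liver P0 mean upward by ~11% of its
SD. Ordering constraints (P1 < P0, plateau below P1) condition the
*subordinate* draw, never P0. Two physical bounds keep draws inside the
study's observed regime: P0 is confined to the published 0.7–5.9 N peak
range, and the plateau must leave a CDP loss of at least 5% of P0 (the
smallest printed per-tissue mean gap is 24% of P0) — without the latter,
independent ratio draws occasionally produce sutures with no declining
phase at all, to which a fit-quality claim cannot meaningfully apply.
An admissible interval carrying no probability mass (e.g. ratio rows pinned
inconsistently with zero SD) raises a generation error.

Per-suture parameters are mutually independent within a suture (no
P0–RCP-loss correlation, although such a dependence is plausible), and
collagen content is drawn per suture from the tissue's published mean ± SD,
independent of that suture's mechanics. Consequently the collagen
correlations produced by the generator are purely *between-tissue* effects
diluted by within-tissue noise — the generator reproduces the signs of the
published correlations, not their magnitudes, and the sign is all the
acceptance properties assert. The generator also omits knot-tying
transients, sensor drift, temperature effects and animal-level clustering
(three rabbits with repeated measures); passing tests therefore validate
the analysis pipeline against the stated curve family and noise model, not
against physiological variability beyond it.

## Statistics

Tissue-level rows are mean ± sample SD (n−1); a single-suture tissue
reports a missing SD and suppresses hypothesis tests. Differences across
tissues use the Kruskal–Wallis rank test (tie-corrected H); pairwise
Mann–Whitney tests run only where the omnibus test is significant at 0.05,
and **no multiple-testing correction is applied** — a deliberate mirror of
the original analysis style, stated prominently so pairwise p-values are
read accordingly. The Mann–Whitney U convention counts (x > y) pairs with
ties as ½.

For small pooled samples the p-values are exact: enumeration over all group
assignments of the pooled values (tie-safe) for pooled n ≤ 10
(Kruskal–Wallis) and combined n ≤ 12 (Mann–Whitney); beyond that,
chi-square (k−1 df) and the normal approximation with tie/continuity
correction. The chi-square reference is badly anti-conservative at the
6-per-group scale this package targets (for {1,2,3} vs {4,5,6} it gives
p = 0.0495 where the exact two-sided p is 0.1), which is why the exact
branch exists and is the tested path.

Pearson correlations (two-sided t, n−2 df) relate collagen/protein content
to RCP loss and plateau ratio, computed on pooled per-suture records
(n = 30 scale) as the primary result, with tissue-mean (n = 5) records
emitted as a secondary view. Constant inputs yield a flagged undefined
record, never r = 0.

## Numerical and scale choices

- Decimation is block-mean onto bin centres; it is mean-preserving on
  uniform grids and never interpolates or upsamples.
- Trace files are CSV with a `#` key=value header; floats are written at
  `%.17g` and re-read with round-trip parsing, so read(write(x)) is
  bit-exact.
- Monte-Carlo suites (parameter recovery across 100 seeded cohorts,
  correlation signs across 200 seeded cohorts) run the simulated sensor at
  50 Hz with the study's noise SD and duration. After decimation to the
  1 Hz analysis grid this leaves ~2.2× more residual noise than the full
  250 Hz setting — a deliberately harder condition at a fifth of the cost.
  Single-trace checks and the acceptance script run at the full 250 Hz.
- Seeded `numpy` Generators are threaded through every stochastic step;
  cohorts are bit-reproducible from their seed, and the pipeline embeds the
  seed and a config hash in every artifact.

## Known limitations

- Independence of per-suture parameters understates the structure real
  tissue likely has (peak tension and cutting damage are plausibly
  correlated).
- The plateau is read at 60 minutes by definition; true asymptotic
  behaviour beyond the record is out of scope.
- Published correlation magnitudes (e.g. collagen vs RCP loss) are not
  reproducible without the original raw data; only their signs are
  testable properties here.
- Animal-level clustering is ignored, as in the original analysis style;
  a mixed-effects treatment would be the natural extension.
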