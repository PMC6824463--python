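# Methods

This note documents the models implemented by `oristress`, the default
parameters and why they were chosen, what the built-in generator does and
does not emulate, and the numerical design decisions that shape the
estimators.

## 1. Replication profiling

### Model

Cells released into S phase under replication stress are sequenced in G1 and
in S. In a bin that has replicated in a fraction *f* of cells, S-phase
coverage is proportional to 1 + *f*; G1 coverage is flat. The per-bin
copy-number ratio S/G1 therefore estimates 1 + *f*, and

```
fired_fraction = clamp(copy_number − 1, 0, 1)
```

An origin is scored **fired** when its fired fraction is ≥ 0.20 (the ≥ 20%
of cells convention; equality counts as fired).

### Copy-number estimation (`compute_copy_number`)

Three anchoring modes control the normalization of the S/G1 ratio:

* `none` — plain ratio; correct when libraries are depth-matched (the
  simulator's output is, by construction).
* `total` — S scaled so genome totals match G1; removes sequencing-depth
  imbalance.
* `modal` (file-mode default) — total scaling followed by division by the
  mode of the ratio distribution, so the unreplicated background sits at
  copy number 1 even when much of the genome has replicated.

Three G1-reference modes control the denominator:

* `binwise` (file-mode default) — raw per-bin G1; divides out per-bin
  coverage bias (mappability, GC) at the cost of doubling counting noise.
* `smoothed` — G1 low-pass filtered at 100 kb; corrects slow bias only.
* `flat` — per-chromosome mean G1. This is the minimum-variance choice when
  G1 coverage is uniform, and is the simulation-analysis default
  (`AnalysisConfig.for_simulation()`).

The distinction matters quantitatively. At 30 reads per 1-kb bin, dividing
by the noisy per-bin G1 count contributes an irreducible error of roughly
`sqrt(2/depth)` per bin to the ratio; pooling the G1 reference removes half
of that variance. The per-origin copy number is further averaged over a
±9 kb window of the **raw** ratio (just inside the 10-kb expected fork
travel under HU, so the window stays on the replicated plateau), which
averages counting noise down by another factor of ~√19. With these choices
the firing-fraction mean absolute error at depth 30 and 500 cells is ≈ 0.04
(reported by the acceptance script as `firing_fraction_mae`).

A single smoothed bin at the origin was deliberately **not** used as the
estimator: the sharp-cutoff Fourier filter overshoots at the top of a
20-kb replicated plateau (Gibbs phenomenon, up to ≈ +18% of the step
height, the (2/π)Si(π) constant), which would bias fired fractions upward
by ~0.1 at strongly fired origins. The windowed raw-ratio mean has no such
bias.

### Smoothing (`fourier_smooth`)

Each chromosome is mirror-padded on both sides and transformed with a real
FFT; Fourier components with wavelength **below 20 kb** (the cutoff; bins at
exactly the cutoff are retained) are zeroed. Mirror padding suppresses
wrap-around artifacts at chromosome ends; the DC component is kept so the
chromosome mean is preserved. Missing bins are linearly interpolated before
the transform and re-flagged missing afterwards. Cosine modes symmetric
under the mirror padding pass the filter at machine precision, which the
test suite uses to verify the pass band and stop band exactly.

### Peak calling (`call_peaks`)

A peak is a change point of the smoothed profile's per-bin derivative from
plus to minus that **persists**: every derivative step within 3 kb before
the apex must be ≥ 0 with at least one > 0, and every step within 3 kb
after must be ≤ 0 with at least one < 0 (flat profiles are not peaks; the
windows span `persistence_bp // bin + 1` steps so that strictly more than
3 kb is covered). A short zero-derivative plateau satisfying the rule
yields one peak at the plateau midpoint (lower median). Chromosome-terminal
windows shorter than the persistence distance cannot host a peak. The
implementation is vectorized; the test suite checks it bin-for-bin against
a brute-force transcription of this definition on random piecewise-linear
profiles.

Peak width (FWHM) is measured on the smoothed profile at half height above
the copy-number-1 baseline, with linear interpolation between bins; peaks
whose flanks run into a valley or chromosome end before crossing half
height are flagged truncated.

## 2. Replication simulation (generator)

The generator is the package's ground-truth instrument. Defaults describe
the study condition: release into S phase under hydroxyurea (HU) with
limited fork travel.

| Parameter | Default | Meaning |
|---|---|---|
| chromosome | 1 × 1 Mb | small test genome |
| bin size | 1 kb | profiling resolution |
| origins | every 25 kb ± 5 kb jitter | 40 origins |
| T_rep | uniform 15–40 min | origin replication timing |
| checkpoint cutoff | 27.5 min | origins with T_rep ≥ cutoff are "late" |
| firing probability | 0.9 permitted / 0.02 suppressed | per cell |
| fork speed | 1.5 kb/min | model default, not a measurement |
| max fork travel | 10 kb | HU-stalled forks |
| S duration | 90 min | sampling time |
| cells | 500 (typical) | population size |
| read depth | 30 / bin | sequencing depth |

Per cell, each origin draws a firing intention; in the HU regime intending
origins fire at release (t = 0). An origin whose position has already been
replicated by an incoming fork is **passively replicated** and does not
count as actively fired. An active origin replicates ±min(fork speed ×
time, max travel); a bin counts as replicated when its midpoint is covered.
Reads are Poisson: G1 ~ Pois(depth), S ~ Pois(depth × (1 + f)).

Origin positions are jittered ±5 kb around the 25-kb grid so that
interorigin distances are non-degenerate (a perfectly regular grid makes
the median spacing identical whether or not extra origins fire). The
minimum origin gap (15 kb) still exceeds the maximal combined extent of the
flanking-gene construction, so annotations never overlap.

**What the generator does not emulate:** replication timing heterogeneity
within an origin class, fork-speed variability, mappability/GC coverage
bias, chromatin context effects on firing, rereplication, and breakage.
These are deliberately out of scope: the generator exists to give the
estimators a known truth, not to be a faithful genome simulator.

## 3. Damage mapping

### Model

The damage-mark IP signal is proportional to the local amount of
replication; at origins flanked by a **convergent** gene pair it is
multiplied by

```
1 + β · (1 + s · (T_rep − T_min))
```

with defaults β = 1 and s = 0.05 /min: later-replicating convergent origins
accumulate disproportionately more damage. Noise is multiplicative
lognormal (sd 0.1) plus a small additive floor; the control (unmodified
histone) track is flat.

### Orientation classification

Replication proceeds outward from the origin, so the leftward fork meets
the left flanking gene head-on iff that gene is transcribed rightward (+),
and the rightward fork meets the right gene head-on iff it is transcribed
leftward (−). A pair is **convergent** when both genes are head-on
(transcribed toward each other across the origin); nonconvergent pairs are
subclassified divergent or codirectional. Origins inside a gene body, or
lacking a flanking gene within 20 kb, are unclassified.

### Estimation

ChIP enrichment is IP/control after equal-total scaling (pseudocount 1);
per-replication damage divides by (smoothed copy number − 1), with bins
replicating in < 5% of cells flagged missing rather than divided. Mean
enrichment within ±2 kb of each classified origin is binned by T_rep
(default edges 15, 20, 25, 30, 35, 40 min) and summarized per orientation
class; `fit_enrichment_trend` reports the origin-count-weighted linear
slope across bin centers.

Because any global scaling of the track multiplies both classes equally,
`estimate_damage_parameters` recovers (β, s) from the
convergent/nonconvergent enrichment **ratio**, which is scale-invariant.

## 4. QFA screening

### Growth model and fitness

Colony density follows the logistic curve g(t) = K·g0·e^{rt} / (K + g0(e^{rt}−1)).
Fits run on log-parameters (positivity) with multi-start
Levenberg–Marquardt, using the overflow-safe form K / (1 + (K/g0 − 1)e^{−rt}).
Fitness combines doubling potential and rate:

```
MDP = log2(K / g0)        (doublings)
MDR = (r / ln 2)(1 − g0/K) (doublings/day)
F   = MDP × MDR
```

A curve that never rises above its inoculum is scored dead (F = 0) rather
than fitted.

### Genetic interaction strength

Per gene, mean control-background fitness and mean query-background fitness
enter a Huber-weighted robust regression ("population line"
F_query ≈ a + b·F_control); robust weighting keeps genuine interactions
from dragging the line. The interaction score is the residual

```
GIS = mean F_query − (a + b · mean F_control)
```

Significance uses a Welch-type statistic whose variance combines the query
replicate error with the control replicate error propagated through the
line (s²_q/n_q + b²·s²_c/n_c, Welch–Satterthwaite degrees of freedom). A
one-sample test against the predicted value alone would ignore the
control-side noise and be anti-conservative by ≈ √2 under the null.
q-values are Benjamini–Hochberg across all testable genes. **Hits** are
genes that are both significant (q < 0.05) and in the top 25% of |GIS|
across all scored genes; negative-GIS hits are enhancers (sicker than
expected), positive suppressors.

Complex enrichment among hits is an upper-tail hypergeometric test per
catalog complex (restricted to the screened universe, minimum two members),
BH-corrected; the test suite verifies it against exhaustive subset
enumeration.

### Generator units

Simulated screens express gene fitness and interaction strength γ in
**relative units** (multiples of the mean control-strain fitness), so
"fitness noise sd 0.05" means 5% of a typical strain's fitness regardless
of the absolute scale (K = 1, g0 = 2⁻⁷, base rate 4/day → absolute scale
F ≈ 40). A query strain's expected relative fitness is a + b·F_control + γ
with a = 0.1, b = 0.85.

## 5. Plasmid topology

Loss rate per generation from the retained-plasmid ratio RMP after G
nonselective generations:

```
loss % / generation = 100 × (1 − RMP^(1/G))
```

with RMP = n_selective / n_nonselective. Confidence intervals are
percentile bootstrap over Binomial(n_nonselective, RMP̂) resamples.

Catenane distributions are normalized band-intensity weights over CatA_n,
n ≥ 1; the summary statistic is the **weighted discrete median** (smallest
n whose cumulative weight reaches one half, with a 10⁻¹² tolerance so an
exact one-half boundary counts). Differences between strains are
median(b) − median(a), with a bootstrap CI from replicate-lane resampling
when lanes exist, otherwise from multinomial resampling at a stated
effective count of 1000 (a stand-in for band-intensity counting noise, not
an estimate of it).

## 6. Open design decisions

* **Problem sizes** in tests and the acceptance script (1-Mb genome, 40
  origins, 400-gene screens, 500-assay round trips) are the package's own
  verification choices, sized so the full suite runs in minutes on one CPU.
* **Estimator defaults** (flat G1 reference and ±9 kb raw-ratio window in
  simulation mode) were fixed from the noise analysis above before the
  validation thresholds were evaluated; file-mode defaults keep the
  conservative bin-wise G1 reference because real coverage is not uniform.
* The **null-screen check** in the acceptance suite simulates replicate
  fitness directly from the generative fitness model rather than refitting
  3,200 growth curves per null screen; the curve-fitting step contributes
  sub-percent fitness error and is validated separately.
* The source literature for this assay family is internally inconsistent
  about the hydroxyurea/phleomycin concentrations used in the damage-mapping
  condition; the package does not model drug concentration at all, only the
  regime (HU-like limited fork travel vs unperturbed), so no resolution is
  attempted here.

## 7. Limitations

* The simulation's per-cell firing model treats origins independently given
  their class probabilities; it has no replication-timing program beyond
  the T_rep cutoff and no fork collapse.
* Fired-fraction recovery degrades below ~20 reads/bin; the reported MAE
  (≈ 0.04 at depth 30, 500 cells) is specific to depth-matched libraries.
* Orientation classification uses only the nearest wholly-flanking genes;
  nested or overlapping transcription units are not modeled.
* The QFA fitness model assumes a shared logistic form across strains;
  diauxic or biphasic growth would need a different parameterization.
* Catenane medians are discrete; bootstrap CIs on the median difference are
  correspondingly step-valued and conservative near ties.
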