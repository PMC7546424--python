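# Methods

`cyanolim` implements the computational chain used to characterise nutrient
(co-)limitation in N2-fixing cyanobacteria and to predict the Pho, Fur and
NtcA regulons of a cyanobacterial genome. This note records the models, the
defaults and the numerical choices, and what the synthetic-data calibration
does and does not demonstrate.

## Growth kinetics

**Exponential fit.** The specific growth rate over an exponential window is
the endpoint log-slope mu = (ln OD_f − ln OD_i)/(T_f − T_i) (day⁻¹), and the
generation time Tg = ln 2 / mu (days). This is deliberately the two-point
formula used in batch-culture practice, not a regression slope: a
user-supplied window is honoured exactly. When no window is given, all
contiguous windows of ≥ 3 points are ranked by endpoint slope subject to
log-linearity R² ≥ 0.95, with ties broken toward the longer window and then
the earlier start; if no window is log-linear enough, the most log-linear
window is used and its R² exposes the problem. Declining cultures yield
mu ≤ 0 and Tg is reported as NaN with a flag, never as a negative time.
Duplicate cultures are fitted per replicate; the treatment-level rate is the
mean and dispersion the spanning range (max − min), the convention for
duplicate designs.

**Quota-Monod model.** Nutrient dependence is mu(Q) = mu′max (Q − Qmin)/Q,
with Q the initial nutrient concentration (units follow the input: e.g. mM
NO3⁻ or µM PO4³⁻), Qmin the minimal concentration supporting growth, and
mu′max (day⁻¹) the asymptotic rate. Fitting is unweighted nonlinear least
squares (`scipy.optimize.curve_fit`), initialised at mu′max = max(mu),
Qmin = min(Q)/2, bounded by mu′max ∈ (0, 10·max mu], Qmin ∈ [0, max Q).
Predicted mu is allowed to be negative below Qmin: extreme-limitation data
genuinely sit in that regime. Under this model the half-velocity
concentration is analytic, K_mu = 2·Qmin, and a bisection cross-check is
exposed (`half_velocity(..., numeric=True)`, agreement ~1e-12 relative).
Because published half-velocity values are often read off the data rather
than the model — and the two conventions disagree — the model-consistent
K_mu and a model-free "empirical K_mu" (the concentration at which a
monotone PCHIP interpolant of the observed points reaches half the observed
maximum rate) are both reported, clearly labelled. Neither is asserted
against any published kinetic table.

## Co-limitation classification

A 2×2 addition design (control, +A, +B, +AB) is summarised by log response
ratios of cell means against the control mean (Eqs. in
`colimitation.log_responses`). Per-replicate ratios are emitted for
plotting but do not vote. The critical threshold — the minimum |log ratio|
significant at level alpha (default 0.05) — is a delta-method construction:
with pooled per-cell variance s² (df = total replicates − 4) and control
mean m₀, SE = sqrt(s²(1/n_t + 1/n₀))/m₀ and the threshold is
t_{1−alpha/2, df}·SE. The construction is pluggable: a user-supplied
constant threshold overrides it, which is also how the calibration
experiments below operate. Designs with single replicates carry no
dispersion and require an external pooled variance. Ratios involving any
non-positive rate are rejected rather than offset-corrected, since silent
offsets distort log ratios.

Each response is trichotomised against ±threshold and the sign pattern maps
to the limitation taxonomy: (+,0,+) serial A-then-B, (0,+,+) serial
B-then-A, (+,+,+) independent co-limitation, (0,0,+) simultaneous
co-limitation, single and negative responses, (0,0,0) no response; any
other pattern is labelled `unclassified(<pattern>)` verbatim rather than
forced into a category.

## Motif models and regulon prediction

**Model building.** From ≥ 2 aligned sites (alphabet ACGTN; N spreads 0.25
to each base) the model holds counts, the PFM, a log2-odds PWM against a
background composition (uniform by default; the genome's mononucleotide
composition for scanning), and per-column information content
IC = 2 + Σ p log2 p bits. The total pseudocount (default 0.5) is
distributed by background frequency. Variable-length collections are
reduced deterministically to the modal site length: a seed model from the
modal-length sites picks each longer site's best-scoring window (leftmost
on ties), the model is rebuilt, and the window choice is repeated once.
This is a desk-scale, deterministic stand-in for de novo width selection;
no further motif discovery is attempted.

**Consensus rendering.** Majority base per column; columns with
IC < 0.25 bits render as `N`; columns whose two top bases are within
`tie_fraction` (default 0.10) render as `[X/Y]`.

**Exact score p-values.** The null distribution of the PWM score of a
background-random word is computed exactly by dynamic programming over a
discretised score lattice (bin ≤ 0.01 bits; column scores are rounded to
the lattice once, so the DP is an exact convolution of the rounded score
and agrees with brute-force enumeration to float accumulation error —
tested at ≤ 1e-12 for width 6). The hard width cap is 32 with a lattice-
size guard; wider motifs need a coarser bin. A hit threshold is a p-value
(default 1e-4), which is comparable across motifs of different widths where
a raw score is not. A low-information motif may be unable to reach a
requested p-value at all (an 8-informative-column motif bottoms out near
3e-5); the threshold then sits above the lattice maximum and the scan
correctly returns nothing — a property, not an error.

**Scanning and assignment.** Both strands of every contig are scanned;
reverse-strand hits report the forward-strand position of the leftmost base
and the matched sequence in motif orientation; ambiguous bases score as the
background-weighted column average. Hits are assigned to every gene whose
promoter window — translation start −800 bp to +40 bp, inclusive at both
ends, measured on the gene's coding strand from the motif's 5′-most base —
contains them. Translation start is used because gene coordinates are what
annotations provide; transcription starts are not assumed. A hit between
divergently transcribed genes is assigned to both; overlapping hits are all
reported, and regulon membership deduplicates at the gene level. COG
histograms split a k-letter gene 1/k per letter and renormalise over
annotated genes. Coordinates are 0-based half-open internally; GFF3 I/O
converts from 1-based inclusive.

## Assay conversions

ARA: N2-fixation rate = ethylene / incubation time / 4 (the 4:1
acetylene:N2 molar factor) / normalizer (cells or nmol total chlorophyll),
with the per-ml bulk rate exposed as an intermediate; ethylene at or below
a configurable detection limit (default 0) reports "undetectable". ROS:
ordinary least-squares slope of blank-corrected fluorescence vs time per
cell, in AU cell⁻¹ min⁻¹ with an hourly accessor (the per-minute base is
the measurement grid; the choice is carried explicitly because conventions
vary). Blanks on a matching time grid are subtracted pointwise; otherwise
the blank's own fitted slope is subtracted. Negative slopes are reported
as-is with a flag.

## Synthetic data and what the calibration shows

Generators are pure functions of `SimConfig`; each draws from its own
stream derived from the master seed, so adding a generator never perturbs
existing fixtures.

* **Growth:** OD(t) = K·OD₀e^{mu t}/(K + OD₀(e^{mu t} − 1)) — exponential
  while OD ≪ K, saturating beyond — with multiplicative lognormal noise
  (sd 0.02 by default), duplicates per treatment, 6 points at 2-day
  spacing, OD₀ = 0.2. Defaults mirror a 10-day batch experiment read every
  other day.
* **Factorial designs:** cell means realise the planted category's sign
  pattern with log-scale margins equal to the effect size; duplicate
  replicates get lognormal noise (sd 0.05). Recovery experiments define the
  effect as a multiple of the design's known population threshold and hand
  that threshold to the classifier, isolating the sign-pattern mapping from
  threshold-estimation noise (the effect multiple is only well-defined
  against a known threshold).
* **Genomes:** 100 kb, i.i.d. background at GC 0.45, 80 genes of 900 bp on
  alternating strands with exponential intergenic gaps (mean 350 bp, min
  60 bp) — a desk-scale stand-in for a ~4 Mb cyanobacterial genome. Planted
  sites honour strand (minus-strand genes receive the reverse complement)
  and collide loudly. Ground-truth regulons are computed by direct
  coordinate arithmetic over all genes, so a site in a shared divergent
  promoter counts for both neighbours.

The calibration battery (`cyanolim.benchmarks`, re-run by
`scripts/acceptance.py`) checks: DP ≡ enumeration for the score null;
100% recovery of consensus plantings at p ≤ 1e-5 on 100 kb with background
hits inside the Poisson band of 2·L·p; ≥ 95% planted-category recovery at
effect 3× threshold over 500 designs per category (false-positive category
calls at effect 0 stay within alpha + 3 points); exact noiseless Monod
inversion and < 5% median mu′max error at sigma 0.02 with 9 points over 200
curves; and mu recovery within ±0.03 day⁻¹ from noisy OD curves. Problem
sizes (100 kb genomes, 200–500 Monte-Carlo repeats) are chosen as the
smallest at which these rates are stable across seeds.

What passing does **not** show: real OD series have lag phases, pigment
drift and instrument error structure the logistic-plus-lognormal generator
lacks; real promoters are not i.i.d. background (composition bias, repeats
and operon structure inflate false positives); binding sites co-evolve with
their genomes, so a model pooled across genera scans a single genome with
unknown sensitivity; and the classifier calibration assumes roughly
lognormal replicate noise. Genome-scale hit and regulon-size counts from
third-party scanners depend on their internal thresholds and on genome
version, and are out of scope here.

## Known limitations

* The exponential-window auto-selection is a heuristic; pathological curves
  (double exponential phases) resolve by the stated tie-breaks, which may
  not match a human's choice. Supply a window to override.
* The delta-method threshold is first-order; with very few replicates and
  large coefficients of variation its alpha calibration is approximate
  (checked by simulation at study-like noise, within ~3 points).
* The empirical half-velocity is interpolation-based and undefined when the
  data never reach half the observed maximum.
* Site trimming assumes the modal-length sites are correctly aligned; it
  does not realign them.
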