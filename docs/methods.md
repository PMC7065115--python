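# Methods

## Model overview

`nipsim` estimates the expected analytical sensitivity of WGS-based NIPS
for T13/T18/T21 as a function of maternal BMI by combining two fitted or
simulated components on a common fetal-fraction (FF) grid (0 to 40% in
0.1% steps, both endpoints included):

1. `p(ff | BMI, ploidy)` — a conditional FF distribution,
2. `AS(trisomy, reads, ff)` — the assay's FF-specific analytical
   sensitivity,

and taking `E[AS] = Σ_ff AS(ff) · p(ff)` with `p` renormalized to sum to 1
over the FF window under study. A failure-threshold policy replaces
`AS(ff)` by 0 for `ff` strictly below the cutoff, modelling laboratories
that report no result on low-FF samples (a missed trisomy among failed
samples counts against sensitivity).

## Conditional FF model

Assumptions, in decreasing order of confidence:

- **Beta scatter.** At fixed BMI and ploidy, FF is beta-distributed. The
  concentration `ν = α + β` is taken from a single pooled maximum-likelihood
  fit to euploid FF (method-of-moments start) and held constant across BMI;
  only the mean moves, along the euploid OLS line `μ = m·BMI + b`, clipped
  to (0.001, 0.5) so the beta parameters stay valid where the line
  extrapolates outside the unit interval. Holding `ν` fixed mirrors the
  observation that the FF distribution's shape is roughly conserved across
  BMI classes while its location shifts left.
- **Rank-space reweighting for trisomies.** Each aneuploid sample's FF is
  converted to its percentile rank `u = F_eu(ff | BMI)` under the euploid
  law for its own BMI; ranking removes the BMI effect, so ranks are pooled
  across BMI. A beta density `g` on [0, 1] is fitted to the ranks — a
  parametric choice that stays boundary-safe with a few hundred aneuploid
  samples where a KDE would leak mass outside [0, 1]. The trisomy's
  conditional law at any BMI is then the euploid beta reweighted by
  `g(F_eu(ff))`. Uniform `g` reproduces the euploid law exactly; the fitted
  densities put T13/T18 mass at low ranks (lower FF) and T21 mass at high
  ranks. This rank-reweighting construction is the module's one structural
  assumption.
- **Discretization.** Grid probabilities are exact cell integrals computed
  through the rank-space CDF: the mass at grid point `ff_i` is
  `G(F(ff_i + h/2)) − G(F(ff_i − h/2))` with `h` = 0.001 and `G` the fitted
  rank-beta CDF (identity for euploid). This equals "density × step" to
  second order in the interior but remains finite at `ff → 0`, where the
  beta density itself diverges once `α < 1` (which the pooled fit produces
  at extreme BMI). Restricting to a narrower window and renormalizing is
  exactly consistent with computing on the narrow window directly.

BMI classes use the half-open clinical intervals [25, 30), [30, 35),
[35, 40), with BMI ≥ 40 class III; a BMI of exactly 25 is overweight.
BMI is weight(kg)/height(m)²; inputs outside (1.0, 2.5) m or (30, 350) kg
are rejected as suspected unit mix-ups rather than silently converted.

## WGS caller simulation

Reads are spread uniformly over `B_total` = ⌊2,875,001,522 / 50,000⌋ bins
tiling the autosomes (GRCh38-derived lengths; chr13 2287, chr18 1607,
chr21 934 bins at the 50-kb default), giving per-bin depth
`λ = effective_reads / B_total`. A trisomic chromosome's bins are Poisson
at `λ(1 + ff/2)`: the fetal compartment contributes fraction `ff` of the
DNA at a 3/2 copy ratio. The per-chromosome statistic (median bin count by
default; mean optionally) is standardized against the mean and SD of a
simulated euploid reference panel (default 10,000 samples) and called
positive one-sided at `z ≥ 3`.

**Effective depth.** Real bin counts are overdispersed. Dividing by a
single scale factor — the index of dispersion (variance/mean), floored at
1 — maps them onto a Poisson regime; the simulator always runs at
`effective_reads = raw_reads / scale`. The calibration reports the total
variation distance between the rescaled count histogram and the matched
Poisson pmf as its goodness-of-fit. The synthetic count generator uses a
gamma-Poisson mixture, for which this rescaling is exact in the first two
moments.

**Sampling shortcut.** The statistic is drawn without materializing bins:
the mean of `B` iid Poisson bins is `Poisson(Bλ)/B` exactly, and the median
is drawn by the order-statistic quantile transform — the middle order
statistic of `B` uniforms is Beta((B+1)/2, (B+1)/2) for odd `B` (the
consecutive middle pair is drawn jointly for even `B`), and pushing it
through the Poisson quantile function reproduces the binned median's
distribution exactly, including its half-integer lattice. A test verifies
the equivalence against direct bin simulation. This is what makes
401-point curves at thousands of replicates and million-replicate null
rates run in seconds on one CPU.

**Median lattice caveat.** On raw integer counts the median lives on a
half-integer lattice whose spacing is 0.8–1.5 reference SDs at the default
depth (1e7 effective reads). Mid-range sensitivities are only mildly
affected, but *extreme tail* probabilities are quantized: the euploid
false-positive rate at `z ≥ 3` lands wherever the lattice happens to cut
the tail (≈0.00% for chr13/chr18, ≈0.06% for chr21) rather than at the
continuous-normal 0.135%, and the chromosome-size ordering of sensitivity
can locally invert at low FF. Production NIPS pipelines median over
*normalized* (continuous) bin depths and do not show this artifact. Null
calibration and the size-ordering property are therefore evaluated with
the mean statistic, whose null is continuous-normal to excellent
approximation; reported sensitivity curves keep the median default.

## Synthetic cohorts

The generator's defaults define the study conditions:

- FF~BMI fits (slope per BMI unit, intercept): euploid (−0.0024, 0.156),
  T13 (−0.0030, 0.156), T18 (−0.0033, 0.165), T21 (−0.0025, 0.164).
- FF beta concentration ν = 30 (free parameter: the underlying per-class
  beta shapes are not published; ν = 30 reproduces a realistic pooled FF
  spread, SD ≈ 5 percentage points at mean 9%).
- Trisomy prevalences T13 1/4000, T18 1/1500, T21 1/500 (population-scale
  generator defaults, not derived from the modelled cohort). Analyses that
  need hundreds of aneuploid records per trisomy to fit percentile shifts
  enrich these to ~1–2% explicitly.
- Ethnicity-specific lognormal BMI mixture (12 codes). Weights and
  locations are qualitative: obesity rates are highest for African, Native
  American and Hispanic strata and lowest for East/Southeast Asian strata.
  Only the induced BMI spread (population SD ≈ 5–6 kg/m²) matters
  downstream.
- Bin-count dispersion φ = 1.8 at 1.8e7 raw reads, so calibration lands at
  1e7 effective reads, the simulator's default depth. The depth default is
  a design choice tuned only to make sensitivity curves rise across the
  0–4% FF window (50% detection near 1.5–2% FF), matching the qualitative
  behaviour of contemporary WGS NIPS assays.

What the generator does **not** emulate: GC-content and mappability
structure, sequencing error, gestational-age FF drift, sex-chromosome
aneuploidies, mosaicism, twins. Tests passing on synthetic cohorts
demonstrate the pipeline's statistical correctness under the stated model,
not the clinical performance of any real assay.

## Numerical choices

- OLS fits use `scipy.stats.linregress`; slope standard errors feed the
  "recovery within 3 SE" checks.
- Beta MLE (`scipy.stats.beta.fit`, location/scale frozen) starts from the
  closed-form method-of-moments estimate; values at exactly 0/1 are
  clipped to [1e-6, 1−1e-6] with a warning inside the fitter only — file
  input with FF outside (0, 1) is rejected outright.
- `expected_as` refuses mismatched grids rather than resampling.
- Sample-size arithmetic (`cohort_size_requirement`) snaps float
  frequencies to shortest-decimal fractions and uses exact rational
  arithmetic, so 100/(0.1·0.02·0.01) is exactly 5,000,000.
- Superiority flags against non-DNA screening use strict inequality; ties
  report "not above".
- Per-grid-point Monte Carlo uses independent spawned substreams of one
  seed sequence; every public sampler is deterministic given its seed.

## Known limitations

The fixed-concentration linear-mean beta, extrapolated to BMI ≈ 50, puts
substantial probability on FF below 1% (the T18 trend line even reaches
mean FF ≈ 0 at BMI 50). Real class-III cohorts are dominated by BMI 40–43
and do not show this much near-zero FF mass; per-class empirical fits
would temper it. Consequently BMI-stratified expected sensitivities
computed here for BMI ≳ 45 are conservative — dominated by model
extrapolation rather than by assay physics — and the class-III sensitivity
floor reported by the acceptance script is far below what per-class
empirical FF distributions would give. The percentile-shift densities are
pooled across BMI classes; a per-class option would need materially more
aneuploid samples than the prevalence-realistic cohorts provide.
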