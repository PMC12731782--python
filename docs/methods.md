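# Methods

`clcassay` reimplements, as a tested library, the analysis chain used to
detect dominant effects of ClC-4 disease variants inside heteromeric
ClC-3/ClC-4 transporters: voltage-clamp trace processing, within-batch
ratio normalization with slope-based phenotype calls, a silenced-subunit
assay, an acidic-pH gain-of-function assay, phasor FLIM-FRET lifetime
analysis, and the statistical layer. Because no recordings are deposited,
the package ships a synthetic-data generator whose outputs carry the
statistical and biophysical structure the analysis assumes; every pipeline
stage is exercised end to end against it.

## Transport model behind the generator

CLC transporters are dimers with one transport pathway per protomer and a
shared ("common") gate that shuts both pathways at once. The generator
models the quasi-steady-state current of a dimer as

    I(V) = n_active · i_unit · p(V) · d(V),
    p(V) = 1 / (1 + exp(-(V - V½)/k)),      d(V) = V / 100 mV,

where `n_active` counts transport-competent protomers (0-2), `i_unit` is
the per-protomer current at the +100 mV reference driving force, `p` is a
Boltzmann open probability for the common gate (the minimal form that
saturates at large positive voltages, the qualitative behaviour these
transporters show), and the driving force is linear and zero at the 0 mV
holding potential. No transport-cycle kinetics are modelled: each voltage
step is treated as instantaneously at steady state, which is also why the
P/N-corrected simulated sweeps are exactly flat within a step.

Co-expression of subunits A (reference, ClC-3-like) and B (variant
ClC-4-like) at expression ratio r produces a binomial mixture of dimers
a²:2ab:b² with a = r/(1+r) — independent pairing, with no assembly bias.
A **dominant** variant shifts the common-gate V½ of *every dimer
containing it* by its full `dv_half`; its `amp_factor` scales only its own
protomer's transport. Silencing the partner subunit (the proton-glutamate
alanine mutant, which dimerizes but cannot transport) zeroes that
protomer's transport without changing the dimer fractions. Gain-of-function
variants add, at acidic pH only, an inward current
`-g_gof · max(0, -(V - V_rev))` carried by variant-containing heterodimers.

### Variant parameter defaults

The study's figures show ratio curves and bar charts without printed shift
magnitudes, so the library's per-variant ΔV½ values are calibrated
defaults, not measurements. They were chosen once so that, at the reported
study size (3 batches × 6-8 oocytes per construct) and under the default
expression variability below, the silenced-subunit assay resolves the
reported graded reduction (K560E strongest, G545S intermediate, R360S
least) reliably — i.e. the generator reproduces the qualitative outcome
the assay is known to detect at that n:

| variant | ΔV½ (mV) | amp_factor | g_gof (µS) |
|---|---|---|---|
| WT    | 0   | 1 | 0 |
| R360S | +10 | 0 | 1.5 |
| V536M | +30 | 1 | 0 |
| G545S | +60 | 1 | 0 |
| K560E | +130 | 1 | 0 |

With smaller spacings (e.g. +20/+40/+60) the three-group ordering at
n = 3×7 is a coin-flip against the per-cell expression scatter; spacings
of this size are within the range reported for dominant common-gate
mutations of muscle-type CLC channels. All values are plain constructor
arguments and can be overridden per analysis.

## Recording simulation

A simulated cell's raw sweep family is

    model IV × (per-cell lognormal expression, σ = 0.3)
             × (per-batch lognormal factor, σ = 0.2)
    + ohmic leak g·V          (g ~ N(1.0, 0.3²) µS, clipped at 0)
    + capacitive transient    (single exponential at each step edge,
                               amplitude 0.01 µA/mV of jump, τ = 0.2 ms)
    + Gaussian noise          (SD 0.05 µA per sample)

sampled at 100 kHz: 5 ms steps from +200 to -40 mV in -10 mV increments
from a 0 mV holding potential, with 2 ms pre/post segments. The P/N
companion is the same acquisition at 0.2× command voltages containing only
the linear components (leak, capacitive transient) plus full-amplitude
noise — instrument noise does not scale with the stimulus. Batch factors
are shared by all constructs measured in a batch, which is precisely what
within-batch normalization exploits. The acidic-pH assay uses a
+160..-160 mV ladder with the same 10 mV step convention; paired
recordings of one cell at pH 7.3/5.3 share expression and leak and differ
only in noise (and the GoF term). All randomness derives from one integer
seed via per-batch/cell/pixel SeedSequence keys; outputs are byte-stable.

The IV-level generators (`simulate_iv_cells`, `simulate_paired_iv_cells`)
produce steady-state values directly with an effective noise SD of
0.02 µA — the value the sweep-level pipeline delivers after P/N
subtraction (×√26 noise inflation) and last-third averaging — for
replicate studies where simulating every sample is wasteful.

What the generator deliberately omits: series-resistance and space-clamp
errors, endogenous oocyte conductances, biological (nonlinear) capacitive
currents, rundown, pH-dependence of the transport cycle itself, and any
instrument response function on the FLIM side. Passing tests therefore
demonstrate correctness of the analysis chain under its stated
assumptions, not robustness to these real-data pathologies.

## Trace processing

* P/N correction: `corrected = raw - pn / pn_scale`, per sample.
* Steady state: mean over the last third of the step segment, indices
  `[floor(2L/3), L)` (the rounding convention is ours; the source
  convention is unstated). Uncorrected sweeps are refused unless a
  diagnostic flag is set.
* Per-sweep measurement-noise SEs are estimated from the within-window
  sample variance and carried on every IV curve; they feed the reference
  gate below.
* Units: oocyte currents in µA, whole-cell in pA, densities in pA/pF
  (per-cell capacitance division; zero/negative/missing capacitance is a
  hard error). Leak-line slopes are reported in current units per mV.

## Ratio normalization and phenotype calls

For each batch, the variant group's mean current at every voltage is
divided by the matched reference group's mean at the same voltage
(batches pair by identifier). Voltages where a batch's reference mean is
within 5 measurement-noise SEs of zero are masked — tiny denominators make
the ratio meaningless. A `per_cell_ratios` flag switches to averaging
per-cell ratios instead of dividing batch means (the two coincide for
balanced noise-free data; batch-mean division is the default).

Classification of the pooled curve (ordered rules):

1. `below_reference_control` — pooled ratio at the top three voltages
   under a configurable floor (default 0.3).
2. `positive_shift` / `negative_slope_gof` — the ratio-vs-voltage slope CI
   excludes zero, by sign.
3. `uniform_reduction` — mean ratio < 0.8 with a flat slope.
4. `wt_like` otherwise.

Slope inference uses a weighted ANCOVA: one intercept per batch plus a
common slope. Expression and batch factors scale a batch's entire ratio
curve multiplicatively, so the batch intercepts absorb them exactly and
the residuals are the independent per-voltage measurement noise; points
are weighted by delta-method ratio SEs propagated from the steady-state
noise estimates (low-voltage ratios near the mask boundary are an order of
magnitude noisier and would otherwise dominate through their leverage).
Two designs we rejected: a pooled fit without batch intercepts
(batch-level scatter masquerades as slope evidence — anticonservative) and
a t-interval over per-batch slopes (valid but df = n_batches - 1 ≈ 2,
severely underpowered). The default call threshold is α = 0.01 rather
than a conventional 95% interval: a categorical phenotype label warrants
high specificity, and the weighted-ANCOVA test has power to spare
(measured on the default synthetic study: 296/300 null replicates called
`wt_like`, 300/300 replicates of a +40 mV dominant shift called
`positive_shift`). Every threshold is a keyword argument; every call
carries a decision trace naming the rule that fired.

The silenced-subunit assay normalizes each variant cell's +170 mV current
to the same batch's silenced-WT control mean and reports mean/SD/n; a
batch without reference cells is a hard error.

## Acidic-pH assay

Per cell: fit the pH 7.3 IV with a straight line over -120..0 mV (at
neutral pH, current below 0 mV is assumed pure leak), extrapolate to all
voltages, subtract from every condition, and normalize to the cell's
leak-subtracted pH 7.3 current at +160 mV. Using the leak-subtracted
denominator (the wording of the source convention is ambiguous between raw
and subtracted) makes the pipeline exactly invariant to per-cell
expression scaling; a `raw_denominator` flag gives the alternative. A
non-positive denominator is a hard error. Groups are compared voltage by
voltage for V ≤ 20 mV with Welch's t-test and star annotations, with no
multiplicity correction — deliberately liberal, mirroring per-voltage
star presentation conventions; treat isolated single-voltage stars
accordingly. The inward gain-of-function signature is expected at the
voltages below the leak-fit range (V < -120 mV), where the subtraction is
an extrapolation and the GoF term is largest.

## Phasor FLIM-FRET

Per pixel, the photon-count decay histogram c_k over one 80 MHz excitation
period is reduced to first-harmonic phasor coordinates

    G = Σ c_k cos(ω t_k) / Σ c_k,   S = Σ c_k sin(ω t_k) / Σ c_k,

with t_k the bin centres and ω = 2πf. Monoexponential decays lie on the
universal semicircle, G = 1/(1+(ωτ)²), S = ωτ/(1+(ωτ)²). Pixels below a
photon floor (default 20) are masked, not NaN-propagated. The predominant
cluster in the (G, S) density map (histogram bin width 0.005) is located
at the modal bin, sized by a local moment estimate, and fitted with a 2-D
Gaussian within ±5σ; non-convergence falls back to the weighted centroid,
flagged. The lifetime is τ = S/(2πfG) and FRET efficiency
E = 1 - τ_DA/τ_D from donor-only and donor+acceptor ROI lifetimes
(negative E — lifetime lengthening — is flagged, not rejected). ROIs are
labels with masks supplied in the sidecar; there is no segmentation, no
IRF deconvolution, no multi-exponential unmixing.

The simulator draws Poisson counts around a *bin-integrated*,
period-wrapped exponential. Wrapping the tail makes the continuous
first-harmonic coefficient exactly the semicircle value, and bin
integration (rather than point sampling) suppresses the alias term of the
discrete transform by an extra factor ~1/n_bins, so at 4096 bins the
transform matches the closed form to ~1e-6 — numerically verified in the
tests at that tolerance.

## Statistics

* **Ratio t-test** (for values normalized to different control batches):
  an unpaired two-sample t-test on natural-log values — the standard
  meaning of a ratio t-test in its unpaired form, since each construct has
  its own control batches. Nonpositive values cannot be logged and raise;
  a `log=False` flag gives the raw-scale test for sensitivity analysis.
  Type-I error at n = 8 vs 8 under a lognormal null measures ~0.047 at
  α = 0.05 over 10⁴ repetitions.
* Welch (unequal variance) is the default two-sample form; pooled-variance
  Student available by flag.
* **ANOVA + Tukey HSD** for absolute current groups, with a per-voltage
  helper restricted to V ≥ 30 mV (below that, currents are too small for
  meaningful comparison).
* **Stars**: none p ≥ 0.05, `*` p < 0.05, `**` p < 0.01, `***` p < 0.001,
  strict inequalities (p = 0.05 earns no star).
* Zero-variance degenerate groups raise rather than reporting p = 0.
* Reports (JSON + markdown) embed seed, config and a provenance hash;
  identical inputs reproduce identical reports.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the full pipeline at the study's
own scale: 3 batches × 6-8 cells per group for ratio phenotyping (100
replicates per scenario), n = 9 vs 13 for the acidic-pH comparison (200
replicates, effect sized at 3× the group-difference SE from a 400-cell
null pilot), 10⁴ t-test repetitions, and 2000-pixel decay images at 10⁴
photons/pixel. These sizes keep a full run in the minutes range on one
core while leaving the stochastic pass criteria well-determined.

## Known limitations

* The Boltzmann/linear-driving-force transport model is the simplest form
  consistent with saturating outward rectification; it is not a kinetic
  cycle model and does not reproduce capacitive "gating-glutamate"
  transients (out of scope by design).
* ΔV½ defaults are calibrated placeholders (above), not measured values.
* The per-voltage GoF comparison is intentionally uncorrected for multiple
  testing.
* Phasor histogram binning and the Gaussian-fit window are declared
  defaults; the original custom acquisition software's choices are
  unknown.
* TMEM9/TMEM9B modulation, vacuolation biology, and imaging-hardware
  effects are not modelled.
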