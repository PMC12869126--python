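# Methods

## The data model

A recording session is ten synchronized channels on one implicit time
grid (`index × sampling_interval`; 10 Hz by default — instrument rates
vary, so the interval is a free parameter). Synchrony is structural:
there are no per-channel timestamps. Three physical couplings are
validated elementwise rather than assumed, because instrument glitches
break them independently per channel:

- hemoglobin conservation: `HB_TOTAL = HB_OXY + HB_RED`,
- band additivity: `BP_TOTAL = BP_LOW + BP_MID + BP_HIGH`,
- saturation consistency: `SO2 = 100 · HB_OXY / HB_TOTAL` where
  `HB_TOTAL > 0`.

Conservation checks use a relative tolerance (default 1e-6, suited to
the exactly consistent generator output; loosen for noisy instrument
exports) with an absolute floor of 1e-9 so zero-valued samples cannot
trip the relative criterion. C_RBC and SO₂ are percentages in [0, 100],
matching how instruments print them; they are never rescaled to
fractions internally.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the optics of the probe. Per sample, each channel is its
group-adjusted baseline plus Gaussian noise; derived channels are
constructed exactly (sums and ratios), so a generated session always
validates.

**What it emulates.** Channel scales typical of pancreatic
recordings (C_RBC ≈ 2%, SO₂ ≈ 65%, total Hb ≈ 60 µM, band perfusion
10/25/15 %RBC·mm/s, conventional perfusion ≈ 120 PU); vasomotion as a
sinusoid (control 12 cycles/min) riding on total perfusion; group
effects as multipliers/shifts; a controllable perfusion–oxygenation
coupling. **What it does not emulate:** 1/f broadband structure, the
multi-band spectral content of real vasomotion (cardiac, respiratory,
myogenic, neurogenic, endothelial components), probe drift,
movement artifacts with temporal structure, or inter-subject baseline
heterogeneity (subjects differ only by noise realization and phase).
Passing tests therefore demonstrate correctness of the computations
under the stated statistical model, not robustness to every feature of
real instrument data.

**Correlation induction.** With independent standard normals `L`
(latent driver) and `e`, the low-speed-band noise is `L` and the
oxygenized-Hb noise is `(wL + e)/√(1+w²)`, giving population
correlation `w/√(1+w²)`; the weight `w = r/√(1−r²)` hits the target
`r` (default 0.5) exactly in expectation. A shared driver, rather than
post-hoc reordering, keeps the temporal structure of both channels
intact.

**Vasomotion placement.** The sinusoid (amplitude 15% of the adjusted
mid+high baseline, random phase per subject) is carried by the mid- and
high-speed bands in proportion to their baselines. The low-speed band
carries the latent driver instead: adding an oscillation there would
inflate its variance with a component uncorrelated with oxygenized Hb
and attenuate the induced correlation below its target. Total perfusion,
as the band sum, still carries the full oscillation. Physiologically
this reads as vasomotion modulating the faster, transport-oriented
flow while the slow nutritive flow couples to oxygen delivery — a
simplification, made for statistical control, and stated here as such.

**Group profiles.** The diseased profile lowers the high-speed band to
0.60, shifts SO₂ by −10 points, scales C_RBC and Hb by 0.80, and slows
vasomotion to 0.7×. Treated profiles interpolate toward control with
the two-week incretin course closest (e.g. high band 0.95, SO₂ −1.5);
the interpolation ordering mirrors the qualitative recovery pattern the
framework is meant to resolve, and the exact numbers are package
choices, fixed once. Artifacts are injected after construction and
deliberately not repaired, so conservation violations remain detectable.
C_RBC/SO₂ are clipped into [0, 100] after noise addition; clip events
are logged at debug level (at the default noise scales they are
vanishingly rare).

## Preprocessing

Quartiles use linear interpolation between order statistics at positions
`(n−1)·p` — numpy's default, R's type 7. The convention is pinned
because the fences, and hence which samples are winsorized, differ
across quantile conventions. Fences are `Q1 − 1.5·IQR` and
`Q3 + 1.5·IQR`, computed once from the raw values; winsorization is a
single pass (no iterative re-fencing), replaces only strict exceedances
with the nearer fence, and never changes the sample count. Repeated
application is not guaranteed to be a fixed point in general (adjusting
values changes the quartiles); the single pass is the contract, and a
property test checks the conditional form (a second pass that finds no
new exceedances changes nothing). At least four samples are required —
below that, interpolated quartiles are dominated by single observations.

Length uniformization repeats every sample of channel `i` exactly
`LCM/len_i` times — integer repetition is the only scheme consistent
with a least-common-multiple target. The LCM of near-coprime lengths
explodes, so a cap (default 10⁶) turns pathological inputs into an
explicit error advising resampling. Winsorization runs before
uniformization: fencing repeated data would triple-count repeated
extremes.

## Normalization

Z-score uses the population standard deviation (divisor `n`), the
natural reading of the σ symbol; the sample-sd variant would be the
other defensible choice and differs by `√(n/(n−1))`. Each transform is
applied per channel over the session timeline (not across channels at a
time point). Degenerate inputs — zero spread, zero norm, zero median —
raise a typed error; the comparison operation converts these to
"inapplicable" flags instead of failing, since a constant channel should
not abort a cohort-level comparison. Min–max is recommended whenever
every channel admits it: it is the only one of the four with a fixed
bounded output interval, which is what makes channels with 100-fold
scale differences directly comparable on one axis. Median scaling is
implemented as pure scaling (`x/Me`), its printed form, although it is
sometimes described as centering-and-scaling.

## Metrics

Band shares are taken against the sum of the three band means rather
than the recorded total channel, so shares always total exactly 100%
even if the total channel carried independent noise. The oxy/red split
is likewise computed from the two component means.

`Mvel = Mbp / C_RBC` uses C_RBC as the printed percent value (2.0, not
0.02) — the formula's symbols are used as printed, and the choice is
fixed here because it changes Mvel by 100×. `IMR = Mbp/(Mvel·Mfre·S)`
takes session time-means as its scalar inputs. S defaults to 0.15 so
that it shares the millimetre length unit with Mvel; the value is
configurable together with a unit tag, and passing the bare 150 (µm)
simply scales IMR by 1/1000. The composite's units are not standardized;
IMR is reported unitless with the S unit logged. Note the algebraic
consequence of the coupling: `IMR = C_RBC/(Mfre·S)`, i.e. the index is
invariant to joint rescaling of perfusion and rises when red-cell
content grows relative to vasomotion-driven throughput.

**Oscillation counting.** Mfre is one count per upward crossing of the
mean, with a Schmitt-trigger hysteresis band of ±0.75 detrended standard
deviations: a crossing is registered only when the signal passes from
below −h to above +h. Zero-hysteresis crossing counts every noise
wiggle near the mean as an oscillation and overcounts by ~15% at the
generator's default noise-to-amplitude ratio; the hysteresis form is
the standard robust variant, leaves clean-sinusoid counts exact, and
recovers the generator's group frequencies to within a few percent. A
periodogram peak serves as an independent cross-check in the test
suite, never as the implementation. A constant trace has rate zero; at
least two full cycles of the rhythm of interest should be recorded for
a meaningful estimate.

## Coherence

Joint binning uses 10 equal-width intervals per variable, half-open with
a closed last interval so the maximum is never dropped. Bin ranges are
pooled across all groups by default so per-group matrices share
intervals and are directly comparable; per-group ranges are available by
flag. Chord payloads export proportions (arc widths = marginals /
n_pairs; chord widths = joint / n_pairs) with raw counts retained, since
either reading of "width" may be wanted by a renderer. Interval-
conditioned sub-diagrams are a payload filter, not separate graphics.

Correlations pool each channel's synchronized samples across the
subjects of a group (matching a per-group analysis with large n), use
Pearson r with the two-sided p-value from `t = r√((n−2)/(1−r²))`, and
flag a pair relevant when `p < 0.05` and `|r| > 0.4`. No
multiple-testing correction is applied — the relevance rule is a plain
per-pair threshold, and with 45 pairs at large pooled n the p-threshold
is rarely the binding constraint anyway; consumers needing family-wise
control should apply it downstream. The dendrogram order comes from
average-linkage clustering on `1 − |r|` (linkage choice is open in this
kind of analysis; average linkage is the common default and is
configurable in the API). Constant channels yield undefined (NaN)
correlations, flagged not-relevant rather than fatal, and are placed at
distance 1 from everything for ordering purposes.

## Pipeline and determinism

The pipeline is a pure function of its configuration document: the
master seed drives per-subject seeds through `numpy.random.SeedSequence`
spawning, JSON is written with sorted keys and fixed separators, CSV
floats use the shortest round-trip representation and are read back with
correctly rounded parsing, and manifests contain only the config hash,
seed and package version (no timestamps). Two runs from one config are
byte-identical.

## Problem sizes

Test and acceptance runs use cohorts of 6 × 9 subjects × 2000 samples
(200 s at 10 Hz) — nine subjects per group mirrors the usual size of
such animal studies, and 2000 samples put the pooled per-group n at
18 000, where the standard error of a correlation of 0.5 is ≈ 0.006 and
recovery within ±0.1 is a wide margin. Convergence checks use single
sessions of 5000 samples with a 3-standard-error band.

## Known limitations

- The generator's stationarity and single-frequency vasomotion make the
  Mfre task easier than real recordings with drifting, multi-component
  rhythms; on real data, band-pass filtering before counting may be
  needed.
- Winsorization assumes artifacts are isolated magnitude outliers;
  sustained baseline shifts pass the fence rule untouched.
- LCM sample-repetition changes the effective sampling density of
  repeated channels; statistics weighted per sample (e.g. pooled
  correlations) will weight repeated samples multiply. Equal-length
  acquisition avoids this entirely.
- Group inference (t-tests/ANOVA) is out of scope; the metric tables
  expose per-subject values and descriptive group summaries for use in
  any statistics environment.
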