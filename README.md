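# microcirc

Analysis toolkit for synchronized microcirculatory perfusion and
oxygenation time series.

Combined laser-Doppler flowmetry (LDF) and diffuse reflectance
spectroscopy (DRS) probes record ten channels from one tissue volume at
once: red-blood-cell tissue fraction (C_RBC, %), oxygen saturation
(SO₂, %), total / oxygenized / reduced hemoglobin (µM), blood perfusion
resolved into three red-cell-speed bands (<1, 1–10, >10 mm/s) plus their
total (%RBC·mm/s), and conventional laser-Doppler perfusion (PU).
Because the channels are acquired synchronously, their sample-by-sample
pairing carries physiology — how perfusion sustains tissue oxygenation —
that per-channel averages miss. `microcirc` provides the desk-side
workflow for such recordings, aimed at microvascular physiology labs
studying perfusion–oxygenation coupling (e.g. in diabetic models):

- **validated sessions** — synchrony, physical ranges, hemoglobin
  conservation (HB_total = HB_oxy + HB_red), band additivity and SO₂
  consistency checked, not assumed;
- **a seeded synthetic cohort generator** — six experimental groups
  (control, diabetic, insulin- and incretin-treated at two durations)
  with configurable effect sizes, vasomotion oscillations, a tunable
  induced correlation between oxygenized hemoglobin and low-speed
  perfusion, and artifact injection for recovery studies;
- **preprocessing** — boxplot-fence winsorization
  (values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] moved to the nearest
  fence) and least-common-multiple length uniformization;
- **four dimensionless transforms** — z-score `(x − x̄)/σ`, min–max
  `(x − min)/(max − min)`, L2 `x/‖x‖`, median scaling `x/Me`, with a
  cross-method comparison that recommends min–max whenever all channels
  admit it;
- **metrics** — speed-resolved perfusion shares, oxygenation fractions,
  and the resistance index `IMR = Mbp / (Mvel · Mfre · S)` with
  `Mvel = Mbp / C_RBC`, Mfre the vasomotion rate (oscillations/min) and
  S a 150 µm reference vessel diameter;
- **coherence analytics** — 10×10 joint histograms of binned perfusion ×
  binned SO₂ (heat-matrix / chord-diagram payloads) and
  relevance-thresholded correlation clustering (`p < 0.05` and
  `|r| > 0.4`, average linkage on `1 − |r|`).

## Worked example

```python
from microcirc import (
    SyntheticConfig, generate_cohort, preprocess_session,
    correlate_channels, ChannelKind, GroupLabel,
)
from microcirc.io import metrics_table

config = SyntheticConfig(n_samples=2000, seed=1)
cohort = generate_cohort(config, n_per_group=9)          # 54 sessions
processed = [preprocess_session(s)[0] for s in cohort]

table = metrics_table(processed)
print(table.groupby("group")[["rel_high", "mean_so2", "mfre", "imr"]].mean().round(2))

report = correlate_channels(processed, GroupLabel.T2DM)
r, p, relevant = report.pair(ChannelKind.HB_OXY, ChannelKind.BP_LOW)
print(f"T2DM oxy-Hb vs low-speed perfusion: r={r:.3f}, p={p:.2g}, relevant={relevant}")
```

prints

```
                rel_high  mean_so2   mfre   imr
group
control            30.00     65.00  11.90  1.12
insulin_1w         27.27     60.02   9.97  1.20
insulin_2w         27.83     61.01  10.37  1.18
liraglutide_1w     28.17     61.50  10.77  1.14
liraglutide_2w     29.51     63.53  11.47  1.13
t2dm               24.01     55.00   8.47  1.26
T2DM oxy-Hb vs low-speed perfusion: r=0.504, p=0, relevant=True
```

`rel_high` is the high-speed band's share of total perfusion (%),
`mean_so2` the mean oxygen saturation (%), `mfre` the vasomotion rate
(oscillations per minute) and `imr` the microvascular resistance index.
The diseased group shows the configured signature — high-speed share and
saturation down, resistance up, vasomotion slowed — and the treated
groups interpolate back toward control, the two-week incretin course
most completely. The correlation between oxygenized hemoglobin and
low-speed perfusion recovers the generator's target of 0.5 and clears
the relevance thresholds.

## Command line

```bash
microcirc simulate --n-per-group 3 --n-samples 600 --seed 5 --out cohort.csv
microcirc preprocess --input cohort.csv --out clean.csv --fences fences.json
microcirc normalize  --input clean.csv --norm minmax --out norm.csv --compare-out compare.csv
microcirc metrics    --input clean.csv --out metrics.csv --s-constant 0.15 --s-unit mm
microcirc coherence  --input clean.csv --out-dir coh/ --bins 10 --range pooled
microcirc export     --input clean.csv --out-dir surfaces/ --norm minmax
microcirc run        --config pipeline.yaml --out-dir artifacts/
```

`run` executes the whole chain (simulate/load → validate → preprocess →
normalize → metrics → coherence → export) from a YAML config and stamps
every artifact directory with a manifest (config hash, seed, package
version); reruns from the same config are byte-identical.

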