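# esngait

Gait event detection from body accelerations with an echo state network
(ESN), plus a Teager–Kaiser energy operator (TKEO) comparator and a full
event-detection scoring protocol.

The package implements the complete pipeline:

1. **`esngait.synthgait`** — synthetic multi-axis gait accelerations and
   heel/toe force profiles with ground-truth annotations for the six gait
   event classes (HS, HP, FF, HO, TP, TO), with configurable cadence,
   cycle jitter, amplitude variability and noise.
2. **`esngait.labeling`** — event extraction from force signals
   (threshold crossings for HS/HO/TO, total-force extrema for HP/FF/TP),
   binary indicator targets, and the mid-stance-phase (MSP) based 70/30
   train/test split.
3. **`esngait.reservoir`** — sparse random reservoir construction
   (spectral-radius rescaling, bias/input scaling) and the leaky
   `tanh` state recursion with transient removal.
4. **`esngait.training`** — ridge-regression readout solved from
   accumulated Gram matrices (the concatenated state matrix is never
   materialized), and gait cycle duration `tau` estimated from the
   5th percentile of heel-strike gaps.
5. **`esngait.decoding`** — refractory peak decoding of the continuous
   readout (minimum inter-peak distance `floor(0.65 * tau * fs)`), NRMSE.
6. **`esngait.tkeo`** — the untrained comparator: TK energy, HS peaks at
   0.7 of the first autocorrelation lag, TO peaks after HS suppression.
7. **`esngait.metrics`** — nearest-event error matching, pooled
   median-bias removal, 65 ms outcome classification (TP/FP/FN/TN),
   TPR/PPV/T1/SPF rates and per-series MAE summaries.
8. **`esngait.core_io`** — shared domain types and plain-text readers /
   writers (delimited timeseries, event files, JSON model archives),
   polyphase resampling.

Default ESN hyperparameters: `N=100`, `alpha=0.1053`, `rho=0.7471`,
`P=0.21`, `Si=2.300`, `Pi=0.41`, `Sb=2.911`, `gamma=1e-6`, 1.25 s
transient. One inference step costs `N^2 + N*(Nin+Nout) + O(N)`
multiply-adds (about `N^2 + 14N` for small channel counts).

Acceleration input units are treated as opaque; training and testing
units must match (no normalization is applied).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (Gram
accumulation equivalence, planted-readout recovery, reservoir spectral
properties, echo-state transient convergence, end-to-end synthetic
detection, TKEO analytics and dominance contrast, metrics oracle,
decoding refractory invariant).

## CLI

```bash
esngait simulate --config sim.yaml --out-dir data/ --seed 1
esngait label    --forces data/forces_000.csv --out data/events_000.csv
esngait train    --manifest manifest.csv --model model.json --seed 1
esngait detect   --model model.json --input data/accel_000.csv --out pred.csv
esngait detect   --method tkeo --input data/accel_000.csv --out pred_tkeo.csv
esngait evaluate --truth data/truth_000.csv --pred pred.csv --out report.csv
esngait run      --config pipeline.yaml --out-dir out/ --seed 1
```

`simulate` configs list simulation specs under `records:`; `run` drives
the whole pipeline (simulate → label → train → detect → evaluate for both
methods) from one YAML file and writes a reproducibility manifest.

Example `pipeline.yaml`:

```yaml
records:
  - {duration_s: 60, cadence_hz: 0.9, cycle_jitter: 0.02, noise_sd: 0.01}
  - {duration_s: 60, cadence_hz: 1.1, cycle_jitter: 0.02, noise_sd: 0.01}
  - {duration_s: 60, cadence_hz: 1.0, cycle_jitter: 0.02, noise_sd: 0.01}
methods: [esn, tkeo]
```

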