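# impactkit

Head-impact detection for instrumented mouthguards: a complete, tested
pipeline from raw multi-sensor kinematic captures to a tuned
gradient-boosted classifier with bootstrapped performance bounds and
feature attributions.

Contact-sport exposure monitoring needs to separate true head/body impacts
("hits") from the many other events that cross a mouthguard's acceleration
trigger — chewing, yelling, handling the device.  `impactkit` is written
for biomechanics and sports-science groups working with such sensors: it
models a device carrying three triaxial accelerometers (3,200 Hz, ±200 g,
12-bit) and a gyroscope (800 Hz, ±2,000 dps, 16-bit), and implements the
full classification workflow:

1. **Trigger emulation** — captures span 20 ms before the first crossing of
   the 10 g left-accelerometer-norm threshold to 80 ms after the last.
2. **Preprocessing** — axis alignment by per-device rotation matrices,
   polyphase resampling of all channels to 3,200 Hz, and *triage*: a causal
   second-order Butterworth low-pass at 300 Hz on the norm followed by a
   10 g threshold, removing vocalisation and other high-frequency noise.
3. **Features** — per aligned signal (12 total): natural-log Welch power
   spectral density averaged in 10-Hz bins over (10, 1600] Hz (159
   bins/signal, 1,908 total), plus random convolutional kernel features
   (max and proportion-of-positive-values per kernel; 600 features/signal
   at the 300-kernel reference), standardised to the training subset.
4. **Modeling** — session-level holdout; class balancing by downsampling;
   stratified 70/15/15 split; an untuned classifier sweep scored by TP%
   and TN% with selection by mean(TP, TN) and smallest |TP − TN|; then
   randomized hyperparameter search for XGBoost (50 candidates, 5-fold
   stratified CV) maximising the Matthews correlation coefficient
   MCC = (tp·tn − fp·fn) / √((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
5. **Evaluation** — TP% = 100·tp/(tp+fn), TN% = 100·tn/(tn+fp), F1,
   sensitivity, precision and MCC on the train / validation / test / rest /
   holdout subsets, each with a percentile bootstrap 95% CI over 10,000
   resamples.
6. **Interpretation** — per-observation TreeSHAP attributions, ranked by
   mean |value| and aggregated by feature family, sensor, and frequency
   band (split at 150 Hz).

Because real match corpora from such devices are proprietary, the package
ships a first-class synthetic capture simulator (damped-sinusoid impacts,
burst-train chewing, narrowband >300 Hz yelling, broadband handling
spikes, rate jitter, ADC quantisation, ~10:1 class imbalance) used by the
test suite and the reproduction script.  See `docs/methods.md` for the
model details and what the simulator does and does not emulate.

## Worked example

```python
import impactkit as ik
from impactkit.pipeline import PipelineConfig, run_pipeline
from impactkit.interpretation import aggregate_attributions

result = run_pipeline(PipelineConfig.synthetic_study(seed=1))
print(result.report.format_table())
print(aggregate_attributions(result.attribution, "frequency_band"))
```

Output (about five minutes on one CPU):

```
Subset          Hits  Non-hits            TP% (95% CI)            TN% (95% CI)           F1 (95% CI)
train            137       137  100.00 (100.00-100.00)  100.00 (100.00-100.00)      1.00 (1.00-1.00)
validation        30        30  100.00 (100.00-100.00)  100.00 (100.00-100.00)      1.00 (1.00-1.00)
test              30        30  100.00 (100.00-100.00)  100.00 (100.00-100.00)      1.00 (1.00-1.00)
rest               0       909        0.00 (0.00-0.00)     99.33 (98.78-99.77)      0.00 (0.00-0.00)
holdout           26       130    96.15 (87.09-100.00)  100.00 (100.00-100.00)      0.98 (0.93-1.00)
<150 Hz     2.085678
>=150 Hz    0.420867
```

Reading this: the tuned classifier recovers every hit and non-hit in the
balanced test subset; on the *rest* set (908 non-hits excluded by
balancing — the realistic ~10:1 regime) specificity stays above 99%; on
the held-out session one of 26 hits is missed.  The rest row's TP% of 0 is
flagged, not a failure — that subset contains no hits by construction.
The frequency-band aggregation shows the classifier draws most of its
spectral evidence from below 150 Hz, where impact energy concentrates.

The same flow is available from the shell:

```bash
impactkit simulate --n 2000 --seed 1 --out corpus.captures.json
impactkit validate corpus.captures.json
impactkit run --n 2000 --seed 1 --out runs/demo
```

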