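# infantmotion

Unsupervised activity recognition for newborns and infants from
body-worn triaxial accelerometer logs.

Newborns cannot report how they feel; their movement can. A chest-worn
accelerometer (raw chip units in [−1000, 1000] at ~40 Hz) captures
whether an infant is sleeping, writhing in agony, moving calmly, or
being handled by a caregiver — but labeling tens of thousands of signal
windows against video is slow and error-prone. `infantmotion`
implements a fully unsupervised pipeline for this problem, aimed at
researchers and engineers working on infant sleep/wellness monitoring:

1. the stream is cut into 160-sample (~4 s) windows with 75% overlap;
2. each window S is transformed per axis into a monotone cumulative
   movement curve:
   z_i = s_i − μ,  d_i = |z_{i+1} − z_i| (with d_{n−1} = d_{n−2}),
   c_i = Σ_{k≤i} d_k —
   a representation invariant to sensor offset and orientation flips;
3. a small 1D convolutional autoencoder (11,423 parameters, implemented
   in NumPy with hand-derived backprop) is trained to reconstruct the
   curves; its encoder compresses each window to a 64-d latent vector;
4. k-means clusters the latents, with the number of clusters n_o chosen
   by the mean silhouette coefficient (largest k ≤ 8 scoring ≥ 0.6);
5. clusters are named sleeping / weak / strong / external-force
   movement from movement-intensity and transient-step statistics.

Because labeled infant recordings of this kind are not public, the package
includes a calibrated regime-switching generator of labeled synthetic
streams (quiet sleep accumulates ~500–600 chip units per window, strong
movement ~6000 on the dominant axis), plus an evaluation suite
(confusion-matrix metrics and Hungarian-matched clustering accuracy).
See `docs/methods.md` for the model, calibration, and limitations.

## Worked example

```bash
# a 1000-second synthetic recording with ground-truth labels
infantmotion simulate --duration 1000 --seed 1 --out rec.log

# train autoencoder + clustering (config holds epochs, seed, thresholds)
python -c "from infantmotion.pipeline import PipelineConfig; \
           PipelineConfig(epochs=150, seed=1).to_yaml('cfg.yaml')"
infantmotion train rec.log --config cfg.yaml --out-dir model
# silhouette sweep: k=2: 0.564, k=3: 0.557, k=4: 0.641, k=5: 0.584, ...
# selected k = 4 (threshold met: True)

infantmotion classify rec.log --model-dir model --out timeline.csv
infantmotion evaluate timeline.csv rec.log.labels.csv --out metrics.json
infantmotion report timeline.csv
# sleeping                     345 segments ( 34.6%)
# strong movement              246 segments ( 24.7%)
# weak movement                268 segments ( 26.9%)
# external force movement      138 segments ( 13.8%)
```

The silhouette sweep peaks at four clusters — the four activity regimes
present in the recording — and the model-selection rule picks k = 4.
`metrics.json` then reports how well the unsupervised labels match the
generator's ground truth: matched accuracy 0.939, macro balanced
accuracy 0.958, macro F1 0.933 for this run. `timeline.csv` holds one
activity label per window in temporal order, the basis for sleep-quality
timelines.

The same commands work on real device logs (one line per sample:
timestamp, frame index, gyro x/y/z, accel x/y/z, sequence number);
`evaluate` additionally needs a per-sample label CSV.

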