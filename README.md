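# effconn

Directed (effective) connectivity estimation from multichannel EEG/ECG
recordings, and emotion-state classification of the resulting connectivity
images.

The pipeline:

1. **io_preprocess** — read BDF/EDF or a plain-text matrix format; zero-phase
   band-pass filter (0.5–45 Hz Butterworth), integer downsampling (default
   256 → 128 Hz), common-average re-reference of the EEG channels, and
   segmentation into 5000 ms windows with 50% overlap. Each window carries a
   stationarity flag from a two-half variance-ratio F-test.
2. **mvar** — multivariate autoregressive (MVAR) model fitting by least
   squares (default order 10; AIC-based selection available), with stability
   (companion spectral radius), residual whiteness (Ljung–Box) and
   correlation-structure consistency diagnostics.
3. **connectivity** — three directed estimators on 35×35 (32 EEG + 3 ECG)
   channel grids, per frequency band (delta/theta/alpha/beta/gamma):
   - **PDC** — column-normalized |Ā(f)| where Ā(f) = I − Σ_r A_r e^{−i2πfr/fs};
   - **DTF** — row-normalized |H(f)| with H = Ā⁻¹;
   - **GC** — pairwise time-domain Granger causality (log residual-variance
     ratio) on band-pass filtered windows.
   Matrix orientation everywhere: entry (i, j) is coupling *from source j to
   target i*.
4. **imaging** — render band-averaged matrices as color PNGs (fixed blue→red
   lookup table, nearest-neighbor cell blocks, default 224×224) in the
   canonical channel order, with metadata in PNG text chunks.
5. **classify** — stratified or subject-grouped 5-fold cross-validation with
   a pluggable backend: `small_cnn` (a from-scratch numpy CNN, CPU-trainable
   in minutes) or `transfer` (adapter that replaces a user-supplied
   pretrained network's final fully connected layer with a 4-way softmax head
   and fine-tunes it: Adam, lr 8e-4, batch 32, ≤30 epochs). Metrics: mean
   one-vs-rest accuracy (note: a random 4-class predictor scores ≈0.625 on
   this scale, not 0.25) and one-vs-rest AUC = ½(sensitivity+specificity);
   a conventional ranking ROC-AUC is reported alongside.
6. **simulate** — synthetic ground-truth MVAR systems: a 5-node
   directionality-recovery fixture and a 4-class EEG/ECG-like emotion dataset
   with class-dependent directed coupling profiles, so the whole pipeline is
   testable without external data.

## CLI

```sh
# generate a labeled synthetic dataset (plain-text matrix files)
effconn simulate --classes 4 --trials 40 --len 30 --coupling 0.4 --seed 7 --out data/

# preprocess one recording into windows
effconn preprocess --in data/happiness_sim000_0000.txt --out w.npz \
    --band 0.5,45 --fs-out 128 --window-ms 5000 --overlap 0.5

# MVAR diagnostics per window
effconn fit --in w.npz --order fixed:10 --diagnostics diag.json

# per-band connectivity matrices and images
effconn connect --in w.npz --method dtf --bands all --order fixed:10 --out conn.npz
effconn render --in conn.npz --out imgs/ --size 224

# 5-fold cross-validated classification of an image directory
effconn classify --imgs imgs/alpha/dtf --k 5 --backend small_cnn --seed 7 \
    --report report.json
```

Input formats: BDF (BioSemi 24-bit), EDF, and a documented plain-text matrix
format (`# fs: ...`, `# labels: ...`, `# kinds: ...` header lines followed by
one whitespace-separated row per channel).

## Library use

```python
from effconn import simulate, pipeline, classify

spec = simulate.SyntheticSpec(trials_per_class=40, trial_s=30.0, coupling=0.4, seed=7)
recordings = simulate.generate_emotion_dataset(spec)
images = pipeline.recordings_to_images(recordings, method="DTF", bands=["alpha"])
dataset = pipeline.images_to_dataset(images)
result = classify.cross_validate(dataset, k=5,
                                 config=classify.TrainConfig(epochs=10, seed=3))
print(result.mean_accuracy)
```
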