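# lumigrain

Analysis pipeline for delayed-luminescence (DL) photon-count decay signals of
stored grain, and classification of storage-year classes with a from-scratch
bidirectional LSTM whose output labels are either one-hot vectors or Walsh
error-correcting codewords.

The pipeline stages:

1. **synthetic** — simulate labeled photon-count traces: hyperbolic decay
   `I(t) = I0 / (1 + t/tau)^beta` per class, constant instrument background
   (9 counts / 0.1 s bin), optional Poisson counting noise; 1000 bins over
   100 s at 0.1 s per bin.
2. **preprocess** — background subtraction, then a width-5 centered sliding
   average.
3. **hyperfit** — nonlinear least-squares fit of the decay law, goodness
   metrics (SSE, RMSE = sqrt(SSE/(N-3)), R²), and the closed-form integral
   intensity E(T).
4. **features** — the 10-component feature vector: (I0, beta, tau, E(T)) from
   the fit plus instantaneous frequency (spectral centroid of a
   Kaiser-windowed periodogram), spectral entropy, approximate entropy,
   median, quartile deviation and mean deviation; z-score normalization with
   statistics fitted on training data only.
5. **walsh** — Walsh codewords from the recursive Hadamard construction
   (rows of H8; pairwise Hamming distance 4, single-error-correcting for 5
   classes) with soft-decision nearest-codeword decoding.
6. **bilstm** — pure-numpy Bi-LSTM with exact BPTT gradients (verified
   against central finite differences), Adam, L2 on the head weights, and
   two heads: softmax/one-hot or per-bit sigmoid/Walsh.
7. **pipeline** — full experiment orchestration: both classifiers trained on
   identical splits and noise streams, confusion tables and accuracy reports.

## CLI

```bash
lumigrain simulate --config examples/experiment.yaml --out data/ --seed 1
lumigrain preprocess --in data/sample_0000.csv --background 9 --window 5 --out clean.csv
lumigrain fit --in clean.csv --out fit.json
lumigrain features --in data/ --out features.csv
lumigrain walsh --order 8 --classes 5
lumigrain train --features features.csv --mode walsh --out model/ --seed 0
lumigrain evaluate --model model/ --features features.csv --out eval.json
lumigrain run --config examples/experiment.yaml --seed 42 --out results/
```

`lumigrain run` executes the whole chain and writes `report_onehot.json`,
`report_walsh.json`, per-model confusion CSVs and training-history CSVs.

## Data formats

- Signal CSV: header `time_s,counts`, one row per 0.1 s bin.
- Dataset manifest CSV: `file,label`.
- Feature table CSV: `I0,beta,tau,E_T,inst_freq,spec_entropy,ap_en,median,quartile_dev,mean_dev,label`.
- Models: directory with `weights.npz` + `meta.json` (head mode, hidden size,
  codebook, normalization statistics).
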