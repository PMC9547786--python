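# neurocouple

Cross-modal prediction of resting-state fNIRS hemodynamics from scalp EEG.

Neurovascular coupling links neural oscillations to cerebral blood
oxygenation: slow fluctuations of oxygenated hemoglobin (HbO) track the
power envelopes of cortical rhythms with a delay of a few seconds.
`neurocouple` implements a CNN-LSTM sequence-to-sequence autoencoder that
learns this mapping — EEG sequence blocks in, fNIRS sequence blocks out —
together with the surrounding pipeline a multimodal EEG-fNIRS study needs:
band decomposition (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–100 Hz),
resting-state filtering, channel quality control, sequence construction,
band-wise reconstruction-error statistics with one-tailed paired t-tests,
and seed-based functional connectivity of the predictions.  It is aimed at
researchers who want to probe which EEG frequency ranges carry hemodynamic
information, on their own recordings or on fully synthetic ground truth.

## The model

An *element* is one second of recording: 500 EEG samples × 21 channels,
20 fNIRS samples × C channels.  For an input block of S elements the
network computes

    (S, 500, 21) → conv(1×7, stride 2) + pool → (S, 125, F1)
                 → conv(1×7, stride 2) + pool → (S, 62, F2)
                 → reshape → LSTM(512) → LSTM(256) → latent (1, 256)
                 → repeat → LSTM(312) → LSTM(695) → reshape (S, 5, 139)
                 → deconv(1×2, stride 2) ×2 → (S, 20, C)

trained to minimize MSE against the min-max-scaled, mean-centered fNIRS
block shifted ahead of the EEG in time.  Reconstruction fidelity is
summarized by the per-timepoint L1 reconstruction error
ε_t = Σ_l |x̂_{t,l} − x_{t,l}| (channels folded into the dimension index
l), and predicted connectivity fields are compared to experimental ones by
RMSE_FC = sqrt(Σ_i (fc_i − f̂c_i)² / C) over channel-wise Pearson r.

Because paired clinical EEG-fNIRS resting-state data are not publicly
available, the package includes a neurovascular-coupling simulator:
band-structured EEG with slow (0.01–0.1 Hz) amplitude modulation of each
rhythm, and fNIRS channels driven by the smoothed Hilbert power envelopes
of their nearest EEG channels convolved with a delayed double-gamma
hemodynamic response, contaminated with Mayer-wave, respiratory and
cardiac oscillations and sensor noise.  The coupling gains are per-band,
gamma-dominant by default, so band selectivity is recoverable ground
truth.  See `docs/methods.md` for the full model description and the
numerical conventions.

## Worked example

Simulate one subject, train a gamma-band model and an uninformative
delta-band control, and compare held-out reconstruction error:

```python
from neurocouple import RunConfig
from neurocouple.pipeline import run_experiment

cfg = RunConfig(seed=1, n_subjects=2, bands=("delta", "gamma"),
                sim=dict(n_fnirs=8, duration_s=480.0),
                connectivity=dict(fc_bands=("gamma",)))
res = run_experiment(cfg)
print(res["comparison"].table.round(3))
print({band: round(float(sum(v) / len(v)), 3)
       for band, v in res["fc_rmse"].items()})
```

prints

```
          delta  gamma
subject1  0.810  0.730
subject2  1.166  0.848
{'gamma': 0.273}
```

Each table entry is the mean held-out reconstruction error (scaled space)
of the autoencoder trained on that subject's EEG band; the gamma-band
models reconstruct the gamma-coupled fNIRS with 10-27 % lower error than
the delta-band controls, whose input band carries no coupling information.
The last line is the RMSE between the experimental seed-connectivity field
and the one computed from the gamma-model predictions (0 would be
identical fields).

The same pipeline is scriptable from the shell:

```sh
neurocouple simulate --duration 480 --n-fnirs 8 --coupling-preset gamma \
    --seed 1 --out sim/            # writes eeg.edf, fnirs.snirf, geometry.json
neurocouple run --config experiment.yaml
```

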