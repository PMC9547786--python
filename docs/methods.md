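# Methods

`neurocouple` predicts resting-state fNIRS hemodynamics from scalp EEG with a
CNN-LSTM sequence-to-sequence autoencoder, and validates the predictions with
band-wise reconstruction-error statistics and seed-based functional
connectivity.  Because no public paired EEG-fNIRS resting-state dataset with
the required layout exists, the package ships a neurovascular-coupling
simulator whose ground truth makes every downstream stage testable.  This
note records the model, the simulator, the numerical conventions, and the
design choices that were genuinely open.

## The cross-modal autoencoder

The network maps an EEG block of `S` one-second elements (500 samples x 21
channels each) to the paired fNIRS block of `S` elements (20 samples x C
channels each, shifted ahead in time).  The encoder is two convolutional
blocks — kernel (1,7), stride (1,2), ReLU, dropout, average pooling — that
reduce each element 500 -> 125 -> 62 points, followed by two LSTMs (512
units returning sequences, then 256 units returning the final hidden state,
which is the latent vector).  The decoder repeats the latent `S` times,
passes it through LSTMs of 312 and 695 units, reshapes each step to
(5, 139), and restores 20 samples per element with two kernel-(1,2),
stride-(1,2) transposed convolutions.  The first pooling stage uses stride
2 (500 -> 250 -> 125) and the second stride 1 (125 -> 63 -> 62); that is the
unique pooling arithmetic consistent with the 125/62 milestone sizes.  The
final deconvolution is linear because the targets are mean-centered and a
ReLU output could not produce negative values.  Feature-map counts
(F1 = 16, F2 = 4, F4 = 8) are configuration knobs; F3 = 139 is forced by
695 = 5 x 139.  The synthetic study widens the second block to F2 = 8:
with only four feature maps the 62-point embedding is a narrow random
bottleneck, and whether a given initialization couples input to output
within the epoch budget becomes a coin flip; eight maps improve the odds
substantially (widening further helps the unconditional fit but dilutes
the band contrast).

Everything is implemented in NumPy with hand-written backpropagation
(including full backpropagation through time for the LSTMs); gradient
correctness is established by finite-difference checks in the test suite.
Training minimizes MSE on min-max-scaled, mean-centered targets.  The
reconstruction error metric (per-timepoint sum of absolute differences) is
an evaluation quantity only, never the training loss.

### Training regimes

Two regimes exist:

* **Faithful recipe** (estimator defaults): plain SGD via BPTT, learning
  rate 0.05, batch 60, 50 epochs, dropout 0.2, gradient global norm clipped
  to 1.0.  Unit-scale uniform [0,1] initialization with ReLU
  LSTM activations diverges within a couple of epochs (the training loop
  aborts with a diagnostic naming the epoch); it remains available as
  `init="unit-uniform"` / `activation="relu"`.  The default initialization
  is small-uniform (U[-0.05, 0.05], forget-gate bias 1) with tanh cells.
  At desk-scale sample counts this recipe fits the unconditional target
  mean but moves input-conditional structure too slowly to observe.
* **Study recipe** (pipeline defaults): Adam (lr 3e-3), full-batch
  gradients, dropout 0.2, 60 epochs over two concatenated recordings.
  Two facts found empirically drive this choice and are worth recording:
  (i) with tens of training windows, minibatch gradient noise exceeds the
  small input-conditional gradient signal, and Adam's per-parameter
  normalization then performs a random walk — full-batch gradients
  restore learning (dropout is tolerable at full batch, where the
  averaged gradient stays informative); (ii) plain SGD at any stable
  learning rate fits only position means within hundreds of updates.
  The architecture is unchanged; only the optimization is scaled to the
  data volume of a single synthetic subject.

The 60/20/20 train/test/validation split is drawn per subject from the run
seed.  Divergence (non-finite loss) aborts with the epoch number.  A fixed
seed reproduces loss curves bit-for-bit on one machine.

### Sequence construction

An element is one second.  Windows of `seq_len` elements are cut
non-overlapping, never crossing a resting-segment boundary, and windows
intersecting an artifact mask are dropped.  The fNIRS target is shifted
`shift_elems` elements ahead of the EEG input; the shift is how the model
is allowed to learn the hemodynamic lag rather than having it imposed.  A
window is emitted only when both the EEG span and the shifted target span
lie inside the record, so `d` seconds of data yield
`floor((d - shift) / seq_len)` windows per contiguous segment.

The estimator default is `seq_len=10`, `shift_elems=1`.  The study
configuration uses `seq_len=5`, `shift_elems=8`: the simulator's
hemodynamic response peaks ~8 s after neural activity (3 s onset delay
plus 5 s to the HRF peak), so an 8-element shift centers the predictable
physiology on the input window (a ridge probe of per-element band power
against the target confirms this: correlation of window means 0.86 at
shift 8 versus 0.03 at shift 1), and 5-element windows double the sample
count while keeping the slow target arc near-constant within a window.
fNIRS is handled at 20 Hz in the model path so an element is exactly 20
points; the simulator emits 19.5 Hz by default with a 20 Hz
model-compatibility mode, and a polyphase resampler converts recordings
between the two.

## The synthetic-data generator

The generator emulates the physiological premise that slow fNIRS
fluctuations track the power envelopes of band-limited cortical rhythms.

**EEG.**  21 channels at 500 Hz on the canonical 10-20 positions projected
onto a spherical head (default radius 85 mm).  Each channel sums five
band-limited Gaussian processes (delta 1-4, theta 4-8, alpha 8-12,
beta 12-30, gamma 30-100 Hz) scaled to configurable per-band variances
(defaults loosely 1/f: 20/10/15/8/5 µV²), plus broadband sensor noise
(1 µV).  A fraction (0.4) of each band's variance is a source common to
all channels, giving realistic cross-channel correlation.  Critically,
each band's amplitude is multiplied by a slow log-normal modulator
`exp(d*s - d²/2)` where `s` is a standardized 0.01-0.1 Hz process
(partially shared across channels) and `d = 0.5`: this is the infra-slow
power modulation of cortical rhythms that resting-state hemodynamics
track.  A stationary band process has no recoverable slow envelope — its
power fluctuations decorrelate on the scale of the inverse bandwidth — so
without the modulator there would be nothing for the cross-modal model to
find, at any training budget.

**fNIRS.**  For each fNIRS channel (quasi-uniform Fibonacci lattice on the
superior hemisphere), the smoothed Hilbert power envelopes (low-passed at
0.4 Hz) of its three nearest EEG channels are mixed with inverse-distance
weights, mean-removed, combined across bands by nonnegative coupling gains
(gamma-dominant by default), convolved with a double-gamma hemodynamic
response (peak 5 s, undershoot 15 s, ratio 1/6) delayed 3 s, and summed
with Mayer (~0.1 Hz, amplitude 0.5), respiratory (0.25 Hz, 0.25) and
cardiac (1 Hz, 0.25) sinusoids plus white noise (sd 0.25) to give HbO.
HbR is a negative multiple (default -0.4) of the same physiology with
independent noise, so HbO/HbR are strongly anticorrelated as in real
recordings.  The response is exactly linear in each coupling gain, and a
band the EEG does not contain contributes nothing even when its gain is
positive.  All draws descend from one integer seed in a documented stream
order.  Nuisance amplitudes were chosen once so that, after resting-state
filtering, the coupled response dominates the target (as it must for the
cross-modal question to be well-posed) while the nuisance peaks remain
visible in the spectrum.

What the simulator does **not** reproduce: volumetric photon transport,
optical-density-to-concentration conversion, eye-blink/electrode-pop
artifact taxonomy, genuine epileptiform activity, or the dense ~138-channel
clinical montages.  Passing tests therefore demonstrate that the pipeline
recovers a known coupling under controlled conditions, not that it would
perform identically on patient data.

## Signal conditioning

EEG is broadband filtered 0.1-100 Hz and decomposed into the five bands
with zero-phase Hamming windowed-sinc FIR filters (transition bandwidth
25 % of the lower band edge, floored at 0.5 Hz; forward-backward
application doubles the ~53 dB stopband).  The fNIRS resting-state filter
(0.01-0.1 Hz) and the 0.2 Hz cardiac/respiratory low-pass are 4th-order
Butterworth sections applied forward-backward: an equally sharp FIR at a
0.01 Hz edge would be longer than a typical resting record.  Channel SNR
rejection removes channels whose RMS is below 30 % of the cross-channel
mean.  PCA motion correction zeroes the top-variance principal components
(count configurable, default 1 when invoked).  Amplitude artifact
rejection flags samples deviating more than 10 % (of the normalized
intensity range) from the channel median and masks them out of sequence
construction rather than interpolating.  Min-max scaling maps each channel
to [0,1] and mean-centers it, returning the inverse parameters so
predictions can be mapped back to physical units.  Welch PSDs use Hann
windows, 4 s segments, 50 % overlap by default.

The synthetic cohort runs PCA correction and artifact masking switched
off: the generator produces no motion artifacts, so at the 10 % threshold
the mask would flag ordinary signal excursions (on Gaussian-like data,
|x - median| > 0.1 of the range is common), and component removal would
subtract shared physiology.  Both operations are exercised by their own
unit tests.

## Evaluation and statistics

The reconstruction error of a block is eps_t = sum_l |xhat_{t,l} - x_{t,l}|
with channels folded into the dimension index, aggregated as the mean over
timepoints (mean rather than sum so values are duration-invariant; `agg="sum"`
is available).  It is computed in the scaled model space by default,
matching the space in which the model was trained.  Band comparison
collects per-subject mean RE per band and runs one-tailed paired t-tests
of the four contrasts [delta|theta|alpha|beta vs gamma] with the
alternative "the other band reconstructs worse than gamma", Bonferroni
corrected by the fixed factor 4.  Zero-variance difference vectors are
flagged degenerate (t = 0, p = 0.5 when the mean is also zero; p -> 0 with
a positive mean).

## Functional connectivity

Channels failing quality gates (mean amplitude outside the cross-channel
mean ± 2 SD, or RMS below 30 % of the mean) are excluded; excluding the
chosen seed channel is a hard error.  Seed connectivity is the Pearson
correlation of the seed time series with every channel (Fisher z
alongside, r clipped at 1 - 1e-12 before arctanh).  The cross-modal field
correlates the experimental seed with each predicted channel, where the
predicted time series is stitched from the model's non-overlapping window
predictions.  Fields are compared by the RMSE of channel-wise r values;
r (not z) is also what is projected onto the head surface with
inverse-cube-distance weights (distances floored at 1 mm; the seed's own
r = 1 is excluded from projection by default because it would dominate
nearby voxels).  The surface grid is a Fibonacci lattice on the simulator's
sphere at a configurable spacing; the anatomical MRI cortex of a clinical
workflow is out of scope, and distances are measured to scalp channel
positions.

## Problem sizes

The test suite and the acceptance script run the synthetic study at sizes
a single CPU handles comfortably: two consecutive 8-minute resting
recordings per subject (mirroring the multiple-recordings-per-patient
protocol of clinical EEG-fNIRS monitoring; each recording is conditioned
separately so no filter runs across a session junction), 8 fNIRS
channels, 5-element sequences, ~190 windows per subject, full-batch Adam
for 60 epochs per band model, 5 cohort seeds for the band-selectivity
recovery check (3 in the acceptance script, which also trains the
full-spectrum models and runs the connectivity comparison).  The capacity probe memorizes a 4-sample batch
of two-element sequences within 500 epochs.

## Known limitations

* On synthetic cohorts the connectivity error of full-spectrum-input
  predictions comes out *larger* than that of gamma-band-input
  predictions — the reverse of what patient data showed.  Min-max scaling
  of broadband EEG compresses the informative gamma amplitudes under the
  delta-dominated range, so full-spectrum models learn less within the
  study's epoch budget; on real recordings, with far more training data,
  the broadband model can exploit all bands.  The comparison is reported,
  not asserted.

* The faithful SGD recipe demonstrates the reference hyperparameters but
  does not produce input-conditional learning at desk scale; all
  quantitative study results use the Adam regime described above.
* The EEG-to-fNIRS spatial coupling (three nearest channels,
  inverse-distance mixing) is an assumption; nothing in the source
  material specifies the implicit spatial pairing.
* Welch defaults (4 s, 50 % overlap), the artifact-rejection reference
  point (channel median), and the per-band re-scaling of band-filtered
  model inputs are choices where the procedure was underspecified.
* EDF output quantizes to 16 bits per channel over the channel's own
  physical range; round trips are exact only to that quantum.
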