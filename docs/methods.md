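# Methods

`vocrep` implements an unsupervised pipeline for characterising animal
vocal repertoires: detected vocalisations are encoded as fixed-size
spectrograms, embedded with a convolutional auto-encoder, projected with
UMAP and grouped with HDBSCAN; the result is scored against expert labels
where those exist. This note records the model, its assumptions, the
defaults and the numerical choices, in enough detail to re-derive every
behaviour from the code.

## Signal model and preprocessing

The unit of analysis is a *detected vocalisation*: a source WAV file plus a
centre time (or onset + duration, converted as `center = onset +
duration/2`). Detection/segmentation is out of scope — inputs are
already-detected units.

Three dataset-specific settings drive preprocessing:

| setting | meaning | how it is set |
|---|---|---|
| `T` (s) | fixed window cut around each unit centre | 3rd quartile of annotated durations (linear-interpolation percentile); long units are cropped, short ones padded by context or zeros |
| `fs` (Hz) | common sampling rate | most common rate in the dataset; other files are polyphase-resampled |
| `NFFT` | Hann STFT window (samples) | chosen per repertoire by spectrogram inspection |

The waveform window is z-normalised, then transformed with an **unpadded,
uncentred Hann STFT** whose hop is

```
hop = (T·fs − NFFT) / n_time        (n_time = 128 by default)
```

rounded to the nearest integer sample. This formula yields `n_time + 1`
full frames; we drop trailing frames to get exactly `n_time` columns,
preserving onset alignment (whether leading or trailing frames should be
dropped is underdetermined; the choice is inconsequential to within one
hop). If integer rounding of the hop leaves the final frame short, the
signal tail is zero-padded. Six named presets
(`vocrep.presets.PRESETS`) pin `(fs, NFFT, T)` for the published benchmark
repertoires; the derived hop in ms reproduces the published settings table
at one-decimal rounding for every row except the california thrasher,
where the formula gives 1.86 ms (printed: 1.8) — the printed `T` values
are themselves rounded quartiles, so exact agreement there is not
derivable from the printed inputs.

The frequency axis is reduced to `n_mels = 128` bins either through a
**mel filterbank** (128 triangular filters, Slaney scale and area
normalisation, spanning 0 to Nyquist — with 128 filters the narrow
low-frequency triangles can be empty, which is inherent to the layout and
harmless after z-normalisation) or through **max-pooling** of contiguous
linear-frequency bin groups (boundaries `round(linspace(0, NFFT/2+1,
129))`), which keeps 128 rows regardless of `NFFT`. Dynamic-range
compression is `none`, `log` (`log(mag/max + 1e-8)`; the ε is relative to
the max-normalised magnitude so the floor is scale-invariant) or `PCEN`
(first-order IIR smoother `s = 0.025`, gain `α = 0.98`, bias `δ = 2`,
root `r = 0.5`, `ε = 1e-6` — the reference defaults of the method, which
has no canonical setting per repertoire). An optional stationary-noise
step subtracts each frequency row's median over time and clips at zero.
Finally each spectrogram is z-normalised (per spectrogram by default;
per-dataset normalisation is a flag — per-spectrogram makes units
comparable regardless of recording gain, at the price of amplifying pure
noise in silent windows). Constant inputs map to all-zeros rather than
dividing by a zero standard deviation.

Spectrogram dimensions must factor as `(k_f·2ⁿ × k_t·2ⁿ)` with `n` the
number of encoder halvings (defaults `k = 4`, `n = 5` → 128×128), so the
decoder's factor-2 up-samplings exactly invert the encoder's strides.

A whole-spectrogram **baseline representation** (32×32 = 1024 raw
magnitude features) is the 4×4 max-pool of the standard 128×128
spectrogram — one code path, same `T`, `fs`, `NFFT`.

## Auto-encoder

Encoder: five 3×3 convolutions with stride 2; channel widths double from
`base_channels = 32` (32, 64, 128, 256), and the fifth, linear convolution
(no batch-norm/ReLU) carries `bottleneck_dim / 16` channels so that
flattening its 4×4 output gives exactly the `bottleneck_dim = 256`
embedding — no extra dense layer. Blocks 1–4 are batch-normalised then
ReLU-activated. Decoder: five stages of ×2 nearest-neighbour up-sampling
followed by two (conv 3×3 + BN + ReLU) blocks — two convolutions per
stage for a larger receptive field — with mirrored widths, then a final
linear 1-channel convolution (inputs are z-normalised and signed, so no
output nonlinearity).

Losses: plain **MSE**, or a **perceptual loss** — the MSE between feature
maps of a frozen convolutional extractor, averaged over maps, which
weights coherent foreground structure (frequency contours) above diffuse
background. The extractor is a contract (`layers` + tap indices), so any
frozen network can be plugged in; the shipped default is a seeded
random-weight extractor of three stride-2 conv+ReLU stages (1→8→16→32
channels, He-initialised, tapped after every ReLU). Random convolutional
features are not a trained perceptual metric, but they implement the same
mechanism — multi-scale local structure matching — and keep the package
dependency-free; the identity extractor reduces the loss to exact MSE and
is the invariant the tests pin.

Training: Adam (lr 1e-3, β = 0.9/0.999), batch size 128, stopping when the
median loss over the last `window = 1000` steps fails to decrease below
the median of the previous 1000 (plus a hard `max_steps` cap so
termination is guaranteed). All layers run in float32 NumPy with explicit
backpropagation; weight init and batch order derive from one seed, so
histories are bit-reproducible on a machine. Loss medians, not means, make
the rule robust to batch-to-batch spikes.

## Projection and clustering

UMAP reduces bottleneck embeddings to 8 dimensions for clustering (2 for
visualisation); neighbourhood size (15) and `min_dist` (0.1) stay at the
reference defaults — only the output dimension is treated as a setting.
The seed is mandatory and recorded in every manifest. HDBSCAN then groups
the projected points with the generic cross-repertoire settings:
`min_cluster_size = 10`, `min_samples = 3`, `cluster_selection_epsilon =
0.1`, *leaf* selection (*eom* selectable; useful for graded repertoires
where leaf over-fragments). Unassigned points carry the `NOISE` (−1)
sentinel; cluster ids are renumbered contiguously from 0. K-means on raw
bottleneck embeddings is deliberately not offered.

## Evaluation

**NMI** between labels `L` and clusters `C` is mutual information
normalised by the arithmetic mean of entropies, `2·I(L;C)/(H(L)+H(C))`,
computed in natural log (the base cancels) over vocalisations that are
both labelled and clustered. NOISE points are excluded from the
contingency table by default; a `noise_policy="singletons"` flag instead
keeps each as its own cluster (the stricter reading — excluding noise can
flatter a clustering that discards hard points). If both partitions are
single-category the normaliser is zero; 1.0 is returned with a warning.
Labels with fewer than 20 occurrences are demoted to unlabelled before
evaluation (exactly 20 is kept).

**Hopkins statistic** `Σu/(Σu+Σw)` with `m = 100`: `u_i` are
nearest-data-neighbour distances of `m` points drawn from a normal with
the dataset's per-dimension mean and standard deviation (full covariance
via flag), `w_i` nearest-*other*-neighbour distances of `m` data points
sampled without replacement. ≈0.5 means unstructured; →1 means
clusterable. The pipeline computes it on the 2-D UMAP view, the space in
which repertoire discreteness is usually inspected (configurable).

**Discriminant-cluster report**: a cluster is discriminant when ≥ 90% of
its labelled members share one type (boundary inclusive); clusters with no
labelled member cannot be assessed and are excluded from that percentage
(but still counted as clusters). `pct_clustered` is the share of *all*
vocalisations — labelled or not — inside discriminant clusters, since the
point of the metric is how much of the detection set could be
bulk-annotated; `n_missed` counts labels never appearing in any
discriminant cluster.

## Synthetic repertoires

The generator emulates the structure the pipeline assumes: `K` unit types
with distinct spectro-temporal contours (constant tone / linear chirp /
sinusoidal FM), harmonic stacks (amplitude 1/h), Hann or flat envelopes,
multiplicative log-normal jitter on frequencies and durations
(default fractional sd 0.02), units placed on a silence-gapped timeline
and mixed with white or pink noise at a controlled per-unit SNR: the
background RMS is fixed (0.01) and each unit is scaled to sit `snr_db`
above it. Defaults mimic the bengalese-finch-like regime: `fs = 32` kHz,
`NFFT = 256`, `T = 0.1` s, durations 50–90 ms. A `graded` mode instead
crowds overlapping chirps into one band with heavy jitter (sd 0.25),
emulating a graded repertoire; it measurably lowers both Hopkins and NMI
relative to the discrete mode, reproducing that contrast as a direction.
Randomness is counter-based (`default_rng([seed, unit_index])`) so any
unit regenerates in isolation.

What passing on synthetic data shows: the chain recovers categorical
structure under ideal detection, controlled SNR and stationary noise. What
it does not show: robustness to detection errors, overlapping units,
reverberation, or the within-type drift of real repertoires.

## Scaled study conditions

The end-to-end check trains on a 6-type, 40-units-per-type repertoire at
20 dB SNR and requires NMI ≥ 0.9 with no missed label. For this run the
package uses its reduced auto-encoder (`base_channels = 4`, bottleneck
kept at 256), MSE loss, batch 32 and a 120-step budget, with every seed
fixed to 1 — a deliberate small-scale configuration chosen so the full
pipeline (including training) completes in minutes on one CPU core while
exercising every stage at full 128×128 resolution. The architecture,
clustering settings and metrics are identical to the full-scale defaults.
A caveat worth stating: at this scale (240 points) the leaf-selection
clustering sits near its fragmentation edge, so the NMI of any single run
depends visibly on the UMAP seed (roughly 0.86–0.93 across seeds on the
same embeddings); the committed seeded run is reproducible bit for bit,
but the margin above 0.9 is a property of that run, not of every seed.

## Known limitations

- The auto-encoder is a CPU float32 NumPy implementation: correct and
  reproducible, but not fast; corpus-scale training (10⁵ units, 10⁵
  steps) wants a GPU framework implementing the same architecture.
- The default perceptual extractor is random-weight, not pretrained;
  plugging in a pretrained image network through the extractor contract is
  expected to sharpen contour emphasis.
- UMAP determinism holds per seed per machine; across library versions
  projections (and hence exact cluster counts) can shift.
- The Hopkins reference distribution is a moment-matched normal; for
  strongly non-Gaussian embedding clouds the 0.5 baseline is approximate.
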