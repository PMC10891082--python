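# Methods

This note records the modelling assumptions, numerical conventions, and
design choices behind `graphser`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline overview

```
                       ┌─ normalize [0,1] ─ edge-detect ─ segment means ─ sliding SD ─ visibility graph A₁ ─┐
utterance (WAV) ───────┤                                                                                    ├─ 11 features ─┐
                       └─ fixed overlapping windows ─ |Pearson r| ─ correlation graph A₂ ───────────────────┘               │
                                                                                                                            ▼
speaker × emotion group of m utterances ── mean / population SD / skewness / kurtosis per feature ── 44-value motif ── RF + LOSO-CV
```

## Structural branch

**Why not a visibility graph of the raw signal?** The natural visibility
graph (VG) is defined for positive-valued series, scales quadratically with
length, and a 16–48 kHz utterance has 10⁴–10⁵ samples. The chain
*edge-detected segments → segment means → sliding-window SD* compresses the
signal onto a prosody-scale series that is nonnegative by construction (SD
≥ 0), short enough for exact VG construction, and still tracks how strongly
the voice fluctuates.

**1-D edge detectors.** Canny, Sobel, and Prewitt are image operators; on a
signal treated as a 1×N grayscale image their horizontal derivative kernels
collapse to `[-1, 0, 1]` (row smoothing is a no-op on one row). `sobel` and
`prewitt` therefore threshold `|x[i+1] − x[i−1]|` directly (`threshold`,
default 0.5 on the unit-range signal). `canny` adds 1-D Gaussian smoothing
(`canny_sigma`, default 1 sample), non-maximum suppression of the gradient
magnitude (plateau ties keep the earlier sample), and hysteresis with
thresholds at the 70th/90th percentiles of the magnitude, which adapts per
utterance instead of fixing absolute thresholds. `canny` is the default
detector. Interior boundaries closer than `min_segment_samples` (default 2)
to the previously kept one are merged, keeping the earlier boundary — a
deterministic tie-break.

**Sliding SD.** Population (1/n) standard deviation over windows starting
at 0, hop, 2·hop (hop = window − overlap); the trailing partial window is
discarded; a series shorter than one window collapses to one pooled value.
RMS pooling is implemented behind `pooling="rms"` but off by default: it is
a weaker emotion cue than SD. If the pooled series would have fewer than 3
points the whole mean series becomes a single SD window and the utterance
is flagged in the log rather than dropped.

**Default window 50 / overlap 25 (library default, not a corpus preset).**
The per-corpus presets (structural window 100–200, statistical 8000–10000
samples) were tuned for multi-second real recordings. On 1–2.5 s synthetic
utterances at 16 kHz the canny segment-mean series is ~250–900 points, so a
200-sample window would leave ≤ 5 VG nodes and nearly degenerate graphs.
The preset-free default of 50/25 yields ~10–35 nodes, small enough for
exact O(n²) VG construction and large enough for the six features to carry
variance. This default was fixed from the series-length analysis above,
before any end-to-end accuracy was measured, and is not revisited; the
corpus presets keep their stated values.

**Visibility construction.** Exact O(n²) sweep: node pair (i, j) is
connected iff the chord slope (x_j − x_i)/(j − i) strictly exceeds the
running maximum of intermediate chord slopes from i. Strict inequality
means a collinear intermediate point *blocks* visibility. A brute-force
triple-loop oracle is kept in the tests and the construction must match it
bit-for-bit.

## Statistical branch

Fixed-length overlapping windows of the **raw** signal (Pearson correlation
is affine-invariant, so normalization would be a no-op); the adjacency is
the absolute correlation, clipped to [0, 1] only against float round-off.
Conventions: the diagonal is zeroed (matching the VG convention and keeping
the averaged-value feature from being inflated by self-correlation), and a
zero-variance window — silence — contributes 0 to all its pairs instead of
raising, so one long pause cannot abort an utterance.

## Graph features

- **DoC** is implemented as the *global* double sum ΣᵢΣⱼAᵢⱼ (= 2|E| for
  binary graphs), a scalar, although "degree" usually denotes a per-node
  quantity.
- **CC** applies the triangle formula verbatim to weights; CCᵢ is defined
  as 0 when kᵢ ≤ 1 to avoid a vanishing or negative denominator. For
  weakly-weighted correlation graphs this guard can zero the statistical
  CC.
- **D** counts any strictly positive entry as an edge (`edge_threshold` =
  0, configurable). Correlation graphs are therefore near-complete and
  their density varies only through exact-zero correlations; D carries most
  of its information in the structural branch.
- **Q** uses deterministic greedy (CNM) agglomeration via networkx for the
  partition and evaluates Q = Σ_c(e_cc − a_c²) with our own edge-mass
  formula (2m = grand sum of A, weights as link mass). A zero-weight graph
  gets Q = 0 on the singleton partition.
- **E = Σλᵢ²** is the sum of *squared* eigenvalues, deliberately not the
  classical graph energy Σ|λᵢ|. For any symmetric A it equals trace(A²),
  and for binary graphs 2|E| — so struct_E duplicates struct_DoC up to this
  identity on binary graphs; both are kept because the feature list is part
  of the method's contract.
- The energy of the correlation graph is omitted (it adds no class
  information), fixing the 6 + 5 = 11 feature split.

## Speaker-based emotional motif

Per (speaker, emotion) group of m utterances, each of the 11 features is
summarized by mean, population (1/m) SD, skewness, and plain
(non-excess) kurtosis → 44 values. Degenerate convention: σ = 0 ⇒ skewness
= kurtosis = 0, which keeps single-utterance groups finite for the
classifier. Groups absent from the data produce no row.

## Evaluation

LOSO-CV: one fold per speaker, all of that speaker's motif rows held out,
forest retrained from scratch each fold (n_trees trees, bootstrap, √p
candidate features per split, unlimited depth, fixed `random_state`), so a
seed reproduces predictions bit-for-bit. UAR is computed on the confusion
matrix pooled across folds because one fold holds at most one motif row per
class, making per-fold recalls 0/1-degenerate; classes without true
instances are excluded from the mean. Macro-F1 and macro-specificity are
reported alongside. No feature standardization is applied — trees are
monotone-invariant. Defaults: 300 trees; the EMODB/DEMoS presets use 500.

## Synthetic corpus

The generator emulates what the pipeline needs from a real SER corpus —
multiple speakers, balanced emotion classes, variable-length utterances,
class-dependent temporal structure — with a three-harmonic carrier whose
fundamental is `f0_base + speaker_offset + f0_slope·t + jitter(t)`
(smoothed Gaussian jitter, ~20 ms correlation scale), amplitude-modulated
at `am_rate` over a smoothed ~3 Hz syllabic on/off gate, plus white noise
at `noise_snr_db`. Speaker offsets are drawn once per speaker from
U(−25, 25) Hz. Emotion identity lives in temporal structure (modulation,
jitter, noise, pitch slope), *not* loudness: structural features are
invariant to positive amplitude scaling, so amplitude could not be a
shortcut. Utterances default to 1–2.5 s at 16 kHz — long enough for the
8000-sample statistical window, short enough for fast tests.

Profile values for the bundled presets were chosen once as plausible
prosodic ranges: `separable5` spreads the classes widely (AM 1.5–8 Hz,
jitter 0.5–7 % of f0, SNR 8–35 dB, slopes −12 to +45 Hz/s) and is the easy
regime used for acceptance; `hard5` compresses the same dimensions into
overlapping ranges for regression monitoring.

**What a green test does and does not establish.** Synthetic classes are
stationary, noise is white, and there are no phonemes, formants, channel
effects, or speaker idiosyncrasies beyond a pitch offset. Passing the
class-recovery test shows the pipeline's graph features transmit temporal
structure end to end — it does not certify any accuracy on real emotional
speech.

## Degenerate inputs and numerical conventions

- Constant signal → min-max normalization error (degenerate-signal).
- Utterance shorter than one statistical window → degenerate-signal error
  naming the utterance; corpus drivers skip and log it.
- Stereo WAV → channel average; 8/16/24/32-bit PCM scaled to [−1, 1).
- Resampling: polyphase band-limited, output length forced to
  `round(n·target/source)`.
- Visibility requires nonnegative input and rejects violations loudly
  (contract error, not silent clipping).
- All tolerances in tests: exact (bit-identical) for VG vs. oracle; 1e−10
  for moments; 1e−8 for spectral identities; 1e−12 for correlation vs.
  direct formula.

## Known limitations

- The 1-D edge-detector adaptation is a modelling choice; the original
  image-domain operators have no canonical 1-D recipe, and segment
  granularity (hence VG size) depends on it. Both syllable-scale and
  transient-scale segmentations are reachable via config.
- Whether the three detectors should be combined or chosen per corpus is
  open; the package picks one per run (`detector=` config).
- struct_DoC and struct_E are numerically identical on binary graphs (see
  above) — the effective structural feature count is 5 plus one duplicate.
- Absolute UARs reported for real corpora are not reproducible here
  without the EULA-gated datasets and their unstated detector settings;
  the package therefore validates behavior on the synthetic corpus only.
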