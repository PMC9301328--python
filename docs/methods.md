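# Methods

This note documents the models, the synthetic study the package tests
itself on, the numerical choices, and the limitations. Nothing here states
an empirical result the test suite or `scripts/acceptance.py` does not
itself compute.

## Generative model of the synthetic study

The generator (`trfnet.synth`) emulates a multi-subject continuous-speech
EEG experiment under the assumptions the analysis chain relies on:

* **Stimulus.** Each trial has a speech-envelope surrogate `s(t)`:
  band-passed Gaussian noise (2–8 Hz, the syllabic-modulation band) with
  modulation depth 0.5 around a unit pedestal, clipped at zero, sampled at
  250 Hz. An alternative path (`extract_envelope`) computes envelopes from
  audio via an ERB-spaced filterbank with power-law compression (exponent
  0.6) and decimation, for users with real stimuli.
* **Cortical response.** Each of 68 regions (ROIs) responds with a causal
  lag kernel on a 0–800 ms grid. Regions are partitioned into communities
  (default 4); regions in one community share a Gabor-shaped template
  (Gaussian-windowed cosine, width 0.12 s, frequency 4.6–5.4 Hz, latency
  0.30–0.50 s, alternating polarity) with small per-region amplitude,
  latency and frequency scatter. Three properties are deliberate:
  the kernels' spectra lie inside the stimulus band (a band-limited
  stimulus cannot identify out-of-band kernel energy, so recovery tests
  would otherwise measure the stimulus, not the estimator); the shared
  response spans a low-dimensional sensor subspace (roughly one dimension
  per community and condition), matching the premise that a compact shared
  subspace exists for hyperalignment to find; and the community partition
  is spatially coherent (contiguous blocks over the source sheet, as real
  functional communities are), so the short-range point-spread of the
  inverse leaks mostly within communities. The "reversed" condition
  shifts the partition boundaries by half a block, permutes community
  identities and redraws templates, planting a different network.
* **Forward model.** 500 sources on a 2-D sheet; each of 128 channels has
  a Gaussian receptive field over the sheet (width 0.6/√C in sheet units)
  plus a smooth random gain component (weight 0.2); singular values are
  clipped so the condition number stays ≤ 20. This is explicitly not a
  head model — what matters for testing is a known, localized,
  well-conditioned mixing.
* **Subject misalignment.** Every subject's data pass through an
  orthogonal matrix rotating ⌊C/2⌋ random planes by the misalignment angle
  (default 0.5 rad), so ‖Q−I‖₂ = 2 sin(θ/2) ≤ θ and signal power is
  preserved exactly. Orthogonality keeps the SNR bookkeeping exact; the
  angle is a free parameter (nothing in real data pins it) chosen to
  represent the combined effect of cap placement and individual anatomy,
  large enough that plain averaging visibly attenuates the shared signal
  (expected overlap cos θ per direction).
* **Noise.** Per-subject, per-trial sensor noise: half 1/f-shaped, half
  white, independent across subjects, scaled so the sensor-space
  signal-to-noise ratio equals `snr_db` exactly (default −12 dB;
  stimulus-tracking cortical responses are far below the ongoing EEG).
  `snr_db = inf` is the noiseless sentinel used by exactness tests.

Default study scale: 21 subjects × 48 trials (24 per condition) × 128
channels at 250 Hz, 5 s per trial. The subject, trial and channel counts
and sampling rate follow the emulated study design; the 5 s trial length
(vs ~60 s stories) and 500 sources (vs a dense cortical grid) are the
package's own desk-scale choices, made once.

## Hyperalignment (MCCA)

Covariance blocks are assembled from per-subject centered data (means are
stored in the model and reused at transform time). The generalized
eigenproblem `Bw = λRw` is solved with `scipy.linalg.eigh` after ridge
stabilization `R + ε·mean(diag R)·I` (ε = 1e−6; finite-sample covariance
blocks are near-singular). Canonical correlations are `ρ = λ/(I−1)` with
the normalizer read as the number of datasets I — the only reading under
which identical datasets give exactly ρ = 1, i.e. a 0–1 scale. Components
with non-positive eigenvalues are dropped and at most min(channel counts)
are kept.

**Component count.** Chance-level components of independent noise form a
flat low floor in the ρ spectrum while genuinely shared components stand
well above it, so the default retains components with ρ > 2 × median(ρ).
An energy rule (smallest K carrying 90% of Σλ) is available but not the
default: at realistic SNR the summed eigenvalue mass of the noise floor
makes it retain nearly all components, which defeats the truncation.

**Averaging space.** The canonical components are aligned across subjects
by construction, so the default averages the truncated component time
courses and renders them in a consensus montage via the pseudoinverse of
the subject-averaged truncated projection. This is the step that actually
compensates montage misalignment: back-projecting per subject first and
averaging the reconstructions (available as `space="electrode-subject"`)
leaves each reconstruction in that subject's own rotated montage, so the
average suffers the same signal cancellation as the naive average — it
denoises but does not align. Component-space output (`space="component"`)
is also available. The three pathways compared throughout are
single-trial (one subject, no denoising), naive average, and hyperaligned
average.

## Inverse solution

Minimum-norm kernel `T = L'(LL' + αI)⁻¹` with α expressed as a fraction
(default 0.05) of the mean eigenvalue of LL'; sLORETA standardization
divides each source estimate by √diag(TL). Orientations are scalar
(fixed), so standardization factors are scalars. ROI time courses are
plain means over member dipoles, no sign flipping (a sign-flip option
exists but is off). The noiseless point-source localization property of
sLORETA is exercised as a test. The consensus montage produced by
hyperalignment differs from the true lead-field montage by an O(sinθ/√I)
random mixing; this, plus the ROI-level point-spread of a C-channel
inverse over 68 regions, is the dominant error in kernel-recovery tests.

## TRF estimation

Forward encoders regress each region's time course on the causally lagged
envelope (lags 0–800 ms at the 4 ms sampling step); all regions share one
design, so the normal equations are factorized once. Backward decoders
regress the envelope on all regions' *future* samples (`x(t+τ)`,
τ ∈ [0, 800] ms) — the response follows the stimulus, so reconstruction
reads the response after the stimulus sample, the standard backward-model
convention. Ridge penalties are trace-normalized (`λ·mean(diag X'X)`);
ridge 0 falls back to least squares. Designs are zero-padded at trial
boundaries and centered trial-wise (no cross-trial leakage; Pearson
accuracy is shift-invariant, which also lets leave-one-out folds pool and
downdate per-trial Gram matrices instead of refitting from raw data).

Leave-one-out evaluation fits on the concatenated training trials with
the ridge chosen per fold from a log grid 1e−3…1e3 by mean reconstruction
correlation over two round-robin inner splits. The default pipeline
decoder uses a 40 ms lag step (21 lags × 68 regions = 1,428 features), a
deliberate compute/fidelity trade-off: the envelope is band-limited to
8 Hz, so 40 ms sampling of the decoder kernel loses little, while the
full 4 ms grid would make the fold-wise eigendecompositions ~100× more
expensive. Per-trial encoder TRFs (the network substrate) keep the full
4 ms grid.

Window statistics (`compare_trf_windows`) use the signed mean kernel
amplitude inside the lag window; pairs with zero difference variance
return t = 0 (identical sets) or raise a degenerate-variance error
(constant nonzero shift), since the paired t statistic is unbounded
there.

## Networks, communities, scales

Connectivity is the Pearson correlation between region TRF lag-courses
over the full grid; zero-variance rows get missing values, >10%
degenerate rows is an error. Condition-level networks are Fisher-z means
of the condition's trial matrices. Density thresholding keeps the
`⌈t·n(n−1)/2⌉` largest-|w| upper-triangle edges, signs preserved,
deterministic lexicographic tie-break; binarization to ±1 is for
display-style export only.

Signed modularity treats positive and negative subgraphs asymmetrically:
`Q = Q⁺ − v⁻/(v⁺+v⁻)·Q⁻`, each `Q±` a Newman modularity with resolution
γ (fixed at 1). The optimizer is a Louvain scheme (greedy local moves
with exact incremental ΔQ, then graph aggregation with self-loops, until
no gain) restarted `n_runs` times with seeded random node orders; the
single-community partition is always a candidate, so the returned Q never
falls below that baseline. Community labels are contiguous from 1 in
order of first appearance.

Variation of information uses plug-in entropies in nats from the
co-membership confusion table; identical partitions (up to relabeling)
return exactly 0.0. For scale selection each density's stability is the
mean VI to the partitions within ±2 neighbouring densities — a windowed
measure, because only a broad stability plateau (not a short accidental
one) indicates a robust scale; the selected density minimizes this among
densities whose separability F1 is within 0.02 of the maximum, ties going
to the smallest density. The consecutive-density VI curve itself is
recorded in the scan. This joint rule is this package's formalization of
an informal "stability + separability + modularity" selection; the
original procedure it models was never fully specified.

## Separability evaluation

Trial networks are vectorized to their upper triangle (row-major;
68 regions → 2,278 features), embedded in 2-D with exact-gradient t-SNE
(PCA-initialized, perplexity 10, seeded; the exact gradient is affordable
at ≤ 50 trials and, unlike Barnes–Hut, maps duplicate trials to
coincident points), and clustered with k-means from random
initializations. F1 is computed after matching cluster ids to the two
condition labels by the assignment that maximizes it, then averaged over
repetitions. Best-assignment matching puts the chance level *above* 0.5
(empirically ≈ 0.55–0.70 at 24+24 trials), so chance is calibrated
empirically rather than assumed.

## What passing tests show — and what they do not

The synthetic generator plants exactly the structure the analysis
assumes: a linear time-invariant response identical across subjects,
orthogonal misalignment, Gaussian 1/f noise independent across subjects,
and community-structured kernels. Passing tests therefore show the
estimators are *correct* and the chain is *coherent* — they do not show
robustness to what real EEG adds: nonstationarity, artifacts (blinks,
EMG), volume-conduction physics, per-subject response differences,
attention drift, or non-orthogonal montage differences. Two honest
consequences of the clean linear world: the decoding advantage of
hyperaligned over naive averaging is real but modest (a well-regularized
decoder is itself a strong denoiser, and misalignment compensation is the
main effect), and network separability is sharper than real data would
give.

## Problem sizes and determinism

Default analyses run at 21 subjects × 48 × 5 s trials, 128 channels, 500
sources, 68 regions; tests and the acceptance script use these defaults
for end-to-end checks and smaller configurations for unit-level checks.
Every stochastic stage draws a child seed derived from the run seed and a
stage label (CRC-mixed `SeedSequence`), so runs are bitwise reproducible
and stages are independently reseedable; reports carry the configuration
hash and can be hashed bit-for-bit.

## Known limitations

* The lead field is a 2-D sheet abstraction; no realistic geometry,
  orientation constraints beyond scalar sources, or tissue conductivity.
* ROI aggregation without sign-flipping can cancel sources if a real
  (signed) lead field were used; with the nonnegative receptive-field
  model this does not arise.
* The signed Louvain is dense-matrix (fine for ≤ a few hundred nodes, not
  for voxel-level graphs).
* `extract_envelope` approximates a gammatone bank with ERB-spaced
  Butterworth bands; for perceptual-model fidelity substitute a true
  gammatone implementation.
* Decoder evaluation uses one condition's 24 trials per fold set, as in
  the emulated design; other splits are not implemented.
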