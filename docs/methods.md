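# Methods

## The model of behaviour

The pipeline treats behaviour as a trajectory through a space of postural
dynamics. Its core assumption is that stereotyped behaviours are epochs in
which the *spectral content* of the posture — which postural modes
oscillate, at which frequencies — is approximately constant, so the
trajectory in a suitable space pauses; transitions between behaviours are
fast excursions. Nothing in the pipeline names or supervises behaviours:
the categories are density peaks of the embedded data.

The stages and their assumptions:

* **Segmentation / registration** assumes one animal per frame, clearly
  contrasted against the background (either polarity; intensities are
  inverted when the body is darker than the background, so aligned stacks
  always carry a bright foreground on an exactly-zero background). Rotation
  is estimated by cross-correlating polar-unwrapped images about the
  intensity centroid (0.5°/bin with parabolic peak interpolation); the
  head/tail 180° ambiguity of a nearly symmetric body is resolved by the
  sign of the intensity skewness along the body axis, which assumes the two
  body halves differ in mass. Translation uses Fourier-upsampled phase
  correlation (default precision 0.05 px) with Fourier shifting, wrapped
  borders zeroed. Size is normalized per movie by a single isotropic factor
  `sqrt(reference_area / median foreground area)`.
* **Postural decomposition** applies PCA in Radon space (line-integral
  projections over 0–179° in 1° steps by default; tests use coarser angle
  sets for speed). When the mode count is not fixed, it is chosen by the
  shuffled-spectrum criterion: eigenvalues are kept while they exceed the
  rank-matched maximum over 3 spectra of column-shuffled data — shuffling
  destroys correlations but preserves marginals, so surviving modes carry
  correlation above finite-sampling error.
* **Spectral features** use the Morlet wavelet with centre frequency
  ω₀ = 5 (a standard trade-off between time and frequency resolution,
  suited to isolating chirps of periodic motion) over 25 channels
  log2-uniformly spaced from 1 Hz to Nyquist. Amplitudes are normalized so
  a unit sinusoid at any channel's centre frequency produces unit response
  at that channel — this flat-response convention is what the tests pin
  down. Phase is discarded, making features invariant to temporal
  alignment. Edges are zero-padded; frames inside the lowest channel's cone
  of influence are retained but flagged (`edge_valid`). Frames with zero
  total amplitude are flagged invalid and excluded from embedding; their
  embedded coordinate is carried forward from the previous frame.
* **Embedding**: KL divergence on normalized spectra (base-2 logs
  throughout, so H = 5 bits ⇔ perplexity 32; a floor of 1e−12 on the
  q-channels guards against zeros, which arise only from degenerate input).
  Per-point kernel widths are bisected until each row's transition entropy
  is within 1e−3 bits of H. The t-SNE objective uses symmetrized joints
  p_ij = (p(j|i) + p(i|j)) / 2N against a Cauchy kernel in the plane, with
  early exaggeration 12× for 250 of 1000 iterations, learning rate N/12,
  and momentum 0.5 → 0.8 — the canonical recipe. Training points are
  importance-sampled per movie (quota ∝ movie length, within-movie
  probability ∝ k-NN radius with k = 32, i.e. inverse local density), so
  rare behaviours are represented. Held-out frames are re-embedded one at a
  time: a transition row to the training set is calibrated at the same H,
  and the point minimizes the KL objective against the fixed training
  coordinates by momentum gradient descent initialized at its nearest
  training neighbour.
* **Map coordinates**: the raw span of a t-SNE solution is arbitrary — it
  grows with training-set size and iteration count — so the pipeline
  rescales pooled coordinates to a fixed RMS map radius (default 6.5)
  before any density estimation. This normalization is what gives the
  density smoothing width σ stable meaning; the default places the working
  σ range (1–2.5) on the plateau between over-segmenting single behaviours
  and merging distinct ones, and state recovery on synthetic cohorts is
  stable across that range.
* **Behavioural map**: density is a histogram on a 301–501² grid convolved
  with an isotropic Gaussian (σ = 1.5 map units by default), normalized to
  unit integral, with the grid extended 3σ beyond the data. The watershed
  of the negated density is restricted to cells above 10⁻³ (pipeline) or a
  configurable fraction of the peak density — an unbounded KDE otherwise
  floods to background — and region labels are ordered by descending peak
  density for reproducibility. Speeds are central differences with a 0.05 s
  Gaussian smoothing window; the pause threshold is the equal-posterior
  point of a two-component Gaussian mixture on log speed (EM via
  scikit-learn, variance floor 1e−6, flagged degenerate when the component
  means sit closer than the sum of their widths). Dwells are maximal
  pausing runs inside one region lasting at least 0.05 s.
* **Phase**: per-mode protophases are Hilbert angles; each is corrected to
  a uniformly rotating phase with an order-4 Fourier transform of its
  empirical distribution, aligned in offset (and 2π branch) to the
  lowest-index oscillating mode so the phase reference is intrinsic to the
  signal, and combined with weights ∝ inverse circular variance of each
  mode's residual. Mode reliability (envelope dipping below 10% of its
  median) gates the weights, never the reference. `reconstruct_phase`
  band-passes each mode around the bout's dominant frequency (half to
  double, zero-phase Butterworth) before the Hilbert transform; without
  it, broadband noise causes phase slips that bias the frequency upward.
  The mean frequency is the median phase-increment slope, robust to
  residual slips. Phase-averaged orbits use 50 bins; bin means are computed
  per bout first, so the SEM reflects between-bout variability including
  phase-estimation wobble rather than the optimistic pooled-frame scatter.
* **Group comparison**: per-individual densities share one grid; the
  pointwise two-sided test is Mann–Whitney U (identical to the Wilcoxon
  rank sum, but tie-corrected — map fringes contain exact zeros for many
  individuals) at α = 0.01 uncorrected, with a Benjamini–Hochberg mask
  reported alongside because pointwise testing on a smoothed map is
  anticonservative. A cell is testable when at least one individual of
  either group has nonzero density there, so behaviours present in only
  one group are testable. Orbit comparisons flag phase bins where group
  means differ by more than 2 combined SEMs, and report the frequency
  difference with its standard error separately — orbit shape and cycle
  frequency can differ independently.

## The synthetic generator

`synthetic.synth_movie` renders an anti-aliased dark elliptical body
(semi-axes 22 × 9 px, intensity 0.65 against a 0.9 background) with a
brighter head blob (breaking the 180° symmetry) and Gaussian-blob
appendages oscillating at set frequencies, under a rigid trajectory, plus
clipped additive Gaussian pixel noise (σ = 0.02). It emulates what the
imagery stage assumes — a rigid contrasting body with moving parts — and
returns the true per-frame pose.

`synthetic.synth_state_timeseries` emulates the statistical structure the
mapping stages assume: a Markov chain over K states (default 6), each a
limit cycle with its own frequency (log-spaced 2–32 Hz, inside the 1–50 Hz
analysis band), unit amplitude, and a random orthogonal pair of loading
vectors over m modes (default 8), with additive Gaussian noise σ = 0.1
(amplitude SNR 10) and mean dwell 1 s. Cohorts add per-individual
lognormal jitter (5%) on amplitudes and frequencies and an optional group
effect (an extra active mode in one state).

What the generator does **not** emulate: occlusions, illumination drift,
non-rigid body deformation, correlated (non-white) sensor noise,
behaviour sequences with long-range structure, or continuous behaviours
without discrete states. Passing tests therefore demonstrate that the
pipeline recovers planted structure of the kind it assumes; they do not
certify performance on real video with those additional complications.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: cohorts of
3 individuals × 2×10⁴ frames at 100 Hz, t-SNE training sets of 2 500
points (the exact-gradient implementation is O(N²); 2 500 was verified to
give the same state recovery as 5 000 on these cohorts), re-embedding in
blocks of 4 000 with transition rows calibrated over the 256 nearest
training candidates (the Gaussian kernel at perplexity 32 is numerically
zero beyond that), and density grids of 301². Gradient loops run in
float32 with preallocated buffers; results are deterministic given the
seed. Covariance fitting subsamples uniformly above 5×10⁵ frames.
Training-set density estimation uses a ≤2 048-point reference subsample
per movie.

Degenerate inputs: blank frames raise a "no animal" error and are excluded
with their indices reported; constant series raise "no oscillation";
zero-amplitude feature frames are flagged and excluded from embedding;
rotationally symmetric foregrounds return angle 0 with a warning;
equidistant transition rows return the uniform distribution with a warning
when their entropy cannot reach the target.

## Known limitations

* Watershed region counts at the extremes of the smoothing range
  (σ ≈ 1.0) vary by ±1–2 across random cohorts; the dwell-to-state
  assignment remains accurate (ARI ≳ 0.8) but the region count is the
  more fragile statistic.
* Re-embedding optimizes each point independently against the fixed map;
  points genuinely between two clusters land on low-density saddles,
  which is intended, but the per-point objective is non-convex and a
  point equidistant from several clusters can settle in any of them.
* The pointwise significance map is uncorrected by design (the FDR mask
  is reported alongside); with heavy smoothing, neighbouring cells are
  strongly dependent and cluster sizes of flagged cells should not be
  over-interpreted.
* The rotation registration assumes the body's intensity skewness along
  its axis is stable; an animal whose apparent head/tail asymmetry flips
  (e.g. strong appendage occlusion) could flip orientation for isolated
  frames.
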