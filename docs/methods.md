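# Methods

This note documents the models, estimators and numerical choices behind
`mseeg`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Signal model and preprocessing

A recording is a channels × samples matrix in microvolts with a sampling
rate and channel labels.  All filters are 4th-order Butterworth band-passes
applied forward–backward (`sosfiltfilt`), i.e. zero-phase: group delay
would corrupt the inter-channel phase relations on which the phase lag
index depends.  Average referencing subtracts the instantaneous mean over
channels; filtering and referencing are both linear and commute (tested to
1e-8).

Clean-segment selection is a deliberate simplification of interactive
artifact review: the recording is tiled into 25-s candidate segments and
each segment is scored by the 95th percentile of per-channel robustly
z-scored absolute amplitude (median/MAD scale), maximised over channels.
MAD-based scaling matters — with mean/SD scaling the artifacts inflate the
scale themselves, and dense bursts can never exceed a fixed z threshold.
Segments scoring above z = 5 are rejected; the lowest-scoring survivors
are concatenated in temporal order until at least 180 s are available.
Bad channels are dropped, not interpolated; region summaries then use the
surviving channels.  Independent-component artifact removal and
spline interpolation are out of scope.

The bundled 22-region scheme (11 regions per hemisphere: frontal-polar,
frontal midline/lateral, central midline/lateral, temporal
anterior/posterior, parietal lateral/midline, parieto-occipital,
occipital) assigns 170 of 214 channels to regions of 7–8 electrodes;
midline/face/neck channels are excluded.  Arbitrary montages can supply
their own 22-region mapping.

## Spectral analysis

Power spectra use the Thomson multitaper method (via MNE's
`psd_array_multitaper`) with time–bandwidth product NW = 4 and 7 DPSS
tapers on 4-s epochs (0.25-Hz grid); the per-channel spectrum is the
median over the 12 epochs, and a region's spectrum is the median over its
channels.  Band power is the sum of PSD bins in half-open bands
[lo, hi) — delta [1,4), theta [4,8), alpha1 [8,10), alpha2 [10,13), beta
[13,30) — so the five bands tile [1, 30) exactly and relative powers sum
to 1 by construction (bin width cancels in the ratio).  A 10-Hz component
belongs to alpha2, not alpha1.  The logit transform log(p/(1−p)) clips p
to [1e-6, 1−1e-6] so degenerate spectra stay finite.  Median frequency
interpolates linearly inside the bin where cumulative 1–30 Hz power
crosses one half; peak frequency is the 1–30 Hz argmax.  Both are taken
per parieto-occipital electrode and summarised by the median.

## Microstate segmentation

GFP_t = √(Σᵢ uᵢ²/n) on average-referenced data (the spatial standard
deviation).  Topographies at strict local GFP maxima are clustered with a
polarity-invariant ("modified") k-means: maps are unit-normalised,
assignment maximises squared spatial correlation, and the template update
is the first principal component of the assigned maps with its sign fixed
to the majority polarity.  20 random restarts, convergence when
assignments stabilise or after 100 iterations, empty clusters re-seeded
at the worst-explained map.  Clustering quality is the global explained
variance (GEV), weighting each peak map by its squared norm.  When more
than 1000 peak maps are available they are deterministically subsampled
to 1000 — standard practice in microstate tooling; templates are
insensitive to this, and it keeps the full k-scan tractable.

The cluster count is selected over k = 2–20 by the Krzanowski–Lai
criterion on the within-cluster dispersion W(k) = mean(1 − r²):
DIFF(k) = (k−1)^(2/p) W(k−1) − k^(2/p) W(k) with p the channel count, and
KL(k) = |DIFF(k)| / |DIFF(k+1)|, maximised globally.  Two numerical
choices stabilise this: (i) for each k one restart is warm-started from
the previous k's templates plus one extra map, keeping W(k) close to
monotone; (ii) the KL denominator is floored at 5 % of max|DIFF| — beyond
the true cluster count both DIFF values hover around zero and their raw
ratio can spike arbitrarily, whereas a genuine elbow has a numerator at
the scale of the largest drop.  All-identical maps (zero dispersion)
return k_min with a warning.

Back-fitting labels every sample with the template of maximal squared
correlation and then applies sliding-window majority relabelling,
iterated to a fixed point (at most 10 passes).  The window is
round(12 ms × fs) samples (12 samples at 1000 Hz) and must be at least
one sample; ties keep the current label.  Templates may be fitted per
recording (default) or supplied externally, so a common template set can
be back-fitted across subjects.

Polarity invariance holds throughout: negating the recording leaves GFP,
peaks, labels and templates (up to sign) unchanged.

## Connectivity

PLI between two channels is (1/k)|Σᵢ sign(sin ΔΦᵢ)| with sign(0) = 0 —
the asymmetry of the phase-difference distribution.  It is 0 for
zero-lag (volume-conducted) synchrony and 1 for any constant nonzero lag,
and is invariant to a common phase offset.

Two estimation routes:

* **Standard PLI** — each of 12 non-overlapping 4-s epochs is
  band-filtered, Hilbert-transformed whole, and contributes one PLI
  matrix; the 12 matrices are averaged.
* **msPLI** — phases come from a single sliding-window Hilbert transform
  of the full-length band-filtered recording (4-s Hanning-tapered windows,
  50 % overlap; each output sample is taken from the central half of its
  window, where the taper is flattest, except at the recording edges).
  For each microstate class the earliest 16 000 samples carrying that
  class's label are stitched in temporal order, cut into 4 periods of
  4000 phase differences, and a PLI matrix is computed per period.  The
  class matrix is the 4-period average, and the subject matrix averages
  all 20 class-period matrices (5 classes × 4 periods).  Stitching needs
  no tapering across segment boundaries: each sample contributes only the
  sign of sin ΔΦ, which no neighbouring sample can alter.  A class with
  fewer than 16 000 labelled samples is a hard error naming the class.

A finite-sample property worth knowing: on band-limited signals the
phase difference of *independent* channels decorrelates only on the
timescale of the inverse bandwidth, so a 4-s theta-band window contains
only ~25 effectively independent phase samples and the null expectation
of a single-window PLI is ≈ √(2/(π·k_eff)) ≈ 0.17 — not the ≈ 0.013 an
i.i.d. calculation at k = 4000 suggests.  Averaging window magnitudes
does not shrink this floor.  PLI computed on one long stitched series
does shrink it (< 0.1 at 180 s), and planted couplings sit far above it;
all contrasts in the validation suite are therefore relative.

Region reduction replaces the channel-space matrix by the 22 × 22 matrix
of means over all electrode pairs spanning two regions.

## Graph measures

All measures act on a symmetric, zero-diagonal weight matrix with entries
in [0, 1] (dense PLI matrices; no thresholding, so no node is ever
artificially disconnected):

* degreeᵢ = mean weight of node i's links;
* Cᵢ = ΣΣ W_ik W_il W_kl / ΣΣ W_ik W_il (k ≠ i, l ≠ i, l ≠ k), Cw = mean;
  zero denominators (leaf/isolated nodes) give Cᵢ = 0 with a warning;
* edge length L = 1/W (∞ for W = 0); shortest paths by Dijkstra;
  Lw = 1/mean(1/L_ij) (harmonic form, finite under disconnection);
  eccentricity Ecᵢ = max_j L_ij, radius = min Ec, diameter = max Ec;
* Kw = ⟨degree²⟩/⟨degree⟩, high for hub-dominated networks;
* Rw = Pearson correlation of endpoint degrees over present edges, with
  each edge contributing both orientations (symmetric in node order);
  returned as NaN when endpoint degrees have no variance (regular graphs);
* gamma = Cw/Cr and lambda = Lw/Lr, where Cr, Lr average 50 surrogate
  networks whose upper-triangle weights are reshuffled (weight multiset,
  symmetry and zero diagonal preserved), the 50-surrogate average being
  repeated 5 times and the repetitions averaged (250 surrogates total —
  our reading of "50 surrogates iterated five times").

Every formula is cross-checked against brute-force implementations on all
random matrices of up to 6 nodes in the test suite.

## Statistics

Group differences use permutation tests (one-way ANOVA F or two-sample
pooled t, 10,000 label permutations by default) with the inclusive
p-estimator (1 + exceedances)/(1 + n_perm), which cannot be zero.
Family-wise error across features uses the max-statistic method: the
maximum statistic over features is recorded per permutation and each
feature's corrected p is the exceedance rate of that maximum — the
standard permutation-coherent multiple-comparison correction.  Correction
is applied within the feature family passed in (by default one band's
regions/links); feature–domain correlations correct across all
(feature, domain) pairs with max-|r|.  Constant features get p = 1 with a
warning.

The classification score is a logistic regression with backward
elimination: the predictor with the largest likelihood-ratio p is removed
until all retained predictors have p < 0.05.  Perfect separation is
flagged and the coefficients refitted with a ridge-penalised logistic
model so the score remains usable.  Link features should be entered as
log values.  The two-stage design fits the model on one group pair and
applies the frozen linear score to a different pair; the operating
threshold maximises the Youden index J = sensitivity + specificity − 1,
with ties broken toward higher specificity, and a score exactly at the
threshold classifies positive (≥ convention).  AUC uses the rank
(Mann–Whitney) statistic.

## Synthetic data generator

The generator emulates the statistical structure the pipeline estimates,
not the biophysics:

* background: per-channel 1/f^α noise (α = 1 by default), RMS 10 µV;
* microstates: n_states (default 5) random orthonormal topographies
  (QR of a seeded Gaussian matrix) switching by a first-order Markov
  chain with geometric dwell (default mean 100 ms, inside the empirical
  50–150 ms range) and uniform transition targets; the active template is
  driven by a 9–11 Hz band-noise activation waveform, and SNR is defined
  as RMS(template signal)/RMS(noise) over the whole matrix (default 2);
* coupling: a CouplingSpec adds a constant-envelope, frequency-modulated
  oscillation inside the named band to both channels of a pair, the
  second copy delayed by the integer sample count matching the requested
  phase lag at band centre, and masked to the requested microstate
  classes.  A constant envelope is used deliberately: Gaussian band noise
  has Rayleigh envelope fading during which the planted lag is masked by
  background noise, capping the downstream PLI near 0.88 however strong
  the source; a constant-envelope rhythm realises the constant-lag
  coupled oscillation that the CouplingSpec ground truth promises.  Strength 1
  scales the source to 3× the noise RMS, making it the dominant rhythm of
  its band;
* group studies: per-subject recordings (seeded via `SeedSequence`
  spawning, so groups are exchangeable at zero effect) plus six
  standard-normal neuropsychological domain z-scores, with optional
  per-group shifts of coupling strength and domain scores.

Not emulated: volume conduction / forward modelling, eye-blink or muscle
artifact morphology, electrode-position geometry, spectral peaks beyond
the activation band, non-stationarity across minutes.  Passing tests
therefore demonstrate estimator correctness and sensitivity under known
ground truth, not clinical performance on real EEG.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 200 random series
(k ≤ 5000) for PLI exactness; 500 trials at k = 4000 for the uniform
null; 100 random ≤ 6-node matrices for graph oracles; twenty 180-s,
24-channel, 1000-Hz recordings at SNR 2 for cluster-count recovery and
three at SNR 5 for label agreement; twenty 180-s 16-channel recordings
with class-confined theta coupling for the msPLI contrast; and 200 null
datasets × 1000 permutations for family-wise-error calibration.  These
sizes give stable Monte-Carlo estimates while keeping a full run to a
few minutes.

## Known limitations

* The artifact score targets amplitude artifacts only; low-amplitude
  artifacts (drowsiness, chewing) pass through.
* Group-level template aggregation across subjects is not implemented;
  external templates can be back-fitted per recording.
* The Krzanowski–Lai floor (5 % of max|DIFF|) is a heuristic guard; very
  shallow true elbows could in principle be damped along with the noise.
* The minimal EDF writer covers equal-rate, 16-bit, single-record-layout
  files only (sufficient for the synthetic export; reading goes through
  MNE's EDF parser).
* With few channels, average referencing mixes every channel into every
  other at ratio 1/n, which can leak a strong planted source into
  nominally uncoupled channels; at realistic channel counts (≥ 64) the
  effect is negligible.
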