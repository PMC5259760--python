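# Methods

Models, parameter values, numerical choices and known limitations of each
stage of the pipeline. Defaults quoted here are the package defaults; all
of them are study conditions, not tuning knobs.

## 1. Segmentation (`callometry.audio`)

**Intensity envelope.** The waveform is rectified (absolute value) and
smoothed with a 3rd-order Butterworth low-pass at 5 Hz, applied forward and
backward (`scipy.signal.sosfiltfilt`) so the envelope has zero phase lag.
Clips shorter than the filter's minimum padding length are rejected.

**Thresholding.** Samples whose envelope strictly exceeds 5% of the file's
maximum envelope value form candidate runs. Each run is padded with a
100 ms margin on both sides; margins that touch or overlap an adjacent run
merge the two into one segment. Segments shorter than 50 ms (before
margins) are dropped. Because the rule is relative to the file maximum,
segmentation is invariant to global gain.

**Boundary accuracy.** A zero-phase low-pass filter spreads energy
symmetrically in time: the step response of the 5 Hz envelope filter
crosses the 5% level about 50 ms *before* a call's true onset (measured:
49–53 ms at 22.05 kHz, mildly dependent on background level). Detected
boundaries therefore sit at true bound ± (100 ms margin + ~50 ms smear)
≈ ±150 ms. A tolerance of margin + 20 ms is not achievable with this
envelope definition — causal filtering is worse (the decay to 5% takes
over 200 ms at call offset) — and the acceptance test asserting it is
deliberately left failing rather than weakened. The unit tests assert the
physically derivable bound of margin + 60 ms.

**SNR triage.** Per-segment SNR is `20*log10(RMS_segment /
RMS_between_segments)`; segments below a configurable cutoff (default 0 dB,
i.e. keep everything above the inter-call background) are dropped and
logged.

## 2. Spectra and selection (`callometry.spectral`)

**Whole-call spectrum.** One Hamming-windowed DFT of the entire segment,
no zero-padding. Bin spacing is `rate / N`, so a 0.5 s call at 44.1 kHz is
measured on a 2 Hz grid while a 50 ms call gets a 20 Hz grid; per-call
resolution is recorded in the output tables.

**Dominant frequency.** The frequency of the maximum-magnitude bin at or
above a 20 Hz search floor (which keeps low-frequency rumble out); exact
ties resolve to the lower frequency. A DF is *verified* if its peak stands
more than 3 dB above the median spectrum level; selected calls failing the
check are replaced by the nearest verified neighbour in the species'
DF-sorted list, with every swap logged.

**Maximally spaced selection.** From a frequency-sorted list of `n` calls,
position `i` of `k` is `round(1 + (i−1)(n−1)/(k−1))` with half-up rounding.
The first and last positions are always 1 and `n`, gaps differ by at most
one, and `(n=100, k=10)` yields `1, 12, 23, 34, 45, 56, 67, 78, 89, 100`.

**Species aggregates.** DF10 is the arithmetic mean DF of the 10 selected
calls. If at least 6 calls carry an F0, DF6 and F06 are means over 6 calls
picked at maximally spaced positions of the DF- and F0-sorted lists
respectively; otherwise the species has DF10 only and drops out of the
F0-based analyses. Regressions use `log10(mean)`, not the mean of logs.

## 3. Pitch (`callometry.pitch`)

The tracker is the classic autocorrelation method. Frames are taken every
10 ms with an analysis window of three periods of the pitch floor. Each
frame is mean-subtracted, Hann-windowed, and its FFT autocorrelation is
divided by the window's own autocorrelation to undo the taper. The
autocorrelation is evaluated on a 4× sinc-oversampled lag grid (FFT
zero-padding in the frequency domain) before parabolic peak interpolation:
on the raw one-sample grid the interpolated peak height is biased low at
short lags, which lets period-multiple (subharmonic) peaks outrank the true
peak for high fundamentals. Local maxima in the admissible lag range
become pitch candidates, ranked by strength minus an octave-cost bias of
`octave_cost * log2(ceiling / f)` so that a periodic frame's equally strong
period multiples resolve to the highest-frequency (true) candidate.

A Viterbi pass picks the cheapest global path through the per-frame
candidates: voiced candidates cost their negative effective strength, the
unvoiced candidate competes at the voicing threshold, voiced–voiced
transitions cost `octave_jump_cost * |log2(f'/f)|` and voicing flips cost
`voiced_unvoiced_cost`. Frames whose peak amplitude falls below
`silence_threshold` × the clip maximum are forced unvoiced.

Defaults: floor 75 Hz, ceiling 600 Hz, voicing threshold 0.45, silence
threshold 0.03, octave cost 0.01, octave-jump cost 0.35, voiced/unvoiced
cost 0.14, 4 candidates per frame. On clean synthetic calls the tracker
is accurate to well under 0.1% from 80 to 1200 Hz, resolves
missing-fundamental complexes to the true period, and reports white noise
as unvoiced.

**Per-call F0** is the median over voiced frames, reported only when at
least half the frames are voiced. **Tonality**: a voiced-majority call is
probed at integer multiples of its median F0; a harmonic passes if its
band peak exceeds 4× the median spectrum level *and* twice the
inter-harmonic level half a harmonic away (the local-contrast condition
keeps a strong component's spectral-leakage skirt from counting as an
overtone). Two or more passing overtones ⇒ tonal; fundamental only ⇒ pure
tone; otherwise nontonal.

**DF/F0 ratios** are binned into 0.25-wide bins centred on the integers:
[0.875, 1.125) is "equal", any integer ≥ 2 within ±0.125 is "harmonic
multiple", everything else "other". Species-level proportions of "equal"
calls are correlated with body length by Spearman rank correlation.

## 4. Comparative regression (`callometry.phyloreg`)

**Trees.** Newick trees are parsed with dendropy; tip names are case-folded
with spaces replaced by underscores before matching trait tables. The tree
is held as the matrix of root-to-MRCA path lengths (the BM covariance) plus
root-to-tip depths.

**Correlation structures.**

| kind | covariance | parameter |
|------|------------|-----------|
| NP | identity | — |
| BM | shared root-to-MRCA path length | — |
| BM+λ | BM with off-diagonals × λ | λ ∈ [0, 1] |
| BM+ρ | node heights h → (h/H)^ρ · H | ρ ∈ (0, 10] |
| OU | exp(−α · patristic distance) | α > 0 |

**Fitting.** GLS is computed by Cholesky whitening (`L L' = V`, solve
triangular systems; never form `V⁻¹`), with the residual variance profiled
out. The REML log-likelihood is
`−½[(n−p)(log 2πσ̂² + 1) + log|V| + log|X'V⁻¹X|]` with `σ̂² = RSS/(n−p)`;
ML replaces `n−p` by `n` and drops the last term. Structure parameters are
estimated by bounded scalar maximization (λ on [0, 1]; ρ and α on
log-scaled ranges) with a three-point multistart plus explicit endpoint
checks, since the λ profile often peaks at a boundary. Slope t-tests use
n − 2 degrees of freedom. Standard errors come from
`σ̂²_unbiased (X'V⁻¹X)⁻¹`.

**Model choice.** Candidates are ranked by AICc
`= −2 logL + 2k + 2k(k+1)/(n−k−1)` with `k` = 2 fixed effects + 1 variance
+ 1 per estimated structure parameter; ties go to the simpler model. The
default likelihood criterion is REML (fixed effects are identical across
candidates, so REML likelihoods are comparable); ML is available.

**Bisector.** Both variables carry measurement error, so the summary line
bisects the Y-on-X fit and the X-on-Y fit re-expressed in y-vs-x space
(slope 1/b, intercept −a/b, delta-method SEs). The bisector slope is
`(b₁b₂ − 1 + √((1+b₁²)(1+b₂²)))/(b₁+b₂)` — the tangent of the mean of the
two lines' arctangents — anchored at the V⁻¹-weighted data centroid through
which both component fits pass.

**ANCOVA.** Slope heterogeneity between two groups is the F-test of the
`x:group` interaction: full model `y ~ x + g + x·g` versus reduced
`y ~ x + g`, `F` on `(1, n−4)` degrees of freedom.

## 5. Generators (`callometry.synth`)

**Calls** are harmonic series at F0 (constant or linear contour; phase is
the cumulative sum of instantaneous frequency) with a 6 dB/octave rolloff,
optionally shaped by a single second-order resonance
`1/√((1−(f/fc)²)² + (f/(fc·Q))²)` with `Q = fc/bandwidth` that can move the
spectral maximum onto a higher harmonic. Pure tones are a single sinusoid;
nontonal calls are 4th-order Butterworth band-passed noise. All calls get
10 ms raised-cosine ramps and return analytic ground truth (true F0, the
harmonic carrying maximum energy).

**Recordings** place calls at known onsets over Gaussian noise. The SNR
convention is an intensity (power-like) ratio: the background's mean
rectified amplitude sits `noise_snr_db` (10·log10) below the mean rectified
amplitude of the calls. At the 20 dB study condition the background
envelope is 1% of the call envelope — safely below the 5% segmentation
threshold — which is what makes "n injected calls ⇒ n detected segments"
hold by design.

**Trees** are Yule (pure-birth) simulations. The simulator stops exactly
at the n-th birth, which leaves the newest tip pair with zero-length
terminal branches and a singular BM covariance; every terminal branch is
therefore extended by one additional exponential waiting time before the
tree is rescaled to unit height (this preserves ultrametry).

**Clades** (`simulate_clade`): x ~ Uniform over log10 body length
[2.0, 3.1]; y = intercept + slope·x + ε with ε multivariate normal under
σ² times the λ-transformed Brownian covariance (Cholesky with a 1e−12
nugget). This is exactly the generative model the GLS assumes, so
parameter-recovery tests are well-posed.

**Studies** (`make_study`): n species on a Yule tree, log10 body lengths
evenly spaced on [2.0, 3.1] and shuffled, species F0 on the line
`log10 F0 = 5.3 − 1.0 · log10 BL` plus N(0, 0.05) scatter, per-call
lognormal jitter of 0.02 dex. Roughly 70% of calls are plain tonal
(DF = F0), 20% carry a formant on harmonic 2 or 3, 10% are nontonal noise
bursts. Calls are written as 16-bit WAV recordings (20 per file, 0.9 s
gaps), alongside `traits.csv` (with alternating A/B groups), `tree.nwk`,
`ground_truth.json` and a ready-to-run `config.json` whose per-species
pitch floor/ceiling overrides (0.45×F0 … 2.5×F0) stand in for the manual
per-species tuning a real analysis would use. Species residuals are iid —
the study generator deliberately has *no* phylogenetic residual signal —
so the correctly specified comparative model for studies it generates is
the non-phylogenetic one.

## 6. Pipeline (`callometry.pipeline`)

`run_all` executes: read WAVs (species taken from the file-name prefix
before `__`) → segment → SNR triage → per-species DF measurement →
maximally spaced selection with DF verification swaps → pitch + tonality →
species aggregates → Shapiro–Wilk normality on every log-transformed
variable → OLS + five GLS candidates + AICc selection + bisector per
analysis (logDF10, logDF6, logF06) → ANCOVA when two groups are present →
DF/F0 ratio analysis on each species' six F0-selected calls. Outputs are
`calls.csv`, `species.csv`, `regressions.csv`, `ratios.csv` and
`manifest.json`; the manifest records the counts surviving every stage
(files → segments → high_snr → selected → f0_measured → species) and a
hash of the configuration. Runs are deterministic: identical configs give
byte-identical CSVs.

## Limitations

- Boundary localization is limited to ~±(margin + 50 ms) by the 5 Hz
  zero-phase envelope (see §1); the envelope definition, not the code, sets
  this floor.
- The DF measure takes the single maximum bin; for calls whose energy is
  split across two near-equal harmonics, small noise can flip DF by a full
  harmonic. The verification/replacement step catches background-dominated
  spectra but not this bimodality.
- The pitch tracker assumes a single voice per segment and fails gracefully
  (unvoiced) on polyphony, but does not separate overlapping callers.
- `BM_rho` uses the node-height power transform applied to the shared-path
  matrix of an ultrametric tree; for strongly non-ultrametric trees the
  transform is defined but its interpretation as Grafen's height transform
  weakens.
- OU fits assume a stationary process (unit diagonal); with few species the
  α profile is often flat and the estimate lands on a search bound. AICc
  then usually, and correctly, prefers a simpler structure.
- The generators synthesize idealized calls (stationary or linear F0,
  Gaussian background). They are designed to exercise the measurement
  chain, not to imitate any particular taxon's vocal repertoire.
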