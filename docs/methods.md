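# Methods

## The decision problem

One classification decision is made per *episode*: an L_e-second frame
(default 8 s) cut from a single-lead ECG at 1-s strides. Inside an
episode, both discrimination indices operate on 2-s *analysis windows*
stepped by 1 s, giving L_e − 1 windows. The 2-s window is a compromise:
whole-episode statistics are dragged down when the rhythm's amplitude
collapses mid-frame (common in decaying VF), while 1-s windows are too
short to be stable. Because each window is renormalised to its own peak,
a damped stretch still contributes a full-scale value — the package
asserts this property directly on fixtures whose amplitude drops 4×
mid-episode.

## Stage 1 — mean signal strength (MAV)

The whole episode is filtered by the stage-1 zero-phase chain (below),
then each 2-s window is divided by its own maximum absolute value and
scored by MAV = (1/N) Σ |x(n)|; the episode index MAV_a is the arithmetic
mean over the L_e − 1 windows. The index separates rhythm classes by duty
cycle: a normal QRS train hugs the baseline most of each cycle (MAV_a
roughly 0.08–0.2, and ≈ 0.64 · peak-fraction for tone-like signals),
whereas VT and VF stay off baseline (≳ 0.33). The decision is strict:
MAV_a > MAV_d routes to the VT/VF branch, with MAV_d = 0.27 for 8-s
episodes the shipped default. No retraining logic is bundled; the
`threshold_histogram` routine recomputes class-conditional index
distributions and suggests a cut maximising sensitivity + w·specificity
(w ≥ 1, our rule) on user-supplied data.

## Stage 2 — EMD residual (NMAV)

Each 2-s window (stage-2 filtered, see below) is decomposed by EMD and
scored by NMAV = mean|x − (imf₁+imf₂)| / mean|x|; NMAV_a is the window
average and NMAV_a < NMAV_d = 0.65 calls VF. The first two IMFs are used
rather than one so residual high-frequency noise (captured by imf₁) does
not spoil the match for VF. When the decomposition yields fewer than two
IMFs the missing ones are zero vectors, so a monotone window scores
exactly 1. The ratio structure makes both indices invariant to positive
rescaling of the raw signal, so calibration does not influence stages 1–2.

### EMD implementation

Sifting subtracts the mean of the upper/lower cubic-spline envelopes
(knots at strict interior extrema; plateaus count once at their first
sample) until the candidate satisfies the mode-count condition (numbers
of extrema and zero crossings differ by ≤ 1) *and* the normalised
change between consecutive sifts,

    SD = Σₙ |h_{k−1}(n) − h_k(n)|² / h_{k−1}(n)²,

falls below 0.2 (the conventional threshold in the EMD literature).
Numerical choices:

* **SD zero guard.** The per-sample ratio is heavy-tailed where the
  denominator is near zero; samples with |h_{k−1}(n)| ≤ 1% of the
  iterate's peak are excluded from the sum. With only an exact-zero
  guard the statistic never settles on broadband inputs.
* **Boundaries.** The two extrema nearest each end are mirrored about
  the endpoints before spline fitting, suppressing end swings. Splines
  are not-a-knot cubics.
* **Termination.** Per IMF, sifting is capped at 100 passes; if the cap
  is hit with the mode-count condition violated (over-sifting can erode
  the count), the last iterate that satisfied it is kept. Decomposition
  stops at the configured IMF budget (2 for the detector), on a monotone
  residue (< 2 maxima or minima), or when the residue falls below
  1e−10 of the input's peak.
* **Completeness** (Σ IMFs + residue = input) holds to machine precision
  by construction and is asserted to 1e−8 relative in the tests.
* **Zero crossings** are sign changes between consecutive nonzero
  samples; a run of exact zeros counts once.

The decomposition is deterministic: identical input and configuration
give bit-identical output.

## Stage 3 — rate and amplitude

The VT branch estimates heart rate from the first difference of the
(stage-1 filtered) episode: half-wave rectification, a causal moving sum
over α+1 samples (α = round(fs/10)), a fixed threshold T_h = 0.25 × the
first global maximum, then greedy peak picking that zeroes γ = round(fs/8)
samples on each side of every accepted peak until the running maximum
drops below T_h. The first peak always counts; the threshold is never
recomputed; masks are clipped at the array edges; the first-difference
start uses x(−1) = x(0). HR = N_p · 60 / L_e, and HR > 180 bpm marks
shockable VT (the border is configurable; clinical practice places it
anywhere in 150–180 bpm). On clean trains the count is exact whenever
pulse spacing exceeds the 2γ masking span; the provable iteration bound
is ⌈N/(γ+1)⌉ + 1 since a mask may overlap previously cleared samples.

The VF branch measures peak absolute amplitude of the **calibrated raw**
episode in μV (the 200 μV coarse-VF border is a physical amplitude, so it
is taken before normalisation or filtering). Without calibration the
coarse/fine split is unavailable and detected VF is treated as coarse for
the shockable scheme — the reading consistent with corpora whose
annotated VF is coarse.

Both thresholds in stages 1–2 and both borders in stage 3 resolve ties
downward: a value exactly at a threshold takes the negative branch.

## Preprocessing chains

All filters are applied forward and backward (zero phase); coefficients
are designed per call from fs.

| stage | steps | defaults |
|---|---|---|
| 1 (MAV, rate) | mean removal → moving-average comb → 1 Hz high-pass → 30 Hz low-pass | comb length round(fs/powerline_hz), powerline 60 Hz; HP 2nd-order Butterworth; LP 4th-order Butterworth |
| 2 (NMAV) | mean removal → 1 Hz high-pass → 20 Hz low-pass | LP 12th-order Butterworth |

Stage 1 filters the episode once before windowing; stage 2 runs inside
the window loop, per its procedure's ordering. The comb length places a
spectral null exactly on the powerline frequency. The comb length, HP
order and stage-1 LP order are house choices (only the cutoffs and the
stage-2 order 12 are fixed by the published chain). Each chain ends with
a second mean subtraction because finite-length zero-phase filtering
leaves a ~1e−3-relative sample mean while the chain's contract is an
exactly zero-mean output. Signals shorter than 3× the longest filter
length are rejected rather than silently truncated.

## Episode slicing and ground truth

Records are sliced at integer-second starts into ⌊duration⌋ − L_e + 1
episodes (1-s stride), half-open sample windows, sample 0 = time 0. When
rhythm annotations are present, an episode's truth label is the class
covering the majority (> 50%) of the frame, ties resolved by the class at
the midpoint; episodes overlapping annotated noise are flagged
`excluded` rather than dropped. The WFDB reader handles header files,
signal formats 16 and 212, and MIT-format annotations — enough for the
standard arrhythmia corpora layouts; CSV input requires the sampling rate
out of band.

## Synthetic fixtures

The generator emulates the morphological contrasts the detector exploits,
at the study's default conditions (fs = 250 samples/s, 8-s episodes,
additive 60 Hz powerline (10 μV), baseline wander (25 μV) and white noise
(5 μV std) against peak amplitudes of 1000 μV for beats and 250–600 μV
for coarse VF — SNR ≥ 20 dB):

* **nsr** — narrow biphasic QRS (≈ 80 ms) with P/T bumps; low duty cycle.
* **vt** — wide (≥ 140 ms, half the cycle) flat-topped complexes with a
  steep depolarisation spike: high duty cycle, asymmetric envelopes, and
  harmonic energy spread so the first two IMFs capture little.
* **vf** — 4–7 Hz quasi-sinusoid with seeded slow AM/FM drift, symmetric
  about baseline.
* **pulse_train** — bare Gaussian pulses for the rate estimator.

Beats are placed on a regular grid with small timing jitter; a VT
episode's truth label uses the achieved discrete rate (beats × 60 /
duration), since beat placement quantises the nominal rate. The composite
signal is rescaled after noise addition so the programmed peak amplitude
is exact. Fixture shape parameters were chosen so each kind lands on the
correct side of both decision thresholds with margin ≥ 0.05; that is a
property of these test instruments, not evidence about clinical data.
What passing tests show is that the implementation realises the intended
decision surfaces; they say nothing about sensitivity/specificity on real
Holter recordings, whose noise, morphology variety and annotation
ambiguity the fixtures deliberately do not model (no respiration
artefacts, electrode motion, fusion beats, or rhythm transitions inside
an episode).

## Problem sizes

The shipped test suite and the acceptance script use 100-seed sweeps for
the EMD properties, 2-s/500-sample windows for decomposition stress
inputs, and a 600-episode reference cohort (200 per class, seeded); these
sizes make the full run complete in a few minutes on one CPU while
keeping every stage exercised at study conditions.

## Known limitations

* Asystole is not detected and noise episodes are only flagged, not
  modelled.
* The corpus-scale results of the original study (multi-database
  sensitivity/specificity tables) require the PhysioNet corpora and are
  out of scope; the evaluation module reproduces the bookkeeping
  arithmetic and scoring machinery instead.
* Fine VF below 100 μV (asystole border) is not treated specially.
* The per-sample SD criterion, even guarded, can stall above threshold
  on broadband inputs; the sift cap plus count-condition rollback
  guarantees termination but such IMFs may sit marginally outside the
  envelope-mean tolerance of `is_imf`.
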