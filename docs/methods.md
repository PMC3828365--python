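# Methods

This note documents the models, estimators and calibration choices behind
`betasleep`, and what the synthetic benchmark does and does not establish
about real recordings.

## Spectral estimation

Spectrograms are short-time periodograms on 4-s windows advanced by 2 s
(50 % overlap), giving 0.25 Hz bins.  The taper is a Gaussian with
σ = window length / 6, so the window's ±3σ support matches its extent; the
taper is symmetric (σ expressed in samples around the window midpoint).
One-sided power is scaled so that the spectrum of a window sums to the
taper-weighted mean square of the signal (Parseval with respect to the
tapered segment): `P[k] = c_k |X[k]|² / Σw²`, `c_k = 2` except at DC and
Nyquist.  Absolute scale is irrelevant downstream because state spectra are
normalized to unit sum over a reference band.

The normalization band is 0.5–100 Hz: DC and sub-0.5 Hz drift are
excluded, as is the mains-adjacent region above 100 Hz.  Band powers sum
bins with inclusive edges (`lo ≤ f ≤ hi`).  Windows are assigned to
hypnogram epochs by their centre time; a window straddling a state
transition inherits the state at its centre.  The number of windows of a
`T`-second trace is `floor((T − 4)/2) + 1`.

## β-peak detection

The aperiodic background is modelled as a power law: a straight line is
fitted (least squares) to log power vs log frequency over 10–55 Hz with
the 15–40 Hz β band excluded.  A β peak is *present* when some local
maximum of the spectrum inside 15–40 Hz reaches at least 2.0× the fitted
background ("prominence").  The detector always returns the most prominent
in-band candidate, so near-threshold spectra can be inspected.  The 2.0
threshold is an operationalization — human scorers detected such peaks by
eye — and is configurable.  A strictly monotone spectrum has no in-band
local maximum and is therefore never a detection, regardless of the ratio.

Session-level β presence (used for onset ages and the genotype table) is
read from the REM spectrum when at least 30 windows (one minute) of REM
were scored, falling back to SWS, quiet wake, then active wake under the
same rule; with fewer than 30 windows everywhere, the best-sampled state
decides.  REM is preferred because the rhythm is strongest there; the
window floor keeps single-bout spectra from deciding a session.  The same
one-minute floor excludes a session from REM-state *summaries* (e.g. the
median θ peak across seeds): a 10-minute session occasionally contains
only one brief REM bout, whose spectrum is dominated by transition
windows.

## Vigilance-state scoring

States are assigned per 2-s epoch by a fixed cascade:

1. epoch mean speed > 2 cm/s → active wake;
2. EMG RMS ≤ 14 µV and θ/δ ratio ≥ 1.5 → REM;
3. EMG RMS ≤ 14 µV and 2–8 Hz fraction of 0.5–100 Hz power ≥ 0.5 → SWS;
4. otherwise quiet wake;

followed by a 3-epoch majority filter (ties keep the centre label, so the
filter never invents a state absent from its window).  EMG tone is the
mean of 0.5-s RMS sub-windows within the epoch; speed is the 1-s moving
average of frame-to-frame displacement times the tracking rate.

The θ/δ ratio uses θ = 4–9 Hz over δ = 2–4 Hz.  The δ band deliberately
excludes the θ range: with a θ rhythm at 6.75–7.5 Hz, any δ definition
overlapping it (e.g. 2–8 Hz) bounds the ratio near 1 and no threshold
above 1 could ever fire.  All thresholds are config-exposed
(`ScoringThresholds`); the defaults were chosen once so that scoring on
default synthetic sessions exceeds 0.90 overall agreement and 0.85 REM
recall against generator ground truth, and they are plausible for real
mouse data (atonia below ~14 µV RMS, waking tone above it) but are *not*
validated against expert-scored recordings.  Epochs are centred on window
centres, so scored hypnograms start at t = 1 s.  "Drowsiness" is not a
scored state; it folds into quiet wake.

## Comodulogram

For two channels' spectrograms restricted to a state mask (default: the
combined active + quiet waking mask), the comodulogram is the Pearson
correlation between the log-power time series of every frequency-bin pair
in 1–55 Hz, with two-sided p-values from the t transform.  Log power tames
the heavy right tail of periodogram power and makes r exactly invariant to
per-channel rescaling; raw-power correlation is available behind a flag.
At least 10 state windows are required.  p-values are reported without
multiple-comparison correction across the ~47 000 bin pairs; the matrix is
descriptive and extrema should be read as effect sizes, not tests.

## Cohort statistics

*β onset* is the age of the first session with a session-level detection —
no persistence requirement, since first detection is the quantity of
interest for a biomarker.  *Clasping onset* is the first monthly
observation with clasping.  *Precedence* is clasp age − β age (positive:
β first); equal onsets count as neither.  Because observations are monthly,
recovered precedence is quantized to the session grid: with a true lag of
6.67 weeks and sessions ~4–5 weeks apart, per-mouse recovered lags range
over roughly 4–9 weeks and the cohort mean lands within one session
interval of the truth.

The genotype × β-presence table uses Pearson's χ² without continuity
correction — `N(ad−bc)²/(r₁r₂c₁c₂)` on a 2×2 table — which yields exactly
18.0 on a perfect 10-vs-8 split (the Yates-corrected value would be ≈14.2).

Band-power group comparisons use fixed-effects two-way ANOVA with
interaction and Type II sums of squares (statsmodels OLS + `anova_lm`),
valid on unbalanced cell counts; on balanced designs Type I/II/III
coincide.  The within-mouse (repeated-measures) structure of the state and
age factors is approximated as fixed — a known limitation that inflates
the error degrees of freedom; a mixed-effects treatment is out of scope.
A response with zero variance returns F = 0, p = 1 rather than 0/0.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
with full ground truth (hypnogram, burst intervals, onset ages).

**State dynamics.** A semi-Markov chain over the four states with
exponential dwell times shifted by one epoch: dwell = 2 s + Exp(mean − 2 s),
so the configured mean is exact and no bout vanishes under 2-s epoch
quantization.  REM is reachable only from SWS.  Default dwell means
(25/15/60/50 s for active wake / quiet wake / SWS / REM) and transition
probabilities describe a sleep-heavy light-phase recording compressed to a
10-minute desk scale; they were chosen so that a default session almost
always contains a few REM bouts.  Epoch labels are the state at each
epoch's midpoint.

**Signals** (µV, default 500 Hz; 2 kHz supported).  Each brain channel is
a 1/f² Gaussian background (25 µV RMS, spectral shaping flat below
0.5 Hz) plus state-gated components with 0.25-s softened edges:

* hippocampal θ: a phase-continuous oscillator during REM (42 µV) and
  active wake (32 µV) at 7.5 Hz (wild-type) or 6.75 Hz (transgenic), with
  5 % slow relative frequency wander; 0.8× of it appears on the frontal
  channel (volume conduction);
* SWS: a 2–8 Hz band-limited noise (65 µV RMS) on both brain channels,
  1/f-sloped inside the band so low frequencies dominate;
* quiet wake: hippocampal 2–5 Hz δ noise (30 µV RMS) — the resting-state
  activity that couples to frontal β in the waking comodulogram;
* EMG: white noise at state RMS 40/20/10/5 µV (wake → REM atonia);
* position: a heading-persistent random walk at the state's mean speed
  (8 cm/s in active wake, else tracker jitter only), reflected at the
  cage walls.

**β bursts** (transgenic only, at ages past the per-mouse onset):
Hann-enveloped sinusoids on the frontal (1.0×) and hippocampal (0.7×)
channels.  Poisson rates 0.5/12/18/24 per minute and mean durations
0.3/0.6/0.8/1.5 s across active wake / quiet wake / SWS / REM encode the
rarely-awake, frequent-in-sleep, long-in-REM phenomenology; amplitude
scales 0.3/0.8/1.4/1.7 preserve the same ordering.  The centre frequency
falls linearly 27 → 23 Hz and the amplitude triples between 9 and 26
weeks, so the mid-symptomatic preset (17.5 weeks) injects 25 Hz.  Bursts
end at least 2 s before a state transition: β collapses at awakening, and
the margin keeps windows that straddle a transition from leaking sleep β
into wake spectra.  The base amplitude (16 µV at 9 weeks) was calibrated
once so that (i) bursts are clearly visible against the background in the
time domain, and (ii) the normalized 15–40 Hz band power ordering
active wake < SWS < REM holds: with a pure 1/f² background the active-wake
spectrum holds ≈1 % of its normalized mass in 15–40 Hz, and sleep β must
carry more than that *after* the large SWS 2–8 Hz mass deflates its
relative share.  A consequence is that detection prominences in REM are
large (10²–10³), not marginal; detection difficulty is instead exercised
by the wild-type (no-β) sessions, which must stay below the 2.0 threshold.

**Cohorts.**  Default: 10 transgenic + 8 wild-type mice, monthly sessions
at 9/13/17/22/26 weeks.  Per transgenic mouse a β-onset age is drawn
uniformly from 10–19 weeks and the clasping age follows 6.67 weeks later —
the range is capped at 19 so both onsets fall inside the session grid, and
the lag is deterministic so ground-truth precedence is exact.  Wild-type
mice never clasp and never burst.  All randomness flows from one seed
through `numpy` `SeedSequence` spawning; identical seeds give byte-identical
EDF files.

## What the benchmark does and does not show

Passing the synthetic suite shows the estimators are correct and the chain
is self-consistent: known injected frequencies, orderings, onsets and
contingencies are recovered through scoring, spectra and statistics.  It
does not validate the scoring thresholds against expert-labelled data, nor
the detector against real 1/f backgrounds (which bend in log-log space and
carry artifacts), and the generator contains no micro-arousals, no EMG
contamination of EEG channels, no electrode drift and no circadian
structure.  Conclusions about real recordings require re-tuning the
thresholds on scored data.

## Numerical details

* Spectrogram agrees with a direct-DFT oracle to <1e-8 relative error.
* Normalized spectra sum to 1 over the reference band to ~1e-15.
* Ties: band peaks break to the lowest frequency; comodulogram extrema to
  the lowest (f_A, f_B); majority-filter ties keep the centre label.
* Degenerate inputs raise typed errors (`betasleep.errors`): traces
  shorter than one window, empty states, <10 comodulogram windows,
  zero-margin contingency tables, empty ANOVA cells.
* EDF is written with 1-s records, 16-bit quantization over a symmetric
  per-channel range re-parsed from the printed header, so writer and
  reader agree exactly; quantization error is ≤ range/65535.  Sessions
  must span a whole number of seconds.
* Default problem sizes (10-minute sessions at 500 Hz, ten seeds per
  preset, one 18-mouse cohort) are the package's benchmark conditions;
  full-length 4-hour, 2 kHz sessions run through the identical code path
  via the config.
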