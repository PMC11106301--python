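# Methods

`mblfp` analyses simultaneously recorded single-channel prefrontal LFP from
small groups of mice (up to four animals per cohort, one session per social
context) together with per-second behavioural annotation. This note
describes the statistical procedures, the synthetic cohort generator that
provides ground truth for them, the numerical choices, and the limits of
what the synthetic experiments can show.

## Signal chain

**Preprocessing.** Raw traces are unitless signed ADC counts at 1024 Hz.
Filtering is a 4th-order Butterworth low-pass at 200 Hz plus second-order
IIR notches at 60 and 120 Hz (Q = 30), all applied forward–backward
(`filtfilt`) so the output is zero-phase: per-second segment boundaries
stay exactly aligned with the behavioural annotation clock. Phase
distortion would not bias per-segment power statistics, but zero-phase
application costs nothing and keeps segment contents well defined. The
filter orders and Q are conventional choices; only the cutoff frequencies
are fixed by the recording set-up (mains at 60 Hz and its harmonic).

**Per-second PSD.** The trace is cut into consecutive 1-s blocks (trailing
partial second discarded) and each block gets a Welch PSD with a periodic
Hamming window spanning the whole block — i.e. a modified periodogram with
a 1 Hz frequency grid. Sub-window averaging is deliberately not used: with
1-s epochs any shorter window could not resolve the 0–3 Hz delta band.
Session-level PSDs are arithmetic means of the per-second PSDs.

**Bands and HLR.** Bands are delta 0–3, theta 4–7, alpha 8–12, beta 13–30,
gamma 31–80 and high-gamma 81–150 Hz, with composites low = 0–12 and
high = 31–150 Hz. Band membership is closed (`lo ≤ f ≤ hi`) on the 1 Hz
grid and the printed 1-Hz gaps between bands (3→4, 7→8 Hz …) are honoured
literally. The 0 Hz bin is excluded everywhere: DC reflects amplifier
offset, not neural activity (configurable via `BandScheme.exclude_dc`).
Band power is the *mean PSD density* over the band's bins (not the
integral); since the same convention is used for both composites, the
high-to-low ratio differs from the integrated-power ratio only by the
constant bandwidth factor 120/12, which cancels in every correlation,
ordering and regression downstream. The HLR — high-band mean density over
low-band mean density, per 1-s segment, always from unnormalised powers —
is the scalar brain-state statistic everything downstream consumes.
Segments with zero low-band power are flagged invalid rather than raising;
invalidity propagates pairwise into all downstream correlations. The
robust-scaled spectrogram ((x − median)/IQR per frequency row) exists only
for display; rows with zero IQR are flagged invalid.

## Behavioural rules

Locomotive states (`inactive`, `active_still`, `active`) are per-second
manual annotations and enter the package as data. Huddles are taken from
per-second contact-group labels; a contiguous run of the same member set
counts as an episode only if it persists strictly more than 10 s and has at
least two members. Any interruption, however short, splits the run *before*
the persistence rule is applied, and a second counts as huddled for an
animal only if it is a member of an episode spanning that second (the
strict per-second membership reading). Immobility-defined sleep flags
inactive runs of at least `min_immobile_s` seconds (default 40 s — a
conventional immobility threshold; the value is an assumption and is
configurable). Sleep seconds are by construction a subset of inactive
seconds.

Cell means of HLR are reported per locomotive state × condition ×
huddle status (optionally × sleep), with n and SD, alongside the
long-format per-second table that an ANOVA would consume; hypothesis
testing itself is out of scope. Seconds with invalid HLR are excluded and
counted.

## Interbrain statistics

**Pair classes.** Lag-0 Pearson correlation between two animals' HLR
series over jointly valid seconds, grouped by provenance: `group` (same
cohort, both group condition — the only socially co-present class),
`group_shuffled` (different cohorts, group condition), `group_single_shuffled`
(same cohort, one group + one single session) and `single_shuffled` (same
cohort, both single). The last three are negative controls. "Cross-
correlation" is implemented at lag 0 only; a lag-scan helper exists but no
default analysis uses it.

**Permutation null.** `n_draws` (default 10,000) random pairs of distinct
series from the whole pool, each giving one r; the null is summarised by
its mean, SD and the mean ± 1.96 SD band, i.e. the 95 % interval of a
normal fitted to the draws. The Gaussian band rather than empirical
percentiles is deliberate: the pool necessarily contains the socially
coupled in-group pairs themselves (18 of 276 possible pairs in a
3-cohort × 4-animal × 2-condition pool), so when coupling is real the
upper empirical percentiles sit inside the coupled cluster and would be
uninformative. Sampling is with replacement across draws, never pairing a
series with itself; the seed is mandatory.

**Locomotion residualisation.** Sessions are cut into 15-min segments; per
segment and per simultaneously recorded pair we compute the HLR correlation
and the locomotive-state correlation (states encoded ordinally
inactive = 0, active-still = 1, active = 2, preserving the mobility
ordering that drives HLR; a one-hot encoding is available). A single
least-squares line of r_HLR on r_locomotion is fitted over all segments of
all conditions, and the residual (observed − predicted) is the interbrain
correlation not explained by shared locomotion. The common (pooled)
reference line is essential: fitting per condition makes each condition's
mean residual identically zero by the OLS identity, so a group-vs-single
residual contrast is only defined against a shared line. Per-condition
fits are still computed and reported for inspection. Segments with a
constant state series are skipped.

**Granger directionality.** For every ordered pair within a group-condition
cohort, the ssr-based F-test at lag 1 on the raw HLR series: restricted
model y_t ~ const + y_{t−1}, full model adds x_{t−1}; F with
(1, n − 3) degrees of freedom. The implementation is our own and is checked
in the test suite against `statsmodels.tsa.stattools.grangercausalitytests`
(ssr_ftest) to 10⁻⁶. Unordered pairs are classified at α = 0.05:
unidirectional iff exactly one direction is significant, bidirectional iff
both, none otherwise; per-animal in/out-degrees summarise the hierarchy.
No multiple-testing correction is applied across the 12 ordered pairs per
cohort by default (a BH/Bonferroni option exists). GC needs contiguous
data, so invalid seconds are linearly interpolated when the gap is ≤ 2 s;
longer gaps split the series and the longest contiguous run is used.

Note a structural property of the classification: when a genuine
unidirectional influence is planted, the reverse direction is a true null,
so even a perfectly calibrated test classifies the pair unidirectional
with probability ≈ 1 − α, not 1. Directionality conclusions from a single
pair therefore carry an irreducible ≈ 5 % bidirectional-misclassification
rate at α = 0.05.

## Synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
measures, with planted ground truth.

**Behaviour.** Each animal's locomotive state is a per-second 3-state
Markov chain. In the group condition a cohort-level huddle process
(exponential gaps, mean 120 s; exponential episode durations, mean 600 s,
truncated below at 11 s; episode size 4/3/2 with probability 0.7/0.2/0.1)
gates the chain: huddled seconds use an inactive-enriched transition
matrix, non-huddled seconds an active-enriched one. Singles evolve
independently under the base matrix. The default rates make full-size
huddles occupy the majority of a session, with occasional breakups —
the qualitative pattern of a group session. The initial state is drawn by
one Markov step from a uniform predecessor so that second 0 already
follows the state-conditional dynamics.

**HLR drivers.** Each animal carries a per-second latent AR(1) driver
(ρ = 0.8, innovation SD 0.15). A cohort-level AR(1) modulator is added
with weight `coupling_strength` (group condition only) — this plants
instantaneous interbrain correlation. Directed influence lives in
`leader_map`: the follower's driver receives `weight` × the leader's
driver at the configured lag (≥ 1 s), and the follower also adopts the
leader's lagged locomotive state with probability `weight` outside huddled
seconds. Influence is implemented at the 1 Hz driver level, not on raw
samples, because the Granger analysis operates on the 1 Hz HLR series.

**Waveforms.** Per-second log-amplitudes for the low and high band are the
sum of a (state, huddle-status) gain cell, ± half the driver (low band
down, high band up — so the driver moves log-HLR directly), and per-second
Gaussian jitter (SD 0.10). Gain cells are antisymmetric in an HLR offset
d + o with d(inactive, active-still, active) = (−0.8, 0, +0.8) and
o(single, huddled, non-huddled) = (0, 0.05, 0.35): mobility raises HLR
strongly, huddling brings group animals back to near single levels, and
non-huddled group animals sit clearly above both — the planted orderings.
The trace itself is FIR-band-limited white noise (low-pass 12 Hz; band-pass
31–150 Hz; 4097 taps) under the per-second amplitude envelopes smoothed
with 50-ms raised-cosine crossfades, riding on 1/f background (exponent 1,
scale 20 counts) and a white floor (5 counts), rounded to 16-bit counts.
Segment-wise stationarity is sufficient because every downstream statistic
is per-1-s-segment. Measured log-HLR from the waveform path correlates
≈ 0.97 with the planted per-second HLR at these noise levels.

**Fast path.** `simulate_hlr_series` emits the per-second HLR implied by
the same latent amplitudes — (high amplitude / low amplitude)², exact up
to a band-shape constant that cancels in every correlation — without
synthesising waveforms. Calibration experiments that need tens to
thousands of replicates use this path; the waveform path is separately
verified to agree with it. Both paths are bit-deterministic given the
config seed.

## Calibration experiment designs

The statistical guarantees are exercised by simulation at sizes chosen to
keep the whole suite fast; sizes are stated with each result.

* **Cell-mean ordering** — default group + single cohorts, 3600 s, five
  seeds; the planted orderings must hold in every seed.
* **Null calibration** — 3 group + 3 single cohorts, 1800 s, in a
  *driver-isolating* configuration (state fixed, no huddles) so the shared
  modulator is the only possible coupling channel; 2000 permutation draws
  (reduced from the 10,000 default via config). With zero coupling the
  in-group mean must sit inside the ±1.96 SD band; with the modulator at
  full weight it must exceed the band's upper edge.
* **Residualisation** — default behavioural dynamics (huddle-synchronised
  states), 3600 s, 3 + 3 cohorts. With driver coupling off, all interbrain
  correlation is locomotion-mediated and residuals must be ≈ 0; adding the
  shared modulator must raise the group residual above the single residual.
* **Granger** — test size and power on directly simulated AR series
  (n = 10,800, matching a 3-h session); planted-edge recovery on 3 cohorts
  with one leader→follower edge each (weight 0.7, lag 1 s) in the
  driver-isolating configuration with *noise-free* observation
  (`band_sigma = 0`). The noise-free choice is deliberate: observation
  noise on a latent AR process genuinely induces reverse-direction Granger
  dependence (the classic noisy-observation/common-cause effect), so exact
  direction recovery is a meaningful check only when the planted edge is
  the sole dependence channel. False-positive behaviour among null pairs
  is measured by the dedicated size experiment instead.

## What the synthetic experiments do not show

The generator is stationary per second, has no spikes, no cross-frequency
coupling, no volume conduction, no electrode artefacts, and its behavioural
model is a gated Markov chain rather than real mouse ethology. Passing
tests therefore demonstrate that the *pipeline* recovers structure it is
designed to measure when that structure is present, and stays calibrated
when it is absent — not that real recordings contain such structure, nor
that the effect sizes resemble those of real data. The raw-HLR series is
approximately lognormal; Pearson correlations on it are attenuated relative
to log-domain correlations, and heavy-tailed segments dominate single
pairs. The analyses nevertheless run on the raw ratio for fidelity to the
procedure they implement.

## Degenerate inputs and numerical choices

Constant series yield undefined correlations and are flagged (NaN),
excluded from class averages and skipped in regressions. Permutation draws
on constant series are dropped. Zero low-band power marks the HLR segment
invalid rather than raising. OLS fits use `numpy.linalg.lstsq`;
F-statistics use the exact `scipy.stats.f` survival function. All
randomness flows from explicit `numpy.random.default_rng` seeds; there is
no hidden global state, and identical seeds give byte-identical on-disk
outputs end to end.
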