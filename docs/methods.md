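# Methods

This note documents the models, rules and numerical choices behind
`sliceglia`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Zero-phase RC filtering

All field-potential filtering uses a two-way first-order RC filter: one
stage applied forward, then backward, so phases cancel exactly and the
amplitude response is the squared single-pass response —
1/(1+(f/f_c)²) for low-pass, (f/f_c)²/(1+(f/f_c)²) for high-pass, and the
product of a high- and a low-pass stage for band-pass. The stage is
realized in the frequency domain with the exact analog response (the rFFT
of the mirror-padded signal multiplied by |H₁(f)|²). A time-domain
first-order IIR discretization (bilinear or impulse-invariant) warps the
response by more than 10 % near a quarter of the sampling rate, which
matters at the 2 kHz rates used for fast benchmarking; the spectral
realization keeps the stated analog response to numerical precision at any
rate. Mirror padding (five time constants of the lowest corner) suppresses
circular wrap-around; zero-phase behaviour is exact by construction, which
the time-reversal test verifies to 1e-9.

## Sharp wave-ripple detection

Sharp waves are detected on the 30 Hz low-passed trace as local extrema
(negative polarity by default, configurable) exceeding
`threshold_sd` × SD of the whole filtered trace — the default threshold is
3.0, within the 2–3 range this family of recordings uses; the SD is taken
over the full filtered trace (the "SD of the signal" is ambiguous between
raw/filtered and whole-trace/baseline; whole filtered trace is the default
and other choices remain available through the API). Event boundaries sit
where the trace recrosses 50 % of the threshold.

The original pipeline eliminated artefacts under supervision. Here that
step is rule-based and configurable: candidates are rejected when their
time above threshold is shorter than 25 ms (1/f noise crosses even a 3 × SD
level in brief swings of ~10 ms, whereas a sharp wave with a 30 ms Gaussian
envelope stays above threshold for ~75 ms), when their boundary width
exceeds 250 ms (slow noise excursions; physiological sharp waves last well
under that), or when an optional amplitude ceiling is exceeded. The
reported peak time is refined on a Gaussian-smoothed copy of the trace
(SD 20 ms, matched to the sharp-wave envelope) with parabolic sub-sample
interpolation; this halves the in-band noise jitter of the raw argmax while
the amplitude is still read from the unsmoothed filtered trace, measured at
the event extremum.

Ripple metrics use the 170–230 Hz two-way band-pass. Within each event
window, negative ripple peaks are local minima whose magnitude exceeds
3 robust SDs (1.4826 × median absolute value) of the band trace; at least
3 such cycles are required for the ripple fields to be defined, otherwise
they stay `nan` and the event is kept. The trigger is the qualifying
negative peak nearest the sharp-wave peak (parabolically refined); the
ripple amplitude is the maximum of the rectified-then-low-passed
(55 Hz; the corner is not fixed by the source procedure and is exposed in
the API) band trace in the window; the ripple frequency is the reciprocal
of the median inter-peak interval after dividing each interval by its
implied cycle count (an interval spanning a missed cycle is an integer
multiple of the carrier period, and the band-pass bounds the period near
the band centre, so the count is unambiguous).

**Prevalence.** A recording is SWR-negative when 2 × SD detection yields no
"detectable" event. Detectability was a supervised judgement; here it is
quantified: a candidate is detectable when its amplitude exceeds the
(1 − α) global-extreme level of a Gaussian process with the filtered
trace's variance and observed local-maximum count, `sd·sqrt(2·ln(n/α))`
with α = 0.01 — it must stand above anything the recording's own noise
floor is expected to produce over the whole recording. Under this rule,
noise-only recordings are misclassified positive with probability ≈ α, and
recordings whose events sit below ~5 noise SDs after filtering would be
called negative; the benchmark conditions (events at 6 × noise SD) sit
safely above.

## ATP-sensor event analysis

ΔF/F uses a per-pixel 20th temporal percentile baseline by default (robust
to sparse transients; a declared pre-event window is the alternative).
Events are 6-connected components of ΔF/F above threshold in T×H×W,
filtered by minimum footprint area (4 px) and duration (2 frames). The
footprint is the component's mask at its peak frame, mirroring the practice
of encircling an event at its intensity maximum; the event trace is the
footprint-mean ΔF/F over the whole movie.

Kinetic features are defined on the trace with linear interpolation between
frames: duration = FWHM, rise = 10–90 % on the ascending limb,
decay = 90–10 % on the descending limb ("peak duration" has no formal
definition in this literature; FWHM and 10–90 % limits are the standard
transient-kinetics choices and are monotone in the generative time
constants). These times are invariant under affine intensity rescaling.
The reported peak ΔF/F is a *core* estimate: the mean ΔF/F over pixels
within 90 % of the lightly smoothed (σ = 1 px) maximum of the peak frame.
A threshold-footprint mean would underestimate the central amplitude by an
amount that grows with event brightness (mean of a Gaussian over its
super-threshold disk), whereas the fraction-of-max core has a constant
≈ −5 % bias regardless of amplitude.

Flash/surge classification log₁₀-transforms (peak intensity, duration,
area), z-scores each feature, and runs k-means with k = 2, ten restarts and
a fixed seed. The log transform reflects the log-normal feature
distributions these events show; whether the original analysis logged
before standardizing is not documented, so the choice is this package's
own. The cluster with the lower mean standardized intensity is named
"flash" — deterministic regardless of k-means index order. Identical
feature rows yield a warning and all-unassigned labels.

Background decay is measured in event-free 12.5 × 12.5 µm ROIs (4 per
movie), rejecting any ROI that overlaps a detected footprint, and an
exponential `A·exp(−t/τ)` is fitted by nonlinear least squares.
Concentration calibration fits a line over the declared linear range of the
(10, 50, 100 nM, 0.5, 1, 5 µM) pipette-puff points and flags estimates
outside the calibrated range as extrapolated; concentration-band
annotations (e.g. "flashes ≲ 100 nM") are derived through this fit, never
hard-coded as class boundaries.

## Process recruitment

Δ%MFI = 100·(R − B)/B with B the mean reporter signal over the 100 s before
the ATP peak. R is the reporter value at the *definitive* peak closest in
time to the ATP peak within the 300 s search window; with no definitive
peak, the 100 s post-peak average is used and the branch is recorded. A
definitive peak must rise at least 3 baseline-SDs above the baseline with
at least that same prominence: weaker rules let noise wobble in the
baseline band — or bumps riding a rising limb — masquerade as the response
peak and collapse Δ%MFI toward zero.

Directed movement: Δ%MFI ≥ 10 % by default (optionally also requiring the
peak branch); prevalence is the directed fraction with a Clopper–Pearson
binomial interval. Latency — reported only graphically in this literature,
so the rule here is the package's own — is the first time after the ATP
peak at which the reporter exceeds baseline + 2 SD(baseline) for at least
2 consecutive samples; `nan` when never exceeded.

## Translocation

Depth is measured from the top surface, increasing downward; zone 1 is the
top zone. Zone intervals are half-open [lo, hi) with the last zone closed,
so boundary cells count exactly once; counts, percentages and optional
per-zone integrated process density are reported for seven equal zones by
default. Minimal displacement sorts both depth samples ascending and
subtracts rank by rank — the monotone matching that minimizes total
absolute movement in one dimension (verified against exhaustive assignment
search for n ≤ 7) — and requires equal cell counts at the two timepoints.
Area coverage consumes an already-binary mask (the original binarization
happened in an external image program with an unstated threshold rule) and
returns the on-pixel percentage.

## Histological metrics

Puncta: Otsu threshold, hole filling, one 8-connected erosion,
connected components, minimum size 4 px (the source procedure applied
erosion but published no size figure). "Touching" pre/post puncta — overlap
or 8-adjacency; no connectivity rule is documented, and 8-adjacency is the
permissive reading — define synapses. Microglial contact uses the Euclidean
distance transform of the microglia mask: a synapse is contacted when the
minimum distance over its pre+post footprint is strictly below 200 nm
(4 px at 50 nm pixels). The microglia mask itself is Otsu + hole filling
*without* erosion (shrinking it would inflate every distance by ~1 px),
plus a contrast guard: Otsu splits even a pure-noise image, so the
foreground must exceed the background by 4 background-SDs or the channel is
treated as empty.

Soma metrics work per 2-D section with per-section aggregation (the
original analysis worked on 3-D stacks; this is a documented
simplification): surface = Σ(circumference × section thickness), covered
surface likewise from outline arcs whose endpoints lie within 1.5 px of the
microglia mask (the zero-gap reading of "clearly touched"), and a soma is
contacted when any single contact arc spans ≥ 0.5 µm. Outlines are
densified to ≤ 1 px segments so arcs resolve below the 0.5 µm rule.

Membrane ribbons: the polyline is extended 250 nm to each side (500 nm
ribbon). Rasterization uses anti-aliased membership (pixels straddling the
ribbon edge contribute fractionally) and the rounded ribbon ends are folded
into an effective length (`L + π·w/4`), so a uniform image of intensity I
yields exactly I × 500 nm per unit length; integrated density divided by
that length is the reported per-length intensity.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions. The LFP generator uses
1/f-coloured noise (the noise spectrum of the source recordings is not
documented; pink spectra are realistic for field potentials and stress the
band filters hardest at low frequencies) at 20 µV SD, sharp waves of
120 µV with a 30 ms Gaussian envelope, negative polarity, a 200 Hz ripple
of 30 µV under the same envelope, Poisson event times (or an exact count
with a 300 ms minimum gap for benchmarking), and a 10 kHz default sampling
rate; benchmarks run at 2 kHz to keep the suite fast, which the filter
realization makes equivalent in response. The movie generator emulates
10-min, 0.5 frame/s acquisitions: an exponentially decaying background
(f₀ = 100, τ = 1200 s), log-normal flash/surge feature clusters
(medians — flash: 0.4 ΔF/F, 30 µm², 10 s, τ_rise 1.5 s, τ_decay 4 s;
surge: 1.6 ΔF/F, 150 µm², 40 s, 5 s, 12 s; log-SD 0.3, which places the
class log-means more than 4 log-SDs apart on every feature), expected
10 flashes and 5 surges per movie, and shot-like noise with SD ∝ √intensity.
Each event's drawn FWHM is honored by inserting a plateau between the
exponential limbs when needed, and the truth records the realized FWHM.
Recruitment pairs use a smoothstep reporter rise (exactly zero before
onset) so latency ground truth is sharp. Puncta scenes place touching
pre/post disk pairs (centres 2r − 3 px apart, so detected masks stay
adjacent after the erosion step), orphans ≥ 6 px from the opposite channel,
and disk-shaped microglia; contact truth applies the same 200 nm rule to
the true mask.

None of the generators model sensor photophysics, bleaching, motion,
3-D structure, or correlated biological variability. Passing tests
demonstrate that the *measurement rules* recover known ground truth under
realistic noise — not that the generators are faithful replicas of real
recordings.

## Problem sizes and numerical choices

The detector benchmark uses 600 s at 2 kHz with 50 events at 6 × noise SD;
clustering agreement uses 20 seeded draws of 90 events; displacement
optimality uses 100 random trials at n ≤ 7 (7! = 5040 permutations);
zone bookkeeping uses 1000 random maps; the synapse pipeline uses five
256×256 scenes of 20 synapses plus 10 orphans. Matching tolerance for
detected vs true sharp waves is ±10 ms; detected synapses match truth
within 3 px of the pair midpoint. Tie-breaks: k-means label naming is by
mean standardized intensity; `select_top_window` takes the first maximal
window; histogram zones are half-open with a closed last zone. Degenerate
inputs (blank images, flat traces, empty event sets) return empty results
or raise errors naming the offending field, as specified per function.

## Known limitations

Detection thresholds interact with the noise model: on noise substantially
more broadband than 1/f the minimum-width artefact rule would need
retuning. The prevalence significance rule assumes approximately Gaussian
filtered noise. The per-2-D-section soma analysis underestimates true 3-D
coverage for processes running oblique to the sectioning plane. Ribbon
rasterization assumes the polyline curvature radius is large compared with
the ribbon half-width.
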