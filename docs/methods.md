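# Methods

`pcdrift` implements the analysis chain for multi-day two-photon
calcium imaging of hippocampal CA1 pyramidal cells in a virtual
corridor, downstream of motion correction, segmentation and spike
deconvolution. This note documents the models, the parameter choices,
and what the synthetic-data validation does and does not show.

## Event noise filtering

Deconvolution emits a non-negative activity value per frame; many
small values reflect fluorescence fluctuations rather than calcium
transients. Each frame with nonzero deconvolved activity becomes a
candidate event, validated against the neuropil-subtracted
fluorescence Fc:

- **peak**: argmax of Fc over the 10-frame window starting at the
  spike frame (first index on ties); Fc_max is the mean of the three
  samples around it (clipped at trace edges);
- **baseline**: least-squares line over Fc at frames −30…−20 relative
  to the spike (11 samples, inclusive); Fc_base is the fitted value at
  −20 and the fit RMSE is the local noise SD;
- **global noise SD**: population SD of Fc samples within
  [0.5, 1.5] × median(Fc). With a zero or negative median the band is
  degenerate or bound-swapped; bounds are sorted and a sub-2-sample
  band yields SD 0;
- **validity**: amplitude Fc_max − Fc_base must *strictly* exceed the
  larger of the two SD estimates. The "larger than local or the
  global noise SD" rule is deliberately read as exceeding both — the
  conservative reading, consistent with the filter's purpose of a
  conservative activity estimate. The or-reading is available via
  `mode="either"`. Events within the first 30 frames have no baseline
  window and fall back to the global SD alone, with Fc_base set to the
  trace median.

Whether sample or population SD was intended is ambiguous; population
SD (ddof=0) is the default and `ddof` is exposed. Overlapping event
windows are processed independently per spike; no merge rule is
applied. Filtering is idempotent, and an injectable `noise_floor`
supports re-thresholding at a known noise level.

## ROI matching, silent cells, multi-day tracking

The activity-based segmenter finds only active cells; an
anatomy-based segmenter run on the mean image finds all somata. An
anatomy ROI *a* and an activity ROI *s* are the same cell iff
|a ∩ s| / |a| > 0.75 — the fraction is of the anatomy mask, the
threshold strict, the best-overlap candidate wins (ties to the lower
ROI id). Anatomy ROIs with no match are silent cells; a stricter
composite (matched but zero filter-surviving events ⇒ silent) is
optional.

Mean images of consecutive days are registered by integer rigid
translation (phase correlation); day-to-day field-of-view motion is
approximately translational and no warping model is assumed. Anatomy
ROIs are linked day-to-day with the same 75% overlap rule after shift
compensation, each later ROI claimable by at most one track. Only
cells with an anatomy ROI on *every* day enter the analysis —
tracks that lose their ROI on any day are dropped entirely. Cross-day
overlap is computed at pixel resolution on shifted masks, without
interpolation.

Transients are attributed to their source ROI by spatial footprint:
the raw trace is smoothed (Gaussian, σ = 2 frames), putative events
are maximal runs above median + 2·SD (population SD of the smoothed
trace), the footprint is the mean movie frame over the run minus the
mean over an equal-length immediately-preceding baseline, restricted
to the ROI bounding box dilated by 5 px, and the Pearson correlation
with the binary mask must exceed 0.5. The baseline length, dilation
radius and correlation threshold instantiate a published recipe whose
constants are not fully specified; all three are config keys. Events
starting too early for a baseline are skipped and counted.

## Place-cell classification

Cells pass through ordered gates; failing any leaves the cell
`active_nonplace` (or `silent` with no surviving events).

1. **Speed filter.** Frames in (lap, spatial-bin) cells whose mean
   speed is below 4 cm/s are excluded from every subsequent
   computation (strict <; a bin averaging exactly 4 cm/s is kept).
2. **Binning.** 80 bins over the 800-cm corridor (10-cm bins). The
   bin count is not externally fixed; it is a config key and all
   computations are parameterized by it.
3. **Reliability.** Pearson correlation between odd-lap and even-lap
   tuning curves (mean filtered activity per bin; lap 1 is odd) must
   reach 0.25. Zero-variance curves fail with reason "degenerate".
4. **Global spatial information.** Skaggs SI in bits/event,
   SI = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄), over visited bins with
   occupancy-weighted mean rate λ̄. Significance by circular shuffle:
   the full activity vector is rotated by a uniform random shift in
   {1..T−1} (identity excluded, since identity shifts bias the null
   toward the observed value), the tuning recomputed against the
   unshuffled behavior, 1,500 shuffles by default; pass iff the
   observed SI strictly exceeds the 99th percentile
   (linear-interpolation percentile) of the null. The rotation is of
   the full trace, masked afterwards.
5. **Field delineation.** Candidate fields are interior local maxima
   of the all-lap tuning curve with height ≥ 6 (inclusive; the unit
   scale follows the deconvolution output, and the synthetic generator
   scales its amplitudes so genuine fields clear it). Plateaus take
   their leftmost bin. If the valley between adjacent peaks exceeds
   half the larger peak, the smaller peak is dropped (equal heights:
   the right one), re-evaluated until stable. Bases are cut at 93% of
   prominence (standard flanking-valley prominence; crossings by
   linear interpolation), widened outward to covering integer bins,
   and overlapping or touching bases merged (merged peak = argmax
   within the union).
6. **Local SI.** Each field's base, extended by half its width on
   both sides (in bins, rounded outward), defines a region; SI is
   computed over valid region frames. The null circularly rotates each
   lap's region samples independently by a uniform per-lap shift;
   laps with fewer than two region frames stay unshuffled. Pass iff
   observed SI strictly exceeds the 95th percentile of 1,500 shuffles.
7. **Lap coverage.** A significant field must carry at least one
   filter-surviving event inside its base bins in at least 30% of
   laps (inclusive). Events are counted on speed-valid frames, for
   consistency with the exclusion rule.

A cell passing gate 4 is a *putative place cell*; one with at least
one field surviving gates 6–7 is a *place cell*.

## Cohort statistics

Per-day silent/active/place fractions are computed over tracked
cells. The unsilencing rate u is, for each consecutive day pair, the
fraction of day-k silent cells active on day k+1; u is the unweighted
mean over pairs (pairs with no silent cells skipped); a
transition-pooled variant is available. Under memoryless
re-recruitment the expected normalized persistently-silent count on
day k is (1−u)^(k−1), day 1 ≡ 1 (the day-1 normalization forces the
exponent to start at 0).

A subtlety worth recording: when u is *measured* on a population
containing a never-unsilencing subpopulation, the measured rate is
already deflated by that subpopulation, and the day-2 theoretical
point (1−û) coincides with the day-2 empirical survival almost
exactly — the day-1→2 pair dominates û. The excess of the empirical
curve over the measured-rate theory therefore becomes resolvable only
from day 3; against the generative (persistent-free) rate it is
present from day 2. The validation suite asserts both forms.

Effect sizes use the percentile bootstrap (5,000 resamples by
default, 2.5/97.5 percentiles); BCa is deliberately not used since the
plain percentile interval is the documented procedure. Group
comparisons wrap scipy's Kolmogorov–Smirnov, Kruskal–Wallis,
Mann–Whitney U and paired t tests; Dunn's rank-based post hoc test is
implemented in-package (z on mean ranks with tie correction, Holm
adjustment by default) since no installed library provides it.

## Intrinsic electrophysiology

From 50-kHz current-clamp sweeps: AP threshold is the membrane
potential at the first sample where the central-difference dV/dt
exceeds 10 mV/ms (per-AP thresholds also available; an optional
boxcar pre-filter guards against wide-band noise producing spurious
slope excursions). Resting Vm is the mean over the pre-step baseline
of a zero-current sweep. Input resistance is the steady-state voltage
deflection divided by the injected current, averaged over AP-free
sweeps; steady state is the last 20% of the step and the baseline the
100 ms before onset — standard choices, both configurable, as the
windows are not externally fixed.

## Synthetic data: what it emulates and what it does not

The behavior generator produces lap-based running in an 800-cm
corridor at 30 Hz: ~35 cm/s mean speed with per-frame noise,
lap-to-lap speed variability (multiplicative SD 0.15), spontaneous
stop bouts (0.05 Hz, 0.3–2 s), a slowdown window before the reward
zone with elevated lick probability, and teleport at the lap end. The
stop bouts and lap-level variability matter beyond realism: they are
the temporal irregularity that makes the circular-shift shuffle a
valid null — with metronomic laps a time rotation relocates a place
field coherently and the shuffle loses its meaning.

Cells are silent (~50% on day 1), active untuned, or place cells
with 1–6 Gaussian fields (single fields most likely; widths 15–30 cm;
peak rates 1.5–3 Hz; per-class event-rate distributions are free
parameters, not calibrated to any recorded dataset). Events are drawn
from an inhomogeneous Poisson process along the trajectory; amplitudes
are lognormal around 150 deconvolved units — chosen so that a typical
place field's tuning peak (~rate/frame-rate × amplitude ≈ 7–15)
clears the height-6 peak threshold, pinning the otherwise arbitrary
unit scale. Fluorescence is the event train times a gain, convolved
with a 1-s exponential indicator kernel, plus Gaussian noise;
configurable small-amplitude false events are injected into the
deconvolved train (only for cells the activity-based segmenter would
have found) so the noise filter faces both true accepts and true
rejects. ROI masks are non-overlapping disks on a jittered grid
(512 × 505 by default); the activity-based label image contains only
cells with at least one drawn event, with slightly smaller footprints.

Across days, each cell's silent/active state follows a two-state
Markov chain (unsilencing rate u, silencing rate), except a pinned
persistently silent subset of day-1 silent cells; field centers
jitter day-to-day (drift SD 20 cm) and the field of view shifts by a
random integer translation up to ±5 px.

Not modeled: optics or point-spread functions, motion artifacts,
neuropil contamination beyond the footprint scenario, non-rigid tissue
deformation, and deconvolution errors other than the injected false
events. Passing tests therefore demonstrate correctness of the
analysis rules and calibration of the statistical tests under a
clean forward model — not robustness to segmentation failures or
registration pathologies in real recordings.

## Validation scales and numerical choices

The calibration and recovery studies (`pcdrift.validation`, also run
by `scripts/acceptance.py`) use problem sizes chosen to make each
property measurable at desk scale: 500 untuned cells × 500 shuffles on
20-lap sessions for the two null calibrations (binomial CIs around the
nominal 1% and 5% levels); 100 single-field and 50 multi-field cells
at 50 laps and 500 shuffles for power and field-count recovery; 20
animals × 1,000 cells × 6 days of state chains for unsilencing-rate
recovery (±0.02); 1,000 repetitions × 2,000 resamples on groups of 100 for bootstrap
coverage (95% ± 2%); 30 simulated cells for ephys recovery (threshold
within one 0.1-mV ramp sample, input resistance within 1 MΩ).
Percentiles use linear interpolation throughout; shuffle p-values are
add-one estimates; all generators take explicit seeds and are
bit-reproducible. Determinism across the pipeline comes from a single
root seed fanned out per stage and cell via `SeedSequence`.

## Known limitations

- Tuning-curve units are tied to the upstream deconvolution scale;
  the height-6 peak threshold must be re-examined for data whose
  deconvolved units differ.
- The global shuffle's validity rests on temporal irregularity of
  behavior; for unnaturally regular running the null is optimistic.
- Cross-day linking is greedy consecutive-day matching; it does not
  revisit earlier assignments, and heavy ROI overlap can in principle
  swap identities (not observed with realistic spacing).
- `register_days` handles translation only; rotation or scaling in
  the field of view will degrade linkage.
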