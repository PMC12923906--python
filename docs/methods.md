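# Methods

This note documents the analysis models implemented in `capipe`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Coordinate and binning conventions

The arena origin is the lower-left corner, x rightwards, y upwards, units
cm. Bin (i, j) (column, row; 0-based) covers the half-open square
[i·w, (i+1)·w) × [j·h, (j+1)·h); the far (top/right) arena edges are closed
so every in-bounds position maps to exactly one bin. At the defaults
(40 × 40 cm, 10 × 10 bins) a bin is 4 × 4 cm. Times are seconds; rates are
events/s.

## Behavioural scoring

A trajectory sample explores object k when the tracked point lies within
`object_radius_cm` (default 2 cm) of the object position. Dwell time is the
half-interval to each neighbouring sample, so the score is robust to
non-uniform sampling. "Total arena exploration time" is interpreted as
total tracked time; an optional immobility filter
(`exclude_immobility_below_cm_s`) removes slow samples from both numerator
and denominator, since whether immobile bouts belong in the denominator is
a genuinely open choice. Only a single tracked point is modelled, so
nose-contact and posture criteria (e.g. climbing exclusion) reduce to the
point-in-radius rule. The discrimination index is the standard bounded
difference-over-sum of displaced vs. stationary exploration times and is
undefined (raises) when both are zero.

## Ensemble recruitment and reactivation

"Active in session s" means: present in the registration map's column for
s, and, when event data are supplied, emitting at least `min_active_events`
events (default 1). Recruitment is 100·|active(s)|/|active(HA)| (HA is the
reference and the denominator; values above 100 % are legal). Reactivation
of an ordered pair uses the earlier session as denominator:
100·|A∩B|/|A|, computed for HA→S1, S1→S2, S2→S3.

## Population bursts

Each cell's ΔF/F trace is z-scored, zero-variance traces are dropped with a
warning, the per-frame mean over cells is taken, and that population signal
is z-scored again (so the output has mean 0, SD 1 by construction).
Candidate bursts are maximal runs of frames with z strictly above
`z_threshold` = 2; runs shorter than `min_duration_s` = 0.05 s are
discarded. Note at 20 fps one frame is exactly 50 ms, so the duration
filter can only act on data with finer temporal resolution; it is exact at
any fps. Magnitude is the mean z over the run (peak z is also recorded)
and participation is the fraction of cells with ≥ 1 deconvolved event in
[onset, offset]. No merging or splitting of runs is applied: thresholding a
calcium-smoothed signal can split one physiological burst into consecutive
runs (or merge a fast train into one run), and without an explicit rule any
post-processing would be arbitrary. Speed coupling is the Spearman
correlation between the population signal and frame-resampled speed, also
reported restricted to burst frames; burst-triggered speed profiles average
speed in ±window (2.5 or 5 s) around burst peaks, skipping bursts whose
window leaves the session, with contrast = peak-bin speed minus the mean of
the two flank bins.

## Place-cell-like classification

Positions are averaged in 0.5 s windows; each event is assigned to the bin
of its window's mean position (events outside the tracked span are dropped
with a warning). Occupancy is 0.5 s × windows per bin; raw rate =
counts/occupancy on visited bins. Smoothing convolves both the spike and
occupancy histograms with an isotropic Gaussian, σ = 1 bin truncated at 3σ
(dividing the two smoothed histograms renormalises the kernel at arena
edges); "width = 1" is read as σ = 1 bin, the common convention.

Skaggs information I = Σᵢ pᵢ(λᵢ/λ̄)log₂(λᵢ/λ̄) is computed on the **raw**
rate map by default: the analytic identities (uniform → 0; all firing in 1
of k equally-occupied bins → log₂ k exactly) hold only without smoothing,
and the shuffle test is self-consistent as long as observed and shuffled
scores use the same map; `smoothed=True` is available.

Significance: the whole event train is rotated circularly in time modulo
the tracked span by offsets drawn uniformly from
[`min_shift_s`, T − `min_shift_s`] (default 10 s, keeping rotations away
from zero), the information is recomputed `n_shuffles` = 500 times, and
p = (# shuffled ≥ observed)/n. The classification is the joint rule
p < 0.05 AND ≥ 20 events (strict inequalities on both: p = 0.05 exactly and
19 events both reject).

Fields: bins ≥ 20 % of the smoothed peak (inclusive), partitioned into
4-connected components; each field records its bins, the unweighted
centroid of bin centres, and area = bins × 16 cm². 4-connectivity was
chosen as the conservative reading of "contiguous" (8-connectivity merges
diagonal neighbours and inflates fields).

Coherence: the box-car value at a visited bin is the mean raw rate over its
visited 3 × 3 neighbours excluding the centre (the classic construction;
the kernel size is a convention); the Pearson correlation over visited bins
with ≥ 1 visited neighbour is Fisher-transformed, with r clipped to
±(1 − 1e−12) before atanh. Constant maps raise.

Object score: a (2·pad+1)² bin square (pad = 2 → 5 × 5) centred on each
object's bin, clipped at edges and unioned over objects; the per-cell score
pools all field bins (|field ∩ mask|/|field|). Pooling was preferred over a
per-field mean because it weights fields by size; the per-field alternative
is a one-line change on the returned fields.

## Functional networks

All n(n−1)/2 Spearman correlations of the full-rate ΔF/F traces (no
down-sampling), p-values from the t-approximation, Bonferroni-multiplied by
the number of pairs; edges require adjusted p < 0.001 and r > 0, with
weight r. Applying the 0.001 threshold to *adjusted* p-values is the
stricter of the two possible readings and is the default
(`correction="none"` gives the raw-p variant). Constant traces stay as
nodes but form no edges (warning).

Centralities: degree/(n−1); Barrat weighted clustering
Cᵢ = [1/(sᵢ(kᵢ−1))] Σ (wᵢⱼ+wᵢₕ)/2 over triangle-closing neighbour pairs
(degree < 2 → 0), chosen because it is the weighted form provided by the R
graph library ecosystem this analysis style comes from; closeness =
inverse mean shortest-path distance with edge length 1/r (strong
correlation = short edge; `one_minus_r` available), computed within each
connected component, isolated nodes scoring 0. Session means are expressed
as 100·session/HA per metric; a zero HA baseline for a single metric (e.g.
zero clustering in a sparse habituation network) yields NaN with a warning
rather than aborting, and only an all-zero baseline raises.

## Statistics

Within-group across sessions: Friedman omnibus when every animal has
exactly one value in every session (paired design; with only two sessions
the signed-rank test itself is the omnibus), Kruskal–Wallis otherwise;
pairwise follow-ups are Wilcoxon signed-rank (paired) or rank-sum
(unpaired), Holm-adjusted. Between groups: two-sided Mann–Whitney U, exact
for n ≤ 25 without ties, normal approximation with tie correction
otherwise. Cell-level metrics (place-cell properties) are analysed at the
cell level; animal-level metrics (bursts, centralities, reactivation)
aggregate per animal first. Degenerate inputs (all values identical) report
statistic 0, p = 1 instead of failing.

## Synthetic data generator

The generator realises the study design: four 10-min sessions at 20 fps,
40 × 40 cm arena with two objects at (10, 20) and (30, 20) cm.

- **Trajectory**: each velocity component is an Ornstein–Uhlenbeck process
  (relaxation τ = 1 s, stationary scale set for a mean speed of 8 cm/s,
  typical of open-field exploration), positions folded back at walls.
- **Events**: inhomogeneous Poisson per cell; rate = base rate (log-normal
  around 0.25 Hz, a realistic deconvolved-transient rate) × Gaussian spatial
  gain for place cells (peak gain 8, width 5 cm) × burst gain during planted
  bursts × a shared log-OU modulation (σ_log = 0.5, τ = 2 s) within
  correlated blocks.
- **Traces**: events convolved with a peak-normalised difference of
  exponentials (rise 0.05 s, decay 0.6 s, a fast-indicator shape) plus
  white Gaussian noise (σ = 0.15 ΔF/F).
- **Active sets**: HA activity is Bernoulli(0.9); each later session keeps
  an earlier-active cell with the preset's directional overlap fraction and
  recruits an earlier-inactive cell with probability 0.5. Overlap is
  directional — the fraction of the earlier session's active set re-active
  later — so the registration map's realised reactivation is binomial
  around the planted value.
- **Presets**: `vehicle_like` (bursts 12/20/22/20 per session at gain 8,
  overlaps HA→S1 0.6, S1→S2 0.8, S2→S3 0.4, 10 % object-tuned cells)
  mirrors a control-group profile — more bursts during object sessions,
  strong re-engagement at re-exposure, a drop at displacement;
  `antagonist_like` (bursts 12/7/7/6 at gain 5, flat overlaps ≈ 0.5, 3 %
  object-tuned) mirrors a β-adrenergic-blockade profile of fewer, weaker
  bursts and flatter reactivation.

What the generator does **not** emulate: imaging/photon noise, motion
artefacts, cell-extraction errors or registration mistakes (the
registration map is exact by construction), biophysical calcium dynamics
beyond the two-exponential kernel, theta/ripple temporal structure, or
behavioural state changes (rest vs. run). Passing tests therefore validate
the *analysis* implementations against known ground truth, not robustness
to extraction artefacts in real recordings.

## Verification battery and problem sizes

The acceptance script and test suite run the full battery at desk scale,
sizes chosen to give tight statistical resolution while keeping the battery
fast: analytic Skaggs identities (exact); shuffle-null calibration with 200
non-spatial cells × 500 shuffles (nominal-rate band 0.02–0.08 at α = 0.05);
place-cell recovery with 50 planted (gain 8, ≥ 50 events) + 50 non-spatial
cells (sensitivity ≥ 0.90, false positives ≤ 0.08); burst recovery with 20
planted bursts in an 800-cell session plus constructed signals for exact
duration and sub-50 ms checks — large populations are used for the
generative check because threshold recrossings at the calcium-kernel tail
of a burst add occasional extra detections when population shot noise near
z = 2 is appreciable (it shrinks as 1/√(population event rate)); network
null calibration over 100 runs of 50 independent cells × 12,000 frames
(≤ 1 false edge in total); centrality equality with brute-force
implementations on 500 random weighted graphs of ≤ 6 nodes (1e−12);
ensemble-overlap recovery on a 400-cell study (±5 points); field-partition
conservation on 1,000 random maps (exact); and byte-identical reruns of
simulate + run at a fixed seed (30 cells, 100 shuffles — determinism is
scale-independent).

## Known limitations

- Events in the final fraction of a second beyond the last complete 0.5 s
  window are dropped from spatial analyses (warning); occupancy therefore
  sums to the session duration within one window.
- The burst-duration filter cannot discard anything at exactly 20 fps
  (one frame = the 50 ms minimum); it is meaningful for higher-rate data.
- Spearman edge p-values use the t-approximation, which is what standard
  statistical software reports for these sample sizes; exact permutation
  p-values are not computed.
- The shuffle null assumes the event train is stationary up to rotation;
  strong non-stationarity (drift, bleaching) inflates false positives in
  real data but is absent from the generator.
- Closeness on disconnected graphs follows the component-wise rule; other
  conventions (harmonic centrality) would differ on fragmented networks.
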