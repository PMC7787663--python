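# Methods

This note documents the models, procedures and numerical choices behind
each module, what the synthetic-data generators do and do not emulate,
and the package's known limitations.

## Behavior

### Tracking (`persistate.tracking`)

The background of a video with an inhomogeneous floor is estimated as
the per-pixel median of 10 segment medians: a fly that sits still for a
fraction of the video contaminates at most a few segment medians, and
the median across segments rejects them. The estimator is exact whenever
each pixel is fly-free in more than half the frames of every segment.

Per frame, the absolute background difference is Gaussian-smoothed
(σ = 1 px) and thresholded (Otsu by default; a fixed threshold can be
supplied). Connected components outside [0.5, 2] × the typical fly area
are discarded as debris or merges. Remaining pixels are k-means
clustered, with k grown from 2 until every cluster's compactness — mean
squared pixel distance to the cluster centroid divided by pixel count —
falls below a threshold (default 1.0, exposed); the least-compact
clusters are dropped and the survivors re-clustered at k = 2. Each final
cluster gets a moment-based ellipse fit (second-moment eigendecomposition
with a 1/12-px² regularization for pixel extent). Frames where two flies
cannot be found raise a `LostFrame` flag rather than fabricating
detections.

Identity linking minimizes summed centroid displacement between
consecutive frames (two flies, so both assignments are compared
directly); assignments within a tie tolerance are flagged. Lost frames
are filled by linear interpolation up to `max_gap` (default 5) frames;
longer gaps split the track. Ellipse orientation carries a 180°
ambiguity, resolved by the displacement direction over a 5-frame window.

### Frame features (`persistate.kinematics`)

Velocities use central differences, `v_i = (p_{i+1} − p_{i−1})·fps/2`;
the endpoints use one-sided differences and are flagged. Forward
velocity is the signed projection on the heading; lateral speed is the
unsigned perpendicular projection; accelerations are central differences
of the signed forward/lateral components, with the lateral one reported
as a magnitude; rotational speed is the absolute derivative of the
unwrapped heading angle. The interaction block projects each fly's
velocity on the (unit) axis joining the flies, signed positive toward
the partner, and reports the heading-to-partner angles as unsigned
magnitudes in [0, 180]° — "degrees the fly must turn to face its
partner" is naturally unsigned, and the downstream state signatures use
only magnitudes. Coincident flies produce NaN interaction features.
Units are mm, seconds and degrees throughout; pixel-to-mm conversion
belongs to ingest (arena diameter 25 mm).

### Discriminative ensemble (`persistate.discriminative`)

Defaults follow the full-scale protocol: 90 linear SVMs (C = 1), each
trained on 3,000 frames per class, validated and tested on 30,000 per
class, all sets pairwise disjoint across classifiers and splits (a
ledger of frame indices is kept and auditable). The 30 best-validated
classifiers are kept (ties broken by index). When a dataset cannot
support disjoint sampling the split sizes shrink proportionally with a
warning. Features are z-scored on each classifier's own training split
so weight magnitudes are comparable across parameters; a consequence is
that rescaling an input feature leaves its weight unchanged. Per
parameter, the kept classifiers' weights are tested against zero with a
one-sample *t*-test and Bonferroni correction (m = 17); the significance
threshold is p < 10⁻⁴ after correction. The one-sample form matches the
stated null hypothesis (weights drawn from a zero-mean normal with
unknown variance).

### State clustering (`persistate.stateclust`)

Each repeat samples the same number of frames from every condition (with
replacement by default), z-scores each parameter over the sampled frames
of that repeat, and runs k-means (k = 20, 500 iterations, k-means++
initialization with a per-repeat seed spawned from the master seed).
Clusters are matched across repeats by the mean squared error between
centroid vectors, solved as an optimal one-to-one assignment
(Hungarian); greedy matching is available as an option. Occupancy is
reported per repeat, cluster and condition (each condition's occupancies
sum to 1), and coverage is the frame fraction held by the largest `n`
clusters, averaged over repeats.

### Epoch analytics (`persistate.ethogram`)

Window features over radius-r windows (default r = 10 frames): mean,
min, max, std over the full window; `change` = endpoint difference
x_{i+r} − x_{i−r}; `diff_neighbor_*` = statistic over the trailing
half-window minus the leading half-window; `zscore_neighbors` =
deviation of the center from the window-without-center, in its SD (0/0
defined as 0, flagged). Edges use truncated windows, flagged. Epochs are
maximal positive runs of at least `min_bout` frames (default 5, ~83 ms
at 60 fps, suppressing single-frame flicker; the underlying protocol
leaves this unstated). Overlapping shoving and chasing labels are
resolved by a precedence rule (shoving first, configurable) only for the
three-state transition sequence; conditioned transition probabilities
are normalized per source over destinations, given that a transition
occurred. Behavior time courses are centered moving averages (2-min
window), truncated at copulation, with the across-session mean at each
time weighted by the sessions still available there. Song–speed
correlation uses non-overlapping 1-min windows pooled per condition;
windows without song are excluded from the bout-duration pairing and
counted. Copulation curves are empirical cumulative incidences with
right-censoring at the session end; proportional-hazards regression is
delegated to lifelines behind a thin wrapper.

## Calcium

Baseline statistics (F₀, σ₀) come from the window [trace start,
stimulus onset); z = (F − F₀)/σ₀ and ΔF/F = (F − F₀)/F₀. ROIs with
σ₀ = 0 or F₀ ≤ 0 are excluded and logged.

**ICA drift removal.** The structural channel is linearly interpolated
across [onset − 20 s, offset + 20 s] (ignoring the stimulus-locked
bleed-through artifact), zero-mean noise matched to its shot noise is
added at the interpolated points, and the result is smoothed with a
50-s moving average (edge-normalized). The two channels are then
separated by a two-component ICA solved in closed form: after whitening,
every rotation of the source pair has unit variance, so the source
maximally correlated with the processed structural channel is the
normalized covariance direction — a deterministic, reference-guided
solution of the two-source problem that avoids the convergence failures
of iterative ICA at a hundred-odd samples. The component whose absolute
correlation with the processed reference exceeds 0.9 is the background;
the other, sign-aligned and least-squares-mapped back to activity-channel
units, is the cleaned trace. Two guards return the activity channel
unchanged: a degenerate reference (flagged `ica_failed`), and a
reference whose variance collapses under the 50-s smoothing (flagged
`ica_skipped_no_drift`) — a white reference carries no drift to
subtract, and removing a chance projection would only corrupt the
signal. Known limitation: drift *inside* the interpolated stimulus
window is unobservable by construction, so cleanup quality is bounded by
how well a straight line approximates the drift there; equivalently,
responses that happen to co-vary with the drift realization lose some
variance. This is inherent to using the structural channel as the only
reference.

**Classification.** Ft1 is the mean z over the stimulus, Ft2 the mean
over the first 300 s after offset. Nonresponsive ⟺ Ft1 ≤ 3; transient ⟺
Ft1 > 3 and Ft2 ≤ 3; persistent ⟺ both exceed 3. A t2 window truncated
by more than half flags the call low-confidence. The rule is monotone:
raising post-offset activity can never turn persistent into transient.

**Response-type clustering.** Persistent and transient traces are
clustered separately; the cluster count per set is the modal choice of
four internal criteria (Calinski–Harabasz, Silhouette, Davies–Bouldin
over counts 2–6; Gap over 1–6 with a uniform-box reference, 20 draws,
seeded), ties resolved toward the smaller count. The tree is Ward
linkage on the euclidean geometry of z-traces: dynamics that share
on/off timing but differ in sustained level are nearly collinear (a
correlation distance merges them), and single/average linkage chains
into outlier-versus-rest splits, so Ward's compact-cluster objective is
the right fit for distinct response dynamics. Types are numbered with
persistent clusters first, each set ordered by descending mean Ft2 then
Ft1; the second persistent type can optionally be re-split into two
sub-dynamics.

**Maps and profiles.** Voxel consistency maps report, per voxel, the
fraction of flies with a type-positive ROI among the flies that imaged
that voxel; a voxel is consistent when the fraction strictly exceeds
0.30, and the reported volume fraction uses as denominator the voxels
imaged by at least 30 % of flies (both thresholds exposed). Mask
overlaps are plain set intersections in percent. Decay profiles take the
per-ROI z value within one volume period of offset + {0, 180, 360} s.
Patch-clamp tuning integrates baseline-subtracted voltage over each
stimulus, normalizes by stimulus duration, then scales the curve to peak
at 1 (skipped, flagged, when all responses are zero).

## Connectome

Deduplication collapses, within each (presynaptic, postsynaptic) cell
pair, single-linkage chains of detections whose presynaptic coordinates
lie strictly within 150 nm; the representative is the lexicographically
smallest coordinate (deterministic), removals are itemized with cluster
ids, and the operation is idempotent. The boundary is strict — two
detections at exactly 150 nm both survive. A global (cross-pair) mode
exists behind a flag. Partner filters: manual mode keeps partners with
≥ 3 synapses; automatic mode keeps a partner iff it has ≥ 6 synapses
*and* its annotated type contains a cell with ≥ 15 synapses, evaluated
per direction; unannotated cells are dropped and logged. Aggregation
sums per annotated type, sorts descending with alphabetical tie-breaks
and reports a cumulative fraction (a valid CDF). Output:input ratios are
rounded to one decimal; zero inputs are reported as the string "n:0"
rather than dividing. Reciprocal partners require a minimum count each
way (default 6, matching the automatic-detection minimum; the source
protocol's legend reads "si synapses", taken as "six"). Autapses are
kept but flagged. Region tallies map nm coordinates through a voxel
transform into an integer-labeled volume, counting out-of-volume
terminals as unassigned.

## Synthetic data (`persistate.synthio`)

The generators define the study conditions for every test; each is a
pure function of (config, seed) and emits labels sufficient to score its
downstream analysis.

**Two-fly sessions.** State switching is a continuous-time Markov chain
discretized per frame as P_frame = I + (P − I)/fps (always a valid
stochastic matrix for a row-stochastic per-second P), with a minimum
dwell (default 1 s). Within a state the male roams toward random
waypoints while the pair drifts along its separation axis at the
state's approach velocity; the female rides the separation vector,
whose direction is a slow random walk and whose length is
Ornstein–Uhlenbeck-regulated around the state's target distance; both
headings are set relative to the partner axis with a per-dwell random
side and small angular noise. Near the arena wall the pair axis is
steered so the drift points inward, keeping the approach velocity
realized instead of cancelled at the boundary. The default states encode
the canonical signatures: *shoving* (2 mm, both flies facing each other,
female pushing toward the male), *chasing* (3 mm, female behind a
retreating male), *disengaged* (9 mm, 90° headings). Angles and
distances are realized essentially exactly (the fidelity tests bound the
fmAngle error by 3° and check O(n^−1/2) convergence of the distance);
the approach velocity is realized approximately (boundary steering and
waypoint wander leak a mean-zero component). Not emulated: body
articulation, wing/leg behavior, male–female contact mechanics,
tracking noise. Passing tests therefore validate the analysis chain, not
a biomechanical model of courtship.

**Calcium traces.** Four response kernels with a 1-s indicator rise:
slow-persistent (post-offset τ = 1000 s), fast-persistent (τ = 300 s),
sustained-transient (τ = 30 s after a full-amplitude stimulus response)
and adapting-transient (decay to a 0.5 plateau with τ = 60 s during the
stimulus, then τ = 30 s). Defaults: 0.1 volumes/s, 5 min baseline +
5 min stimulus + 9.5 min post; amplitude 6σ; half the ROIs responsive,
half of those persistent, each group split evenly between its two
dynamics — balanced classes chosen for testability of classification
and clustering, not as an estimate of in-vivo prevalence (whole-brain
imaging yields far sparser responses). Shared drift is a random walk
smoothed on a ~300-s window ("slow drift over tens of minutes"),
identical in both channels; the red channel adds a stimulus-locked
artifact (5σ). The drift-free activity channel is stored as per-trace
ground truth. GCaMP kinetics beyond the single-exponential rise are not
modeled.

**Synapse tables.** True counts per cell pair are Poisson with mean set
by the expected type-pair totals; duplicates jitter the presynaptic
coordinate by < 100 nm at a configurable rate; false positives land at
random cell pairs and coordinates. A construction flag keeps true
detections of the same pair ≥ 300 nm apart so dedup outcomes are exactly
scorable. The 115-detection QC fixture is constructed, not sampled: 26
parent–duplicate pairs, one TP–duplicate–TP chain, one triple of
mutually close true detections, one duplicate placed beyond the
threshold, the rest isolated on a coarse grid — forcing the removal of
exactly 27 duplicates and 3 true synapses at the 150-nm cut.

**Video and song.** The video generator renders two elliptical flies
orbiting over a smoothed random texture (truth: centroids and
orientations per frame); it does not attempt photorealism or body
postures. The song generator plants a window-level correlation between
total song and female speed by constructing the speed from the
standardized quantized bout amounts, so the noiseless limits are exactly
±1 and intermediate values are recovered up to window-sampling noise.

## Orchestration and determinism

Both pipelines derive every stage seed from the master seed via
`SeedSequence` spawning, so inserting a stage does not shift the streams
of the others; reports carry a configuration hash and the package
version. In the behavior pipeline the clustering stage falls back to all
17 parameters when no parameter reaches significance, and the epoch
stage scores the cluster most enriched in experimental conditions after
assigning every frame to its nearest reference centroid.

## Problem sizes

The test suite and the acceptance script run the protocols at reduced
sizes chosen to keep the full statistical structure while fitting a
desktop run: ensembles of 90 classifiers with 200-frame training splits
(120,000 frames), clustering at k = 6 with 30 repeats of 8,000 frames,
200–400 synthetic ROIs, 20-seed replication for the recovery claims.
Library defaults retain the full-scale protocol values (3,000/30,000
frame splits, k = 20, 99.4-min balanced samples are the caller's choice
of `frames_per_condition`).

## Known limitations

* The per-ROI two-channel ICA cannot recover drift inside the
  interpolated stimulus window, and with very smooth drift the
  background coefficient is estimated from few effective degrees of
  freedom; cleanup quality degrades gracefully but measurably there.
* The behavior generator's approach velocity is approximate near the
  arena boundary (see above).
* Frame-level classifiers can exploit session-realization idiosyncrasies
  when very few sessions per condition are simulated; null-condition
  accuracy approaches chance only as sessions accumulate.
* The tracker's compactness threshold and smoothing width have no
  protocol-specified values; the defaults are exposed and the tests pin
  behavior only on synthetic geometry.
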