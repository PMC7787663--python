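# persistate

Quantitative toolkit for studying **minutes-long persistent internal
states** in *Drosophila* females: how brief optogenetic activation of a
small set of central-brain neurons (pC1d/e) produces lasting changes in
behavior toward males (shoving, chasing), lasting neural activity, and
how the underlying recurrent circuitry looks in the electron-microscopy
connectome.

The package implements the three analysis arms of that research program
as a tested, reusable library, together with synthetic-data generators
that emit ground-truth labels so every stage can be validated without any
imaging or EM downloads:

1. **Behavior** — two-fly centroid tracking on inhomogeneous backgrounds
   (median-of-segment-medians background, iterative k-means pixel
   clustering, ellipse fits); the 17 per-frame kinematic parameters
   (fFV, fLS, fFA, fLA, fRS and male counterparts; mfDist, fmAngle,
   mfAngle, fmFV, fmLS, mfFV, mfLS); an ensemble of linear SVMs on
   disjoint frame samples whose hyperplane weights are tested against
   zero (one-sample *t*, Bonferroni-corrected, p < 10⁻⁴) to find the
   discriminative parameters; repeated condition-balanced k-means
   (k = 20, 30 repeats, per-repeat z-scoring) with optimal cross-repeat
   centroid matching; and epoch-level analytics (JAABA-style window
   features, conditioned transition probabilities, moving-average time
   courses, windowed song–speed correlations, censored copulation
   curves).
2. **Calcium** — per-ROI dual-channel trace processing: baseline
   statistics F₀/σ₀ and z-scoring; two-component ICA removal of slow
   drift using the structural (tdTomato) channel as background reference;
   the 3σ₀ classification (responsive ⟺ Ft1 > 3σ₀; persistent ⟺
   Ft2 > 3σ₀ over the first 5 post-stimulus minutes); consensus
   hierarchical clustering of response dynamics (Calinski–Harabasz,
   Silhouette, Gap, Davies–Bouldin); across-animal voxel consistency
   maps (> 30 % of flies per voxel) and mask overlaps; decay profiles at
   0/3/6 min; patch-clamp integral-voltage tuning curves.
3. **Connectome** — synapse-detection QC and distance-based redundancy
   removal (single-linkage collapse of presynaptic coordinates < 150 nm
   apart), manual (≥ 3 synapses) and automatic (≥ 6 synapses with a
   15-synapse type anchor) partner filters, per-type aggregation with
   cumulative fractions, output:input ratios, reciprocal-partner motifs,
   group connection matrices, and region tallies.

## Worked example

Quality control of automatically detected synapses, on the package's
115-detection reference table (`examples/connectome_qc.py`):

```
detections tested: 115
composition (%):   {'TP': 61.7, 'redundant': 24.3, 'FP': 13.9}
removed by dedup:  {'TP': 3, 'redundant': 27, 'FP': 0}
surviving table:   85 detections, 80.0% true positives
pC1d <-> aIPg-a.0: outputs 588, inputs 0, ratio 588:0
pC1d <-> aIPg-b.0: outputs 38, inputs 39, ratio 1.0
pC1d <-> aIPg-c.0: outputs 39, inputs 14, ratio 2.8
```

Of 115 hand-checked detections, 61.7 % are true synapses and 24.3 % are
duplicate coordinates for the same synapse; collapsing detections whose
presynaptic coordinates lie within 150 nm removes 27 of the 28 duplicates
at the cost of only 3 true synapses. The output:input ratios identify
aIPg-b as the partner with balanced reciprocal connectivity to pC1d — the
recurrent motif implicated in sustaining persistent activity.

Classifying persistent neural activity on synthetic traces
(`examples/persistent_activity.py`):

```
ROIs analyzed:  200
class counts:   {'nonresponsive': 103, 'transient': 48, 'persistent': 49}
agreement with generator labels: 98.0%
consensus clusters: persistent 2, transient 2
```

A ROI is *responsive* when its mean z-scored activity during the stimulus
exceeds 3 baseline standard deviations, and *persistent* when the mean
over the first five post-stimulus minutes also does; the consensus
criteria split each class into two dynamics (slow/fast decay; sustained/
adapting), matching the four planted response types.

The other examples cover behavioral state discovery
(`behavior_state_discovery.py`), tracking (`tracking_demo.py`) and
song–speed correlation (`song_speed_correlation.py`); each prints its
results with a short interpretation.

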