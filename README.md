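# capipe

Analysis pipeline for dorsal-CA1 wide-field calcium imaging recorded while
mice perform a four-session item-place learning task (object-free
habituation HA, novel-object exposure S1, re-exposure S2, and object
displacement S3; 10 min sessions at 20 frames/s in a 40 × 40 cm arena with
two objects).

The package takes the products of cell extraction — ΔF/F trace matrices,
deconvolved event trains treated as spike events, animal trajectories, and a
longitudinal cell-registration map with HA as the reference session — and
computes, per animal and session:

- **Behaviour** — per-object exploration time within a ~2 cm object radius,
  as a percentage of tracked time, and the discrimination index
  DI = (t_displaced − t_stationary)/(t_displaced + t_stationary) ∈ [−1, 1].
- **Ensembles** — active-cell counts normalised to HA, and directional
  reactivation: 100·|A ∩ B|/|A| for session pairs HA→S1, S1→S2, S2→S3.
- **Population bursts** — each cell's trace is z-scored, averaged across
  cells, and the average z-scored again; maximal runs with z > 2 are burst
  events, runs shorter than 50 ms are discarded; per burst we report
  duration, magnitude (mean z), peak z and the fraction of neurons with ≥ 1
  event inside the burst, plus the Spearman coupling of population activity
  to running speed and burst-triggered speed profiles.
- **Place-cell-like classification** — trajectories are down-sampled to
  0.5 s, the arena divided into 10 × 10 bins (~4 cm); spatial selectivity is
  the Skaggs information I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) in bits/event, with
  significance from a 500-fold circular shuffle of the event train (empirical
  p = fraction of shuffled scores ≥ observed). A cell is place-cell-like
  when p < 0.05 **and** it fired ≥ 20 events. Smoothed rate maps
  (Gaussian σ = 1 bin on both spike and occupancy histograms) yield place
  fields (≥ 20 % of peak, 4-connected components), spatial coherence
  (Fisher-z of the raw-rate vs. neighbour-mean correlation) and an object
  score — the overlap of field bins with a 2-bin-padded object mask.
- **Functional networks** — all-pairs Spearman correlations of the ΔF/F
  traces; edges are positive correlations surviving Bonferroni correction at
  adjusted p < 0.001, weighted by r. Per node: degree/(n−1), the Barrat
  weighted clustering coefficient, and closeness (inverse mean shortest-path
  distance with edge length 1/r). Session means are expressed as a
  percentage of HA.
- **Statistics** — Kruskal–Wallis or Friedman omnibus across sessions
  followed by rank-sum / signed-rank pairwise tests, Mann–Whitney U between
  groups, all Holm-adjusted.

A synthetic-data generator (`capipe.synthetic`) produces complete
four-session studies with planted ground truth — place-tuned and
object-tuned cells, synchronous population bursts, controllable
cross-session ensemble overlap and correlated cell blocks, under
`vehicle_like` and `antagonist_like` parameter presets — so every stage is
verifiable without access to recordings.

## Worked example

```python
from capipe import AnalysisConfig, run_pipeline, simulate_study, write_study

sessions, regmap, truth = simulate_study("vehicle_like", n_cells=120, seed=42)
write_study("demo_study", sessions, regmap, truth)
tables = run_pipeline("demo_study", "demo_results", AnalysisConfig(seed=0))

ens = tables["ensembles"]
print(ens[ens.metric == "reactivation_percent"].set_index("session")["value"])
```

prints (rounded)

```
reactivation %:            {'HA->S1': 64.8, 'S1->S2': 85.3, 'S2->S3': 46.5}
burst counts:              {'HA': 21, 'S1': 27, 'S2': 26, 'S3': 34}
burst mean magnitude (z):  {'HA': 3.65, 'S1': 3.57, 'S2': 3.63, 'S3': 3.31}
place-cell-like fraction:  {'HA': 0.31, 'S1': 0.32, 'S2': 0.34, 'S3': 0.32}
degree % of HA:            {'HA': 100.0, 'S1': 153.0, 'S2': 158.1, 'S3': 142.1}
```

The reactivation percentages recover the preset's planted overlap profile
(high S1→S2 re-engagement, a drop after the S3 object displacement); the
network degree rises above the habituation baseline as correlated structure
appears in the object sessions.

The same workflow is available from a shell:

```sh
capipe simulate --preset vehicle_like --n-cells 200 --seed 1 --out study/
capipe run study/ --seed 1 --out results/
capipe report results/
```

`report` pivots the metric table into per-figure-style CSV views
(recruitment, reactivation, place-cell metrics, burst metrics, centralities
vs. HA).

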