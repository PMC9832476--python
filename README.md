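# sfstates

Selectivity-filter state analysis for tetrameric potassium-channel
trajectories.

The selectivity filter (SF) of a K⁺ channel holds five ion binding sites,
S0 (extracellular) to S4 (intracellular), each delineated by two stacked
rings of four oxygen atoms. Channels such as hERG lose conductance under
sustained activation (C-type inactivation), and the competing structural
hypotheses — central constriction of the filter versus widening of its
extracellular entrance — are distinguishable from trajectory data by a small
set of quantitative measures. `sfstates` implements that analysis as a
reusable, tested pipeline for structural bioinformaticians working on
channel gating:

* **Site occupancy by coordination number.** At a probe point *i* the
  coordination number over an atom selection A is

  C*ᵢ* = Σ_{j∈A} (1 − (d*ᵢⱼ*/d_c)⁶) / (1 − (d*ᵢⱼ*/d_c)¹²)
       = Σ_{j∈A} 1 / (1 + (d*ᵢⱼ*/d_c)⁶),

  evaluated in the singularity-free second form. With d_c = 1.4 Å (half a
  site length) over all K⁺ ions it reads ~1 for an occupied site and ~0 for
  an empty one; with d_c = 3.2 Å (a K⁺ first-hydration-shell radius) over
  all oxygens it counts the atoms forming each site (values > 5 characterize
  an intact, conductive-like site).
* **Pore geometry.** Opposite-subunit (diagonal) distances of any atom ring,
  found by farthest-neighbour matching so chain labelling does not matter,
  and filter backbone RMSD against a reference structure (optional Kabsch
  superposition).
* **Cavity profiling.** Coordination numbers at equally spaced points along
  the pore axis through the intracellular cavity (a 20 Å segment starting
  2 Å below S4): the profile **max** over K⁺ estimates cavity ion presence
  independent of the ion's axial position; the profile **min** over oxygens
  flags dehydrated stretches. Contiguous cavity residencies are extracted as
  dwell events (> 10 ns counts as stable binding).
* **State clustering.** Frames are clustered on their S0–S4 occupancy
  vectors (Ward linkage, Euclidean distance); the number of states is the
  silhouette-score maximum over a candidate range; clusters are
  characterized by quartiles, probabilities and medoid representatives.
* **Synthetic ensembles with ground truth.** A generator builds ideal
  four-fold filters (conductive, extracellularly widened, centrally
  constricted), plants ions, waters and Gaussian noise, so every stage is
  testable without microsecond trajectories.

## Worked example

```python
import sfstates as sf

# a 2000-frame synthetic ensemble alternating two ion configurations
schedule = sf.cycling_schedule([(0, 2, 4), (1, 3)], 2000, block=10)
spec = sf.SyntheticSpec(n_frames=2000, noise_sigma=0.2, seed=1,
                        ion_schedule=schedule)
frames, truth = sf.generate_ensemble(spec)

topology = sf.make_topology(frames)
features = sf.compute_features(frames, topology)

results = sf.SiteOccupancyModel(features, k_candidates=range(2, 8)).fit()
print(results.summary())
```

prints

```
Selectivity-filter ion-configuration clustering
===============================================
frames: 2000    candidates: 2..7
selected k (max silhouette): 2

k    silhouette
2     0.9906  <-- selected
3     0.6824
4     0.3442
5     0.3140
6     0.2789
7     0.2824

cluster  probability  mean occupancy S0..S4
0        0.5000        1.00  0.03  1.00  0.03  1.00
1        0.5000        0.02  1.00  0.03  1.00  0.02
```

The silhouette maximum recovers the two planted configurations; each
cluster's mean occupancy vector identifies which sites its ions occupy
(S0/S2/S4 versus S1/S3), and the probabilities are the fractions of frames
in each state. The same workflow applies to real data via
`sf.read_trajectory("topology.pdb", "production.dcd", stride=10)` with a
site scheme from `src/sfstates/data/site_schemes.yaml` (hERG and KcsA
schemes ship by default; schemes are configuration, not code).

A command-line interface wraps the same stages:

```bash
sfstates synth --out run/ --n-frames 500 --sites 0,2,4 --seed 1
sfstates features --topology run/synthetic.pdb --trajectory run/synthetic.dcd \
         --scheme synthetic --out run/
sfstates cluster --features run/features.csv --k-min 2 --k-max 10 --out run/
sfstates distances --structure conductive.pdb --rows "78:O;77:O;76:O;75:O" \
         --out table.tsv
```

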