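# Methods

This note documents the models and procedures implemented in `sfstates`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## The coordination-number switching function

Every occupancy and hydration measure in the package reduces to one
primitive: the coordination number at a probe point *i* over an atom
selection A,

    C_i = Σ_{j∈A} (1 − (d_ij/d_c)^6) / (1 − (d_ij/d_c)^12),

with d_ij the probe–atom distance and d_c a cutoff. The rational form has a
removable singularity at d = d_c (both numerator and denominator vanish);
the implementation evaluates the algebraically identical factorization
1/(1 + (d/d_c)^6), which is smooth everywhere, equals 1/2 at the cutoff, is
strictly decreasing, and decays as (d_c/d)^6. Tests verify continuity at
d_c to 1e-9, monotonicity over random points, and agreement with a per-atom
brute-force loop to 1e-9 on random configurations up to 10³ atoms.

Two cutoffs are used, both configurable:

| parameter | default | rationale |
|---|---|---|
| ion cutoff d_c | 1.4 Å | about half the binding-site length along the pore axis, so one centred K⁺ reads ≈ 1 and an empty site ≈ 0 |
| oxygen cutoff d_c | 3.2 Å | about the radius of a K⁺ first hydration shell, so the value counts site-forming/hydrating oxygens |

Note the tail is heavy: at 1.1·d_c an atom still contributes ≈ 0.37. A
"gap" in a water column therefore reads near zero only when the nearest
oxygen is ≳ 1.6·d_c from the probed point; a 7 Å water gap yields an axis
minimum of ≈ 0.7, not ≈ 0. The tests assert oracle-computed values rather
than an idealized step-function intuition.

## Binding sites and channel anatomy

A site S0–S4 is delineated by two stacked rings of four backbone/side-chain
oxygens (eight atoms); its center is their unweighted mean. Ring membership
is configuration, not code: YAML schemes map each site to two
(residue, atom) rings, resolved in all four subunits. Shipped schemes cover
hERG (carbonyls of 624–627 plus the threonine-623 oxygens), KcsA (the
canonical T75-OG1/T75-O/V76-O/G77-O/Y78-O/G79-O ladder) and the synthetic
pseudo-filter. Subunits are defined by chain identifier in file order;
residue numbers are author numbering and never renumbered. Files with other
than four protein chains trigger a warning rather than an error
(crystal-symmetry expansion to the biological assembly is the user's
responsibility — diagonal distances are meaningless on a monomer).

Opposite-subunit (diagonal) distances are found by farthest-neighbour
matching: of the three perfect matchings of the four ring atoms, the
diagonals are the matching with maximal total distance. This makes the
measure independent of chain labelling conventions. The reported value is
the mean of the two diagonals (the symmetric default; the per-diagonal
values are also returned). Table output rounds to one decimal; internal
precision is full. The per-frame standard deviation is the population SD
(one frame gives exactly 0).

Filter RMSD is computed over a bijective residue map between query and
reference, across all four subunits, using a configurable backbone atom set
(default {N, CA, C, O} — the convention is not forced, since reasonable
backbone definitions differ). Both superposed (Kabsch, the default) and
fixed-frame modes are provided, because trajectory analyses aligned to the
pore axis may prefer the covariant fixed-frame deviation; neither mode is
asserted to be "the" convention.

## Cavity profiling and dwell events

The intracellular cavity is probed along the pore axis on a segment
starting 2 Å below the lower boundary of S4 (the mean plane of its
intracellular oxygen ring) and extending 20 Å intracellularly. The axis is
the configured pore axis (default z) through the mean of the five site
centers, oriented by the S0→S4 direction. Point spacing defaults to 0.5 Å
(41 points); at this spacing the profile extrema are stable to ≈ 1% as an
ion translates along the segment, which is the property the max-based
cavity-ion estimate relies on (the maximum makes the estimate independent
of the ion's axial position). Hydration is the profile minimum over all
oxygen atoms, flagging dehydrated stretches.

Dwell events are contiguous runs of frames in which an ion's axial
coordinate lies within the probed segment and its radial distance from the
axis is ≤ the ion cutoff (1.4 Å). The geometric membership rule is a
design choice — the coordination estimate itself defines no sharp boundary —
and the radial criterion ties it to the same length scale. Runs interrupted
by ≤ 2 frames are not split (tolerance for saving-interval jitter;
configurable). Event ends are exclusive, so duration = (exit − entry) ×
frame interval equals the number of frames inside times the saving interval
(default 0.01 ns). An event counts as stable binding when its duration
exceeds 10 ns.

## State clustering

Frames are clustered on the five S0–S4 K⁺ occupancies only; oxygen
coordination and cavity metrics are descriptive, not clustering features
(ion configurations are directly interpretable and tightly coupled to
filter structure). Clustering is agglomerative with Euclidean distance and
Ward linkage; the dendrogram is built once and cut at each candidate k
(default 2–15). The number of states is the silhouette-score maximum;
exact ties break toward the smaller k (parsimony). Labels are relabelled by
first appearance, making the partition deterministic and row-order
reproducible. When the best silhouette is below 0.25 the selection is
flagged low-confidence and a warning is emitted — the data then do not
support well-separated states.

Silhouette cost is quadratic in the number of rows, so above 20,000 rows a
fixed-seed subsample (stratified by replica) is scored instead; exact mode
is available (`subsample=None`). Cluster summaries report per-feature
means and first/third quartiles (linear-interpolation quantiles), cluster
probabilities (row fractions), and a representative frame — the medoid in
the five-dimensional clustering feature space, computed exactly up to 4,000
rows per cluster and as the centroid-nearest member beyond that. Replicas
pooled into one feature matrix keep (replica, frame) provenance per row.

The fitting surface follows the statsmodels Model/Results convention
(`SiteOccupancyModel(features).fit()` → results with `summary()`,
`silhouette_curve`, `export()`); the underlying operations are plain
functions usable on bare arrays.

## The synthetic generator

The generator emulates exactly the statistical structure the analysis
assumes: six stacked rings of four oxygen pseudo-atoms on a perfect
four-fold axis, ions planted at site centers, an axial water-oxygen column
through the cavity, and isotropic, uncorrelated Gaussian noise per atom per
frame. Defaults:

* ring separation 2.8 Å — one binding-site length, consistent with the ion
  cutoff being half a site length;
* conductive ring diameters 4.5–5.1 Å (intracellular to extracellular),
  taken from the carbonyl diagonal distances of a conductive reference
  filter;
* the widened state inflates the two extracellular rings by +4 Å diameter,
  the magnitude reported for the outer-filter dilation seen in inactivating
  channels; both rings are widened because the shared S0/S1 boundary ring
  must move for both sites to degrade, which reproduces the observed
  "S0 and S1 lost, S3/S4 intact" oxygen-coordination signature;
* the constricted state pinches the two S2-bounding rings by 5.5/8.1, the
  conductive-to-closed Gly Cα diagonal ratio;
* noise σ = 0.1 Å by default (sub-thermal; the generator's pseudo-atoms
  carry no restoring forces, so σ is a free dial of the emulation, and
  study-specific values are set explicitly where tests state them);
* water spacing 2.6 Å, a typical oxygen–oxygen distance in a hydrogen-
  bonded column; an optional gap interval empties part of the column.

Ion schedules are per-frame tuples of occupied sites (constant, cycling or
Markov with geometric dwell times); a fixed ion roster is kept across
frames, with disengaged ions parked in the remote bulk so the atom count is
constant, as in a real trajectory. Cavity residencies are planted as
⌈duration/interval⌉ consecutive frames of a dedicated ion at mid-cavity.
Generation is bit-reproducible for a fixed seed.

What the generator does **not** emulate: correlated thermal motion,
anisotropic ring breathing, water exchange dynamics, protonation states, or
any force-field physics. Passing tests therefore demonstrate that the
measurement and clustering machinery recovers planted structure under
realistic geometry and noise — not that the pipeline's scientific
conclusions transfer to any particular force field or channel.

### Reference stand-ins

`reference_structures()` and `write_kcsa_standins()` build an idealized
conductive/constricted filter pair in KcsA-like numbering (T75–G79, with Cα
rings added). These are synthetic stand-ins, labelled as such in filenames
and docstrings — not deposited crystal structures. Their ring diameters are
constructed to reproduce the published conductive filter geometry (Gly Cα
diagonal 8.1 Å; carbonyl diagonals 5.1/4.7/4.7/4.5 Å for Y78/G77/V76/T75)
and the closed-filter Gly Cα diagonal (5.5 Å), so tests that read them
through the normal PDB path validate the full measurement chain against
those published values.

## Numerical choices and degenerate inputs

* Distances are kept at full double precision; PDB output truncates to the
  format's 3 decimals (round-trip tests use that tolerance; XTC quantizes
  to 0.001 nm).
* An empty atom selection yields coordination 0 by contract, not an error.
* `k = n_rows` yields singleton clusters; silhouette candidates are
  restricted to [2, n_rows − 1].
* Cluster probabilities must sum to 1 within 1e-9 (enforced at
  construction).
* The low-confidence silhouette threshold (0.25) and the dwell gap
  tolerance (2 frames) are documented defaults, not tuned constants.
* Problem sizes in the test suite and acceptance script (e.g. 5,000-frame
  recovery replicates, 3,000-frame acceptance runs, 20/10 seeded
  replicates) are chosen as the smallest sizes at which the studied
  statistics are stable; all scale up linearly via the same entry points.

## Known limitations

* The pipeline measures geometry and occupancy; it does not estimate free
  energies, conduction rates, or per-ion permeation counts.
* Silhouette-based selection inherits silhouette's bias toward compact,
  balanced clusters; rare states below the silhouette resolution may be
  merged.
* Subunit assignment relies on chain identifiers; files with malformed
  chains need user-supplied schemes.
* HOLE-style continuous pore-radius profiling is out of scope; only the
  ring-distance and axis-profile metrics are implemented.
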