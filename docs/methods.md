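# Methods

This note documents the models, conventions and design choices behind
`cnva`, in the order the pipeline runs them.

## Occurrence processing

Cleaning removes records with missing coordinates or year, coordinates
outside valid lon/lat ranges, exact `(species, lon, lat)` duplicates
(first occurrence kept, order preserved), and records before a cutoff
year (default 1950, the usual boundary between historical herbarium
material and modern georeferenced collections). A species left with no
usable records is an explicit error, not a silent empty set.

Spatial thinning retains at most one record per radius (default 5 km)
using a greedy pass: records are visited in a stable order — year
ascending, then longitude, then latitude — and kept iff their
great-circle distance (haversine, 6371-km sphere; adequate at this
scale) to every previously kept record exceeds the radius. Greedy
thinning is order-dependent and not maximal; we chose determinism over
optimality, and the order is part of the contract (the test suite
checks equality with an independent brute-force greedy oracle).

"Urban" records can optionally be dropped as those falling in cells
where a supplied human-footprint raster exceeds a configurable quantile
(default 0.99). There is no principled definition of an urban center at
this resolution; the quantile is deliberately exposed rather than
inferred.

## Range estimation

A species range is delineated by inverse distance weighting: presences
carry value 1, pseudo-absences value 0, and the score at a cell is the
distance-weighted mean with exponent `power` (default 2). Distances are
in km, not degrees, to avoid latitude distortion. A query point
coinciding with a data point takes that point's exact value, so the
score is 1 at presences and 0 at pseudo-absences, and lies in [0, 1]
everywhere. The range is `score >= threshold` (default 0.5) plus every
cell containing a presence.

IDW needs absence points, and none are observed; the main
departure-prone knob is therefore the pseudo-absence design: 10× the
presences, sampled uniformly over background cells excluding a buffer
(the thinning radius) around any presence, from a fixed seed. Raising
the threshold never enlarges the range, and the score surface is tested
against a naive double-loop evaluation to 1e-10.

Habitat-utilization weights $p_i$ over range cells are uniform by
default ($1/N_{range}$), optionally proportional to the IDW score, or —
as a robustness mode — placed on the occurrence cells alone,
proportional to record counts. The occurrence mode is also what the
statistical test batteries use, since it needs no pseudo-absence
sampling.

## Climate preparation

Ensembling is a plain cellwise mean over model members (e.g. a GCM
ensemble). Collinearity filtering computes Pearson correlations over
background cells (unweighted) and greedily drops, while any pair
exceeds the threshold (default |r| > 0.7), the variable with the most
offending partners, breaking ties by larger mean |r| and then by later
list position. The surviving set provably has no pair above the
threshold; which member of a correlated pair survives is a convention,
so the rule is deterministic and documented.

Standardization scales each variable by the background mean and SD of
the *current* stack. Future stacks reuse the current frame — if they
were standardized by their own moments, climate departure would be
biased toward zero. The background over which those moments (and the
global covariance) are computed is the *combined* range of all assessed
species (the union of their ranges), which serves as the "global
distribution" the niche is compared against.

## The niche factor model

See the README for the formulation. Numerical notes:

- The generalized eigenproblem is solved in the $C_S$-whitened space:
  with $C_S = LL^\top$, the Rayleigh quotient becomes an ordinary
  symmetric eigenproblem for $L^{-1} C_G L^{-\top}$, restricted to the
  orthogonal complement of the whitened marginality axis. This is
  numerically stable whenever $C_S$ is positive definite; a singular
  $C_S$ gets a ridge of $10^{-6}\,\mathrm{tr}(C_S)/P$, logged.
- $\rho_1$, the specialization on the marginality axis, is the variance
  ratio $(m^\top C_G\, m)/(m^\top C_S\, m)$ evaluated on that axis; the
  definition is isolated in one place so alternates can be swapped.
- If $\lVert m \rVert = 0$ the model is pure specialization and axis 1
  falls back to the first coordinate axis.
- Loadings follow a deterministic sign convention (largest-magnitude
  element positive); sensitivity uses absolute loadings with each
  factor column scaled to unit norm. Row-wise normalization
  alternatives cannot produce nonnegative $\rho$-weighted sensitivities
  and were rejected.
- The total sensitivity is $S = \sqrt{\bar s}$, the aggregation
  consistent with published CNFA factor tables (the printed totals are
  the root of the mean of the printed factors); the flat mean is
  available behind a flag. Total marginality is the Euclidean norm,
  with an optional legacy divisor of 1.96 used by some earlier
  niche-factor software.

Scale equivariance holds by construction: multiplying a raw variable by
a constant is absorbed by standardization and leaves the model
unchanged (tested).

## Exposure and vulnerability

Departure uses absolute differences — exposure measures the amount of
change experienced, and signed averaging would let opposite shifts
cancel. The total is the Euclidean norm across variables.

Sensitivity factors have a much wider numeric range than exposure
factors, so raw combination lets sensitivity dominate cross-species
comparisons. The remedy is max-min normalization over explicit pools:
one pool for all species' sensitivity factors, one for all species'
exposure factors across the configured scenarios jointly (a
per-scenario pool is a config option). Two totals are computed and both
reported: the *normalized* linear mean $V = \frac1P\sum (1+d')s'$
(default, scale-balanced) and the *classic* root-mean
$V = \sqrt{\frac1P\sum (1+d)s}$ on raw factors, which is consistent
with the per-variable factor $v_j = \sqrt{(1+d_j)s_j}$ that published
factor tables print. Species ranking is by V descending with ties
broken by S then D.

## Spatial surfaces

The per-cell projection formulas are conventions of this package (the
factor model itself only defines whole-range quantities): sensitivity
at a cell is the $\rho$-weighted mean absolute displacement from the
niche centroid along the factor axes; exposure is the RMS standardized
climate change; vulnerability is $\sqrt{s'(1+e')}$ on the normalized
surfaces. Each surface is min-max normalized over the species' range
cells (per species, per quantity) and classified at breaks of 1/3 and
2/3 with values exactly on a break assigned upward. An identically-zero
exposure surface (future = current) is passed through as zeros; any
other constant surface is rejected as degenerate rather than silently
normalized.

## Conservation overlay

PA polygons are rasterized by the cell-center-in-polygon rule —
deterministic, and exact for the generator's edge-snapped rectangles;
exact area-fraction rasterization would be needless precision at the
grid scales involved. Coverage is the percentage of range cells covered
(cos-latitude area weighting available); the per-class breakdown is
reported relative to the whole range, so class area shares sum to 100
and per-class PA shares sum to the total coverage by construction.

The human footprint is resampled bilinearly to the analysis grid,
min-max normalized over range cells, and coupled additively:
$c(x) = \min(1, v(x) + \alpha\,hf(x))$ with $\alpha = 0.5$ by default.
The additive capped index is a declared extension beyond a purely
visual overlay; coupling never decreases a cell's value for
$\alpha \ge 0$, and an all-constant footprint skips coupling with a
warning.

## Synthetic worlds

The generator emulates exactly the features downstream stages depend
on, and no more:

- **Climate fields**: Gaussian-smoothed white noise (kernel width
  `spatial_range`, default 5 cells) gives spatial autocorrelation; the
  realized fields are empirically whitened and then mixed with the
  Cholesky factor of the target correlation matrix, so the realized
  cross-variable correlation matches the target exactly (mixing alone
  is only exact in expectation, and residual sample correlation at
  moderate grid sizes is substantial).
- **Scenarios**: future = current + a smooth shift field per variable,
  scaled so the background mean absolute shift in background-SD units
  equals the scenario amplitude exactly. Defaults are 0.3 SD for the
  moderate and 0.6 SD for the high emission pathway — a doubled shift
  mirroring the relation between the two standard scenario narratives.
  Half of the shift variance (configurable) is carried by a
  west-high/east-low gradient so spatially structured exposure patterns
  are recoverable.
- **Species**: occurrence cells are drawn without replacement with
  probability proportional to a Gaussian niche density in the
  standardized climate (one record per cell, coordinates jittered
  within the cell), which avoids duplicate-coordinate artifacts the
  cleaning stage would remove. Niche center and SD are the ground truth
  that marginality and specialization recovery is tested against.
- **Protected areas**: axis-aligned rectangles snapped to cell edges,
  placed to hit a target coverage fraction within ±2%.
- **Footprint**: a sum of Gaussian bumps at random hotspot centers.

What the generator does *not* emulate: topography-driven climate,
realistic regional geometry, GCM structural differences, observation
bias in occurrence records. Passing tests therefore demonstrate
correctness of the estimators under known ground truth and the
qualitative signatures (narrower niche ⇒ higher sensitivity; larger
shift ⇒ higher exposure; accounting identities), not predictive skill
on real landscapes.

One finite-sample caveat: for a species whose niche matches the
background, the fitted marginality vector is unbiased (its across-seed
mean is ≈ 0), but each single fit carries a noise floor
($\lVert \hat m \rVert \approx 0.35$ at 60 occurrences on a 48×48
world) because spatial autocorrelation leaves few independent climate
patches. Recovery tests are therefore formulated on across-seed means
and on paired contrasts, not on single-fit norms.

## Pipeline and reproducibility

All stage seeds derive from one global seed by stable CRC32 hashing of
`seed:stage:species`, so partial reruns and independently executed
stages agree. The run manifest records the configuration, package
version, variable and scenario sets, and SHA-256 checksums of every
output; re-running a config is bit-identical. Statistical test
batteries use 100 paired seeded worlds at 64×64 cells (the paired
design cancels world-to-world variability); oracle comparisons use
small grids (≤ 25×25) where brute-force evaluation is exact.

The `cnva` console script exposes `simulate`, `thin` and `run`; the
remaining stages operate on in-memory intermediates that `run` executes
in one pass, and are driven through the library API when needed
individually.
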