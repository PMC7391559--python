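# Methods

This note documents the models, rules and numerical choices behind
`nichebar`, and what the synthetic validation does and does not show.

## Binned-range (BR) coding

One environmental axis is partitioned into equal-width bins covering the
union of the accessible-area (M) environments of all species in the
analysis. Edges are aligned outward to multiples of the bin width (a
3.2–34.7 °C range at width 1 becomes 3–35), so bins carry interpretable
labels like `24_25`. Bins are half-open `[a, b)` with the last bin closed;
ties of an occupied limit exactly on an edge therefore belong to the upper
bin, which breaks exact mirror symmetry at edge values — irrelevant for
measured data, but the reason the reflection property in the tests avoids
edge-exact limits.

Per species, a bin is **suitable** (`1`) when it intersects the occupied
range (range mode) or contains at least one occupied value (values mode).
A niche limit is **truncated** when the occupied extreme lies within
ε = 1e-6 × width (configurable) of, or beyond, the accessible extreme on
that side; the rationale is that "coincides" needs a numeric tolerance on
floating-point data. On a truncated side every bin beyond the suitable run
is **unknown** (`?`); on a characterized side such bins are **unsuitable**
(`0`). In values mode a bin containing no accessible value carries no M
evidence and is coded `?` even on a characterized side: `0` is a positive
claim ("present in M, not occupied") and is only made when M actually
samples the bin. Runs of `?` strictly between two suitable bins are
converted to `1` under the assumption of a unimodal response to the
environment; the fill is idempotent and never touches `0` or `1`. Interior
`0` bins between suitable bins (possible only in values mode with patchy
M environments) are kept by default; `--fill-gaps` extends the unimodal
assumption to them as well.

Occupied ranges may optionally be trimmed to symmetric percentiles (e.g.
5/95) in values mode to guard against outlier records; the default uses
raw minima/maxima.

A species whose occupied set is empty is an error at coding time — the
simulator is the place where empty realizations are legitimately discarded.

## Binned ancestral range (BAR) reconstruction

Each bin is an independent character over the ordered alphabet
(`0`, `1`, `?`). The unknown symbol is a bona fide third state, not
missing data: a tip coded `?` is evidence that lineages in that region of
the tree carry unobservable limits, and that ignorance propagates to
ancestors. An alternative mode treating `?` as the ambiguity set {0, 1}
exists for comparison (`unknown_as_ambiguous=True`) but is not the default.

**Maximum likelihood.** The equal-rates 3-state model has off-diagonal
rate q and transition probabilities
P_same(t) = (1 + 2e^(−3qt))/3, P_diff(t) = (1 − e^(−3qt))/3.
The likelihood is computed by the pruning algorithm with per-node
rescaling; the root prior is uniform (1/3 each — the ER stationary
distribution). q is profiled per bin on log scale over [1e-8, 1e3] per
unit branch length: a 40-point grid scan followed by bounded scalar
refinement (xatol 1e-8) around the best grid cell, because the q-profile
can be multimodal — a moderate-rate peak competing with a high-rate
saturation plateau, and for strongly conflicting bins the plateau is the
genuine optimum. When all tips share one state, q is unidentifiable; it is
pinned at the lower bound with a warning and marginals remain valid.
Marginal state probabilities at every node combine the node's subtree
partial likelihood with an "outside" likelihood transported from the rest
of the tree (equivalent to re-rooting at the node). Discrete node calls
take the argmax, except that when the top two marginals differ by less
than a tie tolerance (default 0.05, configurable) the call is `?` — the
model cannot separate the alternatives. Zero-length branches are identity
transitions; multifurcations are handled natively by both passes.

**Parsimony.** Sankoff dynamic programming with unit cost between any two
distinct states, branch lengths ignored. The up-pass computes, for every
node and state, the minimum total cost with the node pinned to that state;
the admissible set is every state attainable in at least one
minimum-cost reconstruction. Singleton sets are called as that state; any
larger set is called `?`.

Both passes are verified against exhaustive enumeration over all internal
state assignments on trees of up to 6 tips (likelihoods and marginals to
1e-9; costs and admissible sets exactly), 200 random instances each.

**Smoothing.** Reconstructed node vectors are smoothed so every bin
strictly between the first and last suitable bin becomes `1` — both `0`
and `?` are filled, extending the unimodal-response rationale used at the
tips to the per-bin reconstructions, which are computed independently and
can otherwise interleave. Smoothing is idempotent and never removes a
suitable bin. A node with no suitable bin at all (every bin `0`/`?`) is
passed through unchanged with a warning; its "lower suitable limit" is
undefined and reported as missing.

**Branch classification.** Comparing a tip (or any descendant) with an
ancestor, per bin: both suitable → retained-suitable; both unsuitable →
retained-unsuitable; suitable only in the descendant → gained; suitable
only in the ancestor → lost; any `?` → indeterminate. The branch summary
is `reduction` (losses only), `expansion` (gains only), `stable`
(neither), or `mixed`.

## Continuous-trait baseline

The traditional approach the binned method is compared against: each
species is a single value (here, median suitable temperature), and a
Gaussian process on the tree generates tip covariances (unit-rate forms;
t_ij = shared root-to-MRCA time, d_i = tip depth):

* BM: t_ij; parameters σ², root mean μ (k = 2).
* OU: e^(−α(d_i + d_j − 2 t_ij)) (1 − e^(−2α t_ij)) / (2α), root at the
  optimum θ (k = 3). This is the *conditional* (fixed-root) form, chosen
  deliberately: it converges to BM exactly as α → 0, so BM is nested in OU
  and logLik(OU) ≥ logLik(BM) always holds. The stationary form (extra
  σ²/2α root variance) diverges in that limit and breaks nesting; the two
  differ numerically from implementations that use the stationary form.
  Below α·depth ≈ 1e-7 the covariance is evaluated as BM to avoid
  catastrophic cancellation.
* EB: (e^(r t_ij) − 1)/r with decay r ∈ [−10/tree height, 0] (k = 3);
  r → 0 recovers BM.
* trend: BM covariance with mean μ + β·depth (k = 3). On an ultrametric
  tree all tip depths are equal, so β is confounded with μ; the fit warns
  and uses a pseudoinverse. For this reason the demonstration baseline
  fits BM/OU/EB only.

σ² and the mean coefficients are profiled analytically (GLS through a
Cholesky factor of the correlation matrix), leaving at most one shape
parameter (α or r) to optimize; that parameter is searched over three
overlapping sub-windows of its bounded (log-scale for α) range, keeping
the best, because the profile can be flat or multimodal. AIC = 2k −
2 logLik selects among models, exact ties broken toward fewer parameters.

Ancestral estimates are conditional expectations (BLUP) under the fitted
model with the fitted mean plugged in:
x̂_a = m_a + C_at C_tt⁻¹ (x − m_t), SE² = C_aa − C_at C_tt⁻¹ C_ta.
The SE does not propagate uncertainty in the mean or in the fitted
parameters; it is the standard conditional-variance band.

## Virtual-species simulator

The simulator emulates the validation scenario on a synthetic landscape
rather than a real raster:

* **Gradient**: a column-linear temperature field from 10 to 35 °C on a
  100 × 100 grid plus i.i.d. Gaussian noise (sd 0.5 °C). This spans every
  simulated niche with ample margin. It does *not* reproduce the skewed
  value distribution of a real continent, where warm values dominate and
  the hottest cells barely exceed the warm niche's upper limit; on such a
  landscape truncation is predominantly one-sided (warm side), whereas the
  linear gradient makes it two-sided. Conclusions drawn from this
  simulator are therefore qualitative.
* **Accessible areas**: connected regions grown by random accretion
  (4-neighborhood, uniform frontier choice) from a uniform seed cell — a
  stand-in for polygon-based M generation, which published workflows leave
  under-specified. Default M sizes are 100–600 cells, chosen so the
  environmental breadth of an M is comparable to the 4 °C niche breadth;
  this reproduces the regime in which the majority of species have at
  least one truncated niche limit (measured ≈ 69% of realized species),
  which is the premise the method addresses. Ms with no suitable cell are
  discarded and redrawn; on this symmetric gradient a narrow niche band is
  missed often, so the observed discard counts are far higher than on a
  warm-dominated real landscape.
* **Species**: a rectangular fundamental niche (suitable iff
  lower ≤ value ≤ upper); the species occupies *every* suitable cell of
  its M (biotic factors ignored). Its profile is built in values mode from
  occupied and M cell values, and its median suitable value feeds the
  continuous baseline.
* **Tree**: forward birth–death simulation stopped when the extant count
  reaches n, plus a final epoch drawn as the waiting time to the next
  event — exact for pure birth (death 0), which the demonstration uses
  (birth 1, death 0, 15 tips). With extinction, dead lineages are pruned
  and complete extinctions retried. Trees are redrawn until one contains a
  clade of exactly 7 tips; cool-niche species are placed on that clade and
  warm-niche species elsewhere, without replacement.
* **Scale**: the demonstration defaults to 500 species per pool (the
  published design); the acceptance script and tests run 60 per pool and
  25–75 seeds, sizes at which every qualitative result is stable and a
  full multi-seed run takes about a minute.

Everything is a pure function of (config, seed); a single
`numpy.random.Generator` seeded once drives all stages.

## What the validation shows — and does not

Across replicate seeds, ML BAR's modal reconstructed lower suitable bin at
the cool-clade MRCA is 24–25 °C, i.e. the method recovers the simulated
expansion of the ancestral lower limit from 25 to 24 °C; warm-background
nodes keep a 25 °C lower limit. The continuous baseline (OU/BM on tip
medians) estimates the cool-clade ancestor *warmer* than the true cool
midpoint (26 °C) in the large majority of replicates — the documented
failure mode. On individual seeds where most cool tips happen to be
truncated at the cold end, neither discrete method can recover 24 °C; that
is correct inference from the evidence, not a defect.

One published qualitative claim does not reproduce under this simulator:
that parsimony fails to fully recover the shift more often than ML. Here
the two fail equally often (each on the hard seeds described above),
because two-sided truncation on the symmetric gradient creates bins whose
interleaved `?`/`1` tips drive the fitted ER rate to its saturation
plateau — verified to be the global optimum of the likelihood, not an
optimizer artifact — flattening ML marginals at exactly the nodes where
parsimony's ambiguity also bites. On a warm-skewed landscape with
one-sided truncation the asymmetry between the methods plausibly returns;
testing that requires a non-linear gradient, which this simulator
deliberately does not include.

## Known limitations

* Bins are reconstructed independently; the smoothing step is the only
  coupling between them, and no rate is shared or compared across bins.
* No rate estimation, Bayesian reconstruction, or stochastic character
  mapping for the binned characters.
* The real-data path (occurrences + rasters + M polygons → profiles) is
  out of scope; profiles arrive as CSV summaries or value sets.
* GLS standard errors are conditional on the fitted parameters.
* The `?`-as-state convention means a clade of uniformly unknown tips
  reconstructs as unknown — by design, the method never concludes niche
  change without positive evidence.
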