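# Methods

## Model

The forecaster treats one-step prediction of a chaotic system as function
approximation on reconstructed attractors.  A multivariate series
`x_1 .. x_N`, sampled at increment `τ` (default 1), is embedded in all valid
`E`-dimensional delay-coordinate manifolds: each manifold is an ordered set
of `E` distinct `(variable, lag)` coordinates with lags in `0 .. L−1`, at
least one of them unlagged.  The count is `C(NL, E) − C(N(L−1), E)`; the
subtracted term removes the all-lagged combinations, which never see the
current state.  Defaults are `E = 3`, `L = 3`, `τ = 1`, all configurable.

Each manifold is scored by a single-manifold Gaussian RBFN: `p` centers
from k-means on the library's delay vectors, one width `σ` equal to the
mean distance from each center to its nearest neighbour center, and
least-squares read-out weights.  Manifolds are ranked by the Pearson
correlation (MAE optional) between their one-step predictions and the
observations on the in-sample points *outside* the library; fitting and
scoring on disjoint data keeps the ranking from rewarding interpolation-only
manifolds while staying strictly inside the in-sample interval.  Ties are
broken by the canonical (lexicographic) manifold order so the ranking is a
total order.  Degenerate (zero-variance) predictions rank last.

The fused model concatenates the kernel blocks of the top `k` manifolds
columnwise and solves one joint ridge least-squares problem for the weight
vector.  `k` defaults to `N`, the number of observed variables: a larger
`k` piles up hidden units and overfits noisy libraries, a smaller one
discards complementary views.  With `k = 1` the model reduces exactly to
the best single multivariate RBFN.

## Parameters that matter

- **Centers per manifold `p`** (default `min(50, max(2, ⌊G/3⌋))`, `G` =
  number of library delay vectors, capped at the number of distinct
  vectors).  One center per ~3 training points gives the kernel layer
  enough resolution to follow the attractor while keeping each block's
  least-squares problem overdetermined.  The same `p` is used when a
  manifold is ranked and when it sits inside the fused network, so the
  fused basis strictly contains each component's basis.
- **Ridge `λ`** (default 0.1).  Targets are z-scored and kernel entries lie
  in (0, 1], so `λ` is scale-free.  The fused design concatenates `k`
  blocks that describe the same trajectory in overlapping coordinates and
  is therefore strongly collinear and square-ish (`k·p ≈ G`); with a merely
  numerical ridge the joint solve interpolates observation noise and the
  fused model falls below its own `k = 1` submodel.  A modest shrinkage
  restores the intended behaviour — the fused model matching the best
  single manifold on clean data and beating it on short noisy libraries —
  and λ = 0.1 was fixed once after comparing those regimes on the
  simulators.  Set `λ ≈ 0` explicitly to study the pure least-squares
  solution (the solver returns the minimum-norm solution when rank
  deficient).
- **z-scoring** (default on).  Euclidean kernel distances are meaningless
  across variables of different magnitude, so each variable is standardized
  with mean/SD estimated on the library only; forecasts are returned on the
  original scale.  Switchable off for pre-scaled data.
- **Width degeneracies.**  Coincident centers contribute their distance to
  the nearest *distinct* center; a single center falls back to the SD of
  the training vectors' norms (1.0 if even that is zero, e.g. a constant
  series); a fully coincident center set is an error, since the Gaussian
  needs `σ > 0`.
- **k-means** uses greedy (k-means++) seeding, a single initialization and
  a 300-iteration cap, seeded per manifold from `(random_state, manifold
  coordinates)` — content-derived seeding makes a duplicated manifold reuse
  identical centers, which is what makes the `k = 1` fused model coincide
  bitwise with the single-manifold fit.
- **No intercept** in the read-out by default (the autoregressive form has
  none); z-scoring removes the mean anyway.

## Evaluation protocols

*Random-library out-of-sample*: 3000 generated samples; the first 500 are
discarded as transient, times 501–2000 are the in-sample portion,
2001–2500 are deliberately never used (the forecaster must not need the
most recent history), and 2501–3000 are the test set.  Libraries of length
25/50/75/100 start at uniform random positions such that they fit inside
the in-sample interval; each library's model predicts every usable test
time, and skills (correlation, MAE) are aggregated over libraries with
quartiles.  Zero-variance correlation is recorded as 0 with a `degenerate`
flag rather than dropped, keeping aggregates over many libraries
well-defined; per-library failures are recorded with their error message.

*Pseudo-out-of-sample* (for short real series): expanding-window one-step
cross-validation — the first 3/4 of the series is the initial training
window, and each test point is forecast from a model refitted on all data
through the preceding time.  A cheaper weights-only refit mode keeps the
hidden layer of the first fit and re-solves only the read-out.

## Simulated study systems

All simulators are deterministic and run in chaotic regimes; noise is
purely observational (added to the finished trajectory, per-variable SD =
`level ×` that variable's noise-free SD, seeded) and never fed back into
the dynamics.

- **Three-species coupled logistic** (default benchmark): logistic maps
  with growth rates (3.78, 3.71, 3.75) coupled in a ring (x←z, y←x, z←y,
  strength 0.2).  Ring coupling makes every variable strongly driven by
  another — the interconnected regime in which multivariate embeddings
  carry information a univariate reconstruction cannot reach.  The
  condition `r(1 − r/4) > c·max(other)` guarantees trajectories stay in
  (0, 1); boundedness and aperiodicity were additionally verified over ten
  random initial states.
- **Hastings–Powell food chain**: the classic tri-trophic continuous-time
  chain at its standard chaotic parameters (a1=5, b1=3, a2=0.1, b2=2,
  d1=0.4, d2=0.01), integrated with RK45 at tight tolerances (rtol 1e−9,
  atol 1e−12, capped internal step) and sampled at τ = 1.
- **LPA flour beetle**: the larvae–pupae–adult map at the chaotic
  treatment parameterization (b=10.45, c_EL=0.01731, c_EA=0.01310,
  c_PA=0.35, μ_L=0.2, μ_A=0.96); zero population is absorbing.
- **Five-species web**: five ring-coupled logistic maps (coupling 0.15),
  same construction and guarantees as the three-species system.

What the generators emulate is the structure of the benchmark problem —
bounded chaotic dynamics, strong interspecific forcing, observational
noise, 3000-sample records.  What they do not emulate: process noise,
irregular or missing sampling, observation functions other than identity
plus Gaussian noise, and non-stationarity.  Passing tests therefore show
that the method recovers interconnected deterministic dynamics from short
noisy windows, not that it handles arbitrary field data.

## Numerical choices and scale of the shipped experiments

Least squares uses LAPACK's rank-revealing `gelsd` (minimum-norm on rank
deficiency); ridge solves go through the equivalent augmented system.
Nearest-neighbour ties in MVE resolve to the earliest library time.  MVE
keeps `⌈√m⌉` views with one neighbour each, both configurable, and its
forecasts are unweighted means of observed library targets, hence always
inside the library's target range.

The test suite and the bundled experiments run the evaluation protocols at
desk scale — 20 random libraries per condition rather than 100 — which
leaves the trends (skill rising with library length, error rising with
noise, fused ≥ univariate on short noisy libraries) clearly resolved; the
CLI default remains 100 libraries.  Trend assertions allow one standard
error of the later condition, since 20-library means retain sampling
noise.

## Known limitations

- Ranking refits every manifold per library; with N = 5 variables there
  are already 335 manifolds, and cost grows combinatorially with N and L.
- The width heuristic can produce overly narrow kernels when many centers
  crowd a low-dimensional manifold; for 1-D systems use a small explicit
  `n_centers`.
- Forecasting is strictly one-step; iterated multi-step forecasting and
  automatic selection of `E` (e.g. false-nearest-neighbours) are out of
  scope.
- The continuous-time food chain is sampled at τ = 1, which under-resolves
  its slow oscillations; it exercises the I/O and evaluation contracts
  rather than providing a high-skill benchmark.
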