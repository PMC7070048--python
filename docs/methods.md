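# Methods

## Model

The universal opportunity (UO) model describes destination choice as a
benefit-ranking process. Every opportunity carries an i.i.d. random
benefit *z* from a continuous distribution *p*(*z*). A traveller at zone
*i* evaluating destination *j* compares three blocks of opportunities:
the *m<sub>i</sub>* at the origin, the *m<sub>j</sub>* at the
destination, and the intervening mass *s<sub>ij</sub>* (opportunities at
zones strictly closer to *i* than *j* is; the origin and destination
themselves are never counted). Weighting the exploratory comparison
(destination beats origin *and* intervening mass) by α and the cautious
one (destination beats origin, origin beats intervening mass) by β, the
probability that *j* wins the comparison is

    Q_ij = ∫ Pr_{m_i + α·s_ij}(z) · Pr_{β·s_ij}(<z) · Pr_{m_j}(>z) dz ,

where Pr<sub>x</sub>(·) refers to the maximum of *x* benefit samplings.
Substituting u = p(<z) collapses the integral to a Beta-type form with
the closed-form solution

    Q_ij = (m_i + α·s_ij)·m_j / [(m_i + (α+β)·s_ij)·(m_i + (α+β)·s_ij + m_j)] ,

independent of the benefit distribution. Choice probabilities are
`P_ij = Q_ij / Σ_{k≠i} Q_ik` and predicted fluxes `T_ij = O_i·P_ij`.
Exponents such as `m_i + α·s_ij` are treated as arbitrary non-negative
reals: the closed form is well defined there, and fitted (α, β) are
continuous, so the integer "number of samplings" reading is not enforced.

At the simplex corners the weight simplifies *exactly* (the numerator
factor cancels one denominator factor) to the radiation model (α=0, β=1),
the opportunity-priority-selection model (α=1, β=0) and the
opportunity-only model (α=0, β=0); probability matrices coincide to
machine precision, which the test suite asserts at 1e−12.

### Assumptions

- One representative agent per origin; no heterogeneity across travellers.
- Zones are points (centroids); intervening mass is defined by
  centroid-to-centroid distance, euclidean (planar) or haversine
  (lon/lat, R = 6371 km).
- Self-flows are undefined: `P_ii = T_ii = 0` everywhere, and the
  similarity index sums over ordered pairs i ≠ j only.
- Trip productions O_i are exogenous (production-constrained model).

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| α | exploratory tendency | dimensionless, α ≥ 0 | fitted |
| β | cautious tendency | dimensionless, β ≥ 0, α+β ≤ 1 | fitted |
| `grid_step` | simplex grid spacing for fitting | — | 0.05 (231 points) |
| `metric` | `euclidean` or `haversine` | — | `euclidean` |
| `tie_policy` | equidistant third zones in s_ij | — | `strict` |
| `ssi_policy` | both-zero pairs in the SSI | — | `exclude` |

**Tie policy.** The defining phrase for s_ij is "strictly closer", so the
default counts nothing for an equidistant third zone. On lattices exact
ties are common, so a `half` policy (tied zones contribute half their
mass) is exposed for robustness; generation and fitting must use the same
policy, and all shipped experiments use `strict`.

**Degenerate denominators.** When `m_i + (α+β)·s_ij = 0` the numerator
factor `m_i + α·s_ij` vanishes too; the ratio is taken at its continuity
limit 1 (the limit as m_i → 0), giving `Q_ij = m_j/(m_i+(α+β)s_ij+m_j)`.
A destination with m_j = 0 always has zero weight. An origin whose entire
weight row is zero raises an error if it has positive outflow, otherwise
the row stays zero and a warning is logged — silent NaNs are worse than a
loud failure.

## Metrics

**Sørensen similarity index.** `SSI = mean of 2·min(T,T′)/(T+T′)` over
ordered pairs i ≠ j. The default `exclude` policy removes pairs with zero
flux in both matrices from numerator and denominator, so identity gives
exactly 1 and disjoint supports give exactly 0 — the two boundary
statements the index is defined by. The `literal` policy divides by
N(N−1) regardless. The two coincide whenever every pair carries flux in
at least one matrix.

**RMSE** is computed over all ordered pairs i ≠ j, structural zeros
included.

**Normalized entropy.** Defined per origin as
`E_i = −Σ_{j≠i} p_ij·log p_ij / log(N−1)` with `0·log 0 := 0`, so
E_i ∈ [0, 1] with 0 a degenerate choice and 1 a uniform one. The
normaliser is log(N−1) because self-choice is excluded: it is the maximum
achievable entropy, which is what makes the quantity "normalized". With
N = 2 the normaliser vanishes; the only valid row (single destination,
p = 1) is defined as E = 1.

**Average travel distance** is `Σ_j P_ij·d_ij` per origin; sweeps report
the unweighted landscape mean (both aggregations are exposed, since
either reading of "average" is defensible).

## Fitting

The SSI surface over the simplex is non-smooth, so fitting is an
exhaustive evaluation of every grid point (default step 0.05, i.e. 231
points), not a continuous optimisation. Evaluations are independent
across grid points; order never matters. Ties within 1e−12 of the best
objective are broken toward the smallest α, then smallest β, and the full
tie list is reported. When the landscape carries no outflows, observed
row sums are used as trip productions — the convention under which a
perfect model attains SSI = 1.

**Objective choice for parameter recovery.** Both `ssi` and `neg_rmse`
objectives are supported. For recovery experiments on sampled trips the
RMSE objective is the right estimator: its expectation is minimised at
the generating parameters regardless of sampling noise, and in the
shipped experiment (15×15 random lattice, 1000 trips/origin, grid step
0.05, 10 seeds) it recovers the truth to within one grid step. The SSI
objective carries a finite-sample bias when the observed matrix is sparse
(≈ 4.5 trips per pair here): its argmax sits ≈ 0.15 away from the truth
at this sampling density, vanishing as trips/origin grows (exact by
100 000). SSI remains the appropriate objective for scoring against
dense empirical matrices, where it is customary.

## Synthetic data

`make_grid_landscape` builds a regular nx×ny lattice (default 15×15,
spacing 1) with either uniform opportunities (m = 100) or i.i.d. uniform
draws on [50, 150]. These sizes make the behavioural surfaces show their
structure clearly while keeping a full 231-point sweep under a second;
the qualitative corner ordering asserted by the tests — mean distance and
entropy minimal at (0, 1), maximal at (0, 0), with the (1, 0) corner in
between — is robust to these choices. `sample_trips` draws each origin's
destinations i.i.d. multinomially from P, so row sums equal
trips/origin exactly. All randomness flows through explicit
`numpy.random.default_rng` seeds; there is no hidden global state.

What the generator does *not* emulate: heavy-tailed city-size
distributions, spatially correlated opportunity fields, irregular zone
geometries, network (road/rail) travel costs, day-to-day variability and
origin-level heterogeneity of real travellers. Passing the recovery and
ordering tests therefore demonstrates internal consistency of model,
sampler and fitter — not predictive validity on empirical OD data, which
must be established per data set.

## Numerical choices

- Algebraic identities are asserted at absolute tolerance 1e−12;
  quadrature agreement at 1e−6.
- The benefit-integral check integrates over the benefit axis *z* using
  the supplied distribution's CDF/PDF with composite Gauss–Legendre
  panels whose breakpoints are quantiles of the distribution (large
  exponents push the integrand's mass into the upper tail, and
  quantile-spaced panels track it). Integrating in *z* rather than after
  the u = F(z) substitution keeps the distribution-freeness check
  genuine. The oracle requires `m_i + (α+β)s > 0`; the closed form owns
  the degenerate limit.
- Grid membership uses a 1e−9 simplex tolerance so steps that do not
  divide 1 exactly (and accumulated float error at α+β = 1) behave.
- CSV output uses 10 significant digits, enough for byte-stable
  round-trips without bloating files.

## Limitations

- Exhaustive search scales linearly in grid points and quadratically in
  zones per point; for very large zone systems (≫10³ zones) the O(n³)
  intervening-opportunity construction dominates and would need a
  sorted-cumulative-sum implementation.
- The SSI small-sample bias above means fitted (α, β) from sparse
  matrices should be read with a grid-step-scale uncertainty in mind.
- No support for polygon zones, network distances, gravity-model
  baselines or cost-based radiation variants.
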