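# uniopp

Universal opportunity models for origin–destination (OD) flow prediction.

`uniopp` implements a two-parameter intervening-opportunities model of
destination choice for human-mobility and spatial-interaction analysis —
the kind of mobility kernel that feeds metapopulation epidemic models,
commuting studies and accessibility work. It is aimed at researchers who
have a zone system (centroids plus an "opportunity" count per zone, e.g.
jobs or POIs) and an observed OD trip matrix, and who want a parsimonious,
interpretable destination-choice model fitted to it.

## The model

A traveller at zone *i* samples a random benefit *z* for every opportunity
and compares the best benefit of a candidate destination *j* against the
best of the origin and of the *intervening opportunities*
*s<sub>ij</sub>* — the total opportunity mass strictly closer to *i* than
*j* is. Two weights on the unit simplex (α ≥ 0, β ≥ 0, α + β ≤ 1) encode
behaviour:

- **α — exploratory tendency**: the destination must beat the origin *and*
  all intervening opportunities (favours distant, high-benefit zones);
- **β — cautious tendency**: the destination must beat the origin while
  the origin already beats the intervening opportunities (favours near
  zones).

Integrating over the benefit distribution gives a closed-form selection
weight, independent of that distribution:

```
Q_ij = (m_i + α·s_ij) · m_j
       ─────────────────────────────────────────────────
       (m_i + (α+β)·s_ij) · (m_i + (α+β)·s_ij + m_j)
```

Choice probabilities are row-normalised, `P_ij = Q_ij / Σ_k Q_ik`, and
predicted fluxes are `T_ij = O_i · P_ij` given each origin's trip
production *O<sub>i</sub>*. The simplex corners recover three classic
models exactly: **radiation** (α=0, β=1), **opportunity priority
selection** (α=1, β=0) and **opportunity only** (α=0, β=0).

Fitting is an exhaustive grid search over the (α, β) simplex, scoring each
candidate against the observed matrix with the Sørensen similarity index
(SSI) or RMSE. Diagnostics include per-origin normalized entropy of the
choice distribution and average travel distance.

## Worked example

Generate a 15×15 lattice of zones with random opportunity counts, sample
1000 trips per origin from a ground-truth model at (α, β) = (0.3, 0.4),
and fit the model back by grid search:

```python
import uniopp as up

land  = up.make_grid_landscape(up.LandscapeSpec(nx=15, ny=15,
                                                opportunity_mode="random",
                                                seed=42))
t_obs = up.sample_trips(land, up.ModelParams(0.3, 0.4),
                        trips_per_origin=1000, seed=42)

model = up.UniversalOpportunityModel(t_obs, land)
res   = model.fit(grid_step=0.05, objective="neg_rmse")
print(res.summary())
```

```
Universal Opportunity Model Results
===========================================
No. zones:                  225
Observed trips:             225000
Objective:                  neg_rmse
Grid step:                  0.05
Grid points:                231
-------------------------------------------
alpha (exploratory):        0.3000
beta (cautious):            0.4000
Best score:                 -2.050063
SSI at optimum:             0.567712
RMSE at optimum:            2.050063
===========================================
```

The generating parameters are recovered exactly at the grid resolution:
the sample is moderately exploratory (α = 0.3) and cautious (β = 0.4).
The RMSE of ≈ 2.05 trips per zone pair is the residual multinomial
sampling noise (≈ 4.4 trips per pair on average); the SSI of ≈ 0.57
reflects the sparsity of a 1000-trip sample spread over 224 destinations,
not model error — against the *expected* fluxes the fitted model is
exact. `res.diagnostics()` adds per-zone entropy (mean 0.736) and average
travel distance (mean 3.11 lattice units).

The same workflows are available from the shell:

```bash
uniopp make-landscape --nx 15 --ny 15 --mode random --seed 42 --out zones.csv
uniopp simulate --zones zones.csv --alpha 0.3 --beta 0.4 --seed 42 --out od.csv
uniopp fit --zones zones.csv --observed od.csv --objective neg_rmse \
           --out-json fit.json --out-surface surface.tsv
uniopp score --zones zones.csv --observed od.csv --predicted od.csv
```

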