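# habitatshift

Land-cover transition accounting and Monte Carlo propagation of
habitat-resource change for the migratory corridor of the eastern monarch
butterfly (*Danaus plexippus*) through northern Mexico and Texas — plus
the seasonal climate/greenness trend tests used to assess habitat quality.

The eastern monarch population passes through this corridor twice a year:
southbound in fall, when adults depend on nectar to build the fat reserves
that carry them through overwintering, and northbound in spring, when
females need both nectar and milkweed (*Asclepias*, the larval host
plant). Whether land-use change in this corridor has eroded those
resources is a standing question in monarch conservation. This package
implements the full estimation pipeline for answering it from categorical
land-cover products, expert elicitation, and field plot surveys, for
ecologists and conservation analysts working with similar area-based
resource models.

## What it computes

**Change accounting** (`habitatshift.change`). From paired categorical
rasters (or published area tables), the transition matrix
`A[i][j]` = area moving from class *i* to class *j*, and per-class
statistics with the standard identities

    net = gain − loss = end − start,  gross = gain + loss,
    annual = net / Δt,  % total = 100 · net / start,

including per-zone (county/municipality) summaries that sum exactly to the
extent-wide matrix.

**Resource distributions** (`habitatshift.resources`). Every land-cover
class *c* gets a seasonal resource distribution `V_c`:

* nectar — a unitless 0–1 suitability score, normal across expert
  respondents on a 5-level rating scale (0.10/0.25/0.5/0.75/0.95),
  translated between classification legends with agreement-matrix
  weighted averages of the mean and SD;
* milkweed — plants/ha, the AIC-best of exponential, negative binomial,
  zero-inflated Poisson and presence-only candidates fitted by maximum
  likelihood to plot counts dominated by zeros (60–91% per class), with
  special rules for sparse classes (forced zeros; parameter midpoints).

**Monte Carlo propagation** (`habitatshift.montecarlo`). Each replicate
draws one value per class, forms the extent totals
`T(t) = Σ_c a_c(t) · v_c` for both dates (×100 ha/km² for densities),
and differences them; 5,000 replicates give the mean and the Monte Carlo
standard error SE = SD/√n of the change and percent change. A closed-form
expectation `Σ_c a_c · E[V_c]` is the built-in oracle, and zone-level
changes can be rescaled across regions by z-scoring against a reference
region's mean and SD.

**Trend tests** (`habitatshift.trends`). Seasonal (Mar–May, Sep–Nov)
per-pixel median composites, extent medians, and OLS fits of value on
year with the two-sided t test on n − 2 df.

**Synthetic data** (`habitatshift.synthetic`) generates every input with
known ground truth (Markov landscape pairs, rating-scale surveys,
zero-inflated plot counts, trending observation stacks, agreement
matrices), so the whole pipeline runs and is tested without any download.

## Worked example

```python
from habitatshift import published_change_summary, published_resource_change

change = published_change_summary("texas")
print(change.loc[["Pasture", "Shrubland", "Dev. Med"],
                 ["net", "gross", "annual", "percent_total"]].round(2))

exp, mc = published_resource_change("texas", "milkweed", "spring",
                                    n_reps=5000, seed=0)
pct, _, pct_se = mc.summary["percent_change_of_totals"]
print(f"2001 stock: {mc.summary['total_t0'][0] / 1e9:.2f} billion plants")
print(f"change 2001-2019: {pct:.2f}% (MC SE {pct_se:.2f})")
print(f"analytic expectation: {exp['percent_change']:.2f}%")
```

prints

```
              net    gross  annual  percent_total
class
Pasture   -5343.0   6407.0 -296.83          -7.32
Shrubland  -353.0  15671.0  -19.61          -0.18
Dev. Med   2749.0   2819.0  152.72          51.12
2001 stock: 1.00 billion plants
change 2001-2019: -2.85% (MC SE 0.07)
analytic expectation: -2.92%
```

Pasture/hay lost the most area in Texas (−7.3%) while medium-intensity
development grew by half; propagated through the per-class milkweed
densities, the state-wide milkweed stock of about a billion plants in
2001 declined roughly 2.9% by 2019. The Monte Carlo mean sits within its
standard error of the closed-form expectation, as it must.

The numbered drivers under `analysis/` run the full story on bundled and
synthetic inputs (`01_simulate_inputs.py` → … → `05_climate_trends.py`),
writing their tables under `results/`. The `habitatshift` console script
exposes each stage (`habitatshift change --region mexico …`,
`habitatshift mc …`, `habitatshift trend …`, `habitatshift simulate …`).

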