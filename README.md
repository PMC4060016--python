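# stepwise-impact

A step-wise landscape model of the impact of an invasive social wasp — the
Asian paper wasp (*Polistes chinensis antennalis*) in New Zealand — that
chains four stages into a per-pixel map of predation pressure:

1. **Where can it live?** A bias-corrected presence-only species distribution
   model (maximum-entropy-style) on 500 m environmental rasters.
2. **How dense is it there?** Nest density and occupancy per land-cover class
   from 10 × 10 m field plots.
3. **How many nests nationally?** Extrapolation of class-specific estimates
   over the suitable area.
4. **What does it eat?** A foraging-intensity model (prey per nest per
   sunshine hour) turning nests into a seasonal prey-consumption raster.

The package is aimed at spatial ecologists who want a transparent,
fully-testable reimplementation of this impact-budget workflow. Because the
original environmental and survey rasters are not redistributable, a
synthetic-landscape generator with known ground truth stands in for them:
every stage can be exercised, and its estimators validated, end to end.

## The model

**Distribution.** With presence cells $i$ and background cells $j$ carrying
standardized features $f$ (linear + quadratic in elevation, degree days base
10 °C, rainfall, solar radiation, annual max/min temperature), coefficients
$\beta$ maximize the penalized presence/background log-likelihood

$$\frac{1}{n_p}\sum_i \beta\cdot f_i \;-\; \log\sum_j e^{\beta\cdot f_j} \;-\; \lambda\lVert\beta\rVert_1 .$$

Sampling bias in the occurrence records is absorbed by weighting the
background sample with a quartic-kernel density grid of the occurrences,
$K(d) = \tfrac{3}{\pi h^2}(1-(d/h)^2)^2$ for $d \le h$. An ensemble of 50
fits on random 75/25 train/test splits yields a mean test AUC and the mean
10% minimum-training-presence threshold that binarizes suitability.

**Density.** Per class $c$: density $D_c = \mathrm{round}(100\,n_{\text{nests}}/n_{\text{plots}})$
nests/ha and occupancy $\psi_c$ (fraction of plots with ≥ 1 nest, 2 dp);
unsurveyed low-preference classes get nominal $(D, \psi) = (3, 0.03)$.
Classes are compared with a tie-corrected Kruskal–Wallis test.

**Extrapolation.** With suitable area $A_c$:
occupied ha $= \lfloor A_c\psi_c\rfloor$, nests $= \lfloor A_c\psi_c D_c\rfloor$,
summed over classes.

**Impact.** Foraging success $F = 60\,r\,m\,q$ prey · nest⁻¹ · h⁻¹ from the
forager return rate $r$, material fraction $m$ and prey fraction $q$;
seasonal foraging time = bright-sunshine hours (radiation ≥ 0.432 MJ m⁻² h⁻¹)
over February–April. Per cell: prey $=$ (25 ha · $\psi_c D_c$) · $F$ · hours.

## Worked example

`python examples/04_impact_budget.py` prints:

```
prey fraction: mean 0.75, range (0.7, 0.8) (one outlier excluded)
foraging success rate: 4.455 prey/nest/hour (reported 4.5; range 2.4-8.4)
seasonal bright-sunshine hours: mean 540 h (range 240-757)

national prey budget: 1,568,118 nests x 4.5 prey/nest/h x 540 h = 3.81 billion prey per season
```

That is, ~1.57 million nests each capturing 4.5 prey per daylight-foraging
hour over a ~540-hour season consume 3–4 billion invertebrate prey items.
The other examples cover landscape simulation (`01`), the distribution model
(`02` — a 50-run ensemble on a biased synthetic landscape, mean test AUC
≈ 0.85), density estimation and the national extrapolation table (`03` —
92,642 occupied ha, 1,568,118 nests), and the full pipeline (`05`).

A thin CLI drives the same stages from the shell:

```sh
stepwise-impact run --seed 1 --out artifacts        # all stages
stepwise-impact sdm --config my.yaml --out artifacts
```

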