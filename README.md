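# slidenorm

Slide-to-slide normalization and evaluation for multiplexed immunofluorescence
(MxIF) cell intensities.

Multiplexed imaging quantifies dozens of protein markers per segmented cell,
but every physical slide carries its own staining and optical conditions.
This *slide effect* shifts and rescales whole intensity distributions, so a
"CD3-positive" cell on one slide may be indistinguishable from background on
another. `slidenorm` is for analysts working with cell-level quantification
tables (one row per cell: slide ID, marker intensities, optional tissue/marker
labels) who need to remove this technical variation before phenotyping or
spatial analysis — and to *measure* how much of it was removed.

## What it implements

**Transformations** of the raw integer median-cell intensities `y`, per slide
`i` and channel `c` with slide mean `μ_ic`:

| name | formula |
|---|---|
| log10 | `log10(y + 1)` |
| mean division | `y / μ_ic` |
| mean division log10 | `log10(y / μ_ic + 1/2)` |

**ComBat normalization** — an empirical-Bayes location-scale model adapted to
slides as batches:

```
Y_ic(u) = α_c + γ_ic + δ_ic ε_ic(u),   γ_ic ~ N(γ̄_c, τ̄²_c),  δ²_ic ~ IG(ω̄_c, β̄_c)
```

The channel is standardized (`Z = (Y − α̂_c)/σ̂_c`), hyperparameters are
moment-matched, per-slide mean/variance effects are shrunk by an iterative EB
fixed point, and the data are adjusted:
`Y* = (σ̂_c/δ̂*_ic)(Z − γ̂*_ic) + α̂_c`. Zeros are kept as data throughout.

**Density registration** — each slide's histogram is smoothed with a
21-function cubic B-spline basis; a strictly monotone 2-parameter warp
`ϕ(x) = C₀ + C₁ ∫ exp{β₁h₁(y) + β₂h₂(y)} dy` is fitted to align the slide's
density with the cross-slide average, and intensities are transported through
the warp.

**Evaluation framework** — k-sample Anderson–Darling alignment statistic
(midrank ties), Otsu threshold discordance across slides, marker-positive
accuracy against manual labels, slide-level variance proportions from a REML
random-intercept model, and UMAP + k-means adjusted-Rand-index label recovery;
aggregated into a one-row-per-method report.

**Synthetic data** — a generator with known slide mean/variance effects,
tissue-class structure and marker-positive mixtures, so every normalizer and
metric is testable without external data.

## Worked example

```python
from slidenorm import (SimConfig, simulate_table, apply_transform,
                       combat_normalize, variance_proportion)

table, truth = simulate_table(SimConfig(n_slides=20, cells_per_slide=1000,
                                        tau=0.5, seed=5))
logt = apply_transform(table, "log10")
adjusted, fits = combat_normalize(logt)

fit = fits["vimentin"]
before = variance_proportion(logt.intensities("vimentin"), logt.data["slide_id"])
after = variance_proportion(adjusted.intensities("vimentin"), adjusted.data["slide_id"])
```

Running this (it is `examples/03_combat_normalization.py`) prints:

```
vimentin: 3 EB iterations, converged=True
hyperparameters: gamma_bar=-0.0000, tau2_bar=0.2328, omega_bar=246.64, beta_bar=245.88
correlation of fitted slide effects with injected truth: 0.998
slide variance proportion: 0.188 before ComBat, 0.000000 after
```

Reading: 18.8% of the log-intensity variance was attributable to which slide a
cell sat on; the fitted per-slide effects match the effects the simulator
injected almost perfectly (r = 0.998), and after adjustment the slide-level
share of variance is zero — ComBat removes slide variation by construction.
The other scripts in `examples/` walk through simulation, the three
transformations, density registration (watch the Anderson–Darling statistic
drop), and the full method-comparison report.

A thin CLI covers the same workflow from a shell:

```bash
slidenorm simulate --slides 20 --cells 2000 --seed 1 --out cells.csv
slidenorm normalize --input cells.csv --out norm.csv --transform mean_divide --method combat
slidenorm evaluate --raw cells.csv --normalized norm.csv --out report
```

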