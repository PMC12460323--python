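# spatioepi

Spatial–temporal heterogeneity analysis for areal disease-incidence panels.

Epidemiologists studying chronic-disease burden at the level of states,
provinces, or districts routinely ask four questions of a unit × year
incidence panel: Is incidence spatially clustered? *Where* are the
persistent hot and cold spots? *Which* covariates (pollution, diet,
socioeconomic factors, …) explain the spatial pattern, alone and in
combination? And how do those effects *drift* over space and time?
`spatioepi` answers all four with a single tested toolchain:

* **Global Moran's I** — I = (N/S₀)·Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², with
  randomization-assumption inference and a permutation test; clustering is
  flagged at z > 2.58 (99% confidence).
* **Getis-Ord Gi\*** — self-inclusive local z-scores, binned hot/cold at the
  90/95/99% thresholds (1.645/1.960/2.576), plus persistence summaries
  across five-year windows.
* **GeoDetector** — the factor detector q = 1 − SSW/SST with noncentral-F
  significance, optimal discretization search (equal interval, geometric,
  natural breaks, quantile), pairwise interaction classification
  (bilinear/nonlinear enhancement, weakening, independence), and a
  10%-perturbation sensitivity analysis of the q values.
* **GTNNWR** — a geographically and temporally weighted neural-network
  regression: a proximity network fuses spatial and temporal distances, a
  weight network turns them into per-coefficient weights wᵢ, and the
  prediction ŷᵢ = Σₖ wᵢₖ βₖᴼᴸˢ xᵢₖ yields interpretable local coefficient
  surfaces βᵢₖ = wᵢₖ βₖᴼᴸˢ that vary over space and time.

A synthetic-data module generates panels with *known* ground truth —
SAR-clustered fields, covariates with exact stratified explanatory power,
and spatiotemporally drifting coefficients — so every stage is validated
end-to-end without any external data. See `docs/methods.md` for the full
model descriptions, defaults, and limitations.

## Worked example

```python
import numpy as np
from spatioepi.synthetic import make_grid_weights, simulate_sar_field, \
    simulate_nonstationary_panel
from spatioepi.autocorr import global_morans_i, getis_ord_gistar
from spatioepi.geodetector import factor_screen

W = make_grid_weights(6, 8)                      # 48-unit lattice
field = simulate_sar_field(W, rho=0.8, seed=1)   # strongly clustered surface
m = global_morans_i(field, W)
print(f"Moran's I = {m.I:.4f}, z = {m.z:.2f}, significant: {m.significant}")

g = getis_ord_gistar(field, W)
from collections import Counter
print("Gi* bins:", dict(Counter(g.bin)))

panel, truth = simulate_nonstationary_panel(seed=7, noise_sd=0.5)
table = factor_screen(panel, class_range=(3, 6))
print(table[table["window"] == "overall"][["factor", "q", "p", "rank"]]
      .to_string(index=False))
```

prints

```
Moran's I = 0.5388, z = 5.26, significant: True
Gi* bins: {'ns': 35, 'hot90': 1, 'hot95': 2, 'cold95': 3, 'hot99': 3, 'cold99': 3, 'cold90': 1}
factor        q        p  rank
    b1 0.668204 0.000867     1
    b2 0.490347 0.085892     2
```

The SAR field with ρ = 0.8 shows strong positive autocorrelation (I = 0.54,
z well above the 2.58 clustering threshold), Gi* classifies a handful of
units as 99%-confidence hot/cold spots, and the factor detector ranks the
covariate with the stronger (and more heterogeneous) planted coefficient
first with a significant q.

## Command line

```sh
spatioepi simulate -o demo_inputs --seed 1     # panel.csv + weights.gal + truth.json
spatioepi moran demo_inputs/panel.csv demo_inputs/weights.gal --per bin
spatioepi run -c config.yaml                   # full four-stage pipeline
```

`spatioepi run` writes Moran series, Gi* bins and persistence, GeoDetector
factor/interaction/sensitivity tables, GTNNWR metrics and coefficient
summaries, a manifest, and a run log into the configured output directory.
`spatioepi.demo.write_demo(dir)` emits a ready-to-run synthetic config.

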