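# alderhydro

Can ring widths of lakeshore black alder (*Alnus glutinosa*) be used to
reconstruct lake-level fluctuations?  `alderhydro` implements the complete
analysis chain needed to ask that question for a set of temperate-humid
lowland lakes, and a synthetic-data generator that emulates the study
setting (three lakes, ~20 riparian alders per shore, short gauging
records), so the whole pipeline is testable end to end without any field
data.

The chain, aimed at dendroecologists and ecohydrologists:

1. **Chronology building** — per-tree core averaging; cubic-smoothing-spline
   detrending with a 50% frequency cutoff at 30 years (RWI = TRW/fit);
   horizontal standardization (RWI = TRW/mean) that keeps all low
   frequencies; Tukey biweight site master chronologies; the quality
   statistics RBAR (mean inter-series correlation), MS (mean sensitivity,
   2|x_t − x_{t−1}|/(x_t + x_{t−1})), AC (lag-1 autocorrelation) and the
   expressed population signal EPS = n·r̄ / (n·r̄ + 1 − r̄), including a
   30-year running EPS.
2. **Drought indexing** — Thornthwaite PET, the climatic water balance
   D = P − PET, and SPEI at accumulation scales k ∈ {6, 12, 24, 36, 48,
   60, 72} months: for each calendar month a three-parameter log-logistic
   is fitted to the k-month sums by probability-weighted moments and
   SPEI = Φ⁻¹(F(x)).  All hydrological variables aggregate over *water
   years* (October of the previous to September of the current year).
3. **Common-signal analysis** — correlation-matrix PCA over the detrended
   tree series (trees as variables, years as observations); monthly
   correlation functions of PC scores with temperature, precipitation and
   SPEI₆ from previous May to current September; cross-site chronology
   correlations.
4. **Reconstruction** — OLS models of water-year lake/groundwater level on
   RWI_t, RWI_{t+1}, RWI_t + RWI_{t+1} or a single water-year SPEI_k,
   selected by calibration R²; reconstructions only where the chronology
   has ≥ 10 trees and running EPS ≥ 0.85; split-sample verification
   (holdout R², reduction of error).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate.py`, then `02`…`05`).  A compact
in-code version for one site:

```python
from alderhydro.pipeline import (RECON_SCALES, build_site_chronologies,
                                 reconstruct_site, spei_suite)
from alderhydro.synthetic_data import (SyntheticConfig, observed_gauge_record,
                                       simulate_site)

cfg = SyntheticConfig()                      # the emulated study conditions
climate, lake, trees = simulate_site(cfg, site_index=0)
site = build_site_chronologies(trees)        # detrended + standardized masters
spei = spei_suite(climate, cfg.latitude_deg, scales=RECON_SCALES)
res = reconstruct_site(site.chron_standardized, spei,
                       observed_gauge_record(lake, cfg))
print(res.window.first_year, res.window.last_year)
print(res.best_rwi.predictors, round(res.best_rwi.r2, 2))
print(res.best_spei.predictors, round(res.best_spei.r2, 2))
```

prints

```
1916 2009
('rwi_t', 'rwi_t1') 0.34
('spei_24',) 0.78
```

meaning: the chronology passes both reliability gates from 1916 to 2009;
the best tree-ring model explains 34% of the observed water-year
lake-level variance over the 40-year gauge record, while a single
24-month SPEI predictor explains 78%.  Running all three sites
(`analysis/05_reconstruct.py`) shows the same contrast everywhere
(RWI R² 0.12–0.34 vs SPEI R² 0.60–0.78), and `analysis/04_common_signal.py`
shows near-zero cross-site chronology correlations with site-separating
PC2 loadings: the stands carry a strong *local* common signal that is only
loosely coupled to lake level — which is exactly why tree-ring-based
lake-level reconstruction is hard here.

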