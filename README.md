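# windforay

Weather-driven analysis of nonroutine movements in GPS-tracked soaring
birds.

Griffon Vultures (*Gyps fulvus*) are central-place foragers: most GPS
fixes fall inside a colony-centred home range, but birds occasionally
leave it — briefly (medium-range movements, MRM) or for long,
potentially wind-driven displacements (long-range movements, LRM).
`windforay` implements the full inference chain that links hourly
weather to these movement types:

1. **Screening** — drop implausible fixes more than 5 km offshore and
   individuals tracked for less than 300 days;
2. **Home range** — a per-individual utilization distribution (UD) from
   an autocorrelation-aware weighted kernel density estimate, and its
   95% isopleth polygon;
3. **Excursion segmentation** — contiguous runs of fixes outside the
   isopleth become excursion tracks, each summarised by five metrics:
   median step length, median heading, maximum distance from the home
   range, duration, and straightness index;
4. **Movement-type clustering** — exact Partitioning Around Medoids
   (k = 2) over the standardized metrics splits tracks into MRM and LRM,
   with silhouette / elbow / gap-statistic diagnostics;
5. **Weather annotation** — each fix joins its nearest ERA5-like grid
   cell and hour; wind speed `W = 3.6·√(u² + v²)` km/h and
   meteorological direction `ψ = (atan2(u, v)·180/π + 180) mod 360`
   (the bearing the wind blows *from*);
6. **Ordered-categorical additive model** — with fix type
   y ∈ {SRM < MRM < LRM},

       P(y ≤ k | x) = logistic(θ_k − η(x)),
       η = f(ψ) + f(W) + f(R_s) + f(doy) + te(ψ, W) + … + b_individual,

   cyclic cubic splines for periodic covariates, curvature-penalized
   cubic splines otherwise, a direction × strength tensor product, and
   i.i.d. Gaussian random intercepts, fitted by penalized Newton
   iteration with AIC-based smoothing-parameter selection;
7. **Duration model** — a Gamma GLMM with log link for LRM duration,
   `log E[T] = β₀ + β_rad·z(median radiation) + … + b_i`, fitted by
   Laplace-approximated maximum likelihood with stepwise-forward LRT
   selection.

Raw tracking data of this kind are not redistributable, so the package
ships a first-class synthetic generator (`windforay.synthetic`) that
emulates the study conditions — colony-centred Ornstein–Uhlenbeck
movement, daytime-only bimodal sampling intervals, weather-triggered
excursions, a regime-switching Mistral/Sirocco wind field — with known
ground truth for every downstream stage.

## Worked example

```python
import numpy as np
from windforay import pipeline, synthetic, track_io

print(track_io.study_totals())
# {'total_gps': 168202, 'total_mrm': 7408, 'total_lrm': 3024, 'srm_pct': 93.8}

cfg = pipeline.RunConfig(
    sim=synthetic.SimConfig(n_individuals=8, start_date="2021-01-01",
                            end_date="2021-12-31", seed=5),
    seed=5)
result = pipeline.run_pipeline(cfg)
print(result.report["conservation"])
# {'n_fixes': 29165, 'label_totals': {'SRM': 27956, 'LRM': 695, 'MRM': 514},
#  'sum_labels': 29165, 'holds': True}
print(result.duration_fit.terms)
# ('median_radiation_z',)
```

The first call reproduces the published per-individual bookkeeping: 20
birds, 168,202 GPS locations of which 7,408 belong to MRMs and 3,024 to
LRMs, so 93.8% of fixes are short-range — the class imbalance that
shapes everything downstream. The pipeline run simulates eight birds
for a year, screens the fixes, estimates home ranges, extracts and
clusters excursions, annotates weather and fits both models; the
conservation block confirms that SRM/MRM/LRM labels partition every
screened fix, and the selected duration model contains the radiation
term whose negative slope the generator encodes.

The same run is available from a shell:

```bash
windforay run --seed 5 --n-individuals 8 --out runs/demo
windforay study-table
```

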