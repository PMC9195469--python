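# mptkit

Multiple-particle-tracking (MPT) diffusion analysis and tissue-slice
viability quantification.

`mptkit` is for researchers who probe the extracellular space of living
tissue — typically organotypic brain slices — by video-tracking inert
nanoparticles, and who pair those measurements with standard slice-health
readouts (alamarBlue metabolic activity, LDH release, PI/EdU nuclei
staining, HIF1α intensity). It takes tracked trajectories (TrackMate-style
XML or CSV), plate-reader tables, and two-channel fluorescence images, and
produces per-particle diffusion descriptors, population summaries, assay
percentages, and statistically compared group contrasts. A synthetic-data
module generates all three input kinds with exact ground truth, so the full
pipeline is testable without any microscope.

## The analysis core

For a trajectory of N positions sampled every Δt seconds, the time-averaged
mean squared displacement at lag n (lag time τ = nΔt) is

    MSD(τ) = (1/(N−n)) Σᵢ [(x_{i+n} − x_i)² + (y_{i+n} − y_i)²]

From it the pipeline derives, per trajectory:

- **D_eff** — effective diffusion coefficient from the Einstein–Smoluchowski
  relation for two-dimensional diffusion, D_eff = MSD/(4τ), averaged over a
  configurable lag window (default lags 1–10);
- **α** — anomalous diffusion exponent from fitting MSD = 4Dτ^α by
  ordinary least squares in log–log space (default lags 1–30);
- **mode** — immobile (α < 0.1), subdiffusive (0.1 ≤ α < 0.9), normally
  diffusive (0.9 ≤ α ≤ 1.1), or superdiffusive (α > 1.1).

Populations are summarized by median and IQR of D_eff, median α, the four
mode fractions, and a precision-weighted geometric ensemble MSD. Group
comparisons follow a normality-gated decision tree (D'Agostino–Pearson K²
→ one-way ANOVA + Tukey, Brown–Forsythe & Welch ANOVA + Dunnett T3, or
Kruskal–Wallis + Dunn), and assay modules implement metabolic-activity
normalization (acute or normal-control mean set at 100%), cumulative %LDH
release against a TX-100 full-lysis control, and Otsu-threshold nuclei
counting with marker-positive percentages.

## Worked example

Simulate a freely diffusing nanoparticle population at the default
acquisition settings (33.3 frames per second, 651 frames, 0.02 μm
localization noise) and recover its transport parameters:

```python
from mptkit import (SimulationConfig, simulate_brownian,
                    analyze_set, summarize_population)

cfg = SimulationConfig(
    n_trajectories=200, n_frames=651, seed=101,
    regime="brownian", regime_params={"D": 0.5},   # μm²/s
)
trajectories, truth = simulate_brownian(cfg)
pop = summarize_population(analyze_set(trajectories))
print(f"median D_eff     : {pop.deff_median:.3f} um^2/s  (simulated D = 0.5)")
print(f"median alpha     : {pop.alpha_median:.3f}")
print("mode fractions   :", {k: round(v, 3) for k, v in pop.mode_fractions.items()})
```

which prints

```
median D_eff     : 0.495 um^2/s  (simulated D = 0.5)
median alpha     : 0.981
mode fractions   : {'immobile': 0.0, 'subdiffusive': 0.095, 'normal': 0.875, 'superdiffusive': 0.03}
```

The median effective diffusion coefficient lands within 1% of the simulated
0.5 μm²/s, the exponent is consistent with normal diffusion (α ≈ 1), and
87.5% of particles are classified normally diffusive — the residual
sub/superdiffusive calls reflect single-trajectory fitting noise at finite
trajectory length.

The same analysis is available from the shell:

```bash
mptkit simulate trajectories --out sim/ --seed 101
mptkit diffuse --in sim/trajectories.csv --out results/
mptkit compare --in values.csv --groups group --value value --mode all_pairs
```

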