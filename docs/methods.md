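# Methods

## Trajectory model and MSD estimation

The pipeline treats a tracked nanoparticle as a time-ordered sequence of 2-D
positions (μm) on a uniform frame grid. The core estimator is the
time-averaged MSD,

    MSD(n) = (1/(N−n)) · Σ_{i=0}^{N−n−1} [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²],

computed for lags n = 1 … max_lag. `max_lag` defaults to ⌊N/3⌋, a common
single-particle-tracking convention: beyond roughly a third of the
trajectory length the number of displacement pairs (N−n) is small and the
MSD estimate noise-dominated. Trajectories must be gap-free before MSD
computation; the quality filter either splits at frame gaps (default) or
drops gapped trajectories, because interpolating across a gap would
fabricate short-lag displacements and bias the MSD downward. The default
minimum length of 10 frames guarantees at least 9 usable lags; a power-law
fit on fewer points is not meaningful.

Derived quantities per trajectory:

- **Effective diffusion coefficient.** D_eff = MSD/(4τ) (two-dimensional
  Einstein–Smoluchowski). The default evaluates the mean of MSD(τ)/(4τ)
  over lags 1–10 (≈ 0.03–0.30 s at 33.3 fps): a window average is less
  variable than any single lag, and short lags are where the diffusive
  approximation is cleanest. The window is configurable and echoed in all
  outputs.
- **Anomalous exponent.** α is the slope of an unweighted ordinary
  least-squares fit of ln MSD on ln τ over lags 1–30 (configurable),
  corresponding to the model MSD = 4Dτ^α. Lags with MSD = 0 carry no
  information on a log scale and are excluded; a trajectory with fewer than
  3 positive-MSD lags is flagged degenerate and assigned α = 0, so a
  perfectly static particle classifies as immobile instead of erroring.
- **Diffusion mode.** immobile (α < 0.1), subdiffusive (0.1 ≤ α < 0.9),
  normal (0.9 ≤ α ≤ 1.1), superdiffusive (α > 1.1). The boundary
  inclusivities are part of the contract and are tested exactly.

Population summaries report median and IQR of D_eff (distributions over
heterogeneous tissue are heavy-tailed, so means mislead), median α, and the
four mode fractions. The ensemble MSD is a precision-weighted geometric
mean of per-trajectory MSDs: geometric, because trajectory MSDs at a fixed
lag are roughly log-normally distributed across a population; weighted by
the number of displacement pairs N−n (default), since the variance of a
time-averaged MSD estimate shrinks with the pairs entering it. An
inverse-variance scheme, w = (N−n)/MSD², is available as an alternative;
"precision weighting" has no single canonical definition and the choice is
recorded in the output metadata.

## Synthetic trajectory generator

The generator emulates the acquisition geometry of slice MPT experiments:
33.3 frames per second, 651 frames per video, positions in μm. Localization
error is modeled as i.i.d. Gaussian noise per frame and axis (default
σ = 0.02 μm) added to the true positions — the standard static-error model
in SPT. Pixel size (default 0.1 μm/pixel) only matters for the optional
pixel-unit export. Four regimes provide ground truth:

- **brownian** — increments N(0, 2DΔt) per axis; true α = 1.
- **fbm** — fractional Brownian motion per axis via exact Cholesky
  factorization of the fractional-Gaussian-noise covariance, with per-frame
  increment variance 2DΔt^{2H}; ensemble MSD ∝ τ^{2H}, so true α = 2H.
  The Cholesky route is exact (the output covariance matches the fBm
  covariance to numerical tolerance, which the tests verify directly) and
  at 651 frames costs one 650×650 factorization per configuration.
- **immobile** — constant true position plus localization noise; the
  expected MSD plateaus at 4σ² at every lag.
- **directed** — v·t along a per-trajectory random unit direction plus an
  optional Brownian term; MSD → v²τ² at long lags (α → 2).

A mixture regime draws components at stated fractions using
largest-remainder apportionment, so component counts are deterministic and
sum exactly to the requested population size. All generators are bitwise
reproducible per seed.

What the generator deliberately does *not* emulate: tracking artifacts
(missed detections, linking errors, drift), motion blur and dynamic
localization error, spatially varying obstacle fields, or any biology of
oxygen-glucose deprivation. Passing recovery tests therefore demonstrate
the correctness of the estimators under the stated motion models, not
robustness to detector or linker pathology — trajectories from real videos
should still be inspected for those failure modes upstream.

## Nuclei-image and assay-table generators

The image fixture renders symmetric 2-D Gaussian blobs (default σ = 2.5 px,
amplitude 150 a.u. against background noise σ = 2 a.u.) at rejection-sampled
centers with a minimum pairwise separation (default 12 px), on a 512×512
frame. The marker channel re-renders a round(positive_fraction·n) subset of
the same centers — perfect colocalization, mirroring overlap-based manual
counting. Ground-truth counts are exact by construction regardless of
noise. Touching-nuclei splitting (watershed) is intentionally absent; the
fixture enforces separation, and real clumped-nuclei images would need a
more capable segmenter.

The assay fixture draws triplicate well readings N(mean, sd) per slice and
timepoint from a user schedule and requires exactly one TX-100 acute
full-lysis control group, which anchors %LDH normalization.

## Assay formulas

- **Metabolic activity**: reading / mean(acute readings) × 100, or against
  the timepoint-matched normal-control mean with the % difference from 100
  reported. Replicates are averaged first; normalization commutes with
  replicate averaging and is invariant to a common gain.
- **Cumulative %LDH release**: media are exchanged at every collection, so
  each reading measures the release during its interval; the per-slice
  running sum divided by the TX-100 acute control absorbance (pooled mean
  across control wells) gives a nondecreasing series that can legitimately
  exceed 100% — no cap is applied. Timepoint order defaults to
  first-appearance order and can be pinned explicitly.
- Blank subtraction is not performed by default; readings are assumed
  blank-corrected upstream if needed.

## Image quantification

Nuclei are segmented on the nuclear channel by Otsu's threshold (256
histogram bins over the observed range, via scikit-image) followed by
8-connected component labeling with a minimum area of 20 px (both
configurable; the area floor suppresses noise specks at the fixture scale).
A nucleus is marker-positive when its mean within-component marker
intensity exceeds the fluorescent cutoff — either a fixed number, which
should be held constant across a batch (the resolved value is echoed in
every result), or derived per image from an Otsu threshold of the marker
channel. An image with zero segmented nuclei yields an *undefined* (NaN)
percentage, never 0%. The whole-frame marker/nuclear mean-intensity ratio
serves protein-level readouts; a common gain cancels.

A numerical note on Otsu: the between-class-variance curve contains exact
plateaus wherever histogram bins are empty, and within a plateau the argmax
is decided by 1-ulp summation noise. Equivalence with an exhaustive
threshold search is therefore asserted on the attained objective value
(identical up to float ties), not on bit-identical thresholds.

## Statistical decision tree

Groups (≥ 2 groups, ≥ 3 observations each) are screened with the
D'Agostino–Pearson K² omnibus at 0.05 per group. Any rejection routes the
comparison to Kruskal–Wallis (tie-corrected) with Dunn's rank post hoc
(Bonferroni family adjustment over the requested pairs). Otherwise equality
of SDs is screened with the Brown–Forsythe median-centered variance test at
0.05 — chosen for consistency with the Brown–Forsythe fallback branch —
routing to either ordinary one-way ANOVA with Tukey–Kramer HSD (p-values
from the studentized-range distribution, inherently family-adjusted) or to
the Welch ANOVA (reported as the primary omnibus p, with the Brown–Forsythe
ANOVA-on-means alongside) with Dunnett-T3-style pairwise Welch t statistics
under a Šidák family adjustment. Groups with n < 8 cannot be screened by
the K² omnibus and force the rank-based branch with a logged note.

All statistics are computed from their published formulas, with
scipy/pingouin equivalents used purely as cross-check oracles in the test
suite; scipy supplies only reference-distribution CDFs. Two structural
properties are worth stating plainly: adjusted p-values are never smaller
than their unadjusted counterparts, and branch selection is a pure function
of the recorded p-values. Because the gate stacks three-plus independent
5%-level screens, truly Gaussian homoscedastic data select the
ANOVA/Tukey branch only ≈ 80% of the time — that is the arithmetic of the
decision rule itself (≈ 0.95³ × 0.95), not an implementation artifact, and
simulations here reproduce it.

## Problem sizes and reproducibility

Recovery simulations use 100–200 trajectories of 651 frames per regime,
decision-tree rates use 100 replicates per scenario (500 for the all-null
family-wise error), and the image grid spans {50, 100, 200} nuclei ×
{0, 25, 50, 75, 100}% positive — sizes at which every Monte-Carlo check is
stable across seeds while the full suite stays fast. Every stochastic test
and the acceptance script derive all randomness from explicit seeds.

## Known limitations

- No drift correction, motion-blur deconvolution, or Bayesian model
  selection between motion models; α-based classification is a fit to a
  single power law even when the underlying MSD is a mixture (e.g.
  noise-floor plus ballistic).
- The tracking-XML reader consumes TrackMate-style exports only; spot
  detection and linking are out of scope.
- D_eff depends on the chosen lag window, and population medians pool all
  supplied trajectories; grouping keys must be managed by the caller when
  slices or videos should be summarized separately.
- The post-hoc variants (Dunn's adjustment flavor, T3 via Welch-t/Šidák)
  follow common software practice; other published variants differ in the
  reference distribution used.
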