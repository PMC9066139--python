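# Methods

This note documents the models, conventions and numerical choices behind
`pmfrisk`, and what the synthetic benchmarks do and do not demonstrate.

## Receptor data and the uncertainty model

The receptor dataset is a daily matrix X (n samples × m species, µg/m³)
with a per-cell uncertainty matrix σ.  Uncertainties follow the EPA
convention used with PMF:

- σ = (5/6)·MDL when the concentration is at or below the method detection
  limit (MDL);
- σ = sqrt((Conc·EF)² + (0.5·MDL)²) above it, with analytical error
  fraction EF = 0.1 by default.

The two branches do not meet at Conc = MDL; the jump is
|5/6 − sqrt(0.26)|·MDL ≈ 0.324·MDL.  We keep the convention as printed and
assert the discontinuity in tests rather than smoothing it.

Screening removes species whose signal-to-noise ratio
S/N = mean(max((x−σ)/σ, 0)) is ≤ 0.2 (inclusive).  Below-detection cells
are substituted with MDL/2 and σ = (5/6)·MDL by default; an `exclude-row`
policy drops the affected days instead, for studies that discard BDL
samples outright.  Whole-row exclusion wastes data, which is why
substitution is the default; both paths are reported in the screening
report.  An optional per-species outlier screen (|z| > 4 on
log-concentration) exists but is off by default because no standard
criterion exists.  PM2.5 total mass is fitted as a "weak" species with σ
tripled so profiles carry a mass row; `include_total=False` switches to
post-hoc non-negative regression of observed mass on the contributions.

## Weighted PMF

The factorization minimizes Q = Σ((x − GF)/σ)² subject to G, F ≥ 0.  The
optimizer is alternating weighted non-negative least squares: with F fixed,
each row of G is an independent convex NNLS problem (scipy's Lawson–Hanson
solver), and symmetrically for columns of F.  Each half-step solves its
subproblem exactly, so Q is non-increasing across sweeps — a property the
test suite asserts on the stored Q trace.  Multiplicative-update NMF was
rejected because it lacks this guarantee at the weighted objective.

- **Multi-start**: default 20 random initializations (10 in the desk-scale
  benchmarks), seeds derived from a base seed by unit increments; the
  lowest-Q_true run wins, ties broken by start index.
- **Convergence**: relative ΔQ < 1e-8 over 10 consecutive sweeps, ceiling
  20 000 sweeps.  Warm-started re-fits (bootstrap, DISP) use ceilings of a
  few hundred sweeps since they start at the base solution.
- **Gauge**: G columns are scaled to unit mean after fitting, so row k of F
  is the mean species apportionment (µg/m³) of factor k.
- **Robust mode** (default on; off in the synthetic benchmarks, whose noise
  is exactly Gaussian): cells with |scaled residual| > α = 4 have σ
  inflated to bring the scaled residual to α, recomputed each sweep.
  Q_robust caps per-cell contributions at α².
- **Q_expected** is the degrees-of-freedom heuristic
  n·m − q·(n+m); Q_true/Q_expected ≈ 1 indicates σ-consistent residuals
  and anchors the factor-count scan.

### Error estimation

**Bootstrap**: days are resampled in circular blocks (default 3 days,
matching serial correlation of daily air-quality data) with replacement;
each replicate is refit from the base solution and each bootstrap factor is
assigned to the base factor maximizing the Pearson correlation of
contribution series, counted as mapped at r ≥ 0.6.  Low mapping rates or
many unmapped factors signal unstable (e.g. collinear) factors.

**DISP**: a profile value F[k, j] is pushed away from its fitted value and
everything else re-optimized; the displacement at which Q rises by dQmax
(levels 4, 8, 16, 32) is found by geometric bracketing plus bisection
(relative tolerance 0.05 on the displacement).  One subtlety is essential:
pinning F[k, j] alone is meaningless because rescaling G[:, k] against
F[k, :] reproduces the base solution at any pinned value.  The displacement
is therefore defined under the unit-mean-G gauge, re-imposed after every G
update during the constrained re-optimization (projected alternating
minimization).  A swap is flagged when some base factor no longer has any
re-optimized contribution series correlating with it at r ≥ 0.6.  Intervals
are clamped to nest across dQmax levels; the downward search is bounded by
zero (non-negativity).

## Source-direction statistics

**CPF** assigns each non-calm hour (speed ≥ 0.5 m/s) its day's factor
contribution; exceedance is a contribution strictly above the 0.75
empirical quantile (linear interpolation).  16 sectors, sector 1 centred on
north, half-open bins [centre − 11.25°, centre + 11.25°).  Sectors with no
hours are reported missing, not zero.  The identity
Σm_θ/Σn_θ = overall exceedance fraction holds exactly and is tested.

**PSCF** bins HYSPLIT trajectory endpoints on a regular lat/lon grid
(default 0.5°, bounding-box origin); exceedance uses the 0.70 quantile.
**WPSCF** multiplies PSCF by 1.0 / 0.7 / 0.4 / 0.2 for n_ij above 3·n_avg,
in (1.5·n_avg, 3·n_avg), in (n_avg, 1.5·n_avg), and below n_avg.  The
published band definition uses strict inequalities and leaves equality
cases ambiguous; counts exactly at a boundary take the lower weight, and
n_avg is the mean over visited cells (configurable to all cells).
Grid-cell argmax ties are broken toward the better-sampled cell.

tdump parsing accepts the standard endpoint layout (met-grid block,
start block, diagnostic-variable line, then fixed-field endpoint lines) and
round-trips through `write_tdump` to ~3-decimal coordinate precision.

## Inhalation risk

ADDinh = C·ET·EF·ED/AT with AT ≡ ED·365·24 enforced, so with EF = 365 the
dose reduces to C·ET/24.  ILCR = ADDinh·IUR; HQ = ADDinh/RfC (an
alternative `ec_mg` convention divides by RfC in mg/m³); HI = ΣHQ.
Chromium is split Cr(VI):Cr(III) = 3:7 before the cancer path; only Cr(VI)
carries a unit risk.  Risk bands: < 1E-06 negligible, > 1E-04 harmful,
boundaries in the tolerable band (the published wording is strict on both
sides).  Required reduction to a target is 1 − target/current, exact
because ILCR is linear in concentration; the fixed-point property is
tested.

Exposure parameters default to the transparent placeholder ET = 24 h/day,
EF = 365 d/y, ED = 30 y (continuous exposure) because receptor-population
values are study-specific; `ExposureParams.calibrate_et` back-solves the
effective ET from any known (concentration, ILCR, IUR) triple so published
tables can be reproduced without guessing.  The bundled toxicity table
carries the IRIS/OEHHA screening unit risks for As, Cr(VI), Ni, Pb and
generic chronic reference concentrations; real assessments should supply
their own CSV.

The source × element risk matrix summarizes each per-source per-element
concentration series g·f (median by default, optionally the 95th
percentile) before the dose chain.  Margins satisfy
Σrow = Σcolumn = grand total to machine precision by construction.

## Synthetic generator

The generator emulates the *structure* of a one-year industrial-city
campaign: marker-dominated source profiles (rows sum to 1; each factor's
designated markers carry 70% of its mass), lognormal daily contributions
(mean 4 µg/m³ per factor, log-sd 0.8) with sinusoidal seasonal modulation
(amplitude 0.5; nitrate-type sources peak mid-January, sulfate mid-July),
Gaussian noise with the MDL-based σ evaluated at the noise-free value
(clipped at zero; lognormal optional), and MDLs at 1–10% of species means.
The flagship scenario is 200 days × 15 species + mass from 6 sources —
deliberately smaller than a 10-factor campaign to keep fits, bootstrap and
DISP desk-scale; a 95-day × 22-species, 10-source scenario
(`paper_shaped_scenario`) exercises campaign shape.  Winds are von Mises
(κ = 8) around a planted sector on exceedance days and uniform otherwise;
trajectories are kinematic walks that curve through a planted grid cell via
random waypoints and dwell there briefly, purely to exercise the gridding
logic.

What passing these benchmarks shows: the estimator recovers
marker-structured sources at realistic noise, the error estimates cover the
truth, and the direction statistics locate planted sources.  What it does
not show: performance on real campaigns with correlated sources, model
misspecification (σ wrong, non-Gaussian errors), chemistry (gas-particle
partitioning), or realistic trace-element mass fractions — synthetic
toxic-element concentrations are orders of magnitude above ambient ng/m³
levels, so synthetic ILCR magnitudes are not interpretable, only their
invariances (linearity, margins) are.

## Determinism

Every generator and estimator output is a pure function of (configuration,
seed); the pipeline derives all stage seeds from one config seed and a
rerun produces a byte-identical summary JSON, which is asserted in tests.
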