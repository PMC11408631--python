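# Methods

This note documents the models and procedures implemented in `otoprov`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Measurement model and window rescaling

**Acid-fractionation correction.** Carbonate δ¹⁸O measured after 72 °C
phosphoric-acid digestion is shifted by −0.09 ‰ to be comparable with 25 °C
analyses; the offset reflects the temperature dependence of the
calcite/aragonite acid-fractionation factor difference. The correction is a
pure additive shift, so datasets carry a `acid_corrected` flag and a second
application raises an error rather than silently biasing every value by
another −0.09 ‰. δ¹³C needs no such correction. The offset and the two line
temperatures are configuration constants.

**Radius–age curves.** For otoliths without daily-increment readings, segment
age ranges are estimated from distance to the core through a piecewise-linear
interpolant of mean radius at age, pooled over increment-read fish captured
in the same year, season and region. "Season" is the calendar quarter — the
coarsest grouping that still separates summer-autumn age-0 batches from
winter-spring age-1 batches. Non-monotone mean radii are resolved by a
pool-adjacent-violators (isotonic) adjustment; queries outside the anchor
hull are clamped with a warning rather than extrapolated, because linear
extrapolation of somatic growth beyond observed ages is not defensible.

**Window values.** The two analysis windows are closed intervals in days post
hatch: larval [0, 60] and juvenile [106, 120]. A segment contributes to a
window iff the median of its age range lies inside it — no partial-overlap
proration, which would require assuming how material is distributed within a
segment. Contributing segments are averaged weighted by milling width in μm
(default). Whether the original rescaling weighted by spatial width or by day
span is not decidable in general; the weighting is a config switch
(`width_um` / `day_span`) and both are exercised by tests. The two weightings
coincide exactly under linear growth and differ little otherwise.

## 2. Provenance classification

**Threshold rule.** Per year-class, the threshold is the *maximum*
juvenile-stage δ¹⁸O over the reference set (age-0 fish of the coastal system
plus age-1 fish of its southernmost region); at-or-below ⇒ local, above ⇒
nonlocal. Age-0 fish of the coastal system lacking the juvenile measurement
are assigned local — they were captured inside the system during their first
summer–autumn. Age-1 fish lacking it stay unclassified for the discriminant
step. Being a sample maximum, the threshold is monotone in the reference set
and sensitive to single extreme values; this motivates a bounded-tail design
in the synthetic generator (§5).

**Linear discriminant.** Pooled-covariance LDA on (larval δ¹⁸O, larval δ¹³C,
radius at 60 dph), trained on threshold-labeled locals and nonlocals of all
year-classes that have both the juvenile measurement and an increment-based
radius. Priors are the training class frequencies — the mainstream default,
consistent with asymmetric per-class accuracies. Features enter
unstandardized (linear discriminants are affine-equivariant). Exact decision
ties (a probability-zero event) go to `local`, mirroring the "lower or equal"
convention of the threshold rule, fixed for determinism. LOOCV refits the
model and priors per fold; a fold whose removal would leave a class with
fewer than two members is skipped with a warning, since the within-class
covariance would be undefined.

## 3. Group statistics

Implemented from their defining formulas (SSCP matrices, rank sums, Welch
moments); scipy provides the underlying distributions and the Shapiro–Wilk
and Levene primitives, and independent implementations (statsmodels MANOVA,
scipy `kruskal`, pingouin Games–Howell, scipy `studentized_range`) serve as
cross-check oracles in the test suite only.

* **MANOVA** — Wilks' Λ = det(E)/det(E+H); Rao's F with
  df₁ = p(k−1), df₂ = t[(n−1)−(p+k)/2] − (p(k−1)−2)/2,
  t = √((p²(k−1)²−4)/(p²+(k−1)²−5)), t = 1 when the denominator vanishes.
  Wilks/Rao was fixed (over Pillai etc.) because its df pair is the one
  conventionally reported for the three-variable, three-group design.
* **Assumption battery** — Shapiro–Wilk per variable × group; Mardia
  multivariate skewness/kurtosis per group; pairwise correlations and VIFs;
  Box's M with the χ² approximation; Brown–Forsythe (median-centred) Levene.
  Cells whose group is too small for a test are marked not-computable.
* **Kruskal–Wallis** — mid-rank ties with the (1 − Σ(t³−t)/(N³−N)) correction;
  all-identical data give H = 0, p = 1 by convention, not an error.
* **Games–Howell** — q = |x̄ᵢ−x̄ⱼ|/√((sᵢ²/nᵢ+sⱼ²/nⱼ)/2), Welch df, adjusted p
  from the studentized range with k = number of groups. Zero-variance pairs:
  equal means ⇒ p = 1; unequal ⇒ p = 0, flagged degenerate.
* **Studentized range** — tail probabilities by numerical integration of the
  standard double-integral definition: the inner range-CDF integral uses a
  fixed 240-point Gauss–Legendre rule on [−9, 9] (the integrand is bounded by
  k·φ(z), so the truncation error is ≈1e−18 and the rule resolves the smooth
  integrand far below the 1e−6 target); the outer mixture over the scale
  estimate s = χ_ν/√ν uses adaptive quadrature (abs. tol 1e−8).
* **Recruitment correlation** — Pearson r on year-to-year first differences
  over consecutive years present in both series, two-sided p from the
  t-transform; differencing removes the shared decadal trend that would
  otherwise inflate the correlation.

Complete-case analysis throughout; no imputation.

## 4. Isoscape and assignment

Predicted otolith δ¹⁸O per cell: δ¹⁸O_oto = a·T + b + δ¹⁸O_w + offset with
a < 0 (enforced), and δ¹⁸O_w = m_r·S + c_r per region. The shipped defaults
(a = −0.18 ‰/°C, b = 2.7 ‰, offset = −0.27 ‰, single region with
m = 0.28 ‰/psu, c = −9.4 ‰) are **non-authoritative placeholders** of
plausible magnitude for temperate NW-Pacific waters, used by the synthetic
generator and tests; real applications must supply calibrated coefficients
for the species and region via configuration.

Window means of T and S are taken over the closed dph window from each
assumed hatch date ([0,60] = 61 days, [106,120] = 15 days), strict on missing
data by default (any missing day ⇒ missing cell) to avoid silently biased
means near coastlines; a coverage fraction (e.g. ≥80%) is configurable. The
environment is averaged first and then transformed (both relations are
linear, so the order only matters under missing data); transform-then-average
is available as a switch. Hatch dates default to every 3 days from April 15
to May 15 ("mid-April" / "mid-May" fixed to the 15th, overridable), with
February and June single-month scenarios supported in configuration. Masks
keep cells within the observed mean ± 1 SD (closed interval); per-window maps
are produced independently rather than intersected across windows, matching
how such predictions are usually displayed. Grids are cell-centred, latitude
increasing northward; inputs must share one grid per run (no regridding).

## 5. Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* **Environment** — T(lat, day) = base − g·(lat − lat_min) + A·sin(2π(doy −
  φ)/365) + smooth seeded spatial noise, with base 19.8 °C, g = 0.6 °C/°,
  A = 6 °C peaking mid-August; salinity ≈34 psu with a −1.5 psu coastal patch
  emulating a less-saline bay. These values put forward-modelled otolith
  δ¹⁸O in the −2…+0.5 ‰ range characteristic of temperate coastal fish.
* **Templates** — locals are resident in warm southern coastal cells and
  experience the full seasonal warming (marked ontogenetic δ¹⁸O decrease);
  nonlocals and offshore fish drift poleward (0.13–0.14°/day) so cooling by
  latitude offsets seasonal warming (flat/increasing δ¹⁸O). Drift speeds are
  plumbing, not biological estimates: they are set so the environmental
  signal matches each group's qualitative trend.
* **Stage moments** — group targets default to local −0.7 ± 0.4 ‰ (larval) →
  −1.5 ± 0.4 ‰ (juvenile), nonlocal −0.3 ± 0.2 → −0.2 ± 0.3, offshore
  −0.1 ± 0.3 → 0.1 ± 0.3. Each fish's daily series receives an affine-in-age
  adjustment so its growth-weighted window means equal targets drawn from
  those moments — emulating between-fish vital/habitat effects the smooth
  environment cannot produce. Targets are drawn from a ±2.5 σ truncated
  normal: stage values are environmentally bounded, and the max-based
  threshold rule is sensitive to exactly the implausible Gaussian tail draws
  an unbounded normal occasionally produces. Truncation changes the realized
  SD by under 2%. With `calibrate_to_moments=False` values are purely
  environment-driven (used for geolocation experiments, where measured values
  must reflect where the fish lived).
* **Growth and measurement** — linear radius growth at 5 μm/day with a
  lognormal fish-level multiplier (σ = 10%), the simplest monotone model
  consistent with observed radius-at-age spread. Nonlocals carry a 1.20× and
  offshores a 1.10× mean growth multiplier; the nonlocal value is the one
  free group parameter with no published moment and was calibrated so the
  simulated discriminant reproduces the canonical cross-validated accuracy
  structure of this study design (≈89% overall, local precision above
  nonlocal precision). Segments partition the radius axis with forced cuts at
  the 60/106/120 dph radii and widths in 30–160 μm; each records the
  growth-weighted mean of the daily values it spans plus N(0, 0.10 ‰)
  analytical noise (both isotopes). Half the fish are "analysed" on the 72 °C
  acid line (+0.09 ‰ on raw δ¹⁸O) to exercise the correction. δ¹³C is
  non-informative noise (−8.0 ± 0.5 ‰ for every group): carbon isotopes mix
  water and metabolic sources and carried no group signal in this design, so
  no environmental δ¹³C model is attempted.
* **Cohort structure** — per year-class (two by default): 70 locals (60%
  age-0 across the three coastal regions, 15% age-1 in the southernmost
  region, 25% age-1 elsewhere), 30 nonlocals (all age-1 in the two northern
  regions) and 20 offshore age-0 fish. 15% of age-0 and 30% of age-1 fish
  lack the juvenile milling, and 8% of age-1 fish lack increment readings,
  exercising the fixed-label, discriminant and curve-mapping paths.
* **Reproducibility** — one master seed spawns independent substreams per
  stage and per fish; identical config + seed gives byte-identical CSVs.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure (group moments, noise, missingness, seasonal
environment) but not oceanographic or behavioural realism: no currents,
no temperature-dependent growth, no spatially varying salinity relation,
piecewise-deterministic movement. Recovery rates on synthetic cohorts
therefore validate the *machinery* (rescaling, threshold, discriminant,
isoscape intersection) under known truth; they are not field estimates of
classification accuracy.

## 6. Numerical and I/O choices

CSV is UTF-8, comma-separated, dot-decimal, ISO-8601 dates; invalid rows are
quarantined to a rejects table with line numbers instead of aborting. Length
thresholds in the age-assignment rule are strict (`< 150 mm`, `< 160 mm`).
netCDF is written in classic format through xarray's scipy backend for
portability. The pipeline stages communicate only through files, so any stage
can be rerun from disk; manifests record a configuration hash and per-stage
row counts.

## 7. Problem sizes

Defaults were chosen so a full study (240 fish, 2 year-classes, a
41 × 39 × 730-day environment, 11 hatch dates × 2 windows) runs in seconds,
and the 2000-replicate MANOVA null calibration in about a second; these sizes
are the package's own defaults for desk-scale reproduction and can be raised
freely in configuration.

## 8. Known limitations

* The isoscape coefficients are placeholders; conclusions about real fish
  require calibrated fractionation and salinity–δ¹⁸O_w relations.
* The threshold rule is a sample maximum: it has no sampling-error control
  and is only as good as the reference set's purity; the generator's bounded
  tails encode that assumption explicitly.
* Radius–age curves pool fish within capture cohorts; strong within-cohort
  growth heterogeneity biases window placement for unread profiles (the
  zero-noise reconstruction identity holds exactly only for increment-read
  fish).
* Hard assignment only: no mixture modelling, no probabilistic
  (likelihood-surface) geolocation beyond the interval mask.
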