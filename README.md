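# otoprov — otolith-isotope provenance analysis

`otoprov` reconstructs where young pelagic fish grew up from the stable-isotope
record in their otoliths. It was built around a recurring study design in
fisheries ecology: micromilled otolith δ¹⁸O/δ¹³C profiles of age-0 and age-1
fish from several coastal regions are rescaled onto two ontogenetic windows
(larval, 0–60 days post hatch; juvenile, 106–120 dph), fish are classified
into **locals** (grew up inside the sampled coastal system) and **nonlocals**
(grew up elsewhere), and the nonlocals' potential nursery areas are mapped by
intersecting a predicted otolith-δ¹⁸O isoscape with their observed isotope
range.

The package ships a synthetic cohort/environment generator with the same
statistical structure, so the entire chain is testable and reproducible
without any field data.

## The science in brief

**Signal.** Otolith δ¹⁸O (‰ VPDB) decreases with ambient temperature and
increases with seawater δ¹⁸O, which itself tracks salinity linearly. A fish
resident in a seasonally warming coastal sea therefore records a marked
ontogenetic *decrease* in otolith δ¹⁸O; fish that drift toward cooler waters
record flat or increasing values. Measurements from a 72 °C phosphoric-acid
line are first shifted by −0.09 ‰ to the 25 °C acid-digestion scale
(temperature-dependent calcite/aragonite acid-fractionation difference).

**Windows.** Micromill segments have heterogeneous resolution (≈5–30 days or
30–160 μm). A segment contributes to a window when the median of its
estimated age range falls inside it; contributing segments are averaged
weighted by milling width. Ages of unread profiles are estimated from
distance to the core via a monotone radius–age curve fitted per capture
cohort.

**Classification.** Per year-class, the *highest* juvenile-stage δ¹⁸O among
the reference fish (age-0 fish of the coastal system plus age-1 fish of its
southernmost region, which all show the local warming signal) defines a
threshold: at-or-below ⇒ local, above ⇒ nonlocal. Age-1 fish lacking the
juvenile measurement are classified by a pooled-covariance linear
discriminant on (larval δ¹⁸O, larval δ¹³C, otolith radius at 60 dph), with
accuracy estimated by leave-one-out cross-validation. The score of class *c*
is ln π_c + μ_cᵀΣ⁻¹x − ½μ_cᵀΣ⁻¹μ_c with Σ the pooled within-class covariance.

**Group statistics.** Locals, nonlocals and offshore fish are compared by
one-way MANOVA using Wilks' Λ = det(E)/det(E+H) with Rao's F approximation,
an assumption battery (Shapiro–Wilk, Mardia, VIF, Box's M, Brown–Forsythe
Levene), per-variable Kruskal–Wallis tests (mid-rank tie correction), and
Games–Howell pairwise comparisons, whose adjusted p-values come from a
studentized-range distribution evaluated by direct numerical integration.

**Geolocation.** For each assumed hatch date (every 3 days, mid-April to
mid-May by default, with February/June scenarios supported), the isoscape
predicts per grid cell the otolith δ¹⁸O a fish would have recorded:
δ¹⁸O_oto = a·T̄ + b + (m_r·S̄ + c_r) + offset, with the window means T̄, S̄
from gridded 10 m temperature/salinity fields. Cells within the observed
group mean ± 1 SD form the potential distribution; counts over hatch dates
measure robustness. Coefficients (a < 0, b, per-region salinity relations)
are configuration inputs; shipped defaults are plausible placeholder
magnitudes for synthetic work, not calibrated constants.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(each is a thin wrapper over the `otoprov` library and the `otoprov` CLI):

```bash
python analysis/01_simulate_cohort.py   --seed 1 --out results/study
python analysis/02_stage_windows.py     --seed 1 --out results/study
python analysis/03_classification.py    --seed 1 --out results/study
python analysis/04_group_statistics.py  --seed 1 --out results/study
python analysis/05_nursery_assignment.py --seed 1 --out results/study
```

prints

```
simulated 240 fish -> results/study/data/
240 fish with larval values; 0 validation flags
LOOCV: 130/142 correct (91.5%)
  predicted local: 108/116 (93%) actually were
  predicted nonlocal: 22/26 (85%) actually were
MANOVA: Wilks lambda 0.428, F(6, 354.0) = 31.14, p = 5.08e-30
Kruskal-Wallis larval_d18O: H = 85.20, p = 3.15e-19
Kruskal-Wallis larval_d13C: H = 0.41, p = 0.814
Kruskal-Wallis radius_at_60dph_um: H = 48.60, p = 2.8e-11
larval: 670 matching cells, mean latitude 38.8 deg N
juvenile: 415 matching cells, mean latitude 46.9 deg N
```

Reading the output: the discriminant separates locals from nonlocals well but
not perfectly (91.5% cross-validated accuracy — larval features overlap by
design); larval δ¹⁸O and otolith radius differ strongly between groups while
δ¹³C carries no group signal (H = 0.41, p = 0.81); and the nonlocals'
predicted distribution shifts northward between the larval and juvenile
windows (38.8 °N → 46.9 °N), the signature of fish tracking cool water
through a warming season.

The same pipeline runs behind a single CLI:

```bash
otoprov run --config run.yaml --seed 1
```

where `run.yaml` selects stages, paths and model coefficients (see
`otoprov.pipeline` for the schema and defaults).

## Layout

```
src/otoprov/          library: data_io, profile_windows, provenance,
                      group_stats, isoscape_assign, synthetic_data,
                      pipeline, cli
analysis/             numbered study drivers (thin wrappers)
scripts/acceptance.py headline-quantity reproduction
tests/                pytest suite (unit, property and end-to-end checks)
docs/methods.md       models, assumptions, parameter choices, limitations
```
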