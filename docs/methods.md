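# Methods

`equipanel` measures the equity of healthcare-resource allocation across the
administrative regions of a tiered facility system — the setting is China's
rural three-tier network of county-level medical and health institutions
(CMHIs), township hospitals (THs) and village clinics (VCs), observed
annually per province over 2003–2020 — using four instruments: the Lorenz/
Gini coefficient, the health resource density index (HRDI), the Theil index
with its between-/within-zone decomposition, and the Mann–Kendall trend
test. This note records the exact formulas implemented, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where more than one reading was defensible.

## Data model

A *balanced* panel: every region observed in every year, with population
(persons), land area (km²), an economic-zone label, and non-negative counts
for the 8 valid (tier, kind) combinations — institutions/beds/personnel per
tier, except that village clinics carry no beds. Regions that appear or
disappear mid-window are rejected rather than imputed: silent imputation
would shift every share-based index, so completing the panel is the user's
explicit decision. Zone membership is an input column, not a hard-coded
scheme, so any partition works; the generator defaults to the three-zone
(eastern/central/western) scheme.

Each index is computed on a single-year cross-section of pairs (mᵢ, eᵢ):
the *calibre* selects the measure mᵢ — population or area — against which
resource quantities eᵢ are compared. All "ordered" contracts refer to the
canonical lexicographic region order so that floating-point summations are
reproducible regardless of input row order.

## Gini coefficient

Regions are sorted ascending by density eᵢ/mᵢ (ties broken by region id),
cumulative shares Xᵢ (measure) and Yᵢ (resource) are formed with the
implicit origin (X₀, Y₀) = (0, 0), and

    G = 1 − Σᵢ (Xᵢ − Xᵢ₋₁)(Yᵢ + Yᵢ₋₁).

Sorting by density is the standard Lorenz construction and guarantees
G ≥ 0; the ascending-density order uses the *active* calibre's measure, so
the geography-calibre Gini sorts by resources per km². On grouped data the
trapezoid formula is algebraically identical to the weighted relative mean
difference Σᵢⱼ wᵢwⱼ|dᵢ−dⱼ|/(2d̄) with wᵢ = mᵢ/M, dᵢ = eᵢ/mᵢ; the test suite
verifies this equivalence on 1000 random instances to 1e-10, and the
transfer property (moving resources from a denser to a sparser region never
raises G) on perturbed instances.

Zero-resource regions are legal (density 0, sorted first); an all-zero
cross-section raises an error rather than returning G = 0, because "no
resources anywhere" is not equity. Fairness bands are half-open:
[0, 0.3) optimal, [0.3, 0.4) normal, [0.4, 0.5) gap, [0.5, 0.6) alert,
[0.6, 1) danger — the conventional thresholds, made non-overlapping at the
boundaries so each G maps to one band.

## Health resource density index

    HRDI = HR / sqrt((A / area_unit) · (P / pop_unit))

the geometric-mean density that a per-capita-only or per-area-only measure
would bias. Display units default to pop_unit = 10³ persons and
area_unit = 1 km²; the index is homogeneous of degree −1 in joint (A, P)
scaling, so orderings and trends are unit-free even though levels are not.
At zone or national scope HR, A and P are summed over members first and the
formula applied to the sums; the aggregate is deliberately *not* the mean of
member HRDIs (a counterexample test pins this).

## Theil index and decomposition

With shares wᵢ = mᵢ/M and sᵢ = eᵢ/E (natural logs throughout):

    T_total = Σᵢ wᵢ ln(wᵢ/sᵢ)
    T_inter = Σ_g (M_g/M) ln((M_g/M)/(E_g/E))
    T_intra = Σ_g (M_g/M) T_g,  T_g computed from zone-internal shares

and T_total = T_inter + T_intra exactly (verified to 1e-10 on 1000 random
31-region instances). Contribution rates T_intra/T_total and
T_inter/T_total are ratios of Theils and hence logarithm-base invariant.
T is bounded below by 0 but *not* bounded above (the supremum is ln(M/mᵢ)
as a region's resources vanish); claims that T lives in [0, 1] hold only
away from extreme concentration, so the implementation asserts
non-negativity only. A region with eᵢ = 0 makes the log diverge and is a
hard error naming the region; users who want exclusion must filter
explicitly, because dropping a region changes every share.

Theil reporting defaults to the population calibre (its trends track the
population-calibre Gini); geography is available symmetrically. The
contribution table rounds yearly percentages to 2 decimals and appends the
arithmetic mean of the rounded yearly values — matching how published tables
of this kind are laid out. The packaged reference table
(`equipanel.datasets.contribution_reference_table`) reproduces its printed
mean row under this convention in seven of eight columns; the TH-personnel
mean was evidently printed from unrounded rates and differs by 0.01.

## Mann–Kendall trend test

S = Σ_{i<j} sgn(xⱼ − xᵢ), tie-corrected variance
Var = [n(n−1)(2n+5) − Σ_t f_t(f_t−1)(2f_t+5)]/18, continuity-corrected
Z = (S∓1)/√Var (0 when S = 0), two-sided normal p, and the star ladder
*** p<0.01, ** p<0.05, * p<0.1. The sign convention makes a rising series
give S > 0 (one sometimes sees the statistic printed with the opposite
subtraction order; that orientation contradicts "positive Z means
increasing" and is treated as a typo). A one-sided option exists behind a
flag; the default is two-sided, matching how the star ladder is normally
reported. Sen's slope, seasonal variants and prewhitening are out of scope.

The tie correction is always applied in full, although ties are
near-impossible in real-valued index series. For an 18-point strictly
monotone series Z = 152/√697 ≈ 5.757 — the ceiling value any saturated
18-year trend produces, independent of the series' values (rank statistic).

`exact_null(n)` gives the exact permutation distribution of S for distinct
values at n ≤ 10, computed with the inversion-count (Mahonian) recurrence —
a permutation with k inversions has S = n(n−1)/2 − 2k — which is identical
to enumerating the n! orderings but feasible; the tests cross-check it
against literal enumeration at n ≤ 6, against the closed-form variance at
n ≤ 8, and against the normal approximation on the α-ladder tails (within
0.03 absolute at attainable S values).

## Growth rates

"Total growth" is (v_T − v₀)/v₀. "Average annual growth" is implemented as
the compound (geometric) rate (v_T/v₀)^(1/(T−t₀)) − 1 by default, with the
arithmetic mean of yearly rates behind `--growth-mean=arithmetic`; the two
readings coincide only under even growth, and sources rarely say which they
used, so both are provided and the default is the one that is exact for
exponential growth.

## Synthetic panel generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without any external download:

- 31 provincial units in three zones (11 eastern / 8 central / 12 western),
  years 2003–2020.
- Populations and areas lognormal, constant over the window; defaults
  centre provinces near 3×10⁷ persons (σ = 0.8) and 3×10⁵ km² (σ = 0.9),
  with zone-level shifts (+0.4/0/−0.3 log-population, −0.6/0/+0.8 log-area)
  emulating the dense-compact-east / vast-sparse-west gradient. This
  gradient is what makes geography-calibre Ginis realistically much larger
  than population-calibre ones, and zone-level HRDI reliably ordered
  east > central > west.
- Resource counts: count = round(base · exp(offset_z + η + trend·Δt) · pop)
  with η ~ N(0, within_sigma + inequality_drift·Δt) drawn independently per
  region-year. Defaults: per-person density bases of realistic magnitude
  per (tier, kind) (e.g. 10⁻⁵ county institutions, 2×10⁻³ county beds per
  person), zone offsets +0.25/0/−0.25, within_sigma 0.3, zero trend and
  zero inequality drift. Counts are rounded to integers with a floor of 1
  where the density is positive (yearbook semantics); `round_counts=False`
  disables rounding for exactness tests.
- Because η is redrawn each year, the zero-trend configuration yields index
  series that are i.i.d. across years — the exact null under which the
  Mann–Kendall stage is calibrated (type-I error 0.05 ± 0.02 over 1000
  panels in the acceptance suite).
- `inject_trend` superimposes monotone dynamics: for gini/theil it ramps an
  extra per-region log-dispersion from 0 to 0.52 (= 0.3·√3) over the
  window, doubling the default total log-density spread by the final year —
  inequity growth of the magnitude the study period exhibits; for hrdi it
  applies a 3 %/yr log-level drift, a typical annual resource growth rate.
  Sign recovery under these defaults is ≥ 95 % over 200 seeds.

What the generator does **not** emulate: migration and population change
over time, spatial autocorrelation beyond the zone level, serial
correlation of the noise (real index series are smoother than i.i.d.
draws, which makes the null calibration conservative relative to real
data), reporting changes and administrative re-definitions, or the actual
magnitudes of any real country's yearbook counts. Passing tests therefore
demonstrate correctness of the estimators and the qualitative behaviour of
the pipeline, not agreement with any published national index values.

## Numerical choices

- Lorenz endpoints are clamped to exactly (1, 1) after cumulative
  summation; G is clipped at 0 to absorb −1 ulp round-off on proportional
  allocations.
- Zone aggregation uses exact (`math.fsum`) per-zone summation; regrouping
  error against the grand totals is at most a couple of ulp.
- Density sort ties break by region id; all series are emitted in ascending
  year order; trend tables derive the sign from sign(Z).
- Display rounding (2 dp percentages, 3 dp Z) happens only in display
  columns; full-precision values are carried in parallel columns of every
  CSV.
- Problem sizes in the test and acceptance suites (31 regions, 18 years,
  200–1000 replicates for calibration properties) match the study
  conditions the generator emulates.

## Known limitations

- The HRDI's numeric scale depends on the configured display units; only
  orderings and trends are asserted against reference behaviour.
- The balanced-panel requirement means real yearbook extracts with late-
  appearing regions must be completed or truncated by the user first.
- The Theil error on zero-resource regions is strict by design; extremely
  sparse tiers (e.g. institutions in city-states) may require the explicit
  exclusion filter and a documented interpretation change.
- `exact_null` covers n ≤ 10; beyond that the normal approximation is the
  only check, which is adequate at the 18-year series length used here.
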