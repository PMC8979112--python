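# Methods

## The pooled-AUC model

The package is built around one algebraic identity. For a sampling
schedule t₀ < … < tₙ the linear trapezoidal AUC is

    AUC = Σₖ (Cₖ + Cₖ₊₁)/2 · (tₖ₊₁ − tₖ) = Σₖ wₖ·Cₖ,

with half-interval weights w₀ = (t₁−t₀)/2, wₖ = (tₖ₊₁−tₖ₋₁)/2,
wₙ = (tₙ−tₙ₋₁)/2. If plasma aliquots are mixed with volumes vₖ ∝ wₖ, the
pooled concentration is Σwₖ·Cₖ/Σwₖ and, since Σwₖ = tₙ−t₀ telescopes,
multiplying by the span recovers the AUC exactly. The identity is exact
only for the **linear** trapezoid, which is why no log-linear variant is
offered.

Two conventions needed fixing where the printed ratio chain of the method
is ambiguous:

- the pre-dose (t₀) sample is included in the pool with weight (t₁−t₀)/2 —
  the realized clinical design (2.5 μL at 0 h out of 480 μL over the
  0–24 h schedule) is only consistent with this alignment;
- weights are stated as half-intervals; the conventional printed ratios
  omit the common factor ½, which cancels in proportions.

Schedules with t₀ > 0 are allowed; every formula uses tₙ−t₀, not tₙ.

### Volume rounding

`pooling_volumes` scales weights to a total volume and rounds to a
pipetting increment (default 0.1 μL, the resolution at which the clinical
480 μL design is exact; pass 0 for exact volumes). Rounding any volume by
more than 1% attaches a warning diagnostic; rounding a volume to zero is
an error because that time point would silently vanish from the pool.
Rounding perturbs the identity by at most the relative volume error; tests
verify < 0.5% for the clinical design over random non-negative profiles.

### Censoring and units

Values flagged below the lower limit of quantification are set to zero
before any pooling or AUC arithmetic and the flags are carried through to
outputs. When measurements are peak areas rather than calibrated
concentrations, AUCs carry "area·h" units; unit strings are opaque labels
and are never converted (semi-quantification: no reference standards are
assumed).

`percent_difference` is unsigned and uses the serial-trapezoid (traditional)
estimate as the reference denominator. Replicate summaries report mean ±
sample SD (n−1; SD 0 for a single replicate).

## Synthetic data generator

The generator produces the statistical structure the screening workflow
assumes, so every stage is testable without external data. It emulates an
oral-dose study sampled at 0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 10, 12, 24 h
with triplicate pooled measurements and a 480 μL pool.

- **Parent kinetics** — one-compartment first-order oral model,
  C(t) = F·D·ka/(V·(ka−ke))·(e^(−ke·t) − e^(−ka·t)); minimal model with a
  single peak and closed-form AUC₀₋∞ = F·D/(V·ke) used as a test oracle.
  ka = ke is rejected rather than special-cased.
- **Metabolites** — first-order formation from the parent's central
  compartment (rate = fraction × ke × parent amount) with elimination km,
  giving a three-exponential Bateman-type solution; when km collides with
  ka or ke (relative distance < 1e-6) the linear system is integrated
  numerically (LSODA, rtol 1e-10) instead — never a silent NaN. Mass
  balance AUCₘ/AUCₚ = fraction·ke/km is checked numerically in tests.
- **Species differences** — per-species multipliers on pathway formation
  fractions make sulfation dominant in the synthetic human and
  glucuronidation dominant in rodents, mirroring the qualitative species
  contrast in phase-II conjugation; fractions are validated to sum ≤ 1 per
  parent after scaling.
- **Assay noise** — multiplicative log-normal with unit mean and stated CV
  (default 10%), preserving non-negativity of areas; additive Gaussian
  noise was rejected because it can produce negative areas. LLOQ censoring
  flags and zeroes measurements below threshold.
- **Default panel** — 10 compounds (2 parents, 8 phase-II metabolites).
  Parameters are invented; the first parent carries the largest F·D/V so
  it dominates exposure, as the highest-exposure prototype compound does
  in the motivating application.
- **Pooled vs serial comparison** — in `pooled_vs_serial_trial` the two
  arms carry *independent* analytical noise: the pooled sample is mixed
  from true plasma and measured once per replicate, while the serial arm
  measures every time point. Pooling an already-measured noisy serial
  profile would reproduce its trapezoid AUC exactly by the identity and
  make the comparison vacuous.
- **Spectra** — Gaussian chromatographic peaks at fixed m/z with analytic
  area height·σ·√(2π), for validating the EIC extractor end to end.

What the generator does **not** emulate: enterohepatic recirculation and
secondary concentration peaks, nonlinear or saturable kinetics,
compound-to-compound conversion, plasma-protein binding, matrix effects,
retention-time drift, or isotope structure in spectra. Passing tests
therefore demonstrate the correctness of the pooling/estimation machinery
under the linear model, not robustness to those real-data features.

Randomness: every entry point takes an explicit integer seed; per-species
and per-compound streams are derived with `numpy.random.SeedSequence`
spawn keys, so adding a species or compound never perturbs the draws of
another. Same seed → byte-identical output tables.

## EIC quantification

Extraction sums centroid intensities within a **closed** ±ppm window
(boundary ties included — documented so it is bit-exact testable), one
point per spectrum with zeros kept. Integration is a plain trapezoid over
a user-supplied retention window: no smoothing, baseline model or peak
detection, matching the targeted semi-quantification use where retention
windows are known inputs. A window holding fewer than two trace points
yields area 0 with a warning. The [M−H]⁻ adduct constant
(−1.007276 Da) is provided as a helper, never auto-applied.
Internal-standard normalization (area ratio) is available but off by
default, since pooled-area workflows are internally consistent without it.
mzML reading supports 32/64-bit float arrays with optional zlib
compression via a small lxml-based reader.

## Exposure screening

Exposure = mean pooled area over replicates × (tₙ−t₀). Multiplying by the
fixed span does not change ranks, but keeps the quantity on the AUC scale.
Ties in exposure are broken by compound id ascending so rankings are
deterministic. Cross-species share is the fraction of another species'
total exposure carried by a reference compound set (a count-based reading
is available via `by_count=True`).

Correlation screening operates on percent profiles (each compound's serial
profile normalized to sum to 100% over time), which removes overall
abundance and compares shapes; raw-profile correlation remains available
by passing unnormalized profiles. Pearson r uses scipy's implementation
(the definitional sum formula is kept as an independent oracle in the
tests); the two-sided p comes from the exact t-distribution with n−2
degrees of freedom. No multiple-testing correction is applied — all raw
p-values are reported so users can apply their own procedure.

Q-marker selection: the candidate is the highest-ranked compound with an
obtainable reference substance; it is selected iff every other compound in
the top k (default 10) correlates with it at r > 0.8 and p < 0.001 (the
conventional screening bounds). Failures are explicit: each companion's r,
p and pass flags are recorded, missing correlations fail that companion,
and an empty candidate set yields a null-candidate report with a reason
rather than an exception.

## Pipeline

`run_pipeline` chains design → data (simulation or an external peak
table) → AUC method comparison → ranking → correlation → Q-marker report,
wrapping each stage so failures name the stage. Units are fixed
package-wide (hours, minutes for retention, microliters); floats are
serialized at full precision, with 2-decimal rounding only in the
human-readable summary. Provenance (config SHA-256, seed, version) is
embedded in the report and the serialized Q-marker document.

## Problem sizes

The method-comparison simulation uses 200 cohorts of 12 time points ×
3 replicates, enough to pin the median cohort difference to well under a
percentage point of Monte-Carlo error; the pooling-identity property is
checked over 1,000 random schedules/profiles; dense-grid oracles use
2×10⁴ points over 0–200 h (parent) and 4×10⁴ over 0–400 h (metabolite
mass balance), where discretization error is below the stated tolerances.

## Known limitations

- No AUC extrapolation to infinity, Cmax/Tmax or compartmental fitting of
  real data — the truncated AUC₀₋ₜₙ is the only exposure metric.
- One pooling design per run: unequal per-subject schedules cannot be
  mixed into a single pool.
- The pooled estimate inherits the trapezoid's discretization bias on
  sparse schedules; the method agrees with the serial trapezoid, not with
  the true integral.
- Q-marker selection is a correlation screen, not a causal or
  pharmacodynamic claim about the selected compound.
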