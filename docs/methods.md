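# Methods

## The model

Daily stand transpiration of a mature rubber-tree (*Hevea brasiliensis*)
plantation is simulated as a potential rate cut down by reduction factors.
Potential (maximal) transpiration is proportional to the FAO-56 reference
evapotranspiration of a grass surface,

    T_max = rm * ET0,

where `rm` is the ratio of maximal transpiration to ET0 under full canopy and
non-limiting water. Three constraints act on `T_max`:

* **Canopy phenology.** `r_LAI = LAI / LAI_max`. Rubber stands in sub-humid
  climates defoliate in the dry season (January–February, refoliation
  complete by late April); the LAI trajectory is a schematic piecewise-linear
  annual curve.
* **Soil water shortage.** `r_REWc = r_LAI` while the root-weighted relative
  extractable water of the topsoil exceeds a critical value `REWc`, and
  declines linearly to zero below it: `r_REWc = (r_LAI/REWc) * REW` for
  `REW <= REWc`. The factor is continuous at the threshold. REW itself is
  `(W - Wm)/(Wf - Wm)` per layer, aggregated over the 0–0.6 m active zone
  with fine-root-length weights (0.63/0.32/0.05); values above 1 indicate
  temporary waterlogging and are retained (the factor saturates anyway).
* **High evaporative demand.** Isohydric stomatal regulation saturates
  transpiration above a critical demand regardless of soil water:
  `r_ET0c = 1` for `ET0 <= ET0c` and `a*ln(ET0) + b` above, clamped into
  [0, 1].

The two simulated series are `T_mod = r_REWc * T_max` (soil constraint only)
and `T_mod_ET0c = min(r_REWc, r_ET0c) * T_max`. The min rather than a
product is deliberate: the soil and atmospheric limitations are alternative
bottlenecks, not independent multiplicative losses.

Default parameters (overridable everywhere): `rm = 1.0`, `LAI_max = 3.9`,
`REWc = 0.4`, `ET0c = 2.3 mm d⁻¹`, `a = −0.585`, `b = 1.2492`.

### Numerical choices

* **Discontinuity at ET0c.** With the default coefficients the log law
  evaluates to ≈0.762 at 2.3 mm d⁻¹, so the piecewise definition jumps from
  1 to 0.762 there. The default `continuity_mode="piecewise_as_printed"`
  keeps the jump; `"continuous_min"` uses `min(1, a·ln(ET0)+b)`, which stays
  at 1 up to `exp((1−b)/a) ≈ 1.53 mm d⁻¹` and is continuous. Both agree
  below that crossing.
* **Clamping.** The raw log law crosses zero near `exp(−b/a) ≈ 8.46 mm d⁻¹`,
  inside the observed demand range (up to ~9 mm d⁻¹); `r_ET0c` is clamped at
  0 because transpiration cannot be negative.
* **Stand scaling.** `T = 0.874 · Jout_day · (A_sapwood / A_ground)` with the
  sapwood-to-ground area ratio 0.0197/17.5 m². This is the dimensionally
  consistent form (kg m⁻² ground d⁻¹ ≡ mm d⁻¹); a version with an extra 10⁻²
  factor sometimes seen typeset alongside the sapwood area in scientific
  notation would predict ~0.02 mm d⁻¹ at realistic flux densities, two
  orders below any observed stand transpiration, and is treated as a
  typographical artifact.
* **Gap policy.** Missing weather intervals, incomplete days and missing
  observations propagate as NaN; the model itself refuses driver gaps so the
  user must gap-fill (see evaluation) or mask first.

## Measurement processing

* **ET0** is computed with the standard daily FAO-56 Penman–Monteith
  equation (Tetens saturation pressure, slope at the daily mean temperature,
  psychrometric constant from station elevation, net radiation from measured
  shortwave with the 0.23 reference albedo and the cloudiness/humidity
  longwave corrections). Actual vapour pressure defaults to
  `RHmean/100 · (es(Tmax)+es(Tmin))/2`.
* **VPDmax** is the maximum per-interval VPD when sub-daily records exist;
  with daily-only data the `vpd(Tmax, RHmin)` proxy is available and should
  be flagged by the caller.
* **Sap flow** uses the transient thermal dissipation (TTD) variant of the
  Granier probe: cyclic 10-min heating / 20-min cooling, signal
  `dT_a = dT_on − dT_off` with `dT_off` interpolated in time, transient
  index `Ka = (dT_0a − dT_a)/dT_a` against the nightly zero-flow maximum
  (pre-dawn window 03:00–06:00 by default, left-closed), and the
  non-species-specific calibration `Js = 12.95 × Ka × 10²` kg m⁻² h⁻¹.
  Negative Ka values are floored at 0 and counted; night-to-night zero-flow
  drift above 5% is flagged. The window and thresholds are configurable
  defaults, not measured facts.
* **Canopy conductance** inverts the well-coupled Penman–Monteith
  approximation `Gc = γλT/(Cpρ·VPD)` (γ = 66 Pa K⁻¹, λ = 2.45 MJ kg⁻¹,
  Cp = 1013 J kg⁻¹ K⁻¹, ρ = 1.204 kg m⁻³). Daily series pair each day's
  VPDmax with its maximum transpiration rate even though the two extremes
  need not be simultaneous — that daily-extrema pairing is the
  field-standard midday diagnostic; converting a daily depth to a peak rate
  assumes a half-sine diurnal course over an effective 12-h daylight window
  (peak = π/2 × the daylight mean). The VPD response is fitted as the
  log-linear form `Gc = G_ref − m·ln(VPD)`, which makes "reference
  conductance at 1 kPa" exact; the hyperbolic Lohammar form
  `G/(1 + VPD/VPD0)` is available as an option since the two conventions
  coexist in the literature and their "sensitivity" parameters are not
  interchangeable.

## Calibration

`calibrate()` (or `ReductionFactorModel.fit`) formalises what is usually
done by eye on scatter plots:

1. restrict to full-canopy days (`LAI ≥ 0.99·LAI_max`) with non-limiting
   soil water (`REW ≥ 0.5`);
2. `ET0c`: grid-searched breakpoint (step 0.1 mm d⁻¹) of a two-segment
   model — through-origin line below, log law above — minimising total SSE.
   A flat SSE profile (purely linear data fits both segments exactly at any
   split) returns the upper grid edge flagged degenerate;
3. `rm`: through-origin slope `Σxy/Σx²` with its standard error on the
   sub-critical-demand subset;
4. `(a, b)`: OLS of T/ET0 on ln(ET0) above the breakpoint, after discarding
   ratios above 1 (reference-crop mismatch and sap-flow overestimation at
   low flows produce super-unity ratios that would bias the law);
5. `REWc`: broken-stick grid search (step 0.05) on T/ET0 vs REW over
   full-canopy, sub-critical-demand days — the demand filter guarantees the
   soil factor is the binding one, so the sub-threshold points lie on the
   declining limb. The estimator refuses to run without observations below
   the non-limiting cutoff (no drying episode ⇒ threshold unidentifiable).

## Evaluation and diagnosis

`metrics` reports RMSE, RRMSE (per-point relative residuals) and R² (squared
Pearson correlation, reported as such). Measured values below 0.05 mm d⁻¹
are excluded from RRMSE with a count: relative errors on near-zero dry-season
fluxes are dominated by the sap-flow method's poor accuracy at low rates.
Gap filling replaces runs of up to 14 missing days with `ET0 × mean(T/ET0)`
over at least 4 valid surrounding days (up to 7 on each side); observed
values are never altered. Season windows: rainy May 1–Oct 31, dry the
calendar-clipped complement within the analysis year.

`run_factorial` simulates all 8 subsets of {LAI, REWc, ET0c} against the
potential `rm·ET0` at permanent full canopy and reports cumulative
regulation ratios per window. When REWc is active without LAI, the slope of
the soil factor uses 1 in place of `r_LAI` — the only reading under which a
singleton-REWc run is well defined, consistent with the observation that the
soil factor already embeds the canopy effect when both are on. Because
factors combine through products ≤ 1 and a final min, adding a factor can
never decrease the reduction (monotonicity in subset inclusion), which the
tests assert.

## Synthetic study conditions

The generator emulates one annual cycle of a drought-prone tropical
sub-humid site (6-month dry season November–April):

* ET0: sinusoid, mean 3.42 mm d⁻¹ (annual ≈ 1250 mm), amplitude 2.2,
  peak mid-March (doy 74), Gaussian noise sd 0.6, clipped to [0.5, 10] —
  reproducing the observed ~1–9 mm d⁻¹ envelope;
* rainfall: wet-season occurrence 0.5 d⁻¹ with gamma depths (mean ≈ 11 mm),
  dry-season occurrence 0.08; a mid-season dry spell (doy 182–225,
  occurrence ×0.05) reproduces the characteristic mid-rains topsoil drying
  into the critical range (REW minima ≈ 0.1–0.3 across seeds);
* topsoil bucket (0–0.6 m, Wf 0.21, Wm 0.07 m³ m⁻³): effective rainfall in
  (75% infiltration, 25 mm d⁻¹ cap), model-simulated uptake out, clipped to
  [Wm, Wf + 0.01] so short waterlogging episodes (REW slightly above 1) can
  occur. The bucket exists only to produce realistic REW trajectories — it
  is not a site water-balance model (runoff, drainage and soil evaporation
  are not represented);
* phenology: LAI_max 3.9 down to 0.4 between Jan 1 and doy 50, recovery by
  doy 120;
* observations: `T_obs = T_true × LogNormal` with mean exactly 1
  (σ² = ln(1+cv²), μ = −σ²/2), cv 0.1 by default — multiplicative because
  sap-flow scaling errors are proportional (tree-to-stand accuracy of order
  20% ≈ 2 cv). An exact inversion to hourly Ka signals (half-sine diurnal
  course, zero at night) closes the loop for testing the sap-flow chain.

What passing tests on this generator do **not** show: realism of rainfall
autocorrelation (no Markov persistence), root-profile dynamics (weights
constant all year), sub-daily stomatal behaviour, storage effects in the
tree, or measurement drift — agreement on synthetic data demonstrates
internal consistency and estimator correctness, not field validity.

## Problem sizes

All simulations are single 365-day years; calibration grids are coarse
(0.1 mm d⁻¹ / 0.05 REW). The whole test suite and the acceptance script
each complete in seconds on one CPU.

## Known limitations

* The piecewise demand law is stand- and clone-specific; its coefficients
  should be re-fitted before transfer to other sites.
* The "sensitivity" of the conductance fit depends on the chosen functional
  form; the package reports the form alongside the parameters and does not
  convert between them.
* Single-tree-mean scaling: stand transpiration uses one mean sapwood area
  and spacing, with no between-tree allometric distribution.
* The dry-season RRMSE is structurally inflated by near-zero measured
  fluxes; the floor exclusion is reported, not hidden.
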