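# Methods

## Scope and data flow

The package implements two connected analyses and the generator that feeds
them:

1. **Screen**: long-format kinetic trace tables (replicate, plate, well,
   time_s, fluorescence) plus plate layouts → per-well normalized maximal
   quench slopes → plate-wise robust Z-scores → replicate-aggregated,
   viability-filtered gene ranking (`screen.ScreenAnalysis` →
   `ScreenResults`).
2. **Electrophysiology**: sweep tables (sweep, time_s, voltage_mV,
   current_pA) and solution descriptors → reversal potentials, LJP
   correction, Nernst/GHK permeability analysis, Hill pH50 fits
   (`ephys`, with `HillPHActivation` → `HillFitResult`).

## Per-well slope statistic

The maximal quench slope is the most negative ordinary-least-squares slope
over all windows of 10 consecutive samples lying fully inside 20–100 s
(stride one sample, endpoints inclusive, ties broken toward the earliest
window).  Each window is centered before regression so a constant trace
yields exactly zero.  The baseline is the mean of all samples strictly before
reagent addition (10 s default, i.e. 10 samples at 1 Hz).

Normalization divides the raw slope by (well baseline mean − mean of
reporter-free background wells over their full traces).  This quotient is
invariant under common optical gain and offset, which is what plate-wise
standardization requires.  The alternative reading — dividing by the baseline
alone — is available via `baseline_only=True`.  A non-positive denominator
(baseline at or below background) marks the well invalid rather than
producing ±inf; invalid wells are excluded from plate statistics and count as
missing replicates downstream.

## Plate standardization and ranking

Z = (x − median)/MAD over a plate's *candidate* wells only, with the raw
(unscaled) MAD; the Gaussian consistency factor 1.4826 is available behind
`scaled_mad=True` but off by default.  A MAD of zero flags the plate
degenerate: its wells carry no Z rather than infinities.  Control wells
receive Z-scores against the candidate statistics for QC display only.

Per gene: the median of replicate Z-scores ranks; the median of replicate
*baseline* Z-scores gates viability at −0.5 (strictly below is filtered);
at least 2 valid replicates are required (3 are expected).  Because
knockdown of the quench pathway moves the signed slope toward zero — i.e.
*above* the (negative) plate median — hits have positive Z, and the default
`loss_of_signal` direction ranks **descending** in median Z.  Ties break by
lexicographic gene id, making output deterministic.

### What the −0.5 baseline filter necessarily does

MAD standardization guarantees, on every plate, that half the candidate
wells have |Z| > 1.  Consequently, for any continuous unimodal model of
baseline variation, the probability that a healthy gene's per-replicate
baseline Z falls below −0.5 is roughly 0.25–0.37, and the probability that
its *median of three* does is ~0.15–0.31.  The filter therefore always
removes a fixed quantile of the library — in our synthetic screens about 30%
— irrespective of noise scale or nuisance structure.  This is a property of
the published procedure itself, not of the generator; analyses that must not
lose healthy genes should treat the baseline Z as a QC annotation instead
(the flag and both medians are always present in the output table).

## Synthetic screen generator

The generator emulates a 384-well iodide-influx quench assay.  Iodide entry
is saturating-exponential, [I](t) = i_ss·(1 − e^(−k(t−t_add))) with
i_ss = 100 mM, and the reporter follows a Stern–Volmer-like hyperbola
F = bg + (f0 − bg)/(1 + [I]/ki_app).  Knockdown scales the entry rate,
k = k0·(1 − effect).  Defaults:

| parameter | default | rationale |
|---|---|---|
| f0, bg | 1000, 100 a.u. | ~10:1 reporter:background, typical plate-reader range |
| k0 | 0.010 s⁻¹ | maximizes the wild-type vs 80%-knockdown separation of the window statistic (forward scan of the noise-free model); puts the steep quench phase inside 20–100 s |
| ki_app | 30 mM | apparent iodide half-quench of the reporter; not established experimentally, configurable placeholder |
| t_add, duration, dt | 10, 300, 1 s | assay timing |
| noise_cv | 0.02 | per-sample fractional read noise at the upper end of FLIPR-class photometric CV; at this level a strong planted hit separates from the null by ~6 MAD units, consistent with a screen able to call a clear top hit |
| well_gain_sd | 0.08 | lognormal per-well optical/cell-density gain |
| plate_shift_sd | 15 a.u. | additive per-plate offset |
| no_fmrf / neutral_ph residual factors | 0.25 / 0.10 | reproduce the control-condition ordering: full quench > no-depolarization > neutral pH > no iodide (flat) |
| controls per plate | 4 × 4 types | plate real estate for controls; not dictated by any source, configurable |

`untransfected_mock` wells carry no reporter and emit background-level
fluorescence; the analysis uses them as the normalization background.
Replicates share the gene→well layout (screens re-run the same plates) and
redraw all noise; the pool-specific off-target perturbation (optional,
default 0) is drawn once and shared across replicates.

What the generator does **not** model: optics of the instrument, cell growth
and transfection efficiency, spatial edge gradients (hooks exist in the
nuisance model but default off), siRNA sequence effects, or pH artifacts on
the reporter.  Passing tests therefore demonstrate correctness of the
statistics under the stated noise structure, not robustness to every
plate-reader pathology.

## Channel model and recordings

Simulated whole-cell current:
I = g_max · a(pH_o) · r(V, t) · Σ_ion P_ion · GHK(V, c_in, c_out), with

* a(pH) = 1/(1 + 10^(n_h·(pH − pH50))), defaults pH50 = 5.3, n_h = 3;
  optional inactivation term 1/(1 + 10^(n_i·(pH_i − pH))) for the biphasic
  decline below pH ~5;
* r relaxing first-order (τ = 100 ms) toward a Boltzmann steady state
  (V½ = +40 mV, slope 25 mV), giving strong outward rectification with
  measurable inward current;
* per-ion constant-field (GHK) flux with integer valences from the ion
  registry (SO₄²⁻ uses z = −2 in the same equation); activities equal
  concentrations.

Because the gating factors multiply the whole flux sum, the zero-current
voltage of a noise-free ramp equals the GHK reversal voltage of the
permeability set — verified against a bracketed root search (`ghk_reversal`,
unique root on [−200, +200] mV by monotonicity) to 0.1 mV.

Ramp protocol: 100 ms at −80 mV then 500 ms from −80 to +80 mV (0.5 ms
steps); step protocol: 1 s steps, −80 to +80 mV in 20 mV increments, flanked
by 0.5 s at −80 mV.

## Electrophysiology analysis choices

* Temperature default 20 °C (recordings at room temperature); exposed
  everywhere.
* LJP sign convention: corrected = measured − LJP.  The shipped solution
  recipes carry the measured junction potentials of the selectivity baths
  against the NMDG-Cl pipette (4.5 mV NaCl, 4.3 mV NaI, 9.5 mV Na₂SO₄).
* E_rev extraction: optional pointwise background subtraction (same voltage
  grid required), centered 5-point boxcar (edge-truncated, disable with
  `smooth_pts=None`), linear interpolation between the bracketing samples of
  the sign change; with several crossings the one nearest the previous
  estimate (or 0 mV) is chosen; no crossing sets a flag instead of raising.
* Bi-ionic permeability ratios are computed for monovalent anions only;
  divalents raise a directed error and their ΔE_rev is reported as-is (no
  Lewis-equation extension).
* Hill fit: bounded trust-region least squares; initialization pH50 from the
  interpolated half-max crossing of per-pH mean |I|, n_h = 3, I_max at the
  largest-magnitude point; bounds n_h ∈ [0.5, 10], pH50 ∈ data range ± 1.
  Flat input (no transition) returns the initializer with
  `converged=False` rather than raising.  The functional form is the
  conventional choice; the fit is performed on +80 mV currents by default,
  with background subtraction left to the caller (subtracting the pH 7.4
  current when available is recommended).
* Series-resistance artifacts, capacitance transients and single-channel
  properties are out of scope.

## Numerical notes

* GHK currents use expm1 and a series expansion for |zFV/RT| < 1e-8, so the
  V = 0 singularity is removable to machine precision.
* Sliding-window OLS is evaluated vectorized over wells (windows centered
  before the dot product); a 2000-gene, 3-replicate screen analyzes in
  ~0.2 s.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical CSV output.

## Problem sizes used in the checks

The end-to-end recovery checks use 2000-gene, 3-replicate screens (6 plates
per replicate) over 100 seeds, and 300–800-gene screens for single-run
contracts; pH50 recovery uses 8 cells × 8 pH values.  These sizes give
stable statistics while keeping the full suite fast on a single CPU; the
full 18090-gene layout is exercised structurally (assignment and coverage)
rather than end-to-end.

## Known limitations

* The quench law and its parameters stand in for unpublished assay optics;
  only the *statistical* structure (monotone saturating quench, gain/offset
  nuisance, control ordering) is claimed to be faithful.
* The viability filter's fixed-quantile behavior (above) caps end-to-end
  planted-hit recovery at roughly the filter's survival rate (~70%), however
  strong the hit; measured rank-1 recovery under the default conditions is
  74/100 seeds, with the planted gene ranked first in every run it survived
  filtering.
* Degenerate plates (zero MAD) are flagged and excluded, not re-run; pooled
  siRNA deconvolution and spatial (B-score) corrections are not implemented.
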