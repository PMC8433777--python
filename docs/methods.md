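# Methods

## Scope and model

`hasec` implements relative (calibration-based) SEC analysis of a
polydisperse polymer, specialised to hyaluronic acid (HA). Two analytical
curves carry all quantitative information:

1. **Concentration curve** — ordinary least squares of peak area on
   concentration (mg/L), one curve per molecular-weight standard. Response
   factors genuinely differ between standards of different MW (an RI
   detector's response per unit mass drifts with hydrodynamic behaviour), so
   curves are never pooled; by default the curve of the standard nearest the
   sample's peak-average MW (in ln MW) quantifies the sample.
2. **Molecular-weight curve** — ordinary least squares of the partition
   coefficient Kav on the *natural* logarithm of standard MW. Kav is used
   instead of raw retention time because it normalises out column geometry:
   Kav = (Ve − V0)/(VT − V0). The slope must be negative; the inverse map
   exp((Kav − b)/a) converts observed retention into MW.

The distribution analysis divides the sample peak into degree-of-
polymerization (DP) fractions. The theoretical mass of a DP-mer is
M(DP) = 846.8·DP + 18 (disaccharide repeat plus terminal water); its
theoretical retention time follows from the MW curve. Fraction *i* (for
grid value DP_i) spans the retention window [tR(DP_{i+1}), tR(DP_i)], so
the windows partition the covered range exactly and the differential areas
telescope to the total peak area (asserted at 1e-6 relative in tests). The
moments use the areas directly as the abundances n_i:

    Mn = Σ nᵢMᵢ / Σ nᵢ        Mw = Σ nᵢMᵢ² / Σ nᵢMᵢ        Đ = Mw/Mn

**Caveat (convention, not bug):** an RI detector's area is proportional to
*mass*, not molar amount. Using areas as n_i therefore makes "Mn" a
mass-weighted mean, one moment higher than the strict molar definition.
This is the convention of the validated wet-lab method the package mirrors,
and the simulator's ground truth uses the same convention, so recoveries
are internally consistent. One visible consequence, tested: for a
log-symmetric peak the apex mass (Mp) lies *below* Mn (Jensen's
inequality), so the ordering is Mp ≤ Mn ≤ Mw — real samples can show
Mn < Mp < Mw through skew, but that ordering is not an invariant.

The DP grid defaults to integers 1..10 000 (M from 864.8 Da to ~8.47 MDa),
configurable (`dp_min`, `dp_max`, `dp_step`). Note DP = 1 is 864.8 Da under
M = 846.8·DP + 18; a quoted lower bound of 828 Da is inconsistent with that
mass law and is not used. DPw is (Mw − 18)/846.8 by the same inversion as
DPn.

## Column geometry and the t0 question

`ColumnGeometry` holds V0, VT, (metadata-only) Vc and the flow rate. The
void/total retention *times* t0/tT may be supplied directly or derived as
V0/flow and VT/flow. These two conventions can disagree — an
instrument-measured void time of 6.00 min at 0.8 mL/min implies 4.8 mL, not
the 6.87 mL void volume. Both are therefore expressible: supplied values
win, derived values fill in when absent. The simulator always uses the
derived, volume-consistent times so that its Kav ↔ time round trip is
exact. Kav values outside [0, 1] (full exclusion / adsorption) are returned
unclamped with a structured warning — clamping would hide real column
artefacts.

## Chromatogram processing

* **Integration** is trapezoidal on the native (possibly non-uniform) grid
  with linear interpolation of the signal at window edges: exact for
  piecewise-linear traces, exactly additive over adjacent windows. A
  cumulative form evaluates all 10 000 DP windows in one vectorised pass.
* **Baseline** subtracts the straight line joining the signal at a window's
  endpoints. On noisy traces a single-sample anchor tilts the baseline by
  the endpoint noise; the analysis workflow therefore anchors the line at
  the mean signal over 0.5 min just inside each endpoint
  (`endpoint_avg_min`, default 0 in the primitive itself — the exact
  endpoint behaviour and its idempotence are kept and tested).
* **Peak detection**: apex at the global maximum, bounds at the nearest
  crossings of `threshold_frac` × apex height (default 0.005) on each side,
  linearly interpolated. On noisy traces single samples dipping below the
  threshold truncate the peak at a noise-dependent point, which flaps the
  M²-weighted tail mass of Mw; the analysis workflow therefore locates apex
  and bounds on a 0.2-min boxcar-smoothed copy (`bound_smooth_min`, default
  0 in the primitive) while height and area always come from the raw trace.
* **Negative differential areas** (baseline noise) are clipped to zero
  *after* the area-conservation check, with a count carried into reports.
  Clipping biases tail moments upward when windows hold only noise, which
  is why the distribution is restricted to the detected peak window in the
  analysis workflow.

## Validation statistics

* CV = 100·s/mean with the sample (n−1) standard deviation.
* Repeatability % = 100 − pooled within-run CV (pooled variance weighted by
  degrees of freedom, over the grand mean); reproducibility % = 100 − CV of
  run means. The percentage transform is a reporting convention fixed here
  explicitly; the underlying CVs are always reported alongside.
* LOD = 3·σ/slope, LOQ = 10·σ/slope with σ a noise estimate in peak-area
  units. The 3/10 factor pair (not 3.3/10) is deliberate: it reproduces the
  reference tables, where LOD = 0.3·LOQ holds exactly for every standard.
  σ can come from a blank window of a trace (`blank_noise_sd`, optionally
  converted to area-equivalent units via a peak-width factor) or from the
  calibration's residual SD; the blank window is the default route.
* Acceptance flags implement CV < 5 % and slope significance at α = 0.05.

## The simulator: what it emulates, and what it does not

`SimulationSpec` emulates an isocratic aqueous SEC run with RI detection on
an Ultrahydrogel-2000-like column. Defaults are the study conditions of the
validated method and are fixed once:

| parameter | default | meaning |
|---|---|---|
| standards | 0.011, 0.095, 1.125, 2.2 MDa | MW calibration set |
| levels | 100–1000 mg/L, 7 levels | concentration design |
| Kav law | slope −0.132, intercept 2.079 | places standards at Kav 0.85–0.15 |
| concentration | 600 mg/L | mid-range sample |
| response factor | 190 area/(mg/L) | within the observed 186–224 range |
| peak sigma | 0.05 min | per-species instrumental broadening |
| noise sd | 400 signal units | ~0.4 % of a 600 mg/L apex |
| drift | 5 units/min | linear baseline drift |
| sampling | 0.01 min | detector export rate |

A log-normal MWD (mass-weighted in ln M) is discretised into 2000
log-spaced species over ±4σ; each species elutes as a Gaussian at its true
retention time with area ∝ mass fraction × concentration × response factor.
All randomness flows from one integer seed through
`numpy.random.default_rng`; a fixed seed gives bit-identical traces.
Ground-truth Mn/Mw/Đ are computed from the noiseless species table under
the same areas-as-n convention as the analysis.

Not modelled: plate-theory band broadening (a single σ stands in),
concentration-dependent viscosity effects, column temperature (metadata
only), pump/gradient behaviour, tailing (an EMG flag was considered and
left out — observed peaks are near-symmetric), inter-detector delay.
Passing recovery tests therefore demonstrates correctness of the
*numerical* pipeline under realistic noise, not robustness to every
instrumental artefact of real data.

## Numerical choices and problem sizes

* OLS fits and t distributions via scipy; two-point MW fits return the
  interpolating line with NaN standard errors (no residual df).
* Pipeline parameter-recovery tests use 20+ seeds of log-normal samples
  with true Đ in [1.18, 1.61] at the default noise level (replicate
  peak-area CV well under 1.7 %): recovered Mn/Mw within 5 %, Đ within
  0.05. Grid-refinement tests confirm halving the DP step moves moments by
  < 0.1 % on smooth peaks. The full suite runs in well under a minute.
* Extrapolation beyond the standards' MW or Kav range, sub-blank
  concentrations, out-of-[0,1] Kav and clipped areas all emit structured
  warnings that the analysis result counts and reports.

## Known limitations

* DP slicing trusts the MW calibration over its full extrapolated range
  (DP 1..10 000 spans far beyond the 0.011–2.2 MDa standards); the
  extrapolation warnings make this visible but cannot correct it.
* The areas-as-n convention (above) means "Mn" is not a strict molar
  number-average; comparisons with absolute methods (MALS) should expect a
  systematic offset for broad distributions.
* Instrumental broadening is not deconvolved; apparent dispersity is
  slightly inflated (≈ +0.003 at the default 0.05-min σ) and peak-window
  truncation slightly deflates it; the net bias stays within the tested
  bands.
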