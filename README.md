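# hasec

Simultaneous determination of **hyaluronic acid (HA) concentration and
molecular-weight distribution** from HPLC size-exclusion chromatography
(HPLC-SEC), as a reusable Python library: from a raw time–signal trace and
calibration standards to Mn, Mw, dispersity, degree-of-polymerization
averages, method-validation statistics (linearity, repeatability,
reproducibility, LOD/LOQ) and spike-recovery rates — plus a synthetic
chromatogram simulator that stands in for the instrument, so every stage is
testable end to end with known ground truth.

It is written for analytical and bioprocess scientists who quantify HA (or
similar polydisperse polysaccharides) in fermentation broths, cosmetics and
pharmaceuticals, and for anyone who wants SEC molecular-distribution
arithmetic as a library instead of vendor software.

## The method

A solute eluting at volume $V_e$ on a SEC column with void volume $V_0$ and
total retention volume $V_T$ has partition coefficient

$$K_{av} = \frac{V_e - V_0}{V_T - V_0},$$

linear in $\ln M$ over the column's working range:
$K_{av} = a\,\ln M + b$ with $a < 0$ (larger chains elute earlier).
HA chains of $DP$ disaccharide repeats have theoretical mass
$M(DP) = 846.8\,DP + 18$ Da, so each $DP$ maps to a theoretical retention
time $t_{R}(DP) = K_{av}(M(DP))\,(t_T - t_0) + t_0$. The sample peak is
sliced into the resulting per-DP windows; the differential areas $n_i$ give

$$\bar M_n = \frac{\sum n_i M_i}{\sum n_i},\qquad
  \bar M_w = \frac{\sum n_i M_i^2}{\sum n_i M_i},\qquad
  Đ = \bar M_w/\bar M_n,\qquad
  \overline{DP}_{n,w} = \frac{\bar M_{n,w} - 18}{846.8}.$$

Concentration comes from a second analytical curve, peak area vs. mg/L, fit
per MW standard. Detection limits use the signal-to-noise factors 3 and 10
(LOD = 3σ/slope, LOQ = 10σ/slope); repeatability/reproducibility are
100 − CV of within-/between-run replicates.

## Worked example

`python examples/02_analyze_sample.py` simulates a culture-broth-like sample
(log-normal MWD, median 0.9 MDa, detector noise and drift), calibrates from
simulated standards and analyzes the trace:

```
                 recovered        true
Mn (Da)          1,060,732    1,064,589
Mw (Da)          1,461,349    1,487,815
dispersity           1.378        1.398
peak MW (Da)       894,576      902,491
conc (mg/L)          598.2        600.0
DPn / DPw        1252.6 / 1725.7
peak window   [8.85, 12.97] min, area 113,664
```

The recovered number/weight-average masses sit within ~2 % of the simulator's
ground truth, the dispersity within 0.02, and the concentration within 0.3 %
of the spiked 600 mg/L. The other examples cover calibration
(`01_column_and_calibration.py`), method validation with acceptance flags
(`03_method_validation.py`) and spike recovery / content conversion
(`04_spike_recovery.py`).

A thin CLI wraps the same workflows for shell use
(`hasec simulate|calibrate-conc|calibrate-mw|analyze|validate|recover`);
chromatograms are plain CSV (`time_min,signal` with `# key: value` metadata
lines), reports JSON, vectors CSV.

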