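# Methods

## The measurement model

`squidms` analyses serial-injection isocratic LC-MS runs: samples are injected
into a continuous isocratic flow at a fixed cadence Δ (default 0.95 min), so
the target analyte of injection *i* elutes inside the window
[t₀ + iΔ, t₀ + (i+1)Δ). Each sample carries a uniformly ¹³C-labelled internal
standard of the analyte at a known concentration C_IS. Because the light and
heavy isotopologues co-elute exactly, any per-injection change in ionisation
efficiency (ion suppression by co-eluting matrix components, primarily salts)
multiplies both channels by the same factor sᵢ. The isotope ratio

    rᵢ = light peak area / heavy peak area

is therefore invariant to sᵢ, and the analyte concentration follows as

    cᵢ = rᵢ · C_IS            (direct isotope-dilution rule)

or, when a matrix-matched standard curve r = a·c + b is available, as
cᵢ = (rᵢ − b)/a. Both paths are implemented; the direct rule is the default
because it needs no calibration run and the isotopologue response factors are
assumed identical.

## Pipeline stages and their numerical choices

**Theoretical m/z** (`chem_masses`). Monoisotopic atomic masses are hardcoded
NIST values to 6 decimals; the protonated adduct uses the proton mass
1.007276 Da (not the hydrogen-atom mass), which reproduces the four published
polyamine [M+H]⁺ values (agmatine 131.1291 / 136.1459, putrescine
89.1073 / 93.1207) to four decimals. Only [M+H]⁺ at charge +1 is supported;
the adduct field is an extension point.

**mzML I/O** (`msdata_io`). Reading streams `<spectrum>` elements, accepts
only centroided MS1 scans (profile data raise an error rather than being
silently centroided), and normalises retention times to minutes whatever the
file's unit dialect, because all cadence arithmetic is in minutes. Writing
emits non-indexed mzML 1.1 with float64 m/z and float32 intensity arrays
(zlib + base64); conformance is checked in the test suite by round-tripping
through Bioconductor's mzR reader.

**EIC extraction** (`eic_extraction`). Per scan, intensities of all centroids
inside the closed ±10 ppm window are *summed* (robust to centroid splitting
at high resolving power; the per-scan maximum is a plausible alternative but
summation is the common convention). Binary search per spectrum; a
brute-force linear scan serves as the test oracle.

**Window segmentation** (`injection_windows`). Windows are half-open
[start, end) with boundary points assigned to the later window, strictly
periodic (drift is deliberately *not* modelled in the schedule — see
limitations). When t₀ is not supplied it is estimated from the
internal-standard trace: local maxima at least Δ/2 apart and above 20 % of
the trace maximum vote with their apex time modulo Δ; the circular median
phase φ is the consensus, and t₀ = φ − Δ/2 so apexes sit at window centres,
maximising the guard distance to both neighbours. The circular median (rather
than mean) makes the estimate robust to a minority of shifted or spurious
apexes. A guard band of `guard_fraction`·Δ (default 0.1) at each window edge
flags possible cross-interference from neighbouring injections; flagged peaks
are still integrated, never dropped.

**Peak integration** (`peak_integration`). One peak per window per channel by
design. Baseline: the minimum of the two window-edge medians (3 samples
each); a `zero` mode is available. Integration bounds: walk outward from the
apex of the baseline-subtracted trace to the nearest local minimum — but a
minimum only terminates the search once the trace has decayed below
max(3·noise, 5 % of apex height), so noise dips on the peak flank are walked
through; without an interior minimum the bounds clip to the window edges
(`saturated_bounds` flag). Area is the trapezoidal integral of the
baseline-subtracted, non-negative-clipped segment; at the default sampling of
σ/5 or better the quadrature error is well under 1 %. Truncating at the 5 %
decay level forfeits at most ~1.5 % of a Gaussian's tail area per side, and
the loss cancels in the isotope ratio because both channels share peak shape.

Detection: the noise level is the larger of (a) the standard deviation of the
guard-band edge samples, skipping an edge whose region contains the apex, and
(b) 1.4826·MAD of the whole corrected window (the peak occupies a minority of
samples, so the MAD tracks baseline noise). The detection statistic is the
maximum of a boxcar-smoothed trace (kernel = max(3, n/32) samples, well below
the chromatographic peak width) minus its median; a window fails detection at
3× noise — the same 3× convention as the LLOD — and is flagged `missing` with
zero area. The smoothing and median-centring exist because the maximum of
~100 noise samples would otherwise routinely exceed 3σ, producing false peaks
in blank windows. These detection/boundary rules are this package's own
reconstruction of serial-injection peak picking; they are not taken from any
published integrator.

**Quantification** (`isotope_quant`). Undefined ratios (heavy channel missing
or zero) propagate as flagged records, never exceptions — a 191-injection
batch must complete. Optional correction for an internal standard of isotopic
purity p subtracts heavy·(1−p)/p from the light area (clipped at 0); it is
off by default. The replicate QC metrics are
NRMSE = √(Σ(yᵢ−ŷ)²/n)/ŷ and the mean absolute percent error 100·mean|yᵢ−ŷ|/ŷ
against a known reference ŷ; "mean error" is interpreted as the *absolute*
percent deviation (a signed alternative would hide compensating errors).

**Calibration** (`calibration`). Weighted least squares of ratio on nominal
concentration; 1/x² weighting by default because a 3-decade range otherwise
lets the top standards dominate the fit. The noise level is the standard
deviation of blank-replicate ratios when ≥ 2 blanks exist, else the residual
standard deviation at the lowest calibrated level. LLOD = 3·noise/slope and
LLOQ = 10·noise/slope, so LLOQ/LLOD = 10/3 identically. A non-positive fitted
slope marks the curve invalid instead of yielding negative limits. The curve
NRMSE normalises the residual RMSE by the mean fitted ratio (the replicate
formula has a scalar reference; a curve does not).

## The simulator and what it does (not) emulate

`simulate` generates runs with exact ground truth: per injection *i*, Gaussian
peaks (σ = 0.05 min) for both channels at t₀ + Δ/2 + iΔ (+ optional linear
drift and apex jitter), with true areas sᵢ·ρ·cᵢ (light) and sᵢ·ρ·C_IS
(heavy) — the *same* lognormal suppression factor sᵢ on both channels, which
is the physical premise being tested. Centroids land at the theoretical m/z
± uniform 2 ppm jitter (inside the 10 ppm window); additive Gaussian baseline
noise is truncated at zero; optional interferent peaks elute at a configurable
phase offset. Defaults: cadence 0.95 min, 12 injections, scan interval
0.01 min (≥ σ/5 sampling), σ_s = 0.10, baseline noise 5 au against a response
of 2 au·min/nM (5000 nM spike ⇒ peak amplitude ≈ 8·10⁴ au), internal standard
250 nM. σ_s and the noise floor are assumptions chosen to give the realistic
qualitative regime — raw areas varying at the ~10 % level while ratios stay
flat — since no distributional data on suppression exist; they are not fitted
to anything. `simulate_dilution_series` realises the 50–50,000 nM, 4-replicate
calibration design; `simulate_cohort` mixes positives (lognormal around a
2170 nM median) with zero-concentration negatives in one shuffled run.

Not emulated: column salt-accumulation chemistry, gradient re-equilibration,
profile-mode m/z peak shapes, detector saturation, and retention drift as a
*schedule* property (drift is a simulator stressor only; the analysis windows
stay strictly periodic, a documented limitation for long batches). Passing
tests therefore demonstrate the correctness of the segmentation/integration/
ratio arithmetic under controlled conditions, not instrument-level accuracy
on real urine matrices — in particular, real-matrix detection limits cannot
be reproduced synthetically.

## Problem sizes

The test suite and the acceptance script use desk-scale runs: 12-injection
replicate sets, one 32-injection dilution series, and one 191-injection
cohort (~182 min of simulated chromatography at 0.01 min per scan), sizes at
which every check runs in seconds while exercising the full pipeline.

## Known limitations

- One peak per window per channel; overlapping or split peaks are counted in
  a QC field but not deconvolved.
- Phase estimation assumes at least two detectable internal-standard apexes
  and a common phase; multi-analyte schedules with different cadences are out
  of scope.
- The 3×-noise detection bar on a windowed maximum is a statistical
  compromise: blank windows are flagged missing ≳ 95 % of the time, not
  always.
- Natural-abundance ¹³C contribution to the heavy channel is ignored
  (negligible at M+4/M+5 separation), as is purity correction by default.
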