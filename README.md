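# squidms

Sequential quantification using isotope dilution (SQUID) for serial-injection
LC–MS: a Python engine that segments continuous serial-injection isocratic
chromatograms into per-sample elution windows, integrates light/heavy
isotopologue peaks, and quantifies target metabolites by isotope dilution —
plus a synthetic run simulator with exact ground truth.

## Who it is for

Targeted metabolomics and clinical screening groups running high-throughput
serial-injection assays (one sample every ~0.95 min into a continuous
isocratic HILIC flow), where a purpose-built tool is needed to bin extracted
ion chromatograms by injection window and correct the large injection-to-
injection ion-suppression variability with ¹³C-labelled internal standards.
The reference use case is screening urinary polyamines (agmatine,
putrescine) as markers of bacterial growth.

## The model

Each injection *i* elutes its target in the window [t₀ + iΔ, t₀ + (i+1)Δ)
at cadence Δ. Ion suppression multiplies the co-eluting light and heavy
isotopologue signals by the same factor sᵢ, so the ¹²C/¹³C peak-area ratio
rᵢ is suppression-invariant and

    cᵢ = rᵢ · C_IS

recovers the absolute concentration from an internal standard spiked at
C_IS. Standard curves (ratio vs nominal concentration, 1/x² weighted) give
LLOD = 3·noise/slope and LLOQ = 10·noise/slope; replicate precision is
NRMSE = √(Σ(yᵢ−ŷ)²/n)/ŷ. See `docs/methods.md` for every numerical choice.

## Worked example

Twelve technical replicates of a 5000 nM agmatine spike with a 500 nM
[U-¹³C]agmatine internal standard, under lognormal ion suppression
(σ_s = 0.10):

```python
import numpy as np, pandas as pd
from squidms import (SimulationConfig, simulate_run, InjectionSchedule,
                     integrate_run, quantify_pairs, nrmse, mean_percent_error)

targets = pd.DataFrame({
    "name": ["agmatine", "[U-13C]agmatine"],
    "formula": ["C5H14N4", "C5H14N4"],
    "n_labeled_13C": [0, 5],
    "role": ["analyte", "internal_standard"],
    "pair_id": ["agm", "agm"],
    "is_concentration_nM": [np.nan, 500.0],
    "mz": [131.129122, 136.145897],
})

config = SimulationConfig(n_injections=12, suppression_sigma=0.10,
                          is_concentration_nM=500.0, seed=42)
run, truth = simulate_run(config)
schedule = InjectionSchedule(t0=config.t0, cadence=config.cadence, n_injections=12)
peaks = integrate_run(run, targets, schedule)
quant = quantify_pairs(peaks, targets)

light = peaks[peaks["target_name"] == "agmatine"]["area"].to_numpy()
print(f"raw light-area NRMSE:        {nrmse(light, light.mean()):.3f}")
print(f"raw light-area mean error:   {mean_percent_error(light, 2.0 * 5000.0):.2f}%")
conc = quant["concentration_nM"].to_numpy()
print(f"corrected conc NRMSE:        {nrmse(conc, 5000.0):.4f}")
print(f"corrected conc mean error:   {mean_percent_error(conc, 5000.0):.2f}%")
```

prints

```
raw light-area NRMSE:        0.090
raw light-area mean error:   7.55%
corrected conc NRMSE:        0.0007
corrected conc mean error:   0.05%
```

Raw peak areas wander at the ~9 % level because every injection draws its own
suppression factor, but the isotope ratio cancels that factor, so the
corrected concentrations sit within a fraction of a percent of the true
5000 nM — the mechanism that makes serial-injection quantification viable.

## Command line

```bash
squid simulate  --seed 7 --out sim/                 # mzML + ground truth
squid quantify  --mzml sim/run.mzml --targets targets.csv \
                --schedule schedule.yaml --out quant/
squid calibrate --mzml cal.mzml --targets targets.csv \
                --schedule cal_schedule.yaml --design design.csv --out cal/
```

Every command echoes its fully-resolved configuration into the output
directory. Target tables (CSV/YAML) carry `name, formula, n_labeled_13C,
role, pair_id, is_concentration_nM`; schedules carry `t0` (optional — it is
estimated from the internal-standard trace when omitted), `cadence`,
`labels`, `guard_fraction`.

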