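"""Extracted ion chromatograms (EICs) from a run.

Per scan, the EIC intensity is the sum of all centroid intensities whose m/z
falls inside the closed target window; scans with no in-window centroid
contribute zero. Summation (rather than the per-scan maximum) is robust to
centroid splitting at high resolving power.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_masses import MzWindow
from .msdata_io import EmptyRunError, Run

__all__ = ["EIC", "extract_eic", "eics_to_csv"]


@dataclass
class EIC:
    """Intensity-vs-time trace for one m/z target, one value per run spectrum."""

    target_name: str
    window: MzWindow
    times: np.ndarray
    intensities: np.ndarray

    def __len__(self) -> int:
        return self.times.size


def extract_eic(run: Run, window: MzWindow, target_name: str = "") -> EIC:
    """Sum in-window centroid intensities per spectrum over the whole run.

    Uses binary search on each spectrum's sorted m/z array; both window bounds
    are inclusive.
    """
    if len(run) == 0:
        raise EmptyRunError("cannot extract an EIC from an empty run")
    times = np.empty(len(run))
    intensities = np.empty(len(run))
    for i, spectrum in enumerate(run.spectra):
        times[i] = spectrum.retention_time
        lo = np.searchsorted(spectrum.mz_values, window.lo, side="left")
        hi = np.searchsorted(spectrum.mz_values, window.hi, side="right")
        intensities[i] = spectrum.intensities[lo:hi].sum() if hi > lo else 0.0
    return EIC(target_name=target_name, window=window, times=times, intensities=intensities)


def eics_to_csv(eics: list[EIC], path: str | Path) -> Path:
    """Export EICs as long-format CSV (target, time_min, intensity)."""
    frames = [
        pd.DataFrame(
            {"target": eic.target_name, "time_min": eic.times, "intensity": eic.intensities}
        )
        for eic in eics
    ]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
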