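"""Standard curves, noise level and the 3x / 10x detection limits.

A dilution series of the unlabelled analyte (constant internal-standard spike)
gives observed isotope ratios versus nominal concentration. A weighted
least-squares line (default 1/x^2 weighting, appropriate for a 3-decade
range) provides slope and intercept; the noise level — the standard deviation
of blank-replicate ratios when blanks exist, else of the residuals at the
lowest calibrated level — sets the limits of detection and quantification at
3 and 10 times the noise respectively, so LLOQ/LLOD = 10/3 by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CalibrationError", "StandardCurve", "fit_curve", "limits", "quantify_with_curve"]

_WEIGHTS = {
    "none": lambda x: np.ones_like(x),
    "1/x": lambda x: 1.0 / x,
    "1/x2": lambda x: 1.0 / x**2,
}


class CalibrationError(ValueError):
    """Too few calibration levels, or an invalid fitted curve."""


@dataclass
class StandardCurve:
    """Fitted ratio-vs-concentration line with its noise level and limits."""

    points: pd.DataFrame = field(repr=False)
    slope: float
    intercept: float
    noise_level: float
    llod_nM: float
    lloq_nM: float
    nrmse: float
    weighting_mode: str = "1/x2"
    valid: bool = True

    def quantify(self, ratio: float) -> tuple[float, bool, bool]:
        """Invert the curve: returns (concentration_nM, below_llod, semi_quantitative)."""
        if not self.valid:
            raise CalibrationError("curve has a non-positive slope; cannot quantify")
        concentration = (ratio - self.intercept) / self.slope
        below_llod = concentration < self.llod_nM
        semi = self.llod_nM <= concentration < self.lloq_nM
        return concentration, below_llod, semi

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        report = {
            "slope_per_nM": self.slope,
            "intercept": self.intercept,
            "noise_level": self.noise_level,
            "llod_nM": self.llod_nM,
            "lloq_nM": self.lloq_nM,
            "nrmse": self.nrmse,
            "weighting_mode": self.weighting_mode,
            "valid": self.valid,
            "n_points": int(len(self.points)),
        }
        path.write_text(json.dumps(report, indent=2))
        return path


def limits(noise_level: float, slope: float) -> tuple[float, float]:
    """LLOD and LLOQ in concentration units: 3x and 10x noise over slope."""
    if noise_level < 0:
        raise ValueError("noise level must be >= 0")
    if slope <= 0:
        raise ValueError("slope must be positive")
    return 3.0 * noise_level / slope, 10.0 * noise_level / slope


def fit_curve(
    points: pd.DataFrame,
    weighting_mode: str = "1/x2",
    noise_mode: str = "auto",
) -> StandardCurve:
    """Fit ratio on nominal concentration by weighted least squares.

    ``points`` needs ``nominal_nM`` and ``ratio`` columns (replicates as
    repeated rows). Blank rows (``nominal_nM == 0``) are excluded from the fit
    but define the noise level when present (``noise_mode="auto"`` or
    ``"blank_sd"``); otherwise the residual standard deviation at the lowest
    level is used (``"low_level_residual_sd"``). A fitted slope <= 0 marks the
    curve invalid rather than producing negative limits.
    """
    if weighting_mode not in _WEIGHTS:
        raise ValueError(f"unknown weighting_mode {weighting_mode!r}")
    points = points.dropna(subset=["ratio"]).copy()
    blanks = points[points["nominal_nM"] <= 0]
    cal = points[points["nominal_nM"] > 0]
    if cal["nominal_nM"].nunique() < 3:
        raise CalibrationError(
            f"need >= 3 distinct nonzero concentrations, got {cal['nominal_nM'].nunique()}"
        )
    x = cal["nominal_nM"].to_numpy(dtype=float)
    y = cal["ratio"].to_numpy(dtype=float)
    weights = _WEIGHTS[weighting_mode](x)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(weights))

    fitted = slope * x + intercept
    residuals = y - fitted
    curve_nrmse = float(np.sqrt(np.mean(residuals**2)) / np.mean(np.abs(fitted)))

    use_blanks = noise_mode in {"auto", "blank_sd"} and len(blanks) >= 2
    if noise_mode == "blank_sd" and len(blanks) < 2:
        raise CalibrationError("blank_sd noise mode requires >= 2 blank replicates")
    if use_blanks:
        noise_level = float(np.std(blanks["ratio"].to_numpy(dtype=float), ddof=1))
    else:
        lowest = cal["nominal_nM"].min()
        low_res = residuals[x == lowest]
        ddof = 1 if low_res.size > 1 else 0
        noise_level = float(np.std(low_res, ddof=ddof))

    valid = bool(slope > 0)
    if valid:
        llod, lloq = limits(noise_level, slope)
    else:
        llod = lloq = float("nan")
    return StandardCurve(
        points=points,
        slope=float(slope),
        intercept=float(intercept),
        noise_level=noise_level,
        llod_nM=llod,
        lloq_nM=lloq,
        nrmse=curve_nrmse,
        weighting_mode=weighting_mode,
        valid=valid,
    )


def quantify_with_curve(ratio: float, curve: StandardCurve) -> tuple[float, bool, bool]:
    """Module-level alias of :meth:`StandardCurve.quantify`."""
    return curve.quantify(ratio)
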