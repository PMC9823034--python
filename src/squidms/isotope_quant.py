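"""Isotope-dilution quantification and replicate-precision QC metrics.

The central identity of isotope dilution: a per-injection ion-suppression
factor multiplies the light and heavy channel equally (the isotopologues
co-elute and experience the same matrix), so the 12C/13C peak-area ratio is
invariant to suppression and the analyte concentration follows directly as
``ratio * C_IS`` for an internal standard spiked at ``C_IS``.

QC metrics are the replicate-precision statistics used for serial-injection
validation: NRMSE ``sqrt(sum((y_i - y_hat)^2)/n) / y_hat`` against a known
reference value, and the mean absolute percent error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import StandardCurve

__all__ = [
    "IsotopeQuantResult",
    "QcMetrics",
    "isotope_ratio",
    "purity_correct",
    "concentration_from_ratio",
    "nrmse",
    "mean_percent_error",
    "quantify_pairs",
]


@dataclass
class IsotopeQuantResult:
    """Per-sample quantification from one light/heavy channel pair."""

    sample_label: str
    light_area: float
    heavy_area: float
    ratio: float | None
    concentration_nM: float | None
    below_llod: bool = False
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class QcMetrics:
    """Replicate-block precision against a known reference value."""

    n: int
    mean_percent_error: float
    nrmse: float


def isotope_ratio(light_area: float, heavy_area: float) -> float | None:
    """12C/13C area ratio; ``None`` (undefined) when the heavy channel is absent.

    An undefined ratio is a flagged record, not an exception: a long clinical
    batch must run to completion.
    """
    if light_area < 0 or heavy_area < 0:
        raise ValueError("peak areas must be non-negative")
    if heavy_area <= 0:
        return None
    return light_area / heavy_area


def purity_correct(light_area: float, heavy_area: float, purity: float) -> float:
    """Remove the light-channel signal contributed by an impure labelled standard.

    A labelled standard of isotopic purity ``p`` carries a light contamination
    of ``(1 - p)/p`` relative to its heavy signal; the corrected light area is
    clipped at zero.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    corrected = light_area - heavy_area * (1.0 - purity) / purity
    return max(corrected, 0.0)


def concentration_from_ratio(
    ratio: float | None, is_concentration_nM: float, response_factor: float = 1.0
) -> float | None:
    """Absolute concentration from the isotope ratio and the IS spike level.

    ``response_factor`` defaults to 1 (identical ionisation of isotopologues);
    a standard-curve slope can be supplied instead.
    """
    if is_concentration_nM <= 0:
        raise ValueError("internal-standard concentration must be positive")
    if response_factor <= 0:
        raise ValueError("response factor must be positive")
    if ratio is None:
        return None
    return ratio * is_concentration_nM / response_factor


def nrmse(y: np.ndarray, y_hat: float) -> float:
    """Normalised root-mean-square error against a scalar reference value."""
    y = np.asarray(y, dtype=float)
    if y.size < 1:
        raise ValueError("need at least one observation")
    if y_hat == 0:
        raise ValueError("reference value must be nonzero")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)) / y_hat)


def mean_percent_error(y: np.ndarray, y_hat: float) -> float:
    """Mean absolute percent deviation from a known reference value."""
    y = np.asarray(y, dtype=float)
    if y.size < 1:
        raise ValueError("need at least one observation")
    if y_hat == 0:
        raise ValueError("reference value must be nonzero")
    return float(np.mean(np.abs(y - y_hat) / abs(y_hat)) * 100.0)


def replicate_qc(y: np.ndarray, y_hat: float) -> QcMetrics:
    return QcMetrics(
        n=len(np.atleast_1d(y)),
        mean_percent_error=mean_percent_error(y, y_hat),
        nrmse=nrmse(y, y_hat),
    )


def quantify_pairs(
    peak_results: pd.DataFrame,
    targets: pd.DataFrame,
    purity: float | None = None,
    curve: "StandardCurve | None" = None,
) -> pd.DataFrame:
    """Join light/heavy peak areas per injection and quantify each pair.

    ``peak_results`` is the table from
    :func:`squidms.peak_integration.integrate_run`; ``targets`` the target
    table with ``role`` (analyte / internal_standard), ``pair_id`` and
    ``is_concentration_nM`` columns. Optional isotopic-purity correction of
    the light area and optional standard-curve quantification (otherwise the
    direct ``ratio * C_IS`` rule). One output row per (injection x pair);
    undefined ratios are flagged, never raised.
    """
    rows = []
    for pair_id, pair in targets.groupby("pair_id"):
        analytes = pair[pair["role"] == "analyte"]
        standards = pair[pair["role"] == "internal_standard"]
        if len(analytes) != 1 or len(standards) != 1:
            raise ValueError(f"pair {pair_id!r} must have exactly one analyte and one IS")
        analyte, standard = analytes.iloc[0], standards.iloc[0]
        is_conc = float(standard["is_concentration_nM"])
        light = peak_results[peak_results["target_name"] == analyte["name"]]
        heavy = peak_results[peak_results["target_name"] == standard["name"]]
        merged = light.merge(
            heavy, on=["window_index", "sample_label"], suffixes=("_light", "_heavy")
        )
        for _, row in merged.iterrows():
            flags = set()
            for col in ("flags_light", "flags_heavy"):
                if row[col]:
                    flags.update(row[col].split(";"))
            light_area = float(row["area_light"])
            heavy_area = float(row["area_heavy"])
            if purity is not None:
                light_area = purity_correct(light_area, heavy_area, purity)
            heavy_missing = "missing" in (row["flags_heavy"] or "")
            ratio = None if heavy_missing else isotope_ratio(light_area, heavy_area)
            if ratio is None:
                flags.add("undefined_ratio")
                concentration, below_llod = None, False
            elif curve is not None:
                concentration, below_llod, semi = curve.quantify(ratio)
                if semi:
                    flags.add("semi_quantitative")
            else:
                concentration = concentration_from_ratio(ratio, is_conc)
                below_llod = False
            rows.append(
                {
                    "window_index": int(row["window_index"]),
                    "sample_label": row["sample_label"],
                    "pair_id": pair_id,
                    "light_area": light_area,
                    "heavy_area": heavy_area,
                    "ratio": ratio,
                    "concentration_nM": concentration,
                    "below_llod": below_llod,
                    "flags": ";".join(sorted(flags)),
                }
            )
    return pd.DataFrame(rows).sort_values(["pair_id", "window_index"]).reset_index(drop=True)
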