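"""Serial-injection cadence model: per-sample elution windows on the time axis.

In a serial-injection isocratic run every sample's target peak elutes at the
same cadence as the injections themselves, so the chromatogram partitions into
contiguous, equal-width, half-open windows ``[t0 + i*cadence, t0 + (i+1)*cadence)``
— one per injection. ``t0`` may be supplied from the instrument schedule or
estimated from the internal-standard trace, whose apexes repeat at the cadence:
each apex time modulo the cadence is a phase sample, the circular median phase
is the consensus apex position, and ``t0`` is placed half a cadence earlier so
apexes sit at window centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as _signal

from .eic_extraction import EIC

__all__ = [
    "ScheduleError",
    "PhaseEstimationError",
    "InjectionSchedule",
    "InjectionWindow",
    "WindowSlice",
    "build_schedule",
    "estimate_phase",
    "assign_windows",
    "load_schedule",
]


class ScheduleError(ValueError):
    """Invalid cadence, label count or window geometry."""


class PhaseEstimationError(RuntimeError):
    """Too few apexes to estimate the injection phase; supply t0 manually."""


@dataclass(frozen=True)
class InjectionWindow:
    """Half-open elution window ``[t_start, t_end)`` of one injection."""

    index: int
    t_start: float
    t_end: float
    sample_label: str

    @property
    def width(self) -> float:
        return self.t_end - self.t_start

    @property
    def center(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class InjectionSchedule:
    """Cadence model for one serial-injection run.

    ``guard_fraction`` is the fraction of the cadence at each window edge
    treated as a guard band: a peak apex landing there is flagged as possible
    cross-interference with the neighbouring injection, never dropped.
    """

    t0: float
    cadence: float
    n_injections: int
    sample_labels: list[str] = field(default_factory=list)
    guard_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ScheduleError(f"cadence must be positive, got {self.cadence}")
        if self.n_injections < 1:
            raise ScheduleError("need at least one injection")
        if not self.sample_labels:
            self.sample_labels = [f"inj{i:03d}" for i in range(self.n_injections)]
        if len(self.sample_labels) != self.n_injections:
            raise ScheduleError(
                f"{len(self.sample_labels)} labels for {self.n_injections} injections"
            )
        if not 0 <= self.guard_fraction < 0.5:
            raise ScheduleError("guard_fraction must be in [0, 0.5)")

    def windows(self) -> list[InjectionWindow]:
        return build_schedule(self.t0, self.cadence, self.n_injections, self.sample_labels)


def build_schedule(
    t0: float, cadence: float, n_injections: int, labels: list[str] | None = None
) -> list[InjectionWindow]:
    """Lay out ``n_injections`` contiguous half-open windows of width ``cadence``."""
    if cadence <= 0:
        raise ScheduleError(f"cadence must be positive, got {cadence}")
    if n_injections < 1:
        raise ScheduleError("need at least one injection")
    if labels is None:
        labels = [f"inj{i:03d}" for i in range(n_injections)]
    if len(labels) != n_injections:
        raise ScheduleError(f"{len(labels)} labels for {n_injections} injections")
    return [
        InjectionWindow(
            index=i,
            t_start=t0 + i * cadence,
            t_end=t0 + (i + 1) * cadence,
            sample_label=labels[i],
        )
        for i in range(n_injections)
    ]


def _circular_median(phases: np.ndarray, cadence: float) -> float:
    """Phase minimising the summed circular distance to all observed phases."""
    best_phase, best_cost = phases[0], np.inf
    for candidate in phases:
        delta = np.abs(phases - candidate)
        cost = np.minimum(delta, cadence - delta).sum()
        if cost < best_cost:
            best_phase, best_cost = candidate, cost
    return float(best_phase)


def estimate_phase(
    is_eic: EIC,
    cadence: float,
    n_injections: int,
    min_relative_height: float = 0.2,
) -> tuple[float, int]:
    """Estimate the first window start ``t0`` from internal-standard apexes.

    Local maxima above a noise floor (``min_relative_height`` of the trace
    maximum, at least half a cadence apart) vote with their apex time modulo
    the cadence; the circular median phase centres the windows. Returns
    ``(t0, n_peaks_used)`` with ``t0`` normalised into ``[0, cadence)``.
    """
    intensities = np.asarray(is_eic.intensities, dtype=float)
    if intensities.size < 3 or intensities.max() <= 0:
        raise PhaseEstimationError("internal-standard EIC is flat or too short")
    dt = float(np.median(np.diff(is_eic.times)))
    distance = max(1, int(round(0.5 * cadence / dt)))
    peaks, _ = _signal.find_peaks(
        intensities, height=min_relative_height * intensities.max(), distance=distance
    )
    if peaks.size < 2:
        raise PhaseEstimationError(f"only {peaks.size} apex(es) detected; need >= 2")
    apex_times = np.asarray(is_eic.times)[peaks]
    phases = np.mod(apex_times, cadence)
    phi = _circular_median(phases, cadence)
    t0 = float(np.mod(phi - cadence / 2.0, cadence))
    return t0, int(peaks.size)


@dataclass
class WindowSlice:
    """The EIC samples falling inside one injection window."""

    window: InjectionWindow
    times: np.ndarray
    intensities: np.ndarray
    empty: bool = False


def assign_windows(eic: EIC, windows: list[InjectionWindow]) -> list[WindowSlice]:
    """Slice an EIC into per-window segments; ``t_start <= t < t_end`` membership.

    Windows must be sorted and non-overlapping. A window entirely outside the
    EIC time span yields an empty, flagged slice.
    """
    for a, b in zip(windows, windows[1:]):
        if b.t_start < a.t_end - 1e-12:
            raise ScheduleError(f"windows {a.index} and {b.index} overlap")
    times = np.asarray(eic.times)
    slices = []
    for window in windows:
        lo = np.searchsorted(times, window.t_start, side="left")
        hi = np.searchsorted(times, window.t_end, side="left")
        slices.append(
            WindowSlice(
                window=window,
                times=times[lo:hi],
                intensities=np.asarray(eic.intensities)[lo:hi],
                empty=hi == lo,
            )
        )
    return slices


def load_schedule(path: str | Path) -> InjectionSchedule:
    """Load a schedule file (YAML mapping or CSV with one label per row).

    YAML keys: ``t0`` (optional; omit to estimate from data), ``cadence``,
    ``labels``, ``guard_fraction``. CSV needs a ``sample_label`` column and
    ``cadence``/``t0``/``guard_fraction`` columns whose first-row values apply
    to the whole run.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        labels = [str(label) for label in spec["labels"]]
        return InjectionSchedule(
            t0=float(spec.get("t0", np.nan)),
            cadence=float(spec["cadence"]),
            n_injections=len(labels),
            sample_labels=labels,
            guard_fraction=float(spec.get("guard_fraction", 0.1)),
        )
    import pandas as pd

    table = pd.read_csv(path)
    if "sample_label" not in table.columns:
        raise ScheduleError(f"{path}: CSV schedule needs a sample_label column")
    labels = [str(label) for label in table["sample_label"]]
    first = table.iloc[0]
    return InjectionSchedule(
        t0=float(first["t0"]) if "t0" in table.columns else float("nan"),
        cadence=float(first["cadence"]),
        n_injections=len(labels),
        sample_labels=labels,
        guard_fraction=float(first.get("guard_fraction", 0.1)),
    )
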