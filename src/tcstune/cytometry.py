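"""Event-level flow-cytometry quantification chain.

Reproduces the fixed processing order used for bacterial reporter
quantification: discard the first 250 and last 100 time-ordered events,
keep the densest 10% of events in log FSC/SSC space (bacterial cells form
a tight scatter cluster; debris is diffuse), optionally require a minimum
FL3 (constitutive mCherry) signal, convert FL1 detector units to MEFL
(molecules of equivalent fluorescein) through a log-log line fit to
calibration-bead peaks, summarize by the geometric mean, and subtract
measured autofluorescence.  :func:`process_sample` is the single entry
point enforcing that order.

Event tables are plain pandas DataFrames with columns
``order_index, fsc, ssc, fl1, fl3`` (FCS binary parsing is out of scope;
tables arrive as CSV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "BeadStandard",
    "CalibrationCurve",
    "PopulationSummary",
    "validate_events",
    "trim_events",
    "density_gate",
    "calibrate_mefl",
    "summarize_population",
    "process_sample",
]

EVENT_COLUMNS = ("order_index", "fsc", "ssc", "fl1", "fl3")

#: detector-unit floor applied before any log transform
CHANNEL_FLOOR = 1.0

#: fixed resolution of the binned FSC/SSC density estimator
DENSITY_BINS = 64


def validate_events(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if len(table) and np.any(np.diff(table["order_index"].to_numpy()) <= 0):
        raise ValueError("order_index must be strictly increasing")
    chan = table[list(EVENT_COLUMNS[1:])].to_numpy(dtype=float)
    if np.any(~np.isfinite(chan)) or np.any(chan < 0):
        raise ValueError("channel values must be finite and >= 0")
    return table


def trim_events(table: pd.DataFrame, n_first: int = 250,
                n_last: int = 100) -> pd.DataFrame:
    """Drop the first ``n_first`` and last ``n_last`` acquisition-ranked events.

    Removes flow-startup and end-of-sample artifacts.  If nothing remains,
    an empty table is returned with a warning (never silent truncation of
    the rule itself).
    """
    validate_events(table)
    n = len(table)
    if n <= n_first + n_last:
        warnings.warn(
            f"trim_events: only {n} events, <= {n_first}+{n_last}; result is empty",
            stacklevel=2,
        )
        return table.iloc[0:0].copy()
    return table.iloc[n_first:n - n_last].copy()


def _bin_index(values: np.ndarray, n_bins: int) -> np.ndarray:
    logv = np.log10(np.maximum(values, CHANNEL_FLOOR))
    lo, hi = logv.min(), logv.max()
    if hi <= lo:
        return np.zeros(len(values), dtype=int)
    idx = np.floor((logv - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def density_gate(table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep the ``ceil(fraction * N)`` events in the densest FSC/SSC region.

    Density is a fixed 64x64 2-D histogram on log10(FSC), log10(SSC)
    spanning each channel's observed range; events are ranked by their
    bin's count (ties broken by acquisition order) and the top fraction
    kept, preserving acquisition order in the output.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    validate_events(table)
    n = len(table)
    if n < 50:
        raise ValueError(f"density_gate needs >= 50 events, got {n}")
    ix = _bin_index(table["fsc"].to_numpy(dtype=float), DENSITY_BINS)
    iy = _bin_index(table["ssc"].to_numpy(dtype=float), DENSITY_BINS)
    flat = ix * DENSITY_BINS + iy
    counts = np.bincount(flat, minlength=DENSITY_BINS * DENSITY_BINS)
    density = counts[flat]
    k = math.ceil(fraction * n)
    # primary key: density desc; secondary: acquisition order asc
    order = np.lexsort((np.arange(n), -density))
    keep = np.sort(order[:k])
    return table.iloc[keep].copy()


@dataclass
class BeadStandard:
    """Calibration-bead peak table: FL1 detector peak vs. known MEFL."""

    fl1_peaks: np.ndarray
    mefl: np.ndarray

    def __post_init__(self) -> None:
        self.fl1_peaks = np.asarray(self.fl1_peaks, dtype=float)
        self.mefl = np.asarray(self.mefl, dtype=float)
        if len(self.fl1_peaks) != len(self.mefl):
            raise ValueError("fl1_peaks and mefl must have equal length")
        if len(self.fl1_peaks) < 3:
            raise ValueError("need >= 3 usable bead peaks")
        if np.any(self.fl1_peaks <= 0) or np.any(self.mefl <= 0):
            raise ValueError("bead peaks and MEFL values must be > 0")
        order = np.argsort(self.fl1_peaks)
        self.fl1_peaks = self.fl1_peaks[order]
        self.mefl = self.mefl[order]
        if np.any(np.diff(self.mefl) <= 0) or np.any(np.diff(self.fl1_peaks) <= 0):
            raise ValueError("MEFL must be strictly increasing with fl1_peak")

    @classmethod
    def read_csv(cls, path) -> "BeadStandard":
        df = pd.read_csv(path)
        return cls(df["fl1_peak"].to_numpy(), df["mefl"].to_numpy())


@dataclass(frozen=True)
class CalibrationCurve:
    """log10(MEFL) = intercept + slope * log10(FL1), least-squares on bead peaks."""

    slope: float
    intercept: float
    fit_r2: float

    def apply(self, fl1) -> np.ndarray | float:
        fl1 = np.asarray(fl1, dtype=float)
        out = 10.0 ** (self.intercept
                       + self.slope * np.log10(np.maximum(fl1, CHANNEL_FLOOR)))
        return float(out) if out.ndim == 0 else out


def calibrate_mefl(beads: BeadStandard) -> CalibrationCurve:
    """Fit the day's MEFL standard curve from calibration-bead peaks."""
    x = np.log10(beads.fl1_peaks)
    y = np.log10(beads.mefl)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("calibration slope must be > 0")
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(float(slope), float(intercept), float(r2))


@dataclass(frozen=True)
class PopulationSummary:
    geo_mean_mefl: float
    sfgfp_mefl: float      # geo mean minus autofluorescence
    n_events: int
    below_lod: bool
    n_floored: int = 0     # events whose FL1 hit the detector-unit floor


def summarize_population(
    table: pd.DataFrame,
    curve: CalibrationCurve,
    autofluorescence: float,
    lod: float,
    fl3_min: float | None = None,
) -> PopulationSummary:
    """Geometric-mean MEFL of a (trimmed, gated) population, minus autofluorescence.

    ``fl3_min``, when given, first removes events below a constitutive-marker
    threshold (the soil workflow's mCherry selection).  sfGFP below the LOD
    (3 * sigma of autofluorescence) is flagged ``below_lod``.
    """
    validate_events(table)
    if lod <= 0:
        raise ValueError("lod must be > 0")
    if fl3_min is not None:
        table = table[table["fl3"] >= fl3_min]
    if len(table) == 0:
        raise ValueError("no events left to summarize")
    fl1 = table["fl1"].to_numpy(dtype=float)
    n_floored = int(np.sum(fl1 < CHANNEL_FLOOR))
    mefl = np.asarray(curve.apply(fl1), dtype=float)
    geo = float(np.exp(np.mean(np.log(mefl))))
    sfgfp = geo - autofluorescence
    return PopulationSummary(geo, sfgfp, len(table), sfgfp < lod, n_floored)


def process_sample(
    table: pd.DataFrame,
    beads: BeadStandard,
    autofluorescence: float,
    lod: float,
    gate_fraction: float = 0.10,
    fl3_min: float | None = None,
) -> PopulationSummary:
    """The full chain in its fixed order: trim -> density gate -> (FL3 gate)
    -> bead calibration -> geometric mean -> autofluorescence subtraction."""
    trimmed = trim_events(table)
    gated = density_gate(trimmed, gate_fraction)
    curve = calibrate_mefl(beads)
    return summarize_population(gated, curve, autofluorescence, lod, fl3_min)
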