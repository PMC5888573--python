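"""Population-heterogeneity statistics for flow-cytometry-like samples.

Operates on vectors of per-event (or per-cell) fluorescence values in
arbitrary units: Shannon entropy of the log-scaled histogram, squared
coefficient of variation, threshold tail fraction, and kernel-density mode
detection for uni-/bimodality calls.  Entropy and mode detection work on
log10-transformed values, mirroring logarithmic flow-cytometry channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, ParameterError, StateError

#: default binning: 256 bins across 4 log10 decades, a coarsened version of a
#: 1024-channel 4-decade log amplifier
DEFAULT_N_BINS = 256
DEFAULT_DECADES = 4.0


@dataclass
class FlowSample:
    """A vector of per-event fluorescence values with channel metadata."""

    values: np.ndarray
    decades: float = DEFAULT_DECADES
    n_channels: int = 1024

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ParameterError("values", "need at least one event")
        if not np.isfinite(self.values).all():
            raise StateError("non-finite fluorescence values in sample")

    def __len__(self) -> int:
        return self.values.size


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, FlowSample):
        return sample.values
    v = np.asarray(sample, dtype=float).ravel()
    if v.size < 1:
        raise ParameterError("sample", "need at least one event")
    if not np.isfinite(v).all():
        raise StateError("non-finite fluorescence values in sample")
    return v


def _log10_positive(values: np.ndarray) -> np.ndarray:
    bad = int((values <= 0).sum())
    if bad:
        raise ParameterError("values", f"{bad} event(s) are <= 0; cannot log-transform")
    return np.log10(values)


def shannon_entropy(sample, n_bins: int = DEFAULT_N_BINS,
                    value_range: Optional[Tuple[float, float]] = None) -> float:
    """Shannon entropy (bits) of the log10 fluorescence histogram.

    H = -sum p_i log2 p_i over occupied bins.  ``value_range`` is in
    log10 units; by default the data range is used, widened to at least
    :data:`DEFAULT_DECADES` decades from its lower end so that samples of
    different spread are binned at comparable resolution.  Out-of-range
    events are clipped into the edge bins.
    """
    if n_bins < 2:
        raise ParameterError("n_bins", f"need >= 2 bins, got {n_bins}")
    logv = _log10_positive(_as_values(sample))
    if value_range is None:
        lo = logv.min()
        hi = max(logv.max(), lo + DEFAULT_DECADES)
        value_range = (lo, hi)
    lo, hi = value_range
    logv = np.clip(logv, lo, hi)
    counts, _ = np.histogram(logv, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def scv(sample) -> float:
    """Squared coefficient of variation, variance / mean^2 (linear scale)."""
    v = _as_values(sample)
    mean = v.mean()
    if mean == 0.0:
        raise ParameterError("sample", "mean is zero; SCV undefined")
    var = v.var(ddof=1) if v.size > 1 else 0.0
    return float(var / mean ** 2)


def tail_fraction(sample, threshold: float) -> float:
    """Fraction of events strictly above ``threshold`` (e.g. 2000 a.u.)."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold", "must be finite")
    v = _as_values(sample)
    return float((v > threshold).mean())


@dataclass
class ModeReport:
    """Result of kernel-density mode detection on log10 values."""

    n_modes: int
    mode_positions: np.ndarray   # linear-scale positions of the density peaks
    mode_fractions: np.ndarray   # fraction of events assigned to each mode

    def __iter__(self):
        return iter((self.n_modes, self.mode_positions, self.mode_fractions))


def detect_modes(sample, prominence: float = 0.05, grid_size: int = 512,
                 bw_method: str = "silverman") -> ModeReport:
    """Count modes of the log10 fluorescence density.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a regular grid;
    modes are local maxima whose height above the flanking minima
    (prominence) reaches ``prominence`` x the global maximum.  Events are
    assigned to the nearest mode by density watershed (split at the minima
    between surviving peaks).
    """
    v = _as_values(sample)
    if v.size < 50:
        raise InsufficientDataError(f"mode detection needs >= 50 events, got {v.size}")
    logv = _log10_positive(v)
    spread = logv.max() - logv.min()
    if spread < 1e-9:
        return ModeReport(1, np.array([10.0 ** logv[0]]), np.array([1.0]))
    kde = gaussian_kde(logv, bw_method=bw_method)
    pad = 3.0 * kde.factor * logv.std(ddof=1)
    grid = np.linspace(logv.min() - pad, logv.max() + pad, grid_size)
    dens = kde(grid)

    peaks, _ = find_peaks(dens, prominence=prominence * dens.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    modes = sorted(int(i) for i in peaks)

    positions = 10.0 ** grid[modes]
    if len(modes) == 1:
        return ModeReport(1, positions, np.array([1.0]))
    boundaries = []
    for a, b in zip(modes[:-1], modes[1:]):
        boundaries.append(grid[a + int(np.argmin(dens[a:b + 1]))])
    idx = np.searchsorted(np.array(boundaries), logv)
    fractions = np.bincount(idx, minlength=len(modes)) / v.size
    return ModeReport(len(modes), positions, fractions)


def summarize(sample, threshold: float = 2000.0,
              n_bins: int = DEFAULT_N_BINS) -> dict:
    """All heterogeneity statistics of one sample as a JSON-ready dict."""
    report = detect_modes(sample)
    return {
        "n_events": int(_as_values(sample).size),
        "entropy_bits": shannon_entropy(sample, n_bins=n_bins),
        "scv": scv(sample),
        "tail_fraction": tail_fraction(sample, threshold),
        "threshold": float(threshold),
        "n_modes": int(report.n_modes),
        "mode_positions": [float(x) for x in report.mode_positions],
        "mode_fractions": [float(x) for x in report.mode_fractions],
    }
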