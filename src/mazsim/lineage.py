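"""Estimators for single-cell lineages and population growth curves.

Consumes Schnitzcells-style lineage tables (one row per frame per lineage:
time, lineage id, length, area, total fluorescence, division flag) and
plate-reader-style growth curves, and implements the estimators used in
mother-machine and batch-growth analyses of toxin-induced stress:

* per-cycle elongation rate (exponential fit of length vs time),
* maximum population growth rate (best 5-point sliding ln-slope),
* recovery time of an induced culture relative to its control,
* per-lineage recovery slope of elongation rate over a late time window,
* consecutive-division cell-length fluctuation slopes,
* normalized fluorescence (total / area), and
* standard two-sample distribution comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError

LINEAGE_COLUMNS = ("time_min", "lineage_id", "length_um", "area",
                   "total_fluorescence", "division")

#: default window (minutes) for the stress-exit slope of elongation rates
RECOVERY_WINDOW = (545.0, 725.0)


def read_lineage_table(path) -> pd.DataFrame:
    """Read a lineage table CSV and check the documented header."""
    df = pd.read_csv(path)
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError("lineage_table", f"missing columns {missing}")
    return df


def elongation_rate(lengths: Sequence[float], times: Sequence[float]) -> float:
    """Exponential elongation rate of one cell cycle (1/min).

    Least-squares slope of ln(length) versus time over the frames from birth
    to division; exact on noiseless exponentials.
    """
    lengths = np.asarray(lengths, dtype=float)
    times = np.asarray(times, dtype=float)
    if lengths.size != times.size:
        raise ParameterError("lengths", "lengths and times differ in size")
    if lengths.size < 3:
        raise InsufficientDataError(
            f"elongation rate needs >= 3 frames, got {lengths.size}")
    if (lengths <= 0).any():
        raise ParameterError("lengths", "lengths must be positive")
    slope, _ = np.polyfit(times, np.log(lengths), 1)
    return float(slope)


def max_growth_rate(biomass: Sequence[float], times: Optional[Sequence[float]] = None,
                    window: int = 5, return_time: bool = False):
    """Maximum sliding-window growth rate of a batch culture (1/min).

    The rate is the largest least-squares slope of ln(biomass) over every
    ``window`` consecutive points (default five points = 40 min at 10-min
    sampling).  With ``return_time=True`` also returns the centre time of
    the winning window and a flag marking a maximum at the series boundary.
    """
    biomass = np.asarray(biomass, dtype=float)
    if times is None:
        times = np.arange(biomass.size) * 10.0
    times = np.asarray(times, dtype=float)
    if biomass.size < window:
        raise InsufficientDataError(
            f"max growth rate needs >= {window} points, got {biomass.size}")
    if (biomass <= 0).any():
        raise ParameterError("biomass", "biomass must be positive")
    logb = np.log(biomass)
    n_win = biomass.size - window + 1
    slopes = np.empty(n_win)
    for i in range(n_win):
        slopes[i] = np.polyfit(times[i:i + window], logb[i:i + window], 1)[0]
    best = int(np.argmax(slopes))
    if not return_time:
        return float(slopes[best])
    t_centre = float(times[best:best + window].mean())
    at_boundary = best == 0 or best == n_win - 1
    return float(slopes[best]), t_centre, at_boundary


@dataclass
class RecoveryTime:
    """Delay (min) of an induced culture reaching max growth rate vs control."""

    delay_min: float
    t_induced: float
    t_control: float
    lower_bound: bool   # induced maximum sits at the series end: report a bound

    def __float__(self) -> float:
        return self.delay_min


def recovery_time(induced: Sequence[float], control: Sequence[float],
                  times: Optional[Sequence[float]] = None,
                  window: int = 5) -> RecoveryTime:
    """Time for the induced culture to reach maximum growth rate, relative to
    the control culture's exit; positive values mean delayed recovery."""
    _, t_i, bound_i = max_growth_rate(induced, times, window, return_time=True)
    _, t_c, _ = max_growth_rate(control, times, window, return_time=True)
    return RecoveryTime(float(t_i - t_c), t_i, t_c, bool(bound_i))


def recovery_slope(rates: Sequence[float], times: Sequence[float],
                   window: Tuple[float, float] = RECOVERY_WINDOW) -> float:
    """Slope of per-division elongation rates vs time inside ``window``.

    Fitted per lineage during the stress-exit phase; a steeper positive
    slope means faster recovery.  Raises if fewer than two observations
    fall inside the window (callers typically skip such lineages).
    """
    rates = np.asarray(rates, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    if sel.sum() < 2:
        raise InsufficientDataError(
            f"recovery slope needs >= 2 observations in {window}, got {int(sel.sum())}")
    return float(np.polyfit(times[sel], rates[sel], 1)[0])


def recovery_slopes_by_lineage(divisions: pd.DataFrame,
                               window: Tuple[float, float] = RECOVERY_WINDOW,
                               time_col: str = "t_div_min",
                               rate_col: str = "elongation_rate_per_min",
                               id_col: str = "cell_id") -> pd.Series:
    """Per-lineage recovery slopes from a tidy division-event table.

    Lineages with fewer than two in-window divisions are skipped with a
    single aggregated warning.
    """
    out: Dict = {}
    skipped = 0
    for lid, grp in divisions.groupby(id_col):
        try:
            out[lid] = recovery_slope(grp[rate_col].to_numpy(),
                                      grp[time_col].to_numpy(), window)
        except InsufficientDataError:
            skipped += 1
    if skipped:
        warnings.warn(f"recovery_slopes_by_lineage: skipped {skipped} lineage(s) "
                      f"with < 2 divisions in window {window}")
    return pd.Series(out, name="recovery_slope")


def length_fluctuation_slopes(division_times: Sequence[float],
                              lengths_before_div: Sequence[float]) -> np.ndarray:
    """Slopes of pre-division cell length between consecutive divisions.

    For each consecutive division pair the slope
    (L_{i+1} - L_i) / (t_{i+1} - t_i) in um/min; negative values mean the
    pre-division length decreased at the next division.  Fewer than two
    divisions yield an empty vector.
    """
    t = np.asarray(division_times, dtype=float)
    L = np.asarray(lengths_before_div, dtype=float)
    if t.size != L.size:
        raise ParameterError("division_times", "times and lengths differ in size")
    if t.size < 2:
        return np.empty(0)
    if (np.diff(t) <= 0).any():
        raise ParameterError("division_times", "division times must be strictly increasing")
    return np.diff(L) / np.diff(t)


def length_fluctuation_slopes_from_table(table: pd.DataFrame) -> Dict[int, np.ndarray]:
    """Per-lineage fluctuation slopes from a Schnitzcells-style frame table.

    The pre-division length of a cycle is taken from the last frame flagged
    as a division within each lineage.
    """
    out = {}
    for lid, grp in table.groupby("lineage_id"):
        div_rows = grp[grp["division"].astype(bool)]
        out[lid] = length_fluctuation_slopes(
            div_rows["time_min"].to_numpy(), div_rows["length_um"].to_numpy())
    return out


def normalized_fluorescence(total_fluor, area):
    """Total fluorescence divided by cell area -- a concentration proxy."""
    total_fluor = np.asarray(total_fluor, dtype=float)
    area = np.asarray(area, dtype=float)
    if (area <= 0).any():
        raise ParameterError("area", "area must be > 0")
    out = total_fluor / area
    return float(out) if out.ndim == 0 else out


@dataclass
class DistributionComparison:
    """Two-sample comparison: location (rank-sum), shape (KS), optional
    paired rank correlation."""

    mannwhitney_p: float
    mannwhitney_stat: float
    ks_p: float
    ks_stat: float
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    degenerate: bool = False


def compare_distributions(x: Sequence[float], y: Sequence[float],
                          paired: bool = False) -> DistributionComparison:
    """Mann-Whitney (location) and Kolmogorov-Smirnov (shape) two-sample
    tests; with ``paired=True`` additionally the Spearman rank correlation
    of the pairs (x_i, y_i), as used for fluorescence-vs-growth association.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise InsufficientDataError("need >= 5 observations per sample")
    degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    mw = stats.mannwhitneyu(x, y, alternative="two-sided")
    ks = stats.ks_2samp(x, y)
    rho = p_rho = None
    if paired:
        if x.size != y.size:
            raise ParameterError("y", "paired mode needs equal-length samples")
        sp = stats.spearmanr(x, y)
        rho, p_rho = float(sp.statistic), float(sp.pvalue)
    return DistributionComparison(
        mannwhitney_p=float(mw.pvalue), mannwhitney_stat=float(mw.statistic),
        ks_p=float(ks.pvalue), ks_stat=float(ks.statistic),
        spearman_rho=rho, spearman_p=p_rho, degenerate=degenerate)
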