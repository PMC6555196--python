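"""Spike trains, binning, cross-correlation and phase-locking summaries.

Phase locking between axons in a bundle is quantified the standard way for
coupled neural oscillators: spikes in an analysis window are binned (1 ms
default), every unordered cell pair's binned trains are cross-correlated
over +/- one mean oscillator period, and the peak correlation value and its
lag are aggregated (mean +/- SD across pairs and initial-condition seeds)
per extracellular conductivity.  Synchronous locking shows up as a peak at
zero lag; anti-synchronous locking as a peak near half the period.

The correlation estimator is the Pearson correlation of the overlapping
bins at each lag, so values are bounded by 1 and comparable across pairs
and conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SpikeTrain",
    "CrossCorrelation",
    "detect_spikes",
    "spike_peak_times",
    "bin_spikes",
    "cross_correlation",
    "bundle_locking_summary",
]


@dataclass
class SpikeTrain:
    """Strictly increasing spike times (ms) from one recording segment."""

    times: np.ndarray
    source: int = 0
    threshold: float = 0.0
    refractory: float = 2.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.times)


@dataclass
class CrossCorrelation:
    """Normalized correlation values on a symmetric lag grid."""

    lags: np.ndarray           # ms, symmetric about 0, bin-width spacing
    values: np.ndarray
    bin_width: float
    normalization: str = "pearson"

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))

    @property
    def peak_lag(self) -> float:
        """Lag of the maximum value; exact ties resolve to the smallest
        absolute lag (relevant for perfectly periodic trains)."""
        vmax = np.max(self.values)
        tied = np.where(self.values >= vmax - 1e-12)[0]
        return float(self.lags[tied[np.argmin(np.abs(self.lags[tied]))]])


def detect_spikes(times, trace, threshold: float = 0.0,
                  refractory: float = 2.0, source: int = 0) -> SpikeTrain:
    """Spike times as linearly interpolated upward threshold crossings.

    Crossings within ``refractory`` ms of the previous accepted spike are
    ignored.  ``times`` must be non-decreasing (a dense-output grid).
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValidationError("time grid must be non-decreasing")
    above = trace >= threshold
    idx = np.where(~above[:-1] & above[1:])[0]
    spikes = []
    last = -np.inf
    for i in idx:
        frac = (threshold - trace[i]) / (trace[i + 1] - trace[i])
        t_cross = times[i] + frac * (times[i + 1] - times[i])
        if t_cross - last >= refractory:
            spikes.append(t_cross)
            last = t_cross
    return SpikeTrain(times=np.array(spikes), source=source,
                      threshold=threshold, refractory=refractory)


def spike_peak_times(times, trace, threshold: float = 0.0,
                     refractory: float = 2.0) -> np.ndarray:
    """Action-potential peak times refined by parabolic interpolation.

    For each detected spike, the local maximum of the trace after the
    threshold crossing is located and refined by fitting a parabola through
    the three samples around it; this resolves peak times well below the
    output-grid spacing.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    train = detect_spikes(times, trace, threshold, refractory)
    peaks = []
    for ts in train.times:
        i0 = int(np.searchsorted(times, ts))
        i1 = min(len(times), i0 + int(np.ceil(refractory
                                              / max(np.diff(times).min(),
                                                    1e-12))))
        seg = trace[i0:i1]
        if len(seg) < 3:
            continue
        k = i0 + int(np.argmax(seg))
        if k == 0 or k >= len(times) - 1:
            peaks.append(times[k])
            continue
        y0, y1, y2 = trace[k - 1], trace[k], trace[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        dt = times[k + 1] - times[k]
        peaks.append(times[k] + delta * dt)
    return np.array(peaks)


def bin_spikes(train: SpikeTrain, window, bin_width: float = 1.0) -> np.ndarray:
    """Counts per half-open bin [t0 + k w, t0 + (k+1) w) inside ``window``."""
    t0, t1 = window
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    if not t1 > t0:
        raise ValidationError("window must satisfy t1 > t0")
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-12))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.times, bins=edges)
    return counts


def cross_correlation(a, b, max_lag_bins: int,
                      bin_width: float = 1.0) -> CrossCorrelation:
    """Pearson correlation of two equal-length count vectors at each lag.

    At lag k >= 0 the correlation is between a[0:N-k] and b[k:N]; a copy of
    ``a`` delayed by k bins therefore peaks at lag +k.  The identity
    cc(a, b)(k) == cc(b, a)(-k) holds exactly.  Zero variance in either
    overlap segment is reported as an error, never silently zeroed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("count vectors must be equal-length 1-D")
    n = len(a)
    if not 0 <= max_lag_bins < n:
        raise ValidationError("max_lag_bins must be < vector length")
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    values = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            xa, xb = a[:n - k] if k else a, b[k:]
        else:
            xa, xb = a[-k:], b[:n + k]
        sa, sb = np.std(xa), np.std(xb)
        if sa == 0 or sb == 0:
            raise ValidationError(
                f"zero-variance overlap at lag {k}: correlation undefined")
        values[i] = np.mean((xa - xa.mean()) * (xb - xb.mean())) / (sa * sb)
    return CrossCorrelation(lags=lags * bin_width, values=values,
                            bin_width=bin_width)


# ---------------------------------------------------------------------------
# bundle phase-locking summary
# ---------------------------------------------------------------------------

def _cell_spike_trains(result, cell_ids, record_segment, window, threshold,
                       refractory):
    """SpikeTrain per cell from the recording segment of each cell."""
    trains = {}
    for ci, seg in record_segment.items():
        tr = detect_spikes(result.times, result.vm[seg], threshold,
                           refractory, source=seg)
        tr = SpikeTrain(times=tr.times[(tr.times >= window[0])
                                       & (tr.times < window[1])],
                        source=seg, threshold=threshold,
                        refractory=refractory)
        trains[ci] = tr
    return trains


def _middle_segments(result):
    """Default recording segment per cell: the middle segment of each."""
    cells = np.asarray(result.metadata.get("cell_index"))
    if cells.ndim == 0 or cells.size != result.vm.shape[0]:
        raise ValidationError(
            "result lacks cell_index metadata; pass record_segment")
    rec = {}
    for ci in np.unique(cells):
        segs = np.where(cells == ci)[0]
        rec[int(ci)] = int(segs[len(segs) // 2])
    return rec


def bundle_locking_summary(results, sigmas=None, seeds=None, window=None,
                           bin_width: float = 1.0, threshold: float = 0.0,
                           refractory: float = 2.0,
                           record_segment: dict[int, int] | None = None,
                           period_ms: float | None = None):
    """Pairwise phase-locking table and mean cross-correlation functions.

    Parameters
    ----------
    results : list of SimulationResult
        One entry per (condition, seed) run of a multi-cell network.
    sigmas, seeds : sequences aligned with ``results``
        Condition labels; taken from result metadata when omitted.
    window : (t0, t1) ms
        Analysis window; default = the last half of each simulation
        (the late, transient-free portion).
    period_ms : float
        Lag range is +/- one oscillator period; measured from the pooled
        inter-spike intervals when not given.

    Returns
    -------
    (pairs, curves) : two pandas DataFrames
        ``pairs``: sigma, seed, cell_i, cell_j, peak_value, peak_lag_ms per
        unordered pair (silent cells excluded and counted in
        ``pairs.attrs['excluded']``).  ``curves``: lag_ms, mean, sd, sigma —
        the mean cross-correlation function per condition.
    """
    rows = []
    curve_rows = []
    excluded = 0
    by_sigma: dict[float, list[np.ndarray]] = {}
    for ridx, res in enumerate(results):
        sigma = (sigmas[ridx] if sigmas is not None
                 else res.metadata.get("sigma"))
        seed = (seeds[ridx] if seeds is not None
                else res.metadata.get("seed"))
        win = window or (res.times[-1] - (res.times[-1] - res.times[0]) / 2,
                         res.times[-1])
        if win[0] < res.times[0] or win[1] > res.times[-1] + 1e-9:
            raise ValidationError("analysis window outside simulation span")
        rec = record_segment or _middle_segments(res)
        trains = _cell_spike_trains(res, sorted(rec), rec, win, threshold,
                                    refractory)
        if period_ms is None:
            isis = np.concatenate([np.diff(tr.times)
                                   for tr in trains.values()
                                   if len(tr) >= 2] or [np.array([])])
            if len(isis) == 0:
                excluded += len(list(combinations(trains, 2)))
                continue
            period = float(np.mean(isis))
        else:
            period = period_ms
        max_lag = max(1, int(round(period / bin_width)))
        counts = {ci: bin_spikes(tr, win, bin_width)
                  for ci, tr in trains.items()}
        for ci, cj in combinations(sorted(trains), 2):
            if len(trains[ci]) == 0 or len(trains[cj]) == 0:
                excluded += 1
                continue
            cc = cross_correlation(counts[ci], counts[cj], max_lag, bin_width)
            rows.append(dict(sigma=sigma, seed=seed, cell_i=ci, cell_j=cj,
                             peak_value=cc.peak_value,
                             peak_lag_ms=cc.peak_lag))
            # the orientation of an unordered pair is arbitrary, so each
            # pair contributes its correlation in both directions; the mean
            # curve is then independent of cell indexing (and symmetric)
            by_sigma.setdefault(sigma, []).append(cc.values)
            by_sigma[sigma].append(cc.values[::-1])
    pairs = pd.DataFrame(rows)
    pairs.attrs["excluded"] = excluded
    for sigma, stack in by_sigma.items():
        # lag grids can differ by one bin across runs; align on the shortest
        m = min(len(v) for v in stack)
        trim = [v[(len(v) - m) // 2:(len(v) - m) // 2 + m] for v in stack]
        arr = np.vstack(trim)
        lag_grid = (np.arange(m) - m // 2) * bin_width
        for i in range(m):
            curve_rows.append(dict(lag_ms=lag_grid[i],
                                   mean=float(arr[:, i].mean()),
                                   sd=float(arr[:, i].std()),
                                   sigma=sigma))
    curves = pd.DataFrame(curve_rows)
    return pairs, curves


def nonzero_lag_peak(curve: pd.DataFrame) -> float:
    """Lag (ms) of the largest local maximum at positive nonzero lag of a
    mean cross-correlation curve (columns lag_ms, mean)."""
    c = curve.sort_values("lag_ms").reset_index(drop=True)
    lag = c["lag_ms"].to_numpy()
    val = c["mean"].to_numpy()
    best = None
    for i in range(1, len(c) - 1):
        if lag[i] <= 0:
            continue
        if val[i] >= val[i - 1] and val[i] >= val[i + 1]:
            if best is None or val[i] > val[best]:
                best = i
    if best is None:
        raise ValidationError("no interior local maximum at positive lag")
    return float(lag[best])
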