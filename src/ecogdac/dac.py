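"""Distance-averaged correlation (DAC).

Pearson correlation is computed for every unordered channel pair in every
analysis window; pooling those values across windows and equidistant pairs
and averaging per unique inter-electrode distance yields the DAC curve,
the package's basic description of how signal similarity falls off with
electrode separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DistanceStructure
from .preprocessing import BandDefinition, WindowSet


@dataclass
class CorrelationStack:
    """Per-window channels × channels Pearson correlation matrices."""

    corr: np.ndarray                    # (n_windows, n, n); NaN = undefined
    window_starts: np.ndarray
    band: BandDefinition | None = None

    @property
    def n_windows(self) -> int:
        return self.corr.shape[0]

    @property
    def n_channels(self) -> int:
        return self.corr.shape[1]


@dataclass
class DACCurve:
    """Mean correlation per unique inter-electrode distance, with 95% CI."""

    distances: np.ndarray               # mm
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray                       # pooled pair×window count per distance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_mm": self.distances,
            "mean_r": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def window_correlations(ws: WindowSet) -> CorrelationStack:
    """Pearson correlation per unordered channel pair per window.

    Pairs involving a zero-variance channel in a window are undefined (NaN)
    and excluded from all downstream averages rather than zero-filled.
    """
    if ws.data.shape[1] < 2:
        raise ValueError("need at least 2 samples per window")
    n_w, _, n_ch = ws.data.shape
    out = np.empty((n_w, n_ch, n_ch))
    warned = False
    for w in range(n_w):
        x = ws.data[w] - ws.data[w].mean(axis=0)
        sd = x.std(axis=0)
        bad = sd == 0
        if bad.any() and not warned:
            warnings.warn("zero-variance channel(s) in a window; "
                          "their pairs are undefined and dropped")
            warned = True
        safe_sd = np.where(bad, 1.0, sd)
        c = (x.T @ x) / x.shape[0] / np.outer(safe_sd, safe_sd)
        c[bad, :] = np.nan
        c[:, bad] = np.nan
        np.fill_diagonal(c, np.where(bad, np.nan, 1.0))
        out[w] = np.clip(c, -1.0, 1.0)
    return CorrelationStack(out, ws.starts.copy(), ws.band)


def _pair_values(stack_corr: np.ndarray, ds: DistanceStructure) -> list[np.ndarray]:
    """Pooled correlation values per distance group (NaNs dropped)."""
    vals = []
    for g in ds.pair_groups:
        v = stack_corr[:, g[:, 0], g[:, 1]].ravel()
        vals.append(v[~np.isnan(v)])
    return vals


def distance_average(stack: CorrelationStack, ds: DistanceStructure) -> DACCurve:
    """DAC pooled over all windows and equidistant pairs, with normal 95% CI."""
    if stack.n_windows == 0:
        raise ValueError("empty correlation stack")
    if stack.n_channels != ds.n_channels:
        raise ValueError("correlation stack and distance structure disagree "
                         "on channel count")
    means, lo, hi, ns = [], [], [], []
    for v in _pair_values(stack.corr, ds):
        if v.size == 0:
            means.append(np.nan); lo.append(np.nan); hi.append(np.nan); ns.append(0)
            continue
        m = v.mean()
        sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        means.append(m); lo.append(m - 1.96 * sem); hi.append(m + 1.96 * sem)
        ns.append(v.size)
    return DACCurve(ds.unique_distances.copy(), np.array(means),
                    np.array(lo), np.array(hi), np.array(ns))


def bootstrap_distance_average(stack: CorrelationStack, ds: DistanceStructure,
                               n_boot: int = 2000, seed: int = 0) -> DACCurve:
    """DAC with percentile-bootstrap 95% CI on the pooled mean."""
    rng = np.random.default_rng(seed)
    means, lo, hi, ns = [], [], [], []
    for v in _pair_values(stack.corr, ds):
        if v.size == 0:
            means.append(np.nan); lo.append(np.nan); hi.append(np.nan); ns.append(0)
            continue
        m = v.mean()
        bs = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
        q = np.percentile(bs, [2.5, 97.5])
        means.append(m); lo.append(q[0]); hi.append(q[1]); ns.append(v.size)
    return DACCurve(ds.unique_distances.copy(), np.array(means),
                    np.array(lo), np.array(hi), np.array(ns))


def per_window_dac(stack: CorrelationStack, ds: DistanceStructure) -> np.ndarray:
    """One DAC curve per window: (n_windows, n_distances) array.

    This is the distribution behind per-window boxplots; its pair-count
    weighted mean over windows equals the pooled DAC when no values are
    undefined.
    """
    if stack.n_windows == 0:
        raise ValueError("empty correlation stack")
    out = np.empty((stack.n_windows, ds.unique_distances.size))
    for k, g in enumerate(ds.pair_groups):
        v = stack.corr[:, g[:, 0], g[:, 1]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, k] = np.nanmean(v, axis=1)
    return out


def correlation_matrix_dac(corr: np.ndarray, ds: DistanceStructure) -> np.ndarray:
    """Distance-average a single correlation (or covariance-share) matrix."""
    ii, jj, gg = ds.pair_group_index()
    vals = corr[ii, jj]
    sums = np.bincount(gg, weights=vals, minlength=len(ds.pair_groups))
    return sums / ds.group_sizes
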