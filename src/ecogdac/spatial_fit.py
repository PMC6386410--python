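"""Circular 2D Gaussian fits of component weight maps.

A component whose weights, laid out on the grid, form a single smooth
radially decaying peak is consistent with a compact volume-conducted
source; the 5-parameter fit

    w(x, y) ~ A * exp(-((x - B)^2 + (y - C)^2) / (2 D^2)) + E

quantifies that with its goodness-of-fit R², and the width D (in grid-pitch
units) gives the spatial scale of the coherent region.  Checkerboard-like
weight maps fit poorly (low R²); flat linear gradients are absorbed by a
very wide Gaussian centered far off the grid, which is why the center and
width bounds are generous rather than tight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .decomposition import ComponentContribution
from .grid import ElectrodeGrid

#: center bound: within this many pitches of the grid on either side
CENTER_BOUND_PITCHES = 40.0
#: width bounds in pitches: no narrower than one pitch, capped to prevent
#: numerical escape while still permitting the wide-Gaussian gradient case
WIDTH_MIN_PITCHES = 1.0
WIDTH_MAX_PITCHES = 400.0


@dataclass
class GaussianFit:
    """Result of fitting one component's weight map.

    Center and width are in grid-pitch units.
    """

    amplitude: float       # A > 0
    center_x: float        # B
    center_y: float        # C
    width: float           # D >= 1 pitch
    offset: float          # E
    r_squared: float
    degenerate: bool = False

    def predict(self, pos_pitch: np.ndarray) -> np.ndarray:
        d2 = ((pos_pitch - [self.center_x, self.center_y]) ** 2).sum(1)
        return self.amplitude * np.exp(-d2 / (2 * self.width**2)) + self.offset


def _model(params: np.ndarray, pos: np.ndarray) -> np.ndarray:
    a, b, c, dd, e = params
    return a * np.exp(-((pos[:, 0] - b) ** 2 + (pos[:, 1] - c) ** 2)
                      / (2 * dd**2)) + e


def fit_component_map(weights: np.ndarray, grid: ElectrodeGrid) -> GaussianFit:
    """Bounded least-squares circular Gaussian fit of one weight map.

    ``weights`` must align with the grid's included channels (or with all
    channels, in which case the included subset is taken).  Five starts are
    tried — the four interior quarter points of the grid and the
    magnitude-weighted center of mass — and the lowest-SSE solution kept.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] == grid.n_channels:
        w = w[grid.included_mask]
    pos = grid.included_positions / grid.pitch
    if w.shape[0] != pos.shape[0]:
        raise ValueError("weights do not align with the grid's included channels")
    if w.size < 6:
        raise ValueError("need at least 6 channels to fit 5 parameters")

    sst = ((w - w.mean()) ** 2).sum()
    if sst <= (1e-12 * max(1.0, float(np.abs(w).max()))) ** 2 * w.size:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, float(w.mean()),
                           r_squared=0.0, degenerate=True)

    xmin, ymin = pos.min(0)
    xmax, ymax = pos.max(0)
    lb = [1e-12, xmin - CENTER_BOUND_PITCHES, ymin - CENTER_BOUND_PITCHES,
          WIDTH_MIN_PITCHES, -np.inf]
    ub = [np.inf, xmax + CENTER_BOUND_PITCHES, ymax + CENTER_BOUND_PITCHES,
          WIDTH_MAX_PITCHES, np.inf]

    xr, yr = xmax - xmin, ymax - ymin
    starts = [(xmin + fx * xr, ymin + fy * yr)
              for fx, fy in ((0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75))]
    mass = np.abs(w)
    if mass.sum() > 0:
        starts.append(tuple((pos * mass[:, None]).sum(0) / mass.sum()))

    a0 = max(float(w.max() - w.min()), 1e-6)
    d0 = max(WIDTH_MIN_PITCHES, 0.25 * max(xr, yr, 1.0))
    best, best_sse = None, np.inf
    for bx, by in starts:
        x0 = np.clip([a0, bx, by, d0, float(w.min())], lb, ub)
        try:
            sol = least_squares(lambda p: _model(p, pos) - w, x0,
                                bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float((sol.fun**2).sum())
        if sse < best_sse:
            best, best_sse = sol, sse
    if best is None:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                           r_squared=np.nan, degenerate=True)
    a, b, c, dd, e = best.x
    return GaussianFit(float(a), float(b), float(c), float(dd), float(e),
                       r_squared=float(1.0 - best_sse / sst))


@dataclass
class WidthSummary:
    median_width: float
    ci_low: float
    ci_high: float
    n: int


def width_summary(fits: list[GaussianFit], r2_threshold: float = 0.7,
                  n_boot: int = 5000, seed: int = 0) -> WidthSummary:
    """Median width of well-fit components with a bootstrap 95% CI.

    The median is used because fitted widths are strongly right-skewed; the
    CI is a percentile bootstrap of the median with ``n_boot`` resamples.
    """
    widths = np.array([f.width for f in fits
                       if not f.degenerate and f.r_squared > r2_threshold])
    if widths.size == 0:
        warnings.warn("no fits pass the R² threshold; width summary undefined")
        return WidthSummary(np.nan, np.nan, np.nan, 0)
    rng = np.random.default_rng(seed)
    med = float(np.median(widths))
    boots = np.median(
        rng.choice(widths, size=(n_boot, widths.size), replace=True), axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return WidthSummary(med, float(lo), float(hi), int(widths.size))


def contribution_by_r2(
    fits: list[GaussianFit],
    contribs: ComponentContribution,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean component contributions per R² bin.

    Returns one row per bin with mean percent of the DAC drop and of the
    variance (NaN for empty bins), plus the equal-contribution reference
    level 100 / n_components that all bars would sit at if the drop were
    spread evenly over components.
    """
    if len(fits) != contribs.percent_dac_drop.size:
        raise ValueError("fits and contributions must align by component")
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    bins = np.asarray(bins, dtype=float)
    r2 = np.array([max(f.r_squared, 0.0) for f in fits])
    which = np.clip(np.digitize(r2, bins) - 1, 0, bins.size - 2)
    ref = 100.0 / len(fits)
    rows = []
    for b in range(bins.size - 1):
        sel = which == b
        rows.append({
            "r2_low": bins[b],
            "r2_high": bins[b + 1],
            "n_components": int(sel.sum()),
            "mean_percent_dac_drop": float(contribs.percent_dac_drop[sel].mean())
            if sel.any() else np.nan,
            "mean_percent_variance": float(contribs.percent_variance[sel].mean())
            if sel.any() else np.nan,
            "equal_contribution_reference": ref,
        })
    return pd.DataFrame(rows)
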