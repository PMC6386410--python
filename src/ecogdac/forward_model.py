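"""Gaussian spatial-component forward model of grid covariance.

Each latent component contributes to every channel through a circular 2D
Gaussian weight profile

    W[i, j] = A_j * exp(-((x_j - x_i)^2 + (y_j - y_i)^2) / (2 sigma_j^2)),

so that with unit-variance, mutually uncorrelated components the channel
covariance is exactly ``W @ W.T``.  Independent per-channel noise adds
``epsilon`` to the diagonal and a common reference signal adds ``rho``
everywhere, giving the modified correlation

    r'[i, j] = (Sigma[i, j] + eps*delta_ij + rho)
               / sqrt((Sigma[i, i] + eps + rho) (Sigma[j, j] + eps + rho)).

In the limit of many identically sized components sampled densely over a
large area the correlation becomes a pure Gaussian of inter-channel
distance with standard deviation sqrt(2) * sigma — noise lowers the
apparent intercept of the distance-averaged correlation and a reference
raises its large-distance asymptote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .dac import DACCurve, correlation_matrix_dac
from .grid import DistanceStructure, ElectrodeGrid, build_distance_structure


@dataclass
class ModelMixingSpec:
    """Random mixing-matrix ensemble on a rectangular model grid.

    Distances are in grid-pitch units.  Component centers are uniform over
    the grid extent expanded by ``center_margin_fraction * sigma`` on each
    side; amplitudes are uniform draws from ``amplitude_range``, sorted
    descending, then scaled by ``exp(-amplitude_decay * k)`` for
    k = 1, 2, 3, ... to mimic the decreasing variance spectrum of measured
    components.
    """

    grid_shape: tuple[int, int] = (10, 15)       # (rows, cols)
    n_components: int = 150
    sigma: float = 2.0
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    amplitude_decay: float = 0.1
    center_margin_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class NoiseRefSpec:
    """Covariance-scale channel-noise (epsilon) and reference (rho) weights.

    ``epsilon`` is the variance added independently to every channel (the
    square of a per-channel noise amplitude); ``rho`` is the covariance
    added uniformly to every channel pair (the square of a constant
    reference weight).
    """

    epsilon: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.rho < 0:
            raise ValueError("epsilon and rho must be nonnegative")


@dataclass
class ModelMixing:
    """A sampled mixing matrix with its generating geometry."""

    weights: np.ndarray          # (n_channels, n_components)
    centers: np.ndarray          # (n_components, 2), pitch units
    amplitudes: np.ndarray
    grid: ElectrodeGrid = field(repr=False)


def model_grid(grid_shape: tuple[int, int]) -> ElectrodeGrid:
    """Unit-pitch rectangular model grid."""
    return ElectrodeGrid.rectangular(*grid_shape, pitch=1.0)


def sample_mixing_matrix(spec: ModelMixingSpec,
                         grid: ElectrodeGrid | None = None) -> ModelMixing:
    """Draw one random Gaussian-component mixing matrix."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if grid is None:
        grid = model_grid(spec.grid_shape)
    pos = grid.positions
    m = spec.center_margin_fraction * spec.sigma
    lo = pos.min(axis=0) - m
    hi = pos.max(axis=0) + m
    centers = rng.uniform(lo, hi, size=(spec.n_components, 2))
    amps = np.sort(rng.uniform(*spec.amplitude_range, spec.n_components))[::-1]
    amps = amps * np.exp(-spec.amplitude_decay * np.arange(1, spec.n_components + 1))
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    W = amps[None, :] * np.exp(-d2 / (2.0 * spec.sigma**2))
    return ModelMixing(W, centers, amps, grid)


def _weights(W) -> np.ndarray:
    return W.weights if hasattr(W, "weights") else np.asarray(W, dtype=float)


def analytic_covariance(W, nr: NoiseRefSpec | None = None) -> np.ndarray:
    """Sigma' = W W^T + epsilon * I + rho * ones."""
    Wm = _weights(W)
    nr = nr or NoiseRefSpec()
    n = Wm.shape[0]
    return Wm @ Wm.T + nr.epsilon * np.eye(n) + nr.rho * np.ones((n, n))


def analytic_correlation(W, nr: NoiseRefSpec | None = None) -> np.ndarray:
    """Correlation matrix implied by the (noise/reference-modified) model."""
    cov = analytic_covariance(W, nr)
    d = np.diag(cov)
    if np.any(d <= 0):
        raise ValueError("silent channel: zero model variance on some channel")
    r = cov / np.sqrt(np.outer(d, d))
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def analytic_dac(
    W,
    ds: DistanceStructure | None = None,
    nr: NoiseRefSpec | None = None,
    grid: ElectrodeGrid | None = None,
) -> DACCurve:
    """Exact distance average of the analytic correlation matrix.

    No sampling is involved: the model correlation of every included pair is
    averaged within each equidistant group.  CI bounds equal the mean.
    """
    if ds is None:
        if grid is None:
            raise ValueError("provide a DistanceStructure or an ElectrodeGrid")
        ds = build_distance_structure(grid)
    r = analytic_correlation(W, nr)
    r = r[np.ix_(ds.channel_indices, ds.channel_indices)] if (
        r.shape[0] != ds.n_channels) else r
    mean = correlation_matrix_dac(r, ds)
    return DACCurve(ds.unique_distances.copy(), mean, mean.copy(), mean.copy(),
                    ds.group_sizes.copy())


@dataclass
class GaussianDacFit:
    """Parameters of ``a * exp(-d^2 / (2 s^2)) + c`` fit to a DAC curve."""

    amplitude: float
    sigma: float
    offset: float
    r_squared: float
    converged: bool = True


def _dac_gauss(d, a, s, c):
    return a * np.exp(-(d**2) / (2.0 * s**2)) + c


def fit_dac_gaussian(curve: DACCurve, max_sigma: float = 1e3) -> GaussianDacFit:
    """Least-squares Gaussian fit (free amplitude and offset) to a DAC curve.

    A free offset absorbs the large-distance asymptote a common reference
    induces, and a free amplitude the intercept drop induced by channel
    noise.  On non-convergence the result is flagged with NaN R².
    """
    d = np.asarray(curve.distances, dtype=float)
    y = np.asarray(curve.mean, dtype=float)
    ok = ~np.isnan(y)
    d, y = d[ok], y[ok]
    if d.size < 4:
        raise ValueError("need at least 4 distances to fit")
    span = y.max() - y.min()
    s0 = float(np.median(d))
    if span > 0:
        half = y.min() + span / 2
        below = np.flatnonzero(y <= half)
        if below.size:
            s0 = max(float(d[below[0]]), float(d.min()) / 2, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, _ = curve_fit(
                _dac_gauss, d, y,
                p0=[max(span, 1e-3), s0, float(y.min())],
                bounds=([0.0, 1e-6, -1.0], [2.0, max_sigma, 1.0]),
                maxfev=20000,
            )
    except RuntimeError:
        return GaussianDacFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    resid = y - _dac_gauss(d, *p)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else 0.0
    return GaussianDacFit(float(p[0]), float(p[1]), float(p[2]), float(r2))


def mean_model_dac(
    sigma: float,
    n_iterations: int = 200,
    spec: ModelMixingSpec | None = None,
    nr: NoiseRefSpec | None = None,
    seed: int = 0,
) -> tuple[DACCurve, DistanceStructure]:
    """Mean of per-iteration analytic DAC curves over random mixing matrices."""
    base = spec or ModelMixingSpec()
    grid = model_grid(base.grid_shape)
    ds = build_distance_structure(grid)
    ss = np.random.SeedSequence(seed)
    curves = np.empty((n_iterations, ds.unique_distances.size))
    for i, child in enumerate(ss.spawn(n_iterations)):
        it_spec = ModelMixingSpec(
            grid_shape=base.grid_shape, n_components=base.n_components,
            sigma=sigma, amplitude_range=base.amplitude_range,
            amplitude_decay=base.amplitude_decay,
            center_margin_fraction=base.center_margin_fraction,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        mm = sample_mixing_matrix(it_spec, grid)
        curves[i] = analytic_dac(mm, ds, nr).mean
    mean = curves.mean(axis=0)
    return (
        DACCurve(ds.unique_distances.copy(), mean, mean.copy(), mean.copy(),
                 ds.group_sizes * n_iterations),
        ds,
    )
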