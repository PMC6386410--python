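"""Whitening-normalized ICA/PCA decomposition and per-component attribution.

The central algebraic device: any linear decomposition ``s = W z`` whose
components are mutually uncorrelated with unit variance satisfies
``cov(s) = W W^T``.  ICA and PCA both admit this normalization (the scale of
each component is arbitrary so long as its weight column is scaled
inversely), so the correlation structure of a window decomposes exactly into
rank-1 contributions ``Sigma^c = w_c w_c^T`` — one per component.  The
reduced correlation of a component keeps the full covariance in the
denominator so that the component curves sum to the full correlation, and a
component's share of the distance-resolved drop in correlation follows by
subtracting each curve's zero-distance value.

The common average reference (CAR) is the projector ``C = I - J/N``; applied
to the weight columns it recenters every component map to zero mean and
annihilates a spatially uniform (reference-like) component.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dac import correlation_matrix_dac
from .grid import DistanceStructure

#: keep-count caps matching common grid sizes (<=32 channels: 20, else 30)
SMALL_GRID_CHANNELS = 32
N_KEEP_CAP_SMALL = 20
N_KEEP_CAP_LARGE = 30
VARIANCE_CAPTURE = 0.95


@dataclass
class MixingMatrix:
    """A whitening-normalized decomposition of one analysis window.

    weights : (n_channels, n_components) — W
    components : (n_components, n_samples) — unit-variance time courses z
    so that ``W @ z`` reconstructs the rank-reduced, mean-removed window and
    ``W @ W.T`` equals its rank-reduced sample covariance.
    """

    weights: np.ndarray
    components: np.ndarray
    method: str = "ica"
    band: str | None = None
    window_id: int | None = None
    channel_ids: list[str] | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def covariance(self) -> np.ndarray:
        return self.weights @ self.weights.T


@dataclass
class ComponentContribution:
    """Per-component shares of variance and of the DAC drop."""

    distances: np.ndarray
    percent_variance: np.ndarray        # (k,), sums to 100 over components
    percent_dac_drop: np.ndarray        # (k,)
    reduced_curves: np.ndarray          # (k, n_distances)
    reduced_zero: np.ndarray            # (k,) zero-distance value per component
    full_curve: np.ndarray              # (n_distances,)

    @property
    def reduced_drops(self) -> np.ndarray:
        return self.reduced_curves - self.reduced_zero[:, None]

    @property
    def full_drop(self) -> np.ndarray:
        return self.full_curve - 1.0


def _symmetric_decorrelate(R: np.ndarray) -> np.ndarray:
    """Nearest orthogonal matrix (R R^T)^(-1/2) R."""
    u, _, vt = np.linalg.svd(R)
    return u @ vt


def _infomax_rotation(Y: np.ndarray, seed: int) -> np.ndarray:
    from mne.preprocessing import infomax

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            R = infomax(Y, extended=True, rng=seed, verbose="error")
        except TypeError:  # older mne spells the seed argument differently
            R = infomax(Y, extended=True, random_state=seed, verbose="error")
    return _symmetric_decorrelate(R)


def _fastica_rotation(Y: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.decomposition import FastICA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica = FastICA(whiten=False, fun="cube", random_state=seed,
                      max_iter=2000, tol=1e-6)
        ica.fit(Y)
    return _symmetric_decorrelate(ica.components_)


def decompose_window(
    window: np.ndarray,
    method: str = "ica",
    n_keep: int | None = None,
    seed: int = 0,
    band: str | None = None,
    window_id: int | None = None,
    channel_ids: list[str] | None = None,
) -> MixingMatrix:
    """Decompose one samples × channels window into W and unit-variance z.

    PCA first reduces to ``n_keep`` dimensions (default: the smallest count
    capturing >= 95% of variance, capped at 20 for grids of up to 32
    channels and 30 otherwise); for ``method="ica"`` an extended-infomax
    rotation is then estimated in the whitened space and symmetrically
    decorrelated, so the whitening identity holds exactly.  Components are
    sign-canonicalized (largest-magnitude weight positive) and ordered by
    descending weight power.  If ICA fails the PCA result is returned with a
    warning.
    """
    X = np.asarray(window, dtype=float)
    if X.ndim != 2:
        raise ValueError("window must be samples × channels")
    n, n_ch = X.shape
    if n <= n_ch:
        warnings.warn("window has no more samples than channels; "
                      "the decomposition may be unstable")
    if n_keep is not None and n_keep > n_ch:
        raise ValueError("n_keep cannot exceed the channel count")

    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("window has zero variance")
    if n_keep is None:
        var = s**2
        frac = np.cumsum(var) / var.sum()
        cap = N_KEEP_CAP_SMALL if n_ch <= SMALL_GRID_CHANNELS else N_KEEP_CAP_LARGE
        n_keep = min(int(np.searchsorted(frac, VARIANCE_CAPTURE) + 1), cap, rank)
    n_keep = min(n_keep, rank)

    Y = U[:, :n_keep] * np.sqrt(n)                    # whitened scores, var 1
    K = (s[:n_keep] / np.sqrt(n))[:, None] * Vt[:n_keep]   # Y @ K = X_k

    how = method.lower()
    if how == "pca":
        R = np.eye(n_keep)
    elif how in ("ica", "infomax", "fastica"):
        rot = _fastica_rotation if how == "fastica" else _infomax_rotation
        try:
            R = rot(Y, seed)
        except Exception as exc:  # pragma: no cover - depends on solver
            warnings.warn(f"ICA did not converge ({exc}); falling back to PCA")
            R = np.eye(n_keep)
            how = "pca"
    else:
        raise ValueError(f"unknown method {method!r}")

    Z = Y @ R.T                                       # samples × k, cov = I
    W = K.T @ R.T                                     # channels × k

    # sign canonicalization and power ordering
    peaks = np.abs(W).argmax(axis=0)
    signs = np.sign(W[peaks, np.arange(n_keep)])
    signs[signs == 0] = 1.0
    W = W * signs
    Z = Z * signs
    order = np.argsort(-(W**2).sum(axis=0), kind="stable")
    return MixingMatrix(W[:, order], Z[:, order].T, method=how, band=band,
                        window_id=window_id, channel_ids=channel_ids)


def reduced_covariance(W, c: int) -> np.ndarray:
    """Rank-1 covariance contribution of component ``c``: outer(w_c, w_c)."""
    Wm = W.weights if isinstance(W, MixingMatrix) else np.asarray(W, dtype=float)
    if not 0 <= c < Wm.shape[1]:
        raise IndexError(f"component index {c} out of range")
    w = Wm[:, c]
    return np.outer(w, w)


def reduced_dac(
    W,
    ds: DistanceStructure,
    drop_tolerance: float = 1e-9,
) -> ComponentContribution:
    """Attribute the DAC and its drop with distance to individual components.

    Reduced correlation uses the component's rank-1 covariance over the full
    covariance denominator, so component curves sum exactly to the full
    curve.  A component's percent of the DAC drop is the mean over nonzero
    distances of its share of the total drop; distances where the total drop
    is below ``drop_tolerance`` in magnitude are excluded from that mean.
    """
    Wm = W.weights if isinstance(W, MixingMatrix) else np.asarray(W, dtype=float)
    if Wm.shape[0] != ds.n_channels:
        raise ValueError("weight rows must match the distance structure")
    k = Wm.shape[1]
    cov = Wm @ Wm.T
    d = np.diag(cov)
    if np.any(d <= 0):
        raise ValueError("silent channel: zero variance in W W^T diagonal")
    denom = np.sqrt(np.outer(d, d))

    percent_variance = 100.0 * (Wm**2).sum(axis=0) / np.trace(cov)

    ii, jj, gg = ds.pair_group_index()
    pair_vals = Wm[ii] * Wm[jj] / denom[ii, jj][:, None]        # (n_pairs, k)
    n_g = len(ds.pair_groups)
    sums = np.zeros((n_g, k))
    np.add.at(sums, gg, pair_vals)
    curves = (sums / ds.group_sizes[:, None]).T                 # (k, n_dist)

    reduced_zero = (Wm**2 / d[:, None]).mean(axis=0)            # mean diag share
    full_curve = correlation_matrix_dac(cov / denom, ds)
    total_drop = full_curve - 1.0
    valid = np.abs(total_drop) >= drop_tolerance
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} distance(s) with near-zero total DAC drop "
            "excluded from percent-drop averaging"
        )
    if valid.any():
        drops = curves - reduced_zero[:, None]
        shares = drops[:, valid] / total_drop[valid][None, :]
        percent_drop = 100.0 * shares.mean(axis=1)
    else:
        percent_drop = np.full(k, np.nan)

    return ComponentContribution(
        distances=ds.unique_distances.copy(),
        percent_variance=percent_variance,
        percent_dac_drop=percent_drop,
        reduced_curves=curves,
        reduced_zero=reduced_zero,
        full_curve=full_curve,
    )


def car_matrix(n: int) -> np.ndarray:
    """Common-average-reference projector C = I - J/N."""
    if n < 2:
        raise ValueError("CAR needs at least 2 channels")
    return np.eye(n) - np.ones((n, n)) / n


def apply_car(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean from samples × channels data."""
    return data - data.mean(axis=1, keepdims=True)


def apply_car_to_weights(mm: MixingMatrix) -> MixingMatrix:
    """Re-reference a mixing matrix: each weight column loses its mean.

    A constant (reference-like) column maps to zero; component time courses
    are unchanged because CAR acts on channels, not on time.
    """
    W = mm.weights - mm.weights.mean(axis=0, keepdims=True)
    return replace(mm, weights=W, components=mm.components.copy())


def write_mixing_csv(mm: MixingMatrix, path: str | Path,
                     index_path: str | Path | None = None,
                     seed: int | None = None) -> None:
    """Channels × components weights as CSV plus a JSON index sidecar."""
    ids = mm.channel_ids or [f"ch{i}" for i in range(mm.n_channels)]
    df = pd.DataFrame(mm.weights, index=ids,
                      columns=[f"component_{k}" for k in range(mm.n_components)])
    df.index.name = "channel"
    df.to_csv(path)
    if index_path is not None:
        Path(index_path).write_text(json.dumps({
            "band": mm.band,
            "window": mm.window_id,
            "method": mm.method,
            "seed": seed,
            "n_components": mm.n_components,
        }, indent=1))
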