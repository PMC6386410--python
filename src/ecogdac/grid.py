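"""Electrode-grid geometry and equidistant-pair bookkeeping.

Every downstream quantity in this package — distance-averaged correlation,
the Gaussian forward model, component weight-map fits — is defined relative
to the planar layout of the electrode grid.  This module holds the channel
positions and precomputes the grouping of channel pairs by inter-electrode
distance, so that "average over all equally spaced pairs" is a single
vectorized reduction everywhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class DegenerateGridError(ValueError):
    """Raised when fewer than two included channels are available."""


@dataclass
class ElectrodeGrid:
    """Channel identities and 2D positions of a planar electrode grid.

    Parameters
    ----------
    channel_ids : list of str
        One label per channel.
    positions : (n_channels, 2) array
        x/y coordinates in millimetres.
    pitch : float
        Nominal center-to-center spacing between neighboring electrodes (mm).
    included_mask : (n_channels,) bool array, optional
        Channels surviving quality exclusion.  Excluded channels keep their
        positions (useful for plotting weight maps) but never enter pair
        enumeration or correlation averages.
    """

    channel_ids: list[str]
    positions: np.ndarray
    pitch: float
    included_mask: np.ndarray | None = None
    allow_colocated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_channels, 2) array")
        if len(self.channel_ids) != self.positions.shape[0]:
            raise ValueError("number of positions must equal number of channel_ids")
        if not np.isfinite(self.positions).all():
            raise ValueError("all positions must be finite")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")
        if self.included_mask is None:
            self.included_mask = np.ones(len(self.channel_ids), dtype=bool)
        else:
            self.included_mask = np.asarray(self.included_mask, dtype=bool)
            if self.included_mask.shape != (len(self.channel_ids),):
                raise ValueError("included_mask must have one entry per channel")
        if not self.allow_colocated:
            pos = self.positions[self.included_mask]
            if pos.shape[0] != np.unique(pos, axis=0).shape[0]:
                raise ValueError(
                    "included channels share a position; pass allow_colocated=True "
                    "if this is intentional (test fixtures only)"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def included_indices(self) -> np.ndarray:
        return np.flatnonzero(self.included_mask)

    @property
    def included_positions(self) -> np.ndarray:
        return self.positions[self.included_mask]

    @classmethod
    def rectangular(
        cls,
        rows: int,
        cols: int,
        pitch: float = 1.0,
        prefix: str = "ch",
        included_mask: np.ndarray | None = None,
    ) -> "ElectrodeGrid":
        """Regular rows × cols grid with the given pitch (row-major ids)."""
        xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
        pos = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * pitch
        ids = [f"{prefix}{i}" for i in range(rows * cols)]
        return cls(ids, pos, pitch, included_mask=included_mask)

    # --- JSON geometry sidecar -------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "pitch_mm": self.pitch,
            "channels": [
                {
                    "id": cid,
                    "x_mm": float(x),
                    "y_mm": float(y),
                    "included": bool(inc),
                }
                for cid, (x, y), inc in zip(
                    self.channel_ids, self.positions, self.included_mask
                )
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeGrid":
        payload = json.loads(Path(path).read_text())
        chans = payload["channels"]
        return cls(
            channel_ids=[c["id"] for c in chans],
            positions=np.array([[c["x_mm"], c["y_mm"]] for c in chans]),
            pitch=float(payload["pitch_mm"]),
            included_mask=np.array([c.get("included", True) for c in chans]),
        )


@dataclass
class DistanceStructure:
    """Pairwise distances between included channels, grouped by distance.

    All index arrays refer to positions within the *included* channel set
    (the same ordering as rows/columns of correlation matrices computed on
    included channels); ``channel_indices`` maps back to the full grid.
    """

    channel_indices: np.ndarray            # global indices of included channels
    distance_matrix: np.ndarray            # (n_inc, n_inc), mm
    unique_distances: np.ndarray           # sorted, mm (excludes 0 unless co-located pairs)
    pair_groups: list[np.ndarray]          # each (n_pairs_g, 2) of included-space indices

    @property
    def n_channels(self) -> int:
        return self.channel_indices.size

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([g.shape[0] for g in self.pair_groups])

    def pair_group_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (i, j, group) arrays over all unordered pairs."""
        ii = np.concatenate([g[:, 0] for g in self.pair_groups])
        jj = np.concatenate([g[:, 1] for g in self.pair_groups])
        gg = np.concatenate(
            [np.full(g.shape[0], k) for k, g in enumerate(self.pair_groups)]
        )
        return ii, jj, gg


def build_distance_structure(
    grid: ElectrodeGrid, tolerance: float | None = None
) -> DistanceStructure:
    """Enumerate all unordered included-channel pairs grouped by distance.

    Distances differing by less than ``tolerance`` (default ``1e-6 * pitch``)
    are merged into one group whose representative distance is the group
    mean; on lattice grids this collapses floating-point duplicates of the
    same geometric distance without merging genuinely distinct spacings.
    """
    if tolerance is None:
        tolerance = 1e-6 * grid.pitch
    idx = grid.included_indices
    if idx.size < 2:
        raise DegenerateGridError("degenerate grid: need at least 2 included channels")
    pos = grid.positions[idx]
    diff = pos[:, None, :] - pos[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))

    iu, ju = np.triu_indices(idx.size, 1)
    pair_d = dmat[iu, ju]
    order = np.argsort(pair_d, kind="stable")
    sorted_d = pair_d[order]
    # split where consecutive sorted distances jump by >= tolerance
    breaks = np.flatnonzero(np.diff(sorted_d) >= tolerance) + 1
    group_slices = np.split(np.arange(sorted_d.size), breaks)

    unique, groups = [], []
    for sl in group_slices:
        sel = order[sl]
        unique.append(float(sorted_d[sl].mean()))
        groups.append(np.column_stack([iu[sel], ju[sel]]))
    return DistanceStructure(
        channel_indices=idx,
        distance_matrix=dmat,
        unique_distances=np.array(unique),
        pair_groups=groups,
    )
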