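"""Electrode montages: channel labels, 3-D positions, and neighbor graphs.

A montage is the spatial scaffold for every topographic operation in the
package: the instantaneous spatial filter needs each channel's nearest
neighbors, and the ERN region of interest is defined as the channels
surrounding the topography's minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class ElectrodeMontage:
    """Ordered set of scalp electrodes with positions on the unit sphere.

    Parameters
    ----------
    channel_ids
        Unique channel labels, one per electrode, in data row order.
    positions
        ``(n_channels, 3)`` Cartesian coordinates (arbitrary length units,
        conventionally unit-sphere).
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray
    _dist: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.channel_ids) != pos.shape[0]:
            raise ValueError("channel_ids and positions length mismatch")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if pos.shape[0] < 2:
            raise ValueError("montage needs at least 2 channels")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_dist", cdist(pos, pos))

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def index(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)

    def neighbors(self, g: int) -> np.ndarray:
        """Indices of the ``g`` nearest channels (self excluded) per channel.

        Returns an ``(n_channels, g)`` integer array ordered by increasing
        distance; ties broken by channel index for determinism.
        """
        if not 1 <= g < self.n_channels:
            raise ValueError(f"g must be in [1, {self.n_channels - 1}], got {g}")
        order = np.argsort(self._dist, axis=1, kind="stable")
        return order[:, 1 : g + 1]  # column 0 is self (distance 0)

    def nearest_to(self, channel_id: str, n: int) -> list[str]:
        """The ``n`` channels closest to ``channel_id``, including itself."""
        if n > self.n_channels:
            raise ValueError("n exceeds channel count")
        i = self.index(channel_id)
        order = np.argsort(self._dist[i], kind="stable")
        return [self.channel_ids[j] for j in order[:n]]


def make_montage(n_channels: int, vertex_label: str = "Cz") -> ElectrodeMontage:
    """Build a synthetic upper-hemisphere montage with a vertex channel.

    Channels are spread quasi-uniformly over the upper unit hemisphere with a
    Fibonacci lattice; the channel closest to the vertex (0, 0, 1) is labelled
    ``vertex_label`` (the conventional Cz position), the rest ``E1``… in
    lattice order.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n_channels  # upper hemisphere: z in (0, 1)
    r = np.sqrt(1 - z**2)
    theta = 2 * np.pi * i / golden
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    vertex = int(np.argmax(pos[:, 2]))
    labels = []
    k = 1
    for j in range(n_channels):
        if j == vertex:
            labels.append(vertex_label)
        else:
            labels.append(f"E{k}")
            k += 1
    return ElectrodeMontage(tuple(labels), pos)


def read_sfp(path) -> ElectrodeMontage:
    """Read a whitespace-delimited montage file: ``label x y z`` per line."""
    labels, coords = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed montage line: {line!r}")
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:]])
    return ElectrodeMontage(tuple(labels), np.asarray(coords))


def write_sfp(montage: ElectrodeMontage, path) -> None:
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.channel_ids, montage.positions):
            fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")
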