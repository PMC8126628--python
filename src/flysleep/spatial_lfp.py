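"""Local field potential forward models and electrode geometries.

Two LFP estimators are provided.  The network-mean estimator averages the
membrane potential over all neurons.  The distance-weighted estimator places
the neurons and a point electrode on a 2-D plane and sums each neuron's
potential weighted by a single-neuron shape function

    f(r) = 1            for r < theta
    f(r) = (theta/r)^gamma   for r >= theta

with decay exponent gamma >= 0 and cutoff distance theta > 0 (the cutoff
avoids the point-source singularity).  Both estimators act on the raw
simulated potentials; band-limiting happens downstream in signal_analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpatialLayout",
    "LfpParams",
    "mean_lfp",
    "shape_function",
    "distance_lfp",
    "circle_layout",
    "grid_layout",
]


@dataclass(frozen=True)
class LfpParams:
    """Shape-function parameters for the distance-weighted LFP."""

    gamma: float = 2.0   # decay exponent (dimensionless)
    theta: float = 10.0  # cutoff distance (um)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass(frozen=True)
class SpatialLayout:
    """Per-neuron 2-D positions plus the electrode position, in um."""

    positions: np.ndarray  # (n, 2)
    electrode: np.ndarray  # (2,)
    kind: str = "custom"

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        el = np.asarray(self.electrode, dtype=float).reshape(2)
        if pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(el))):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "electrode", el)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def distances(self) -> np.ndarray:
        """Euclidean distance of each neuron from the electrode (um)."""
        return np.linalg.norm(self.positions - self.electrode, axis=1)

    def save(self, path: str | os.PathLike) -> None:
        """Text serialization: index, x, y rows; electrode in the header."""
        idx = np.arange(self.n)
        np.savetxt(path, np.column_stack([idx, self.positions]),
                   fmt=["%d", "%.6f", "%.6f"],
                   header=f"electrode {self.electrode[0]} {self.electrode[1]} kind {self.kind}")


def mean_lfp(V: np.ndarray) -> np.ndarray:
    """Network-mean LFP: per-timepoint average of the membrane potentials.

    ``V`` is (n, T); returns a length-T series in mV.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.size == 0:
        raise ValueError("empty potential matrix")
    return V.mean(axis=0)


def shape_function(r, params: LfpParams = LfpParams()):
    """Distance weight f(r): 1 inside the cutoff, power-law decay outside.

    Continuous at r = theta and non-increasing in r.  Accepts arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")
    far = r >= params.theta
    out = np.ones_like(r)
    out[far] = (params.theta / r[far]) ** params.gamma
    return out[()]


def distance_lfp(V: np.ndarray, layout: SpatialLayout,
                 params: LfpParams = LfpParams()) -> np.ndarray:
    """Distance-weighted LFP: Phi(t) = sum_i V_i(t) f(r_i).

    Linear in V; with gamma = 0 every weight is 1 and Phi = n * mean_lfp.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[0] != layout.n:
        raise ValueError(f"V has {V.shape[0]} rows for layout n={layout.n}")
    w = np.atleast_1d(shape_function(layout.distances(), params))
    return w @ V


def circle_layout(n: int, radius: float = 100.0) -> SpatialLayout:
    """Neurons equally spaced on a circle, electrode at the center.

    All neurons sit at the same distance (the radius), so every weight is
    equal and the distance-weighted LFP is exactly proportional to the
    network mean.
    """
    if n < 1 or radius <= 0:
        raise ValueError("need n >= 1 and radius > 0")
    ang = 2 * np.pi * np.arange(n) / n
    pos = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return SpatialLayout(positions=pos, electrode=np.zeros(2), kind="circle")


def grid_layout(rows: int, cols: int, spacing: float = 100.0,
                origin=(100.0, 100.0), electrode=(150.0, 500.0)) -> SpatialLayout:
    """Row-major square lattice of neurons with a point electrode.

    The first neuron sits at ``origin``; x increases along columns, y along
    rows, with ``spacing`` um between lattice neighbors.
    """
    if rows < 1 or cols < 1 or spacing <= 0:
        raise ValueError("need rows, cols >= 1 and spacing > 0")
    ox, oy = origin
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    pos = np.column_stack([ox + cc * spacing, oy + rr * spacing]).astype(float)
    return SpatialLayout(positions=pos, electrode=np.asarray(electrode, dtype=float),
                         kind="grid")
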