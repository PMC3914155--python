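"""Electrode arrays and current-source grids.

Coordinate convention
---------------------
All geometry is expressed in micrometers, in a local Cartesian frame attached
to the cortical patch: ``x`` and ``y`` are tangential, ``z`` is cortical depth,
positive downward from the pia.  Conversion to SI units happens only inside the
volume-conductor kernels.

Linear indexing of lattice nodes is x-fastest, then y, then z: node
``(a, b, c)`` has flat index ``a + m_x * (b + m_y * c)``.  Every matrix in the
package (lead fields, Laplacians) uses this single convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeArray",
    "SourceGrid",
    "build_grid",
    "build_lattice_array",
    "centered_grid",
    "neighbor_indices",
    "named_layouts",
    "get_layout",
]


@dataclass(frozen=True)
class ElectrodeArray:
    """Positions of N recording sites plus lattice metadata.

    Parameters
    ----------
    positions : (N, 3) float array, micrometers
    n_x, n_y : int
        Shank counts along the two tangential axes (0 when the layout is not
        a full lattice).
    n_z : int
        Recording sites per shank.
    labels : list of str
        Per-site identifiers.
    """

    positions: np.ndarray
    n_x: int
    n_y: int
    n_z: int
    labels: tuple = field(default=())
    name: str = ""

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        object.__setattr__(self, "positions", pos)
        if self.is_lattice and self.n_x * self.n_y * self.n_z != len(pos):
            raise ValueError("n_x * n_y * n_z does not match number of positions")
        # all sites must be distinct
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.min(d2) <= 0.0:
            raise ValueError("electrode positions must be pairwise distinct")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"ch{i:03d}" for i in range(len(pos)))
            )

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def is_lattice(self) -> bool:
        return self.n_x > 0 and self.n_y > 0 and self.n_z > 0

    def bounding_box(self):
        """(min_xyz, max_xyz) of the site positions, micrometers."""
        return self.positions.min(axis=0), self.positions.max(axis=0)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "n_z": self.n_z,
            "labels": list(self.labels),
            "positions_um": self.positions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeArray":
        return cls(
            positions=np.asarray(d["positions_um"], dtype=float),
            n_x=int(d.get("n_x", 0)),
            n_y=int(d.get("n_y", 0)),
            n_z=int(d.get("n_z", 0)),
            labels=tuple(d.get("labels", ())),
            name=d.get("name", ""),
        )


@dataclass(frozen=True)
class SourceGrid:
    """Regular 3D lattice of candidate source nodes.

    ``guard_mask`` marks nodes that are kept in the inverse (they implement a
    free boundary condition absorbing sources from outside the electrode-covered
    volume) but are excluded from every reported metric.
    """

    origin: np.ndarray
    shape: tuple  # (m_x, m_y, m_z)
    d: float  # inter-node spacing, micrometers
    guard_mask: np.ndarray = None  # bool per node, True = guard
    guard_widths: tuple = (0, 0, 0)  # per-side guard planes along x, y, z

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        object.__setattr__(self, "origin", origin)
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be three positive integers")
        object.__setattr__(self, "shape", shape)
        if not (self.d > 0):
            raise ValueError("inter-node spacing d must be positive")
        gw = tuple(int(g) for g in self.guard_widths)
        object.__setattr__(self, "guard_widths", gw)
        if self.guard_mask is None:
            object.__setattr__(self, "guard_mask", _guard_mask(shape, gw))
        else:
            gm = np.asarray(self.guard_mask, dtype=bool).reshape(self.n_nodes)
            object.__setattr__(self, "guard_mask", gm)

    @property
    def n_nodes(self) -> int:
        m_x, m_y, m_z = self.shape
        return m_x * m_y * m_z

    @property
    def positions(self) -> np.ndarray:
        """(M, 3) node coordinates, x-fastest ordering."""
        m_x, m_y, m_z = self.shape
        a = np.arange(m_x)
        b = np.arange(m_y)
        c = np.arange(m_z)
        A, B, C = np.meshgrid(a, b, c, indexing="ij")
        # x-fastest flat order: index = a + m_x*(b + m_y*c)
        idx = np.stack([A, B, C], axis=-1).reshape(-1, 3, order="F")
        # order="F" on the (m_x, m_y, m_z, 3) stack flattens x fastest
        return self.origin[None, :] + idx * self.d

    def flat_index(self, a, b, c):
        m_x, m_y, _ = self.shape
        return np.asarray(a) + m_x * (np.asarray(b) + m_y * np.asarray(c))

    def unflatten(self, j):
        m_x, m_y, _ = self.shape
        j = np.asarray(j)
        a = j % m_x
        b = (j // m_x) % m_y
        c = j // (m_x * m_y)
        return a, b, c

    @property
    def interior_shape(self) -> tuple:
        gx, gy, gz = self.guard_widths
        m_x, m_y, m_z = self.shape
        return (m_x - 2 * gx, m_y - 2 * gy, m_z - 2 * gz)

    def to_dict(self) -> dict:
        return {
            "origin_um": self.origin.tolist(),
            "shape": list(self.shape),
            "d_um": self.d,
            "guard_widths": list(self.guard_widths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceGrid":
        return cls(
            origin=np.asarray(d["origin_um"], dtype=float),
            shape=tuple(d["shape"]),
            d=float(d["d_um"]),
            guard_widths=tuple(d.get("guard_widths", (0, 0, 0))),
        )


def _guard_mask(shape, guard_widths):
    m_x, m_y, m_z = shape
    gx, gy, gz = guard_widths
    mask3 = np.zeros((m_x, m_y, m_z), dtype=bool)
    if gx:
        mask3[:gx, :, :] = True
        mask3[-gx:, :, :] = True
    if gy:
        mask3[:, :gy, :] = True
        mask3[:, -gy:, :] = True
    if gz:
        mask3[:, :, :gz] = True
        mask3[:, :, -gz:] = True
    return mask3.reshape(-1, order="F")


def build_grid(origin, counts, d, guard_widths=(0, 0, 0)) -> SourceGrid:
    """Build a regular source lattice.

    Node ``(a, b, c)`` sits at ``origin + (a*d, b*d, c*d)``; flat indexing is
    x-fastest.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 1 for c in counts):
        raise ValueError("counts must be >= 1 on each axis")
    if not (float(d) > 0):
        raise ValueError("d must be positive")
    return SourceGrid(origin=origin, shape=counts, d=float(d), guard_widths=guard_widths)


def centered_grid(array: ElectrodeArray, counts, d, guard_widths=(0, 0, 0),
                  offset=(0.0, 0.0, 0.0)) -> SourceGrid:
    """Grid centered on the array's bounding box (plus an optional offset).

    With even node counts the lattice is staggered half a spacing off the
    bounding-box center, which keeps nodes away from electrode positions.
    """
    lo, hi = array.bounding_box()
    center = 0.5 * (lo + hi) + np.asarray(offset, dtype=float)
    counts = tuple(int(c) for c in counts)
    extent = (np.asarray(counts) - 1) * float(d)
    origin = center - extent / 2.0
    return build_grid(origin, counts, d, guard_widths=guard_widths)


def neighbor_indices(grid: SourceGrid, j: int):
    """Indices of face-adjacent nodes (lattice distance exactly d); 3-6 entries."""
    if not (0 <= j < grid.n_nodes):
        raise IndexError(f"node index {j} out of range [0, {grid.n_nodes})")
    a, b, c = grid.unflatten(j)
    m_x, m_y, m_z = grid.shape
    out = []
    for da, db, dc in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        na, nb, nc = a + da, b + db, c + dc
        if 0 <= na < m_x and 0 <= nb < m_y and 0 <= nc < m_z:
            out.append(int(grid.flat_index(na, nb, nc)))
    return out


def build_lattice_array(counts, pitch, origin=(0.0, 0.0, 0.0), name="") -> ElectrodeArray:
    """Full-lattice electrode array: ``counts`` sites per axis at per-axis ``pitch``.

    ``pitch`` may be a scalar (equidistant) or a (px, py, pz) triple.
    """
    counts = tuple(int(c) for c in counts)
    pitch = np.broadcast_to(np.asarray(pitch, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)
    n_x, n_y, n_z = counts
    xs = origin[0] + np.arange(n_x) * pitch[0]
    ys = origin[1] + np.arange(n_y) * pitch[1]
    zs = origin[2] + np.arange(n_z) * pitch[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pos = np.stack([X, Y, Z], axis=-1).reshape(-1, 3, order="F")
    return ElectrodeArray(positions=pos, n_x=n_x, n_y=n_y, n_z=n_z, name=name)


# Standard layouts used throughout the validation experiments.  The 128-site
# probe: 4x4 shanks at 400 um tangential pitch, 8 sites per shank at 200 um
# axial pitch, shank tips reaching 1600 um depth (topmost site at 200 um).
_LAYOUTS = {
    "array128": dict(counts=(4, 4, 8), pitch=(400.0, 400.0, 200.0)),
    "array64_equidistant": dict(counts=(4, 4, 4), pitch=(400.0, 400.0, 400.0)),
    "sim_9x9x15": dict(counts=(9, 9, 15), pitch=(100.0, 100.0, 100.0)),
}


def named_layouts():
    """Names of the standard array layouts shipped with the package."""
    return sorted(_LAYOUTS)


def get_layout(name: str) -> ElectrodeArray:
    """Return a standard array layout by name.

    ``array128``
        4x4 shanks at 400 um pitch, 8 sites/shank at 200 um pitch (N=128),
        spanning depths 200-1600 um.
    ``array64_equidistant``
        the equidistant 400 um subset used for the interpolation baseline
        (N=64), depths 200-1400 um.
    ``sim_9x9x15``
        simulation-only dense array, 100 um pitch on all axes (N=1215),
        depths 200-1600 um.
    """
    if name not in _LAYOUTS:
        raise KeyError(f"unknown layout {name!r}; choose from {named_layouts()}")
    spec = _LAYOUTS[name]
    counts = spec["counts"]
    pitch = np.asarray(spec["pitch"], dtype=float)
    extent = (np.asarray(counts) - 1) * pitch
    # tangentially centered on the origin, topmost site at 200 um depth
    origin = np.array([-extent[0] / 2.0, -extent[1] / 2.0, 200.0])
    return build_lattice_array(counts, pitch, origin=origin, name=name)
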