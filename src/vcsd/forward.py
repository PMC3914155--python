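"""Lead-field assembly and reference handling.

The lead field ``G`` maps point currents (A) at the source-grid nodes to
potentials (V) at the electrodes: ``phi = G @ I``.  With the grid's cubic
volume elements, point currents and current source density are related by
``I_j = C_j * d^3``, so the same matrix maps CSD once the volume factor is
absorbed (the solvers do this).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import h5py
import numpy as np

from .conductors import InfiniteHomogeneousConductor
from .errors import ProximityError, ReferenceStateError
from .geometry import ElectrodeArray, SourceGrid

__all__ = [
    "LeadField",
    "assemble_leadfield",
    "average_reference_operator",
    "apply_average_reference",
    "save_leadfield",
    "load_leadfield",
]

MONOPOLAR = "monopolar_vs_infinity"
AVERAGE = "average_reference"


@dataclass(frozen=True)
class LeadField:
    """N x M lead-field matrix with its provenance.

    ``reference`` records whether rows are monopolar potentials against a
    reference at infinity or have been transformed to the average reference.
    """

    matrix: np.ndarray
    array: ElectrodeArray
    grid: SourceGrid
    conductor_kind: str
    reference: str = MONOPOLAR
    fingerprint: str = ""

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def _fingerprint(array, grid, model) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(array.positions).tobytes())
    h.update(json.dumps(grid.to_dict(), sort_keys=True).encode())
    if isinstance(model, InfiniteHomogeneousConductor):
        h.update(f"InfH:{model.sigma}".encode())
    else:
        h.update(json.dumps(model.to_dict(), sort_keys=True).encode())
    return h.hexdigest()[:16]


def assemble_leadfield(array: ElectrodeArray, grid: SourceGrid, model,
                       exclusion_radius=None) -> LeadField:
    """Assemble the N x M lead field for one array/grid/conductor triple.

    Raises :class:`ProximityError` when any electrode sits within
    ``exclusion_radius`` (default ``grid.d / 10``) of a grid node: the
    monopole kernel diverges there and such layouts are rejected explicitly.
    """
    if exclusion_radius is None:
        exclusion_radius = grid.d / 10.0
    epos = array.positions
    spos = grid.positions
    # proximity guard (chunked to bound memory on large grids)
    offenders = []
    for lo in range(0, len(epos), 64):
        block = epos[lo:lo + 64]
        d2 = np.sum((block[:, None, :] - spos[None, :, :]) ** 2, axis=-1)
        bad = np.argwhere(d2 < exclusion_radius ** 2)
        for bi, bj in bad:
            offenders.append((int(lo + bi), int(bj), float(np.sqrt(d2[bi, bj]))))
    if offenders:
        raise ProximityError(offenders)
    matrix = model.greens_matrix(epos, spos)
    return LeadField(
        matrix=matrix, array=array, grid=grid,
        conductor_kind=getattr(model, "kind", type(model).__name__),
        reference=MONOPOLAR, fingerprint=_fingerprint(array, grid, model),
    )


def average_reference_operator(n: int) -> np.ndarray:
    """H = I - (1/n) * ones: projects out the common mode of n channels."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def apply_average_reference(lead_field: LeadField, potentials):
    """Transform the lead field rows and the potentials to the average reference.

    Returns ``(lead_field, potentials)`` with the lead field flagged; applying
    it twice is rejected since the transform is a projection whose repeated
    bookkeeping would silently hide a reference mismatch.
    """
    if lead_field.reference == AVERAGE:
        raise ReferenceStateError("lead field is already average-referenced")
    n = lead_field.n_electrodes
    phi = np.asarray(potentials, dtype=float)
    if phi.shape[0] != n:
        raise ValueError(f"potentials first axis must have length {n}")
    g = lead_field.matrix - lead_field.matrix.mean(axis=0, keepdims=True)
    phi_ref = phi - phi.mean(axis=0, keepdims=True)
    return replace(lead_field, matrix=g, reference=AVERAGE), phi_ref


def save_leadfield(lead_field: LeadField, path) -> None:
    """Cache a lead field to HDF5 with enough metadata to detect staleness."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=lead_field.matrix)
        f.attrs["reference"] = lead_field.reference
        f.attrs["conductor_kind"] = lead_field.conductor_kind
        f.attrs["fingerprint"] = lead_field.fingerprint
        f.attrs["array"] = json.dumps(lead_field.array.to_dict())
        f.attrs["grid"] = json.dumps(lead_field.grid.to_dict())


def load_leadfield(path, expected_fingerprint=None) -> LeadField:
    """Load a cached lead field; a fingerprint mismatch raises ValueError."""
    with h5py.File(path, "r") as f:
        fp = f.attrs["fingerprint"]
        if expected_fingerprint is not None and fp != expected_fingerprint:
            raise ValueError(
                f"stale lead-field cache: fingerprint {fp} != {expected_fingerprint}")
        return LeadField(
            matrix=f["matrix"][()],
            array=ElectrodeArray.from_dict(json.loads(f.attrs["array"])),
            grid=SourceGrid.from_dict(json.loads(f.attrs["grid"])),
            conductor_kind=f.attrs["conductor_kind"],
            reference=f.attrs["reference"],
            fingerprint=fp,
        )
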