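"""Container for CSD values defined on a source grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SourceGrid

__all__ = ["CSDVolume"]


@dataclass(frozen=True)
class CSDVolume:
    """CSD values over a grid: shape (M,) or (M, T) for time series.

    ``lambda_used`` is set only for regularized inverse solutions; ``method``
    is one of ``vcsd``, ``icsd3d`` or ``phantom``.
    """

    values: np.ndarray
    grid: SourceGrid
    method: str = "phantom"
    lambda_used: float = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != self.grid.n_nodes:
            raise ValueError(
                f"values first axis ({v.shape[0]}) must match grid nodes "
                f"({self.grid.n_nodes})")
        object.__setattr__(self, "values", v)
        if self.method == "vcsd" and self.lambda_used is None:
            raise ValueError("vcsd volumes must record lambda_used")
        if self.method != "vcsd" and self.lambda_used is not None:
            raise ValueError("lambda_used is only meaningful for vcsd volumes")

    @property
    def n_nodes(self) -> int:
        return self.grid.n_nodes

    def as_3d(self):
        """Values reshaped to (m_x, m_y, m_z[, T]), x-fastest unflattening."""
        extra = self.values.shape[1:]
        return self.values.reshape(self.grid.shape + extra, order="F")

    def interior_values(self):
        """Values at non-guard nodes only."""
        return self.values[~self.grid.guard_mask]
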