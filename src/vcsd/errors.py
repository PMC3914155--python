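"""Exception types shared across the package."""


class SingularityError(ValueError):
    """An observation point coincides (or nearly coincides) with a source point."""


class ProximityError(ValueError):
    """Electrodes fall inside the exclusion radius of grid nodes.

    Carries the offending ``(electrode_index, node_index, distance_um)`` triples.
    """

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            f"{len(self.pairs)} electrode/node pairs violate the exclusion radius; "
            f"first offenders: {self.pairs[:5]}"
        )


class ConvergenceError(RuntimeError):
    """The spherical-harmonic series did not converge within ``max_terms``.

    Attributes
    ----------
    partial_sum : float or ndarray
        Value of the truncated series at the point the error was raised.
    n_terms : int
        Number of terms that were summed.
    """

    def __init__(self, message, partial_sum=None, n_terms=None):
        super().__init__(message)
        self.partial_sum = partial_sum
        self.n_terms = n_terms


class RankDeficiencyError(ValueError):
    """The unregularized normal matrix is numerically singular (advise lambda > 0)."""


class ReferenceStateError(ValueError):
    """Average reference applied twice, or mixed reference conventions."""


class SelectionError(RuntimeError):
    """No finite score on the regularization search grid."""


class DegenerateInputError(ValueError):
    """Input with no usable variance/energy (e.g. zero-variance potentials)."""
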