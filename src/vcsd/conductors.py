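"""Volume conductor models: infinite homogeneous and layered anisotropic sphere.

Two models are provided, mirroring the two Green's functions used by the
inverse method:

``InfiniteHomogeneousConductor`` (InfH)
    unbounded, homogeneous, isotropic medium; the monopole kernel is the
    closed form ``1 / (4 pi sigma r)``.

``LayeredSphereConductor`` (SphIh)
    concentric spherical regions, each with its own radial and tangential
    conductivity, embedded in an unbounded isotropic outer medium (open
    boundary: a monopole's current escapes to infinity where the potential
    vanishes).  The kernel is computed by the Legendre-series expansion in
    :mod:`vcsd._sphere_series`.

Geometric registration of the local Cartesian frame (x, y tangential; z =
cortical depth, positive down from the pia, micrometers) to the sphere: the
ROI axis passes through the sphere center, depth maps to decreasing radius,
and tangential offsets displace the point perpendicular to that axis, i.e.
a local point (x, y, z) sits at sphere-frame position (x, y, R_pia - z)
relative to the center.  A flat grid plane therefore bulges slightly relative
to the spherical layers, exactly as a flat probe does in curved cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from ._sphere_series import SphereSeriesEngine, summate
from .errors import SingularityError

__all__ = [
    "InfiniteHomogeneousConductor",
    "Shell",
    "LayeredSphereConductor",
    "default_cortex_profile",
    "load_profile",
    "save_profile",
]

_UM = 1e-6  # micrometers -> meters


@dataclass(frozen=True)
class InfiniteHomogeneousConductor:
    """Infinite homogeneous isotropic medium with conductivity ``sigma`` (S/m)."""

    sigma: float = 0.3
    kind: str = field(default="InfH", init=False)

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")

    def greens(self, r_e_um, r_s_um) -> float:
        """Potential (V) at ``r_e`` of a unit point current (A) at ``r_s``."""
        return float(self.greens_matrix(np.atleast_2d(r_e_um), np.atleast_2d(r_s_um))[0, 0])

    def greens_matrix(self, obs_um, src_um) -> np.ndarray:
        obs = np.atleast_2d(np.asarray(obs_um, dtype=float))
        src = np.atleast_2d(np.asarray(src_um, dtype=float))
        diff = obs[:, None, :] - src[None, :, :]
        dist_m = np.sqrt(np.sum(diff * diff, axis=-1)) * _UM
        if np.any(dist_m <= 1e-12):
            raise SingularityError("observation point coincides with a source point")
        return 1.0 / (4.0 * np.pi * self.sigma * dist_m)


@dataclass(frozen=True)
class Shell:
    """One concentric region: outer radius (um) and radial/tangential sigma (S/m).

    The first shell of a profile is the central ball (its region extends to
    the sphere center); subsequent shells are annuli.
    """

    outer_radius_um: float
    sigma_radial: float
    sigma_tangential: float


class LayeredSphereConductor:
    """Layered inhomogeneous, anisotropic spherical volume conductor.

    Parameters
    ----------
    shells : sequence of :class:`Shell`, strictly increasing radii.  The last
        shell's outer radius is taken as the pia surface: local depth 0 maps
        onto that radius.
    outer_sigma : conductivity (S/m) of the unbounded medium above the pia.
    center_xy_um : tangential offset of the sphere axis from the local origin.
    series_tolerance, max_terms, accelerate : series controls; the tolerance
        is the relative-term cutoff for early truncation.
    """

    kind = "SphIh"

    def __init__(self, shells, outer_sigma=1.5, center_xy_um=(0.0, 0.0),
                 series_tolerance=1e-8, max_terms=512, accelerate=True):
        shells = [s if isinstance(s, Shell) else Shell(*s) for s in shells]
        radii = np.array([s.outer_radius_um for s in shells], dtype=float)
        if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
            raise ValueError("shell radii must be strictly increasing and positive")
        for s in shells:
            if s.sigma_radial <= 0 or s.sigma_tangential <= 0:
                raise ValueError("conductivities must be positive")
        if outer_sigma <= 0:
            raise ValueError("outer_sigma must be positive")
        self.shells = tuple(shells)
        self.outer_sigma = float(outer_sigma)
        self.center_xy_um = tuple(float(v) for v in center_xy_um)
        self.series_tolerance = float(series_tolerance)
        self.max_terms = int(max_terms)
        self.accelerate = bool(accelerate)
        self._engine = None

    # ------------------------------------------------------------ registration

    @property
    def pia_radius_um(self) -> float:
        return self.shells[-1].outer_radius_um

    @property
    def center_um(self) -> np.ndarray:
        cx, cy = self.center_xy_um
        return np.array([cx, cy, self.pia_radius_um])

    def register(self, points_um):
        """Map local points to (radius_um, unit_vector) in the sphere frame."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        v = np.empty_like(p)
        v[:, 0] = p[:, 0] - self.center_um[0]
        v[:, 1] = p[:, 1] - self.center_um[1]
        v[:, 2] = self.pia_radius_um - p[:, 2]
        r = np.sqrt(np.sum(v * v, axis=1))
        if np.any(r <= 0):
            raise ValueError("point coincides with the sphere center")
        return r, v / r[:, None]

    # ----------------------------------------------------------------- kernel

    @property
    def engine(self) -> SphereSeriesEngine:
        if self._engine is None:
            self._engine = SphereSeriesEngine(
                boundaries_m=[s.outer_radius_um * _UM for s in self.shells],
                sigma_r=[s.sigma_radial for s in self.shells],
                sigma_t=[s.sigma_tangential for s in self.shells],
                sigma_out=self.outer_sigma,
                n_max=self.max_terms,
            )
        return self._engine

    def greens(self, r_e_um, r_s_um) -> float:
        """Potential (V) at ``r_e`` of a unit point current (A) at ``r_s``."""
        return float(self.greens_matrix(np.atleast_2d(r_e_um), np.atleast_2d(r_s_um))[0, 0])

    def greens_matrix(self, obs_um, src_um, pair_chunk=2_000_000) -> np.ndarray:
        """Dense kernel matrix (n_obs, n_src), V per unit A."""
        obs = np.atleast_2d(np.asarray(obs_um, dtype=float))
        src = np.atleast_2d(np.asarray(src_um, dtype=float))
        n_obs, n_src = len(obs), len(src)
        eng = self.engine

        pts = np.vstack([obs, src])
        radii_um, units = self.register(pts)
        radii_m = radii_um * _UM
        ln_in, sg_in, ln_out, sg_out, region = eng.point_tables(radii_m)
        psi = eng.psi(radii_m)

        i_obs = np.arange(n_obs)
        i_src = n_obs + np.arange(n_src)
        out = np.empty((n_obs, n_src))
        rows_per_chunk = max(1, int(pair_chunk // max(n_src, 1)))
        for lo in range(0, n_obs, rows_per_chunk):
            hi = min(lo + rows_per_chunk, n_obs)
            ro = i_obs[lo:hi]
            cosg = np.clip(units[ro] @ units[i_src].T, -1.0, 1.0).ravel()
            ia = np.repeat(ro, n_src)
            ib = np.tile(i_src, hi - lo)
            ra, rb = radii_m[ia], radii_m[ib]
            dist = np.sqrt(np.maximum(ra * ra + rb * rb - 2.0 * ra * rb * cosg, 0.0))
            if np.any(dist <= 1e-12):
                raise SingularityError(
                    "observation point coincides with a source point")
            swap = rb < ra
            imin = np.where(swap, ib, ia)
            imax = np.where(swap, ia, ib)
            g = np.exp(psi[imin] - psi[imax])
            kmin = region[imin]
            phi = summate(
                eng, ln_in, sg_in, ln_out, sg_out, kmin, imin, imax, cosg, g,
                series_tolerance=self.series_tolerance,
                accelerate=self.accelerate,
            )
            out[lo:hi, :] = phi.reshape(hi - lo, n_src)
        return out

    # -------------------------------------------------------------- profile IO

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "outer_medium_sigma": self.outer_sigma,
            "center_xy_um": list(self.center_xy_um),
            "shells": [
                {
                    "outer_radius_um": s.outer_radius_um,
                    "sigma_radial": s.sigma_radial,
                    "sigma_tangential": s.sigma_tangential,
                }
                for s in self.shells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, **kwargs) -> "LayeredSphereConductor":
        shells = [
            Shell(s["outer_radius_um"], s["sigma_radial"], s["sigma_tangential"])
            for s in d["shells"]
        ]
        return cls(
            shells,
            outer_sigma=float(d.get("outer_medium_sigma", 1.5)),
            center_xy_um=tuple(d.get("center_xy_um", (0.0, 0.0))),
            **kwargs,
        )


def default_cortex_profile(**kwargs) -> LayeredSphereConductor:
    """A plausible synthetic six-layer cortical profile (not measured data).

    White-matter core, six cortical-layer shells spanning depths 0-2000 um on
    a 5 mm pia radius, saline above the pia.  Conductivities are generic
    gray-matter values with mild layer-wise anisotropy; they stand in for a
    measured profile, and every validation experiment in this package uses
    the same profile for the forward and inverse models.
    """
    shells = [
        Shell(3000.0, 0.14, 0.14),   # white matter core (depth > 2000 um)
        Shell(3400.0, 0.42, 0.30),   # L6    (1600-2000 um)
        Shell(3950.0, 0.40, 0.32),   # L5b   (1050-1600 um)
        Shell(4250.0, 0.38, 0.35),   # L5a   (750-1050 um)
        Shell(4600.0, 0.45, 0.36),   # L4    (400-750 um)
        Shell(4850.0, 0.40, 0.33),   # L2/3  (150-400 um)
        Shell(5000.0, 0.35, 0.35),   # L1    (0-150 um)
    ]
    kwargs.setdefault("outer_sigma", 1.5)  # saline film above the pia
    return LayeredSphereConductor(shells, **kwargs)


def load_profile(path, **kwargs) -> LayeredSphereConductor:
    """Read a layered-sphere profile from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return LayeredSphereConductor.from_dict(d, **kwargs)


def save_profile(model: LayeredSphereConductor, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)
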