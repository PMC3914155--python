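"""Numerical engine for the layered anisotropic sphere Green's function.

The potential of a monopolar point current source in a radially layered
medium (each region with its own radial and tangential conductivity, plus an
unbounded isotropic medium outside the last boundary) is expanded in Legendre
polynomials of the angle between the source and observation radii:

    phi(r_e, r_s) = sum_n  -(2n+1) / (4 pi W_n) * f_in(r_<) * f_out(r_>) * P_n(cos g)

where, for each degree n, ``f_in`` is the radial solution regular at the
origin, ``f_out`` the one decaying at infinity, and ``W_n`` their conductivity
Wronskian ``sigma_r r^2 (f_in f_out' - f_out f_in')`` (constant in r).  Within
a region with conductivities (sigma_r, sigma_t) the radial solutions are
powers ``r^nu`` and ``r^(-nu-1)`` with

    nu(n) = -1/2 + sqrt(1/4 + (sigma_t/sigma_r) n (n+1)),

and the solutions are chained across region boundaries by continuity of the
potential and of the radial current density.  Coefficients are tracked with
per-region log scales so the chaining stays finite at high degree.

Convergence is geometric with ratio ``exp(-(Psi(r_>) - Psi(r_<)))`` where
``Psi' = sqrt(sigma_t/sigma_r) / r`` along the radial path; for observation
and source radii close to each other this is slow, so the summation subtracts
a two-term asymptote ``(c0 + c1/n) g^n`` fitted to the last computed terms and
adds its closed-form Legendre sums back analytically:

    sum_n g^n P_n(x)     = (1 - 2 g x + g^2)^(-1/2)
    sum_n g^n P_n(x) / n = ln( 2 / (1 - g x + sqrt(1 - 2 g x + g^2)) )

When every region shares one isotropic conductivity the exact term is
proportional to ``g^n``, the fitted asymptote reproduces it exactly and the
summation collapses to the closed form 1/(4 pi sigma |r_e - r_s|) to machine
precision at any truncation depth.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConvergenceError

_LN4PI = math.log(4.0 * math.pi)


class SphereSeriesEngine:
    """Radial-solution tables for one layered-sphere model.

    Parameters
    ----------
    boundaries_m : ascending array of region outer radii, meters.  Region k
        spans (boundaries[k-1], boundaries[k]); region 0 is the central ball.
    sigma_r, sigma_t : per-region conductivities, S/m.
    sigma_out : isotropic conductivity of the unbounded medium beyond the
        last boundary (the model is open: monopole current escapes to
        infinity, where the potential vanishes).
    n_max : highest Legendre degree tabulated.
    """

    def __init__(self, boundaries_m, sigma_r, sigma_t, sigma_out, n_max=512):
        b = np.asarray(boundaries_m, dtype=float)
        if b.ndim != 1 or len(b) < 1 or np.any(np.diff(b) <= 0) or b[0] <= 0:
            raise ValueError("boundaries must be strictly increasing and positive")
        sr = np.asarray(sigma_r, dtype=float)
        st = np.asarray(sigma_t, dtype=float)
        if len(sr) != len(b) or len(st) != len(b):
            raise ValueError("one (sigma_r, sigma_t) pair per region is required")
        if np.any(sr <= 0) or np.any(st <= 0) or sigma_out <= 0:
            raise ValueError("conductivities must be positive")
        self.b = b
        self.K = len(b)
        self.sr = sr
        self.st = st
        self.sigma_out = float(sigma_out)
        self.n_max = int(n_max)
        self._build_tables()

    # ------------------------------------------------------------------ tables

    def _nus(self, n):
        """nu for inside regions 0..K-1 plus the outer region (isotropic: nu=n)."""
        kappa = self.st / self.sr
        nu_in = -0.5 + np.sqrt(0.25 + kappa * n * (n + 1.0))
        return np.concatenate([nu_in, [float(n)]])

    def _build_tables(self):
        K, b = self.K, self.b
        n_deg = self.n_max + 1
        sr_all = np.concatenate([self.sr, [self.sigma_out]])
        NEG = -1e30  # stands in for log(0); dominates any basis exponent

        # per-degree, per-region coefficients of the two fundamental
        # solutions, kept as (log magnitude, sign) plus a region scale L so
        # the chaining never leaves the representable range of doubles
        self.nu = np.empty((n_deg, K + 1))
        tabs = {}
        for name in ("inn", "out"):
            tabs[name] = {
                "lnA": np.empty((n_deg, K + 1)), "sA": np.empty((n_deg, K + 1)),
                "lnB": np.empty((n_deg, K + 1)), "sB": np.empty((n_deg, K + 1)),
                "L": np.empty((n_deg, K + 1)),
            }

        def ref_radius(k):
            return b[k] if k < K else b[K - 1]

        def store(name, n, k, lnA, sA, lnB, sB, L):
            t = tabs[name]
            t["lnA"][n, k], t["sA"][n, k] = lnA, sA
            t["lnB"][n, k], t["sB"][n, k] = lnB, sB
            t["L"][n, k] = L

        def cross_step(f, h, s1, s2, nu2):
            """Match (value f, radial-flux combination h = rho*flux/sigma_r1)
            into a region with (sigma_r2, nu2); returns the two projections
            onto that region's growing/decaying solutions before the basis
            exponent shift."""
            P = (f * (nu2 + 1.0) + (s1 / s2) * h) / (2.0 * nu2 + 1.0)
            Q = (f * nu2 - (s1 / s2) * h) / (2.0 * nu2 + 1.0)
            return P, Q

        def lg(v):
            return math.log(abs(v)) if v != 0.0 else NEG

        for n in range(n_deg):
            nus = self._nus(n)
            self.nu[n] = nus
            # --- solution regular at the origin, chained outward
            lnA, sA, lnB, sB, L = 0.0, 1.0, NEG, 0.0, 0.0
            store("inn", n, 0, lnA, sA, lnB, sB, L)
            for k in range(K):
                rho = b[k]
                nu1, nu2 = nus[k], nus[k + 1]
                s1, s2 = sr_all[k], sr_all[k + 1]
                # region k basis at its own outer boundary: u = v = 1
                m = max(lnA, lnB)
                fa = sA * math.exp(lnA - m)
                fb = sB * math.exp(lnB - m)
                f = fa + fb
                h = fa * nu1 - fb * (nu1 + 1.0)
                P, Q = cross_step(f, h, s1, s2, nu2)
                lx = math.log(rho / ref_radius(k + 1))  # <= 0
                lnA2 = lg(P) - nu2 * lx
                lnB2 = lg(Q) + (nu2 + 1.0) * lx
                mm = max(lnA2, lnB2)
                lnA, sA = lnA2 - mm, math.copysign(1.0, P) if P else 0.0
                lnB, sB = lnB2 - mm, math.copysign(1.0, Q) if Q else 0.0
                L = L + m + mm
                store("inn", n, k + 1, lnA, sA, lnB, sB, L)
            # --- solution decaying at infinity, chained inward
            lnA, sA, lnB, sB, L = NEG, 0.0, 0.0, 1.0, 0.0
            store("out", n, K, lnA, sA, lnB, sB, L)
            for k in range(K - 1, -1, -1):
                rho = b[k]
                nu1, nu2 = nus[k + 1], nus[k]
                s1, s2 = sr_all[k + 1], sr_all[k]
                lx1 = math.log(rho / ref_radius(k + 1))  # <= 0
                a1 = lnA + nu1 * lx1
                a2 = lnB - (nu1 + 1.0) * lx1
                m = max(a1, a2)
                fa = sA * math.exp(a1 - m)
                fb = sB * math.exp(a2 - m)
                f = fa + fb
                h = fa * nu1 - fb * (nu1 + 1.0)
                P, Q = cross_step(f, h, s1, s2, nu2)
                # target region evaluated at its own outer boundary: u = v = 1
                lnA2, lnB2 = lg(P), lg(Q)
                mm = max(lnA2, lnB2)
                lnA, sA = lnA2 - mm, math.copysign(1.0, P) if P else 0.0
                lnB, sB = lnB2 - mm, math.copysign(1.0, Q) if Q else 0.0
                L = L + m + mm
                store("out", n, k, lnA, sA, lnB, sB, L)

        self._inn = tabs["inn"]
        self._out = tabs["out"]

        # conductivity Wronskian per inside region (constant in r; evaluated
        # from both solutions' coefficients within the region)
        nu_in = self.nu[:, :K]
        t1, t2 = self._inn, self._out
        c1 = t1["lnA"][:, :K] + t2["lnB"][:, :K]
        c2 = t2["lnA"][:, :K] + t1["lnB"][:, :K]
        m = np.maximum(c1, c2)
        cross = (t1["sA"][:, :K] * t2["sB"][:, :K] * np.exp(c1 - m)
                 - t2["sA"][:, :K] * t1["sB"][:, :K] * np.exp(c2 - m))
        mag = self.sr[None, :] * (2.0 * nu_in + 1.0) * b[None, :K] * np.abs(cross)
        with np.errstate(divide="ignore"):
            self.lnW = t1["L"][:, :K] + t2["L"][:, :K] + m + np.log(mag)
        self.sgW = -np.sign(cross)

        # asymptotic log-decay Psi(r) = integral of sqrt(st/sr)/r (continuous)
        s_ratio = np.sqrt(self.st / self.sr)
        psi_b = np.zeros(K)
        for k in range(1, K):
            psi_b[k] = psi_b[k - 1] + s_ratio[k] * math.log(b[k] / b[k - 1])
        self._s_ratio = s_ratio
        self._psi_b = psi_b

    # ----------------------------------------------------------------- points

    def region_of(self, radii_m):
        r = np.asarray(radii_m, dtype=float)
        if np.any(r >= self.b[-1]):
            raise ValueError("points must lie strictly inside the outer boundary")
        if np.any(r < 0):
            raise ValueError("negative radius")
        return np.searchsorted(self.b, r, side="left")

    def psi(self, radii_m):
        r = np.asarray(radii_m, dtype=float)
        reg = self.region_of(r)
        idx = np.maximum(reg - 1, 0)
        anchor = self.b[idx]
        with np.errstate(divide="ignore"):
            psi = self._psi_b[idx] + self._s_ratio[reg] * np.log(r / anchor)
        return psi

    def point_tables(self, radii_m):
        """Log-magnitude/sign of both radial solutions at each point, all degrees.

        Returns ``(ln_in, sg_in, ln_out, sg_out, region)`` with the first four
        shaped (n_max+1, n_points).
        """
        r = np.asarray(radii_m, dtype=float)
        reg = self.region_of(r)
        ref = self.b[reg]  # region reference radius (outer boundary)
        with np.errstate(divide="ignore"):
            lx = np.log(r / ref)
        out = []
        for t in (self._inn, self._out):
            nu_p = self.nu[:, reg]  # (n_deg, P)
            a1 = t["lnA"][:, reg] + nu_p * lx[None, :]
            a2 = t["lnB"][:, reg] - (nu_p + 1.0) * lx[None, :]
            m = np.maximum(a1, a2)
            val = (t["sA"][:, reg] * np.exp(a1 - m)
                   + t["sB"][:, reg] * np.exp(a2 - m))
            with np.errstate(divide="ignore"):
                ln = t["L"][:, reg] + m + np.log(np.abs(val))
            out.append((ln, np.sign(val)))
        (ln_in, sg_in), (ln_out, sg_out) = out
        return ln_in, sg_in, ln_out, sg_out, reg


def summate(engine, ln_in, sg_in, ln_out, sg_out, kmin, imin, imax, cosg, g,
            series_tolerance=1e-8, accelerate=True, max_terms=None,
            tail_error_limit=0.02):
    """Sum the Legendre series for a batch of (source, observation) pairs.

    ``imin``/``imax`` index the point tables by ascending radius per pair,
    ``kmin`` is the region of the smaller radius, ``cosg`` the cosine of the
    angle between the two radii and ``g`` the per-pair geometric decay ratio.
    Returns potentials in V/A.
    """
    n_avail = ln_in.shape[0] - 1
    n_used = n_avail if max_terms is None else min(int(max_terms), n_avail)
    x = np.asarray(cosg, dtype=float)
    npairs = x.shape[0]

    acc = np.zeros(npairs)
    s_geo = np.zeros(npairs)
    s_log = np.zeros(npairs)
    gpow = np.ones(npairs)
    p_nm1 = np.zeros(npairs)
    p_n = np.ones(npairs)  # P_0
    t_prev = np.zeros(npairs)
    t_last = np.zeros(npairs)
    gp_prev = np.ones(npairs)
    gp_last = np.ones(npairs)
    quiet = 0
    n_stop = n_used
    for n in range(n_used + 1):
        if n == 1:
            p_nm1, p_n = p_n, x.copy()
        elif n > 1:
            p_new = ((2 * n - 1) * x * p_n - (n - 1) * p_nm1) / n
            p_nm1, p_n = p_n, p_new
        lnt = (math.log(2 * n + 1) - _LN4PI
               + ln_in[n, imin] + ln_out[n, imax] - engine.lnW[n, kmin])
        sg = -(sg_in[n, imin] * sg_out[n, imax] * engine.sgW[n, kmin])
        t = sg * np.exp(lnt)
        acc += t * p_n
        s_geo += gpow * p_n
        if n >= 1:
            s_log += gpow * p_n / n
        t_prev, t_last = t_last, t
        gp_prev, gp_last = gp_last, gpow.copy()
        gpow *= g
        if n >= 16 and n % 8 == 0:
            scale = max(np.max(np.abs(acc)), 1e-300)
            if np.max(np.abs(t * p_n)) < series_tolerance * scale:
                quiet += 1
                if quiet >= 2:
                    n_stop = n
                    break
            else:
                quiet = 0

    if not accelerate:
        scale = np.maximum(np.abs(acc), 1e-300)
        rel = np.abs(t_last * p_n) / scale
        bad = rel > series_tolerance
        if np.any(bad):
            raise ConvergenceError(
                f"series not converged for {int(np.sum(bad))} pairs after "
                f"{n_stop + 1} terms (max residual term {np.max(rel):.2e})",
                partial_sum=acc, n_terms=n_stop + 1)
        return acc

    # two-term asymptote (c0 + c1/n) g^n fitted to the last two exact terms
    nl = n_stop
    with np.errstate(divide="ignore", invalid="ignore"):
        y2 = t_last / gp_last
        y1 = t_prev / gp_prev
        c1 = (y1 - y2) * nl * (nl - 1.0)
        c0 = y2 - c1 / nl
        den = np.maximum(1.0 - 2.0 * g * x + g * g, 0.0)
        sq = np.sqrt(den)
        f_full = 1.0 / np.maximum(sq, 1e-300)
        l_full = np.log(2.0 / np.maximum(1.0 - g * x + sq, 1e-300))
        tail = c0 * (f_full - s_geo) + c1 * (l_full - s_log)
    usable = (gp_last > 1e-280) & np.isfinite(tail)
    tail = np.where(usable, tail, 0.0)
    phi = acc + tail

    # residual after the two-term correction decays like g^n / n^2; bound its
    # tail with a coefficient of the order of |c1|.  The bound ignores the
    # oscillation of P_n and is conservative by orders of magnitude, so it is
    # used only as a guard against genuinely non-convergent (near-singular)
    # geometry, not as an accuracy statement.
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(
            usable,
            np.abs(c1) * gp_last * g
            / ((nl + 1.0) ** 2 * np.maximum(1.0 - g, 1.0 / (nl + 1.0))),
            0.0,
        )
    rel = est / np.maximum(np.abs(phi), 1e-300)
    bad = ~np.isfinite(phi) | (rel > tail_error_limit)
    if np.any(bad):
        raise ConvergenceError(
            f"series not converged for {int(np.sum(bad))} pairs after "
            f"{nl + 1} terms (est. max relative tail {np.nanmax(rel):.2e})",
            partial_sum=phi, n_terms=nl + 1)
    return phi
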