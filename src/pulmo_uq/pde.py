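"""1D pulse-wave propagation on a vessel network.

Solves the cross-sectionally averaged Navier-Stokes system

    dA/dt + dq/dx = 0
    dq/dt + d(q^2/A + B(A))/dx = -2*sqrt(pi)*mu*q / (rho*delta*sqrt(A))

per vessel, closed by an algebraic pressure-area wall law (linear elastic or
empirical tangent nonlinear), flow conservation + pressure continuity at
junctions, a prescribed periodic inflow at the root inlet, and three-element
Windkessel (RCR) outlets at terminal vessels.  ``B(A)`` is the pressure flux
potential with dB/dx = (A/rho) dptilde/dx, available in closed form for both
wall laws because vessels are straight (A0, chi constant per vessel).

Numerics: Richtmyer two-step Lax-Wendroff in the interior (second order in
space and time); boundaries closed by outgoing Riemann invariants
W+- = u +- phi(A), phi(A) = int_{A0}^{A} c(A')/A' dA', integrated along the
characteristic with a predictor-corrected foot and the friction source, and
solved together with the boundary condition by damped Newton iteration
(junctions: 3 characteristics + 2 pressure continuities + 1 flow
conservation).  The Windkessel ODE is discretized by the trapezoidal rule.
All internal arithmetic is cgs; pressures convert to mmHg at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import MMHG_PER_CGS, PhysicalConstants
from .exceptions import ConfigurationError, DomainError, SolverError
from .network import NominalWindkessel, VesselNetwork

__all__ = [
    "PhysicalConstants",
    "WallModel",
    "SimulationGrid",
    "HaemoFields",
    "stiffness",
    "wall_pressure",
    "area_from_pressure",
    "boundary_layer_thickness",
    "simulate",
    "check_cfl",
]


# ---------------------------------------------------------------------------
# Wall models
# ---------------------------------------------------------------------------

def stiffness(r0, f1: float, f2: float, f3: float):
    """Radius-dependent wall stiffness chi(r0) = f1*exp(f2*r0) + f3 (cgs)."""
    chi = f1 * np.exp(f2 * np.asarray(r0, dtype=float)) + f3
    if np.any(chi <= 0):
        raise DomainError("stiffness chi(r0) must be positive")
    if np.isscalar(r0):
        return float(chi)
    return chi


@dataclass
class WallModel:
    """Constitutive pressure-area law and its stiffness relation.

    ``kind`` selects the linear elastic law p = (4/3) chi (sqrt(A/A0) - 1)
    or the empirical nonlinear law p = chi tan[(pi/gamma)(A/A0 - 1)] (gamma
    sets the maximal lumen area A_inf = A0 (1 + gamma/2)).  ``stiffness_mode``
    selects constant stiffness (f1 = 0, shared f3), the exponential
    radius-dependent relation, or per-vessel values supplied in
    ``chi_per_vessel``.
    """

    kind: str = "linear"
    f1: float = 0.0
    f2: float = 0.0
    f3: float = 5.0e4
    gamma: float | None = None
    stiffness_mode: str = "constant"
    chi_per_vessel: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "nonlinear"):
            raise ConfigurationError(f"unknown wall kind {self.kind!r}")
        if self.stiffness_mode not in (
            "constant", "radius_dependent", "vessel_specific"
        ):
            raise ConfigurationError(
                f"unknown stiffness_mode {self.stiffness_mode!r}"
            )
        if self.kind == "nonlinear":
            if self.gamma is None or self.gamma <= 0:
                raise ConfigurationError("nonlinear wall requires gamma > 0")
        if self.stiffness_mode == "constant" and self.f1 != 0.0:
            raise ConfigurationError("constant stiffness requires f1 = 0")
        if self.stiffness_mode == "vessel_specific" and not self.chi_per_vessel:
            raise ConfigurationError(
                "vessel_specific stiffness requires chi_per_vessel"
            )

    def chi(self, r0: float, vessel_id: int | None = None) -> float:
        """Stiffness for a vessel of unstressed radius ``r0``."""
        if self.stiffness_mode == "vessel_specific":
            if vessel_id is None or vessel_id not in self.chi_per_vessel:
                raise DomainError(
                    f"no vessel-specific stiffness for vessel {vessel_id}"
                )
            chi = self.chi_per_vessel[vessel_id]
            if chi <= 0:
                raise DomainError("stiffness chi must be positive")
            return float(chi)
        return stiffness(r0, self.f1, self.f2, self.f3)


def wall_pressure(
    A,
    A0: float,
    wall: WallModel,
    r0: float,
    vessel_id: int | None = None,
    conv: float = 1.0 / MMHG_PER_CGS,
):
    """Transmural pressure (mmHg) at area ``A`` under the wall law.

    Vectorized over ``A``.  For the nonlinear law the tangent argument must
    lie inside (-pi/2, pi/2), i.e. A < A0 (1 + gamma/2).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise DomainError("area must be positive")
    chi = wall.chi(r0, vessel_id)
    s = A / A0
    if wall.kind == "linear":
        p = (4.0 / 3.0) * chi * (np.sqrt(s) - 1.0)
    else:
        theta = (math.pi / wall.gamma) * (s - 1.0)
        if np.any(np.abs(theta) >= math.pi / 2):
            raise DomainError(
                "tangent argument out of (-pi/2, pi/2): area beyond the "
                "maximal lumen area A0*(1 + gamma/2)"
            )
        p = chi * np.tan(theta)
    p = p / conv
    return float(p) if p.ndim == 0 else p


def area_from_pressure(
    p,
    A0: float,
    wall: WallModel,
    r0: float,
    vessel_id: int | None = None,
    conv: float = 1.0 / MMHG_PER_CGS,
):
    """Exact inverse of :func:`wall_pressure` (``p`` in mmHg)."""
    pt = np.asarray(p, dtype=float) * conv
    chi = wall.chi(r0, vessel_id)
    if wall.kind == "linear":
        root = 1.0 + 0.75 * pt / chi
        if np.any(root <= 0):
            raise DomainError("pressure below the collapse limit -4 chi/3")
        A = A0 * root ** 2
    else:
        A = A0 * (1.0 + (wall.gamma / math.pi) * np.arctan(pt / chi))
    return float(A) if A.ndim == 0 else A


def boundary_layer_thickness(constants: PhysicalConstants) -> float:
    """Stokes boundary-layer thickness delta = sqrt(mu*T / (2*pi*rho)), cm."""
    return math.sqrt(constants.mu * constants.T / (2.0 * math.pi * constants.rho))


# ---------------------------------------------------------------------------
# Grids and fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationGrid:
    """Numerical discretization settings.

    Defaults are the fine reference discretization (dx = 0.025 mm,
    dt = 1.34e-5 s); desk-scale runs pass coarser values.  The run stops
    after ``n_cycles`` cardiac cycles or earlier once the maximum relative
    cycle-to-cycle pressure change drops below ``convergence_tol``.
    """

    dx: float = 0.0025
    dt: float = 1.34e-5
    n_cycles: int = 10
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ConfigurationError("dx and dt must be positive")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")


@dataclass
class HaemoFields:
    """Last-cycle haemodynamic fields on the network.

    ``A``/``q``/``p`` are lists (one entry per vessel, in network order) of
    arrays with shape (n_store, n_nodes); ``t`` holds the within-cycle sample
    times (s) and ``x`` the per-vessel node coordinates (cm, 0 = inlet).
    Pressures are in mmHg.
    """

    network: VesselNetwork
    t: np.ndarray
    x: list[np.ndarray]
    A: list[np.ndarray]
    q: list[np.ndarray]
    p: list[np.ndarray]
    delta: float
    converged: bool
    n_cycles_run: int
    max_courant: float
    cycle_change: float
    grid: SimulationGrid
    #: flat (A, q) arrays at the final time, usable as a warm start
    final_state: tuple[np.ndarray, np.ndarray] | None = None

    def _vindex(self, vessel_id: int) -> int:
        for i, v in enumerate(self.network.vessels):
            if v.id == vessel_id:
                return i
        raise KeyError(vessel_id)

    def pressure_series(self, vessel_id: int, x_frac: float = 0.5) -> np.ndarray:
        """Pressure time series (mmHg) at fractional position ``x_frac``."""
        i = self._vindex(vessel_id)
        x = self.x[i]
        xq = x_frac * x[-1]
        p = self.p[i]
        j = min(np.searchsorted(x, xq), len(x) - 1)
        if j == 0:
            return p[:, 0].copy()
        w = (xq - x[j - 1]) / (x[j] - x[j - 1])
        return (1.0 - w) * p[:, j - 1] + w * p[:, j]

    def flow_series(self, vessel_id: int, x_frac: float = 0.5) -> np.ndarray:
        i = self._vindex(vessel_id)
        x = self.x[i]
        xq = x_frac * x[-1]
        q = self.q[i]
        j = min(np.searchsorted(x, xq), len(x) - 1)
        if j == 0:
            return q[:, 0].copy()
        w = (xq - x[j - 1]) / (x[j] - x[j - 1])
        return (1.0 - w) * q[:, j - 1] + w * q[:, j]

    def cycle_averaged_pressure(self, vessel_id: int, x_frac: float = 0.5) -> float:
        return float(np.mean(self.pressure_series(vessel_id, x_frac)))


# ---------------------------------------------------------------------------
# Low-level kernel (cgs units throughout)
# ---------------------------------------------------------------------------

_GLX = np.array([
    -0.9602898564975363, -0.7966664774136267, -0.5255324099163290,
    -0.1834346424956498, 0.1834346424956498, 0.5255324099163290,
    0.7966664774136267, 0.9602898564975363,
])
_GLW = np.array([
    0.1012285362903763, 0.2223810344533745, 0.3137066458778873,
    0.3626837833783620, 0.3626837833783620, 0.3137066458778873,
    0.2223810344533745, 0.1012285362903763,
])

_THETA_MAX = 0.5 * math.pi * (1.0 - 1e-9)


@njit(cache=True)
def _ptilde_k(A, A0, chi, gam, kind):
    s = A / A0
    if kind == 0:
        return (4.0 / 3.0) * chi * (math.sqrt(s) - 1.0)
    th = (math.pi / gam) * (s - 1.0)
    return chi * math.tan(th)


@njit(cache=True)
def _dptilde_k(A, A0, chi, gam, kind):
    if kind == 0:
        return (2.0 * chi / 3.0) / math.sqrt(A * A0)
    s = A / A0
    th = (math.pi / gam) * (s - 1.0)
    cs = math.cos(th)
    return chi * math.pi / (gam * A0 * cs * cs)


@njit(cache=True)
def _wavespeed_k(A, A0, chi, gam, kind, rho):
    return math.sqrt(A * _dptilde_k(A, A0, chi, gam, kind) / rho)


@njit(cache=True)
def _Bflux_k(A, A0, chi, gam, kind, rho):
    s = A / A0
    if kind == 0:
        return (4.0 * chi * A0 / (9.0 * rho)) * (s * math.sqrt(s) - 1.0)
    th = (math.pi / gam) * (s - 1.0)
    return (chi * A0 / rho) * (
        s * math.tan(th) + (gam / math.pi) * math.log(math.cos(th))
    )


@njit(cache=True)
def _phi_k(A, A0, chi, gam, kind, rho):
    # phi(A) = int_{A0}^{A} c(A')/A' dA'
    s = A / A0
    if kind == 0:
        c0 = math.sqrt(2.0 * chi / (3.0 * rho))
        return 4.0 * c0 * (s ** 0.25 - 1.0)
    pref = math.sqrt(chi * math.pi / (rho * gam))
    half = 0.5 * (s - 1.0)
    mid = 0.5 * (s + 1.0)
    tot = 0.0
    for i in range(8):
        sp = mid + half * _GLX[i]
        th = (math.pi / gam) * (sp - 1.0)
        tot += _GLW[i] / (math.cos(th) * math.sqrt(sp))
    return pref * half * tot


@njit(cache=True)
def _area_ok(A, A0, gam, kind):
    if A <= 0.0:
        return False
    if kind == 1:
        th = (math.pi / gam) * (A / A0 - 1.0)
        if th >= _THETA_MAX or th <= -_THETA_MAX:
            return False
    return True


@njit(cache=True)
def _clamp_area(A, A0, gam, kind):
    if kind == 1:
        lo = A0 * max(0.05, 1.0 - 0.49 * gam)
        hi = A0 * (1.0 + 0.49 * gam)
    else:
        lo = 0.05 * A0
        hi = 20.0 * A0
    if A < lo:
        return lo
    if A > hi:
        return hi
    return A


@njit(cache=True)
def _qin_eval(t, T, tab):
    ntab = tab.shape[0]
    tau = t % T
    x = tau / T * ntab
    i = int(x)
    f = x - i
    i = i % ntab
    j = (i + 1) % ntab
    return tab[i] * (1.0 - f) + tab[j] * f


@njit(cache=True)
def _char_target(A, q, off, n, dxv, A0, chi, gam, kind, rho, fric, dt, outlet,
                 lam_new, fric_new, use_new):
    """Riemann-invariant target at a boundary after one dt.

    outlet=True: right boundary, outgoing W+ = u + phi, speed u + c.
    outlet=False: left boundary, outgoing W- = u - phi, speed c - u.
    The characteristic foot solves x_B - x_f = dt/2 (lam(x_f, t^n) +
    lam(x_B, t^(n+1))) by fixed-point iteration and the friction source is
    integrated with the trapezoidal rule along the characteristic.  On the
    predictor pass (``use_new`` false) the new-time boundary values are
    approximated by the old ones; the corrector pass passes ``lam_new`` /
    ``fric_new`` evaluated at the provisional t^(n+1) boundary solution.
    """
    if outlet:
        ib = off + n - 1
        inb = ib - 1
    else:
        ib = off
        inb = ib + 1
    ub = q[ib] / A[ib]
    cb = _wavespeed_k(A[ib], A0, chi, gam, kind, rho)
    un = q[inb] / A[inb]
    cn = _wavespeed_k(A[inb], A0, chi, gam, kind, rho)
    if outlet:
        lam_b = ub + cb
        lam_n = un + cn
    else:
        lam_b = cb - ub
        lam_n = cn - un
    fa_b = fric * q[ib] / (A[ib] * math.sqrt(A[ib]))
    fa_n = fric * q[inb] / (A[inb] * math.sqrt(A[inb]))
    if not use_new:
        lam_new = lam_b
        fric_new = fa_b
    # fixed-point iteration for the foot position
    xi = lam_b * dt / dxv
    for _ in range(3):
        if xi < 0.0:
            xi = 0.0
        if xi > 1.0:
            xi = 1.0
        lam_f = (1.0 - xi) * lam_b + xi * lam_n
        xi = 0.5 * (lam_f + lam_new) * dt / dxv
    if xi < 0.0:
        xi = 0.0
    if xi > 1.0:
        xi = 1.0
    phib = _phi_k(A[ib], A0, chi, gam, kind, rho)
    phin = _phi_k(A[inb], A0, chi, gam, kind, rho)
    if outlet:
        Wb = ub + phib
        Wn = un + phin
    else:
        Wb = ub - phib
        Wn = un - phin
    W = (1.0 - xi) * Wb + xi * Wn
    fa_foot = (1.0 - xi) * fa_b + xi * fa_n
    return W + dt * 0.5 * (fa_foot + fric_new)


@njit(cache=True)
def _solve_inlet(qnew, Wm, A_init, A0, chi, gam, kind, rho, cref):
    """Newton for the inlet area given prescribed flow and the W- target."""
    A = A_init
    for _ in range(30):
        c = _wavespeed_k(A, A0, chi, gam, kind, rho)
        r = qnew / A - _phi_k(A, A0, chi, gam, kind, rho) - Wm
        if abs(r) / cref < 1e-10:
            return A, True
        dr = -qnew / (A * A) - c / A
        step = -r / dr
        # damped update with domain clamping
        ok = False
        for _h in range(20):
            Anew = _clamp_area(A + step, A0, gam, kind)
            rnew = qnew / Anew - _phi_k(Anew, A0, chi, gam, kind, rho) - Wm
            if abs(rnew) <= abs(r):
                A = Anew
                ok = True
                break
            step *= 0.5
        if not ok:
            A = _clamp_area(A + step, A0, gam, kind)
    c = _wavespeed_k(A, A0, chi, gam, kind, rho)
    r = qnew / A - _phi_k(A, A0, chi, gam, kind, rho) - Wm
    return A, abs(r) / cref < 1e-8


@njit(cache=True)
def _solve_outlet(Wp, pt_old, q_old, A_init, q_init, A0, chi, gam, kind, rho,
                  R1, R2, Cw, dt, cref):
    """Newton for (A, q) at a Windkessel outlet.

    Couples the outgoing W+ characteristic with the trapezoidal
    discretization of dp/dt - R1 dq/dt = q (R1+R2)/(R2 C) - p/(R2 C).
    """
    A = A_init
    q = q_init
    g_old = q_old * (R1 + R2) / (R2 * Cw) - pt_old / (R2 * Cw)
    for it in range(30):
        pt = _ptilde_k(A, A0, chi, gam, kind)
        g = q * (R1 + R2) / (R2 * Cw) - pt / (R2 * Cw)
        r0 = q / A + _phi_k(A, A0, chi, gam, kind, rho) - Wp
        r1 = (pt - pt_old) - R1 * (q - q_old) - 0.5 * dt * (g + g_old)
        r0s = r0 / cref
        r1s = r1 / chi
        if abs(r0s) < 1e-10 and abs(r1s) < 1e-10:
            return A, q, True
        c = _wavespeed_k(A, A0, chi, gam, kind, rho)
        dpt = _dptilde_k(A, A0, chi, gam, kind)
        j00 = -q / (A * A) + c / A
        j01 = 1.0 / A
        j10 = dpt * (1.0 + 0.5 * dt / (R2 * Cw))
        j11 = -R1 - 0.5 * dt * (R1 + R2) / (R2 * Cw)
        det = j00 * j11 - j01 * j10
        if det == 0.0:
            return A, q, False
        dA = -(r0 * j11 - j01 * r1) / det
        dq = -(j00 * r1 - r0 * j10) / det
        base = abs(r0s) + abs(r1s)
        scale = 1.0
        accepted = False
        for _h in range(20):
            An = _clamp_area(A + scale * dA, A0, gam, kind)
            qn = q + scale * dq
            ptn = _ptilde_k(An, A0, chi, gam, kind)
            gn = qn * (R1 + R2) / (R2 * Cw) - ptn / (R2 * Cw)
            r0n = qn / An + _phi_k(An, A0, chi, gam, kind, rho) - Wp
            r1n = (ptn - pt_old) - R1 * (qn - q_old) - 0.5 * dt * (gn + g_old)
            if abs(r0n / cref) + abs(r1n / chi) <= base:
                A = An
                q = qn
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            A = _clamp_area(A + dA, A0, gam, kind)
            q = q + dq
    pt = _ptilde_k(A, A0, chi, gam, kind)
    g = q * (R1 + R2) / (R2 * Cw) - pt / (R2 * Cw)
    r0 = (q / A + _phi_k(A, A0, chi, gam, kind, rho) - Wp) / cref
    r1 = ((pt - pt_old) - R1 * (q - q_old) - 0.5 * dt * (g + g_old)) / chi
    return A, q, abs(r0) < 1e-8 and abs(r1) < 1e-8


@njit(cache=True)
def _lin6(J, b):
    """In-place Gaussian elimination with partial pivoting (destroys J, b)."""
    n = 6
    for k in range(n):
        piv = k
        mx = abs(J[k, k])
        for i in range(k + 1, n):
            if abs(J[i, k]) > mx:
                mx = abs(J[i, k])
                piv = i
        if mx == 0.0:
            return False
        if piv != k:
            for j in range(k, n):
                tmp = J[k, j]
                J[k, j] = J[piv, j]
                J[piv, j] = tmp
            tmp = b[k]
            b[k] = b[piv]
            b[piv] = tmp
        for i in range(k + 1, n):
            fkt = J[i, k] / J[k, k]
            for j in range(k + 1, n):
                J[i, j] -= fkt * J[k, j]
            b[i] -= fkt * b[k]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= J[i, j] * b[j]
        b[i] = s / J[i, i]
    return True


@njit(cache=True)
def _junc_residual(x, Wp, Wm1, Wm2,
                   A0p, chip, gamp, kp,
                   A01, chi1, gam1, k1,
                   A02, chi2, gam2, k2,
                   rho, crefp, cref1, cref2, qscale, r):
    """Fill the 6 scaled residuals; return the max norm."""
    r[0] = (x[1] / x[0] + _phi_k(x[0], A0p, chip, gamp, kp, rho) - Wp) / crefp
    r[1] = (x[3] / x[2] - _phi_k(x[2], A01, chi1, gam1, k1, rho) - Wm1) / cref1
    r[2] = (x[5] / x[4] - _phi_k(x[4], A02, chi2, gam2, k2, rho) - Wm2) / cref2
    ptp = _ptilde_k(x[0], A0p, chip, gamp, kp)
    r[3] = (ptp - _ptilde_k(x[2], A01, chi1, gam1, k1)) / chip
    r[4] = (ptp - _ptilde_k(x[4], A02, chi2, gam2, k2)) / chip
    r[5] = (x[1] - x[3] - x[5]) / qscale
    nrm = 0.0
    for i in range(6):
        if abs(r[i]) > nrm:
            nrm = abs(r[i])
    return nrm


@njit(cache=True)
def _solve_junction(Wp, Wm1, Wm2, x,
                    A0p, chip, gamp, kp,
                    A01, chi1, gam1, k1,
                    A02, chi2, gam2, k2,
                    rho, r, J, step, xn, rn):
    """Damped 6x6 Newton for a bifurcation (workspace passed by caller).

    Unknowns x = (Ap, qp, A1, q1, A2, q2); residuals: three outgoing
    characteristics, two pressure continuities, one flow conservation,
    nondimensionalized by reference wave speeds / stiffness / flow scale.
    Solution is left in ``x``.
    """
    crefp = _wavespeed_k(A0p, A0p, chip, gamp, kp, rho)
    cref1 = _wavespeed_k(A01, A01, chi1, gam1, k1, rho)
    cref2 = _wavespeed_k(A02, A02, chi2, gam2, k2, rho)
    qscale = A0p * crefp
    for _it in range(30):
        nrm = _junc_residual(x, Wp, Wm1, Wm2, A0p, chip, gamp, kp,
                             A01, chi1, gam1, k1, A02, chi2, gam2, k2,
                             rho, crefp, cref1, cref2, qscale, r)
        if nrm < 1e-10:
            return True
        for i in range(6):
            for j in range(6):
                J[i, j] = 0.0
        cp = _wavespeed_k(x[0], A0p, chip, gamp, kp, rho)
        c1 = _wavespeed_k(x[2], A01, chi1, gam1, k1, rho)
        c2 = _wavespeed_k(x[4], A02, chi2, gam2, k2, rho)
        J[0, 0] = (-x[1] / (x[0] * x[0]) + cp / x[0]) / crefp
        J[0, 1] = (1.0 / x[0]) / crefp
        J[1, 2] = (-x[3] / (x[2] * x[2]) - c1 / x[2]) / cref1
        J[1, 3] = (1.0 / x[2]) / cref1
        J[2, 4] = (-x[5] / (x[4] * x[4]) - c2 / x[4]) / cref2
        J[2, 5] = (1.0 / x[4]) / cref2
        dptp = _dptilde_k(x[0], A0p, chip, gamp, kp)
        J[3, 0] = dptp / chip
        J[3, 2] = -_dptilde_k(x[2], A01, chi1, gam1, k1) / chip
        J[4, 0] = dptp / chip
        J[4, 4] = -_dptilde_k(x[4], A02, chi2, gam2, k2) / chip
        J[5, 1] = 1.0 / qscale
        J[5, 3] = -1.0 / qscale
        J[5, 5] = -1.0 / qscale
        for i in range(6):
            step[i] = -r[i]
        if not _lin6(J, step):
            return False
        scale = 1.0
        accepted = False
        for _h in range(20):
            for i in range(6):
                xn[i] = x[i] + scale * step[i]
            xn[0] = _clamp_area(xn[0], A0p, gamp, kp)
            xn[2] = _clamp_area(xn[2], A01, gam1, k1)
            xn[4] = _clamp_area(xn[4], A02, gam2, k2)
            nn = _junc_residual(xn, Wp, Wm1, Wm2, A0p, chip, gamp, kp,
                                A01, chi1, gam1, k1, A02, chi2, gam2, k2,
                                rho, crefp, cref1, cref2, qscale, rn)
            if nn <= nrm:
                for i in range(6):
                    x[i] = xn[i]
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            for i in range(6):
                x[i] = x[i] + step[i]
            x[0] = _clamp_area(x[0], A0p, gamp, kp)
            x[2] = _clamp_area(x[2], A01, gam1, k1)
            x[4] = _clamp_area(x[4], A02, gam2, k2)
    nrm = _junc_residual(x, Wp, Wm1, Wm2, A0p, chip, gamp, kp,
                         A01, chi1, gam1, k1, A02, chi2, gam2, k2,
                         rho, crefp, cref1, cref2, qscale, r)
    return nrm < 1e-8


@njit(cache=True)
def _run_lw(A, q, n_nodes, offs, dxv,
            A0v, kindv, chiv, gamv,
            junc, term_v, R1a, R2a, Ca,
            root, qin_tab, T, dt, ns, n_cycles, conv_tol, ramp,
            rho, fric,
            store_map, n_store,
            A_store, q_store, A_prev):
    """Advance the network for up to ``n_cycles`` cardiac cycles.

    Returns (status, loc_vessel, loc_step, cycles_run, max_courant,
    cycle_change, converged).  Status codes: 0 ok, 1 CFL violation,
    2 Newton failure, 3 nonphysical state (area out of wall-law domain).
    """
    nv = n_nodes.shape[0]
    N = A.shape[0]
    nj = junc.shape[0]
    nt = term_v.shape[0]
    F2 = np.empty(N)
    S2 = np.empty(N)
    Ah = np.empty(N)
    qh = np.empty(N)
    F2h = np.empty(N)
    S2h = np.empty(N)
    An = np.empty(N)
    qn = np.empty(N)
    Wp_t = np.empty(nt)
    pt_old_t = np.empty(nt)
    q_old_t = np.empty(nt)
    Wj = np.empty((nj, 3))
    # junction Newton workspace
    xj = np.empty(6)
    rj = np.empty(6)
    Jj = np.empty((6, 6))
    stepj = np.empty(6)
    xnj = np.empty(6)
    rnj = np.empty(6)
    max_cour = 0.0
    cycle_change = 1e30
    converged = False
    cycles_run = 0

    for cyc in range(n_cycles):
        for l in range(ns):
            tn = (cyc * ns + l) * dt
            tnp = tn + dt
            # fluxes and sources at t^n
            for v in range(nv):
                o = offs[v]
                n = n_nodes[v]
                A0 = A0v[v]
                chi = chiv[v]
                gam = gamv[v]
                kd = kindv[v]
                for jx in range(o, o + n):
                    a = A[jx]
                    qq = q[jx]
                    F2[jx] = qq * qq / a + _Bflux_k(a, A0, chi, gam, kd, rho)
                    S2[jx] = fric * qq / math.sqrt(a)
            # half steps (cell jx spans nodes jx, jx+1)
            for v in range(nv):
                o = offs[v]
                n = n_nodes[v]
                A0 = A0v[v]
                chi = chiv[v]
                gam = gamv[v]
                kd = kindv[v]
                lam = dt / (2.0 * dxv[v])
                for jx in range(o, o + n - 1):
                    a = 0.5 * (A[jx] + A[jx + 1]) - lam * (q[jx + 1] - q[jx])
                    qq = 0.5 * (q[jx] + q[jx + 1]) - lam * (F2[jx + 1] - F2[jx]) \
                        + 0.25 * dt * (S2[jx] + S2[jx + 1])
                    if not _area_ok(a, A0, gam, kd):
                        return 3, v, cyc * ns + l, cycles_run, max_cour, \
                            cycle_change, converged
                    Ah[jx] = a
                    qh[jx] = qq
                    F2h[jx] = qq * qq / a + _Bflux_k(a, A0, chi, gam, kd, rho)
                    S2h[jx] = fric * qq / math.sqrt(a)
            # interior update
            for v in range(nv):
                o = offs[v]
                n = n_nodes[v]
                A0 = A0v[v]
                gam = gamv[v]
                kd = kindv[v]
                lam = dt / dxv[v]
                for jx in range(o + 1, o + n - 1):
                    a = A[jx] - lam * (qh[jx] - qh[jx - 1])
                    qq = q[jx] - lam * (F2h[jx] - F2h[jx - 1]) \
                        + 0.5 * dt * (S2h[jx] + S2h[jx - 1])
                    if not _area_ok(a, A0, gam, kd):
                        return 3, v, cyc * ns + l, cycles_run, max_cour, \
                            cycle_change, converged
                    An[jx] = a
                    qn[jx] = qq
            # boundaries: predictor pass from the t^n state, then one
            # corrector pass with foot/source terms re-centred on the
            # provisional t^(n+1) boundary solution (keeps the closure
            # second order in time)
            qinlet = _qin_eval(tnp, T, qin_tab)
            # smooth first-cycle ramp suppresses the impulsive start-up
            # transient; cycles >= 2 (and the converged state) are unaffected
            if ramp and tnp < T:
                sr = math.sin(0.5 * math.pi * tnp / T)
                qinlet *= sr * sr
            for ti in range(nt):
                tv = term_v[ti]
                ie = offs[tv] + n_nodes[tv] - 1
                pt_old_t[ti] = _ptilde_k(A[ie], A0v[tv], chiv[tv], gamv[tv],
                                         kindv[tv])
                q_old_t[ti] = q[ie]
            for bc_pass in range(2):
                corr = bc_pass == 1
                # inlet of the root vessel
                o = offs[root]
                if corr:
                    u1 = qn[o] / An[o]
                    c1 = _wavespeed_k(An[o], A0v[root], chiv[root],
                                      gamv[root], kindv[root], rho)
                    lam_new = c1 - u1
                    fr_new = fric * qn[o] / (An[o] * math.sqrt(An[o]))
                else:
                    lam_new = 0.0
                    fr_new = 0.0
                Wm_root = _char_target(
                    A, q, offs[root], n_nodes[root], dxv[root], A0v[root],
                    chiv[root], gamv[root], kindv[root], rho, fric, dt,
                    False, lam_new, fr_new, corr)
                crefr = _wavespeed_k(A0v[root], A0v[root], chiv[root],
                                     gamv[root], kindv[root], rho)
                Ainit = An[o] if corr else A[o]
                Ain, okI = _solve_inlet(qinlet, Wm_root, Ainit, A0v[root],
                                        chiv[root], gamv[root], kindv[root],
                                        rho, crefr)
                if not okI:
                    return 2, root, cyc * ns + l, cycles_run, max_cour, \
                        cycle_change, converged
                An[o] = Ain
                qn[o] = qinlet
                # junctions
                for ji in range(nj):
                    pv = junc[ji, 0]
                    d1 = junc[ji, 1]
                    d2 = junc[ji, 2]
                    ip = offs[pv] + n_nodes[pv] - 1
                    i1 = offs[d1]
                    i2 = offs[d2]
                    if corr:
                        up = qn[ip] / An[ip]
                        cp = _wavespeed_k(An[ip], A0v[pv], chiv[pv],
                                          gamv[pv], kindv[pv], rho)
                        lp_new = up + cp
                        fp_new = fric * qn[ip] / (An[ip] * math.sqrt(An[ip]))
                        u1 = qn[i1] / An[i1]
                        c1 = _wavespeed_k(An[i1], A0v[d1], chiv[d1],
                                          gamv[d1], kindv[d1], rho)
                        l1_new = c1 - u1
                        f1_new = fric * qn[i1] / (An[i1] * math.sqrt(An[i1]))
                        u2 = qn[i2] / An[i2]
                        c2 = _wavespeed_k(An[i2], A0v[d2], chiv[d2],
                                          gamv[d2], kindv[d2], rho)
                        l2_new = c2 - u2
                        f2_new = fric * qn[i2] / (An[i2] * math.sqrt(An[i2]))
                    else:
                        lp_new = l1_new = l2_new = 0.0
                        fp_new = f1_new = f2_new = 0.0
                    Wj[ji, 0] = _char_target(
                        A, q, offs[pv], n_nodes[pv], dxv[pv], A0v[pv],
                        chiv[pv], gamv[pv], kindv[pv], rho, fric, dt, True,
                        lp_new, fp_new, corr)
                    Wj[ji, 1] = _char_target(
                        A, q, offs[d1], n_nodes[d1], dxv[d1], A0v[d1],
                        chiv[d1], gamv[d1], kindv[d1], rho, fric, dt, False,
                        l1_new, f1_new, corr)
                    Wj[ji, 2] = _char_target(
                        A, q, offs[d2], n_nodes[d2], dxv[d2], A0v[d2],
                        chiv[d2], gamv[d2], kindv[d2], rho, fric, dt, False,
                        l2_new, f2_new, corr)
                    if corr:
                        xj[0] = An[ip]
                        xj[1] = qn[ip]
                        xj[2] = An[i1]
                        xj[3] = qn[i1]
                        xj[4] = An[i2]
                        xj[5] = qn[i2]
                    else:
                        xj[0] = A[ip]
                        xj[1] = q[ip]
                        xj[2] = A[i1]
                        xj[3] = q[i1]
                        xj[4] = A[i2]
                        xj[5] = q[i2]
                    okJ = _solve_junction(
                        Wj[ji, 0], Wj[ji, 1], Wj[ji, 2], xj,
                        A0v[pv], chiv[pv], gamv[pv], kindv[pv],
                        A0v[d1], chiv[d1], gamv[d1], kindv[d1],
                        A0v[d2], chiv[d2], gamv[d2], kindv[d2],
                        rho, rj, Jj, stepj, xnj, rnj)
                    if not okJ:
                        return 2, pv, cyc * ns + l, cycles_run, max_cour, \
                            cycle_change, converged
                    An[ip] = xj[0]
                    qn[ip] = xj[1]
                    An[i1] = xj[2]
                    qn[i1] = xj[3]
                    An[i2] = xj[4]
                    qn[i2] = xj[5]
                # terminal Windkessel outlets
                for ti in range(nt):
                    tv = term_v[ti]
                    ie = offs[tv] + n_nodes[tv] - 1
                    if corr:
                        ut = qn[ie] / An[ie]
                        ct = _wavespeed_k(An[ie], A0v[tv], chiv[tv],
                                          gamv[tv], kindv[tv], rho)
                        lt_new = ut + ct
                        ft_new = fric * qn[ie] / (An[ie] * math.sqrt(An[ie]))
                    else:
                        lt_new = 0.0
                        ft_new = 0.0
                    Wp_t[ti] = _char_target(
                        A, q, offs[tv], n_nodes[tv], dxv[tv], A0v[tv],
                        chiv[tv], gamv[tv], kindv[tv], rho, fric, dt, True,
                        lt_new, ft_new, corr)
                    creft = _wavespeed_k(A0v[tv], A0v[tv], chiv[tv],
                                         gamv[tv], kindv[tv], rho)
                    Ainit = An[ie] if corr else A[ie]
                    qinit = qn[ie] if corr else q[ie]
                    Aout, qout, okT = _solve_outlet(
                        Wp_t[ti], pt_old_t[ti], q_old_t[ti], Ainit, qinit,
                        A0v[tv], chiv[tv], gamv[tv], kindv[tv], rho,
                        R1a[ti], R2a[ti], Ca[ti], dt, creft)
                    if not okT:
                        return 2, tv, cyc * ns + l, cycles_run, max_cour, \
                            cycle_change, converged
                    An[ie] = Aout
                    qn[ie] = qout
            # CFL check on the new state
            for v in range(nv):
                o = offs[v]
                n = n_nodes[v]
                for jx in range(o, o + n):
                    c = _wavespeed_k(An[jx], A0v[v], chiv[v], gamv[v],
                                     kindv[v], rho)
                    cour = (abs(qn[jx] / An[jx]) + c) * dt / dxv[v]
                    if cour > max_cour:
                        max_cour = cour
            if max_cour > 1.0:
                return 1, -1, cyc * ns + l, cycles_run, max_cour, \
                    cycle_change, converged
            A[:] = An
            q[:] = qn
            m = store_map[l]
            if m >= 0:
                for jx in range(N):
                    A_store[m, jx] = A[jx]
                    q_store[m, jx] = q[jx]
        cycles_run = cyc + 1
        # cycle-to-cycle convergence on pressure
        if cyc > 0:
            num = 0.0
            den = 1e-30
            for m in range(n_store):
                for v in range(nv):
                    o = offs[v]
                    n = n_nodes[v]
                    for jx in range(o, o + n):
                        pnow = _ptilde_k(A_store[m, jx], A0v[v], chiv[v],
                                         gamv[v], kindv[v])
                        pold = _ptilde_k(A_prev[m, jx], A0v[v], chiv[v],
                                         gamv[v], kindv[v])
                        d = abs(pnow - pold)
                        if d > num:
                            num = d
                        if abs(pnow) > den:
                            den = abs(pnow)
            cycle_change = num / den
            if cycle_change < conv_tol:
                converged = True
                A_prev[:] = A_store
                break
        A_prev[:] = A_store
    return 0, -1, -1, cycles_run, max_cour, cycle_change, converged


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------

def _inflow_table(inflow, T: float, n_tab: int = 2048) -> np.ndarray:
    """Resample an inflow waveform onto a uniform periodic table over [0, T)."""
    if hasattr(inflow, "t") and hasattr(inflow, "y"):
        t = np.asarray(inflow.t, dtype=float)
        qv = np.asarray(inflow.y, dtype=float)
    else:
        t, qv = inflow
        t = np.asarray(t, dtype=float)
        qv = np.asarray(qv, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("inflow times must be strictly increasing")
    if t[-1] > T * (1 + 1e-9):
        raise ConfigurationError(
            f"inflow series spans {t[-1]:.4g}s, longer than the period {T}s"
        )
    tt = np.arange(n_tab) * (T / n_tab)
    # periodic continuation: wrap the sample grid into [t0, t0+T)
    tau = (tt - t[0]) % T + t[0]
    tper = np.concatenate([t, [t[0] + T]])
    qper = np.concatenate([qv, [qv[0]]])
    return np.interp(tau, tper, qper)


def simulate(
    network: VesselNetwork,
    wall: WallModel,
    wk: NominalWindkessel,
    inflow,
    grid: SimulationGrid | None = None,
    constants: PhysicalConstants | None = None,
    n_store: int = 256,
    init_state: tuple[np.ndarray, np.ndarray] | None = None,
) -> HaemoFields:
    """Run the pulse-wave simulation and return the last cardiac cycle.

    Parameters
    ----------
    wk : NominalWindkessel
        RCR parameters per terminal vessel (already scaled if desired).
    inflow : TimeSeriesData | (t, q) pair
        One period of root inflow (ml s^-1) on a strictly increasing grid.
    n_store : int
        Number of evenly spaced within-cycle samples kept per node.
    init_state : (A, q) flat arrays, optional
        Warm start from a previous run on the same grid (e.g. the
        ``final_state`` of a neighbouring parameter point); when given, the
        start-up inflow ramp is skipped and fewer cycles are needed to reach
        the periodic state.
    """
    grid = grid or SimulationGrid()
    constants = constants or PhysicalConstants()
    nv = len(network)
    id2idx = {v.id: i for i, v in enumerate(network.vessels)}
    n_nodes = np.empty(nv, dtype=np.int64)
    dxv = np.empty(nv)
    A0v = np.empty(nv)
    chiv = np.empty(nv)
    gamv = np.empty(nv)
    kindv = np.empty(nv, dtype=np.int64)
    for i, v in enumerate(network.vessels):
        n = max(int(math.ceil(v.L / grid.dx)) + 1, 3)
        n_nodes[i] = n
        dxv[i] = v.L / (n - 1)
        A0v[i] = v.A0
        chiv[i] = wall.chi(v.r0, v.id)
        gamv[i] = wall.gamma if wall.kind == "nonlinear" else 1.0
        kindv[i] = 1 if wall.kind == "nonlinear" else 0
    offs = np.zeros(nv, dtype=np.int64)
    offs[1:] = np.cumsum(n_nodes)[:-1]
    N = int(n_nodes.sum())
    junc = np.array(
        [[id2idx[p], id2idx[d1], id2idx[d2]] for p, d1, d2 in network.junctions],
        dtype=np.int64,
    ).reshape(-1, 3)
    term_ids = [v.id for v in network.terminal_vessels]
    wk_pos = {tid: k for k, tid in enumerate(wk.terminal_ids)}
    missing = [tid for tid in term_ids if tid not in wk_pos]
    if missing:
        raise ConfigurationError(
            f"Windkessel parameters missing for terminal vessels {missing}"
        )
    term_v = np.array([id2idx[tid] for tid in term_ids], dtype=np.int64)
    R1a = np.array([wk.R1[wk_pos[tid]] for tid in term_ids])
    R2a = np.array([wk.R2[wk_pos[tid]] for tid in term_ids])
    Ca = np.array([wk.C[wk_pos[tid]] for tid in term_ids])
    root = id2idx[network.root.id]

    T = constants.T
    ns = max(int(round(T / grid.dt)), 2)
    dt = T / ns
    n_store = min(n_store, ns)
    store_idx = np.floor(np.arange(n_store) * ns / n_store).astype(np.int64)
    store_map = -np.ones(ns, dtype=np.int64)
    # the kernel stores AFTER advancing local step l (state time (l+1) dt),
    # so sample time idx*dt is produced by step (idx - 1) mod ns
    store_map[(store_idx - 1) % ns] = np.arange(n_store)

    qin_tab = _inflow_table(inflow, T)
    delta = boundary_layer_thickness(constants)
    fric = -2.0 * math.sqrt(math.pi) * constants.mu / (constants.rho * delta)

    if init_state is not None and init_state[0].shape == (N,):
        A = init_state[0].copy()
        q = init_state[1].copy()
        ramp = False
    else:
        A = np.repeat(A0v, n_nodes).astype(float)
        q = np.zeros(N)
        ramp = True
    A_store = np.empty((n_store, N))
    q_store = np.empty((n_store, N))
    A_prev = np.empty((n_store, N))

    status, loc_v, loc_step, cycles_run, max_cour, change, converged = _run_lw(
        A, q, n_nodes, offs, dxv, A0v, kindv, chiv, gamv,
        junc, term_v, R1a, R2a, Ca, root, qin_tab,
        T, dt, ns, grid.n_cycles, grid.convergence_tol, ramp,
        constants.rho, fric, store_map, n_store,
        A_store, q_store, A_prev,
    )
    if status != 0:
        where = (
            f"vessel {network.vessels[loc_v].id}" if 0 <= loc_v < nv
            else "network"
        )
        tfail = loc_step * dt
        if status == 1:
            raise SolverError(
                f"CFL violation at t={tfail:.5g}s (max Courant {max_cour:.3f})"
            )
        if status == 2:
            raise SolverError(
                f"Newton iteration failed to converge at {where}, t={tfail:.5g}s"
            )
        raise SolverError(
            f"nonphysical state (area outside wall-law domain) at {where}, "
            f"t={tfail:.5g}s"
        )

    t_store = store_idx * dt
    xs, As, qs, ps = [], [], [], []
    for i, v in enumerate(network.vessels):
        o, n = int(offs[i]), int(n_nodes[i])
        Ai = A_store[:, o:o + n].copy()
        qi = q_store[:, o:o + n].copy()
        s = Ai / A0v[i]
        if kindv[i] == 0:
            pt = (4.0 / 3.0) * chiv[i] * (np.sqrt(s) - 1.0)
        else:
            pt = chiv[i] * np.tan((math.pi / gamv[i]) * (s - 1.0))
        xs.append(np.linspace(0.0, v.L, n))
        As.append(Ai)
        qs.append(qi)
        ps.append(pt / constants.conv)
    return HaemoFields(
        network=network, t=t_store, x=xs, A=As, q=qs, p=ps,
        delta=delta, converged=bool(converged), n_cycles_run=int(cycles_run),
        max_courant=float(max_cour), cycle_change=float(change), grid=grid,
        final_state=(A.copy(), q.copy()),
    )


def stable_dt(
    network: VesselNetwork,
    wall: WallModel,
    dx: float,
    constants: PhysicalConstants | None = None,
    safety: float = 0.35,
) -> float:
    """Time step satisfying the CFL condition with headroom.

    Uses the largest rest-state wave speed over the network's vessels; the
    ``safety`` factor absorbs pulsatile area dilation and advective velocity.
    """
    constants = constants or PhysicalConstants()
    cmax = 0.0
    for v in network.vessels:
        chi = wall.chi(v.r0, v.id)
        if wall.kind == "linear":
            c = math.sqrt(2.0 * chi / (3.0 * constants.rho))
        else:
            c = math.sqrt(chi * math.pi / (constants.rho * wall.gamma))
        cmax = max(cmax, c)
    return safety * dx / cmax


def check_cfl(
    grid: SimulationGrid,
    fields: HaemoFields,
    wall: WallModel,
    constants: PhysicalConstants | None = None,
) -> tuple[bool, float]:
    """Verify dt * max(|u| + c)/dx <= 1 over the stored fields.

    Returns (satisfied, max Courant number).
    """
    constants = constants or PhysicalConstants()
    max_cour = 0.0
    for i, v in enumerate(fields.network.vessels):
        A = fields.A[i]
        q = fields.q[i]
        if not np.all(np.isfinite(A)) or not np.all(np.isfinite(q)):
            raise DomainError("fields must be finite")
        chi = wall.chi(v.r0, v.id)
        s = A / v.A0
        if wall.kind == "linear":
            c = np.sqrt(2.0 * chi / (3.0 * constants.rho)) * s ** 0.25
        else:
            theta = (math.pi / wall.gamma) * (s - 1.0)
            c = np.sqrt(
                chi * math.pi * s / (constants.rho * wall.gamma)
            ) / np.cos(theta)
        dx = fields.x[i][1] - fields.x[i][0]
        cour = float(np.max((np.abs(q / A) + c) * grid.dt / dx))
        max_cour = max(max_cour, cour)
    return max_cour <= 1.0, max_cour
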