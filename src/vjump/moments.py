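"""The closed mean-squared-displacement moment system of the run/rest process.

Taking moments of the transport equations against the test functions
1, ||x||^2, v.x and ||v||^2 yields eight coupled Volterra
integro-differential equations for, per state (p = running, r = resting):

* N   -- particle number (conserved in total),
* D^2 -- displacement second moment,
* B   -- velocity-displacement correlation,
* V^2 -- velocity second moment,

with memory entering through convolutions of the delay kernels
``Phi_tau``, ``Phi_omega`` (and their (t-s)- and (t-s)^2-weighted
variants) against the history of the unknowns.  The observable MSD is
(D_p^2 + D_r^2)/N_0.

Two independent solvers are provided.  :func:`solve_moments_time`
integrates in the time domain: kernels are split into an impulse (whose
endpoint contribution is taken at full weight, recovering the Markovian
ODE system exactly for exponential laws) plus a regular part handled by
trapezoidal quadrature, with Crank-Nicolson for the differential
operators — both second-order accurate.  :func:`solve_moments_laplace`
solves the transformed algebraic system block-by-block (N, then V, then
B, then D) and inverts numerically at each output time; it shares no
time-stepping code with the first solver and serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import DelayKernel

__all__ = [
    "MomentConfig", "MomentState", "solve_moments_time",
    "solve_moments_laplace", "total_msd", "long_time_slope",
]

SERIES = ("N_p", "N_r", "D_p2", "D_r2", "B_p", "B_r", "V_p2", "V_r2")


@dataclass(frozen=True)
class MomentConfig:
    """Inputs of the moment system.

    ``V_p2_0`` defaults to S_T^2 * N_p0, the value consistent with the
    stationary balance of the velocity moment equation (agents that start
    mid-run carry a typical squared speed); pass a number to override.
    """

    run_kernel: DelayKernel
    rest_kernel: DelayKernel
    psi_d: float
    S_T2: float
    N_p0: float
    N_r0: float
    dt: float
    T: float
    V_p2_0: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.psi_d < 1.0:
            raise ValueError("psi_d must lie in [0, 1)")
        if self.N_p0 < 0 or self.N_r0 < 0 or self.N_p0 + self.N_r0 <= 0:
            raise ValueError("need N_p0, N_r0 >= 0 with a positive total")
        if self.dt <= 0 or self.T < self.dt:
            raise ValueError("need dt > 0 and T >= dt")

    @property
    def v_p2_initial(self) -> float:
        return self.S_T2 * self.N_p0 if self.V_p2_0 is None else self.V_p2_0

    @property
    def n_total(self) -> float:
        return self.N_p0 + self.N_r0


@dataclass(frozen=True)
class MomentState:
    """Solution of the moment system on a uniform time grid."""

    t: np.ndarray
    series: dict[str, np.ndarray]
    n_total: float

    def __getattr__(self, name):
        try:
            return self.series[name]
        except KeyError:
            raise AttributeError(name) from None


def _initial_vector(cfg: MomentConfig) -> np.ndarray:
    y0 = np.zeros(8)
    y0[0] = cfg.N_p0
    y0[1] = cfg.N_r0
    y0[6] = cfg.v_p2_initial
    return y0


# indices into the state vector
_NP, _NR, _DP, _DR, _BP, _BR, _VP, _VR = range(8)


def _local_matrix(a_tau: float, a_omega: float, psi_d: float, S_T2: float) -> np.ndarray:
    """Coefficients of the current-time values in the right-hand side.

    ``a_tau``/``a_omega`` are the endpoint weights of the respective
    convolutions (impulse + half a trapezoid panel of the regular kernel);
    the (t-s)-weighted convolutions have no endpoint contribution.
    """
    L = np.zeros((8, 8))
    L[_NP, _NP], L[_NP, _NR] = -a_tau, a_omega
    L[_NR, _NP], L[_NR, _NR] = a_tau, -a_omega
    L[_DP, _BP], L[_DP, _DP], L[_DP, _DR] = 2.0, -a_tau, a_omega
    L[_DR, _DP], L[_DR, _DR] = a_tau, -a_omega
    L[_BP, _VP], L[_BP, _BP], L[_BP, _BR] = 1.0, -a_tau, psi_d * a_omega
    L[_BR, _BP], L[_BR, _BR] = a_tau, -a_omega
    L[_VP, _VP], L[_VP, _NR] = -a_tau, S_T2 * a_omega
    L[_VR, _VP], L[_VR, _VR] = a_tau, -a_omega
    return L


def solve_moments_time(cfg: MomentConfig) -> MomentState:
    """Solve the eight-equation system by trapezoid + Crank-Nicolson stepping."""
    n_steps = int(round(cfg.T / cfg.dt))
    dt = cfg.dt
    t = dt * np.arange(n_steps + 1)

    c_tau, k_tau0 = cfg.run_kernel.on_grid(dt, n_steps, 0)
    _, k_tau1 = cfg.run_kernel.on_grid(dt, n_steps, 1)
    _, k_tau2 = cfg.run_kernel.on_grid(dt, n_steps, 2)
    c_om, k_om0 = cfg.rest_kernel.on_grid(dt, n_steps, 0)
    tau_reg = bool(np.any(k_tau0)) or bool(np.any(k_tau1))
    om_reg = bool(np.any(k_om0))

    a_tau = c_tau + 0.5 * dt * k_tau0[0]
    a_om = c_om + 0.5 * dt * k_om0[0]
    L = _local_matrix(a_tau, a_om, cfg.psi_d, cfg.S_T2)
    step_matrix = np.eye(8) - 0.5 * dt * L
    step_inv = np.linalg.inv(step_matrix)

    Y = np.zeros((8, n_steps + 1))
    Y[:, 0] = _initial_vector(cfg)
    # RHS at t=0: empty history, impulse endpoint only
    L0 = _local_matrix(c_tau, c_om, cfg.psi_d, cfg.S_T2)
    F_prev = L0 @ Y[:, 0]

    def history(m: int) -> np.ndarray:
        """History part (nodes 0..m-1, plus the j=0 half panel at lag m) of
        each convolution entering the RHS at t_m."""
        h = np.zeros(8)
        if tau_reg:
            # sum_{j=1}^{m-1} K[m-j] g_j  (+ half panel at j=0, lag m)
            w0 = 0.5 * dt
            ks0 = k_tau0[m - 1:0:-1]
            ks1 = k_tau1[m - 1:0:-1]
            ks2 = k_tau2[m - 1:0:-1]
            sl = slice(1, m)
            conv0 = lambda idx: dt * (ks0 @ Y[idx, sl]) + w0 * k_tau0[m] * Y[idx, 0]
            conv1 = lambda idx: dt * (ks1 @ Y[idx, sl]) + w0 * k_tau1[m] * Y[idx, 0]
            conv2 = lambda idx: dt * (ks2 @ Y[idx, sl]) + w0 * k_tau2[m] * Y[idx, 0]
            c_np = conv0(_NP)
            c_d = conv0(_DP) + 2.0 * conv1(_BP) + conv2(_VP)
            c_b = conv0(_BP) + conv1(_VP)
            c_v = conv0(_VP)
            h[_NP] -= c_np
            h[_NR] += c_np
            h[_DP] -= c_d
            h[_DR] += c_d
            h[_BP] -= c_b
            h[_BR] += c_b
            h[_VP] -= c_v
            h[_VR] += c_v
        if om_reg:
            ks = k_om0[m - 1:0:-1]
            sl = slice(1, m)
            convw = lambda idx: dt * (ks @ Y[idx, sl]) + 0.5 * dt * k_om0[m] * Y[idx, 0]
            c_nr = convw(_NR)
            c_dr = convw(_DR)
            c_br = convw(_BR)
            c_vr = convw(_VR)
            h[_NP] += c_nr
            h[_NR] -= c_nr
            h[_DP] += c_dr
            h[_DR] -= c_dr
            h[_BP] += cfg.psi_d * c_br
            h[_BR] -= c_br
            h[_VP] += cfg.S_T2 * c_nr
            h[_VR] -= c_vr
        return h

    for m in range(1, n_steps + 1):
        h_new = history(m)
        rhs = Y[:, m - 1] + 0.5 * dt * (F_prev + h_new)
        Y[:, m] = step_inv @ rhs
        F_prev = L @ Y[:, m] + h_new

    series = {name: Y[i] for i, name in enumerate(SERIES)}
    return MomentState(t=t, series=series, n_total=cfg.n_total)


# ---------------------------------------------------------------------------
# Laplace-space solver (independent cross-check)
# ---------------------------------------------------------------------------

def _transform_solution(cfg: MomentConfig, lam: np.ndarray) -> dict[str, np.ndarray]:
    """Solve the transformed algebraic system at complex nodes ``lam``.

    The system is lower block-triangular: the N pair feeds the V pair,
    which feeds the B pair, which feeds the D pair.  Convolutions with
    (t-s)^k weights transform to (-1)^k-th derivatives of the kernel
    transform, available in closed form.
    """
    pt, pt1, pt2 = cfg.run_kernel.laplace_derivatives(lam)
    po, _, _ = cfg.rest_kernel.laplace_derivatives(lam)
    Np0, Nr0, Vp0 = cfg.N_p0, cfg.N_r0, cfg.v_p2_initial
    psi, S2 = cfg.psi_d, cfg.S_T2

    def solve2(a11, a12, a21, a22, b1, b2):
        det = a11 * a22 - a12 * a21
        return (b1 * a22 - b2 * a12) / det, (a11 * b2 - a21 * b1) / det

    # N block: (lam + Pt) Np - Po Nr = Np0 ; -Pt Np + (lam + Po) Nr = Nr0
    Np, Nr = solve2(lam + pt, -po, -pt, lam + po, Np0, Nr0)
    # V block
    Vp = (Vp0 + S2 * po * Nr) / (lam + pt)
    Vr = pt * Vp / (lam + po)
    # B block: (lam + Pt) Bp - psi Po Br = (1 + Pt') Vp
    #          -Pt Bp + (lam + Po) Br = -Pt' Vp
    Bp, Br = solve2(lam + pt, -psi * po, -pt, lam + po,
                    (1.0 + pt1) * Vp, -pt1 * Vp)
    # D block: (lam + Pt) Dp - Po Dr = 2(1 + Pt') Bp - Pt'' Vp
    #          -Pt Dp + (lam + Po) Dr = -2 Pt' Bp + Pt'' Vp
    Dp, Dr = solve2(lam + pt, -po, -pt, lam + po,
                    2.0 * (1.0 + pt1) * Bp - pt2 * Vp,
                    -2.0 * pt1 * Bp + pt2 * Vp)
    return {"N_p": Np, "N_r": Nr, "D_p2": Dp, "D_r2": Dr,
            "B_p": Bp, "B_r": Br, "V_p2": Vp, "V_r2": Vr}


def solve_moments_laplace(cfg: MomentConfig, grid,
                          terms: int = 18, euler: int = 15,
                          a: float = 18.4) -> MomentState:
    """Solve the moment system in Laplace space and invert on ``grid``.

    Grid times must be positive (the t = 0 values are the initial
    conditions and are prepended if 0 is included in the grid).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("grid times must be >= 0")
    tpos = grid[grid > 0]
    ktot = terms + euler
    k = np.arange(ktot + 1)
    sign = np.where(k == 0, 0.5, 1.0) * (-1.0) ** k
    from scipy.special import comb
    w = comb(euler, np.arange(euler + 1)) / 2.0 ** euler

    lam = (a + 2j * np.pi * k)[None, :] / (2.0 * tpos[:, None])  # (nt, k)
    sols = _transform_solution(cfg, lam)
    series = {}
    for name, vals in sols.items():
        terms_k = np.real(vals) * sign
        partial = np.cumsum(terms_k, axis=1)
        inv = np.exp(a / 2.0) / tpos * (partial[:, terms:terms + euler + 1] @ w)
        full = np.empty_like(grid)
        full[grid > 0] = inv
        if np.any(grid == 0):
            y0 = _initial_vector(cfg)
            full[grid == 0] = y0[SERIES.index(name)]
        series[name] = full
    return MomentState(t=grid, series=series, n_total=cfg.n_total)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def total_msd(state: MomentState) -> np.ndarray:
    """The observable MSD curve (D_p^2 + D_r^2) / N_0 on the state's grid."""
    return (state.series["D_p2"] + state.series["D_r2"]) / state.n_total


def long_time_slope(t, curve, window: tuple[float, float]) -> float:
    """Least-squares slope of ``curve`` over the time ``window``."""
    t = np.asarray(t, dtype=float)
    curve = np.asarray(curve, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("window must contain at least 3 grid points")
    coeffs = np.polyfit(t[mask], curve[mask], 1)
    return float(coeffs[0])
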