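"""Large-time effective diffusion constant of the run/rest process.

Under parabolic (long-time, large-space) scaling, the density of agents
obeys a diffusion equation with

    D_eff = (S_T^2 / n) * mu_tau^2 / (mu_tau + mu_omega)
            * [ 1/(1 - psi_d) + (sigma_tau^2/mu_tau^2 - 1)/2 ],

where mu_tau, sigma_tau^2 are the mean and variance of the run-duration
law, mu_omega the mean rest duration, psi_d the index of persistence and
S_T^2 the mean squared run speed.  The bracket splits into the Markovian
contribution 1/(1 - psi_d) and a non-Markovian correction that vanishes
for exponential runs; to first order the rest law enters only through its
mean.  The large-time MSD grows like 2 * n * D_eff * t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import TimeDistribution
from .simulator import TurningKernel

__all__ = [
    "DiffusionParams", "effective_diffusion", "from_model", "msd_slope",
    "heat_kernel_2d",
]


@dataclass(frozen=True)
class DiffusionParams:
    mu_tau: float
    mu_omega: float
    sigma2_tau: float
    psi_d: float
    S_T2: float
    n_dim: int = 2

    def __post_init__(self):
        if self.mu_tau <= 0 or self.mu_omega <= 0:
            raise ValueError("mean durations must be > 0")
        if self.sigma2_tau < 0:
            raise ValueError("sigma2_tau must be >= 0")
        if not 0.0 <= self.psi_d < 1.0:
            raise ValueError("psi_d must lie in [0, 1)")
        if self.n_dim < 1:
            raise ValueError("n_dim must be >= 1")


def effective_diffusion(p: DiffusionParams) -> float:
    """Evaluate the closed-form effective diffusion constant."""
    bracket = 1.0 / (1.0 - p.psi_d) + 0.5 * (p.sigma2_tau / p.mu_tau**2 - 1.0)
    return p.S_T2 / p.n_dim * p.mu_tau**2 / (p.mu_tau + p.mu_omega) * bracket


def msd_slope(p: DiffusionParams) -> float:
    """Large-time MSD growth rate 2 * n * D_eff (the slope of the MSD curve)."""
    return 2.0 * p.n_dim * effective_diffusion(p)


def from_model(run_dist: TimeDistribution, rest_dist: TimeDistribution,
               turning: TurningKernel, n_dim: int = 2) -> DiffusionParams:
    """Diffusion parameters implied by a full model specification."""
    mu_tau, sigma2_tau = run_dist.moments()
    mu_omega = rest_dist.mean
    return DiffusionParams(
        mu_tau=mu_tau,
        mu_omega=mu_omega,
        sigma2_tau=sigma2_tau,
        psi_d=turning.persistence_index,
        S_T2=turning.mean_squared_speed,
        n_dim=n_dim,
    )


def heat_kernel_2d(x, t: float, D: float, N0: float = 1.0):
    """Planar heat-kernel density N0 * exp(-||x||^2/(4Dt)) / (4*pi*D*t).

    ``x`` is an (..., 2) array of positions (or a single position pair).
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if D <= 0:
        raise ValueError("D must be > 0")
    x = np.asarray(x, dtype=float)
    r2 = np.sum(x**2, axis=-1)
    out = N0 / (4.0 * np.pi * D * t) * np.exp(-r2 / (4.0 * D * t))
    return float(out) if out.ndim == 0 else out
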