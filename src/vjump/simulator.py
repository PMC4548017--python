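"""Stochastic (Gillespie) simulation of the two-state velocity-jump process.

An agent alternates between *runs* — straight-line motion at a constant,
freshly drawn velocity — and *rests*, during which it is stationary but
remembers its orientation.  Run durations are drawn from ``f_tau``, rest
durations from ``f_omega``, and on each run start the new heading is the
previous heading plus a von Mises turn while the speed is redrawn from a
memoryless speed law.  The process is planar (n = 2).

Two interfaces are provided: :func:`simulate_path` builds an explicit
:class:`SamplePath` (phase list) for a single agent, while
:func:`ensemble_msd` runs a vectorised ensemble and returns positions /
mean squared displacement on a time grid without materialising paths —
use it for the large ensembles needed for density comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .distributions import TimeDistribution

__all__ = [
    "SpeedLaw", "DegenerateSpeed", "LognormalSpeed", "TurningKernel",
    "Phase", "SamplePath", "SimConfig", "draw_turn", "simulate_path",
    "position_at", "empirical_msd", "ensemble_positions", "ensemble_msd",
    "persistence_index", "kappa_from_psi",
]


def persistence_index(kappa: float) -> float:
    """Index of persistence psi_d = I1(kappa)/I0(kappa) for a planar von Mises turn law."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return float(i1e(kappa) / i0e(kappa))


def kappa_from_psi(psi_d: float, kappa_max: float = 1e3) -> float:
    """Invert psi_d = I1(kappa)/I0(kappa) for the concentration kappa."""
    if not 0.0 <= psi_d < 1.0:
        raise ValueError("psi_d must lie in [0, 1)")
    if psi_d == 0.0:
        return 0.0
    hi = persistence_index(kappa_max)
    if psi_d >= hi:
        return kappa_max
    return brentq(lambda k: persistence_index(k) - psi_d, 0.0, kappa_max, xtol=1e-12)


# ---------------------------------------------------------------------------
# speed laws
# ---------------------------------------------------------------------------

class SpeedLaw:
    """A positive speed distribution h(s); memoryless in the previous speed."""

    def sample(self, rng: np.random.Generator, m: int) -> np.ndarray:
        raise NotImplementedError

    @property
    def mean_square(self) -> float:
        """E[s^2], the mean squared speed S_T^2 of a fresh run."""
        raise NotImplementedError


@dataclass(frozen=True)
class DegenerateSpeed(SpeedLaw):
    """All runs share the same fixed speed."""

    speed: float = 1.0

    def sample(self, rng, m):
        return np.full(m, self.speed)

    @property
    def mean_square(self):
        return self.speed**2


@dataclass(frozen=True)
class LognormalSpeed(SpeedLaw):
    """Lognormal speed with prescribed mean square E[s^2] and log-sd sigma."""

    mean_square_target: float
    sigma: float = 0.25

    @property
    def _mu_log(self) -> float:
        return 0.5 * np.log(self.mean_square_target) - self.sigma**2

    def sample(self, rng, m):
        return rng.lognormal(self._mu_log, self.sigma, size=m)

    @property
    def mean_square(self):
        return self.mean_square_target


# ---------------------------------------------------------------------------
# turning kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurningKernel:
    """Separable reorientation law: von Mises turn angle x memoryless speed.

    ``kappa`` is the von Mises concentration (kappa = 0 gives uniform
    reorientation), ``mu_angle`` the mean turn (0 for symmetric turning),
    and ``speed_law`` the distribution of the fresh run speed.
    """

    kappa: float = 0.0
    mu_angle: float = 0.0
    speed_law: SpeedLaw = field(default_factory=DegenerateSpeed)

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def persistence_index(self) -> float:
        return persistence_index(self.kappa)

    @property
    def mean_squared_speed(self) -> float:
        return self.speed_law.mean_square

    def angle_pdf(self, theta):
        """Von Mises density of the turn angle (relative to mu_angle)."""
        theta = np.asarray(theta, dtype=float)
        return np.exp(self.kappa * (np.cos(theta - self.mu_angle) - 1.0)) / (
            2.0 * np.pi * i0e(self.kappa)
        )


def draw_turn(prev_angle, kernel: TurningKernel, rng: np.random.Generator):
    """New absolute heading after a reorientation, wrapped to [0, 2*pi)."""
    prev_angle = np.asarray(prev_angle, dtype=float)
    size = None if prev_angle.ndim == 0 else prev_angle.shape
    delta = rng.vonmises(kernel.mu_angle, kernel.kappa, size=size)
    out = np.mod(prev_angle + delta, 2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# sample paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    state: str          # "run" | "rest"
    start_time: float
    duration: float
    velocity: tuple[float, float]  # orientation-carrying but defunct during rests


@dataclass(frozen=True)
class SamplePath:
    phases: tuple[Phase, ...]
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def t_end(self) -> float:
        last = self.phases[-1]
        return last.start_time + last.duration


@dataclass(frozen=True)
class SimConfig:
    run_dist: TimeDistribution
    rest_dist: TimeDistribution
    turning: TurningKernel = field(default_factory=TurningKernel)
    t_end: float = 100.0
    n_paths: int = 1
    init_run_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        if not 0.0 <= self.init_run_fraction <= 1.0:
            raise ValueError("init_run_fraction must lie in [0, 1]")


def simulate_path(cfg: SimConfig, rng: np.random.Generator,
                  start_state: str | None = None) -> SamplePath:
    """Generate one truncated sample path of the run/rest process.

    The initial phase starts fresh at t = 0 (no stationary-renewal age);
    the initial heading is uniform and the initial speed drawn from the
    speed law.  ``start_state`` overrides the Bernoulli(init_run_fraction)
    choice of the t = 0 state.
    """
    if start_state is None:
        start_state = "run" if rng.random() < cfg.init_run_fraction else "rest"
    angle = rng.uniform(0.0, 2.0 * np.pi)
    speed = float(cfg.turning.speed_law.sample(rng, 1)[0])
    state = start_state
    t = 0.0
    phases: list[Phase] = []
    while t < cfg.t_end:
        if state == "run":
            dur = float(cfg.run_dist.sample(rng, 1)[0])
            vel = (speed * np.cos(angle), speed * np.sin(angle))
        else:
            dur = float(cfg.rest_dist.sample(rng, 1)[0])
            # defunct velocity field: remembers the orientation while resting
            vel = (np.cos(angle), np.sin(angle))
        dur = min(dur, cfg.t_end - t)  # truncate at T_end
        phases.append(Phase(state, t, dur, vel))
        t += dur
        if state == "run":
            state = "rest"
        else:  # a fresh velocity is selected upon resuming a run
            angle = draw_turn(angle, cfg.turning, rng)
            speed = float(cfg.turning.speed_law.sample(rng, 1)[0])
            state = "run"
    return SamplePath(tuple(phases))


def position_at(path: SamplePath, t: float) -> np.ndarray:
    """Position at time t by piecewise-linear interpolation of the phases."""
    if t < 0 or t > path.t_end + 1e-12:
        raise ValueError(f"t={t} outside [0, {path.t_end}]")
    pos = np.array(path.origin, dtype=float)
    for ph in path.phases:
        if ph.start_time >= t:
            break
        frac = min(t - ph.start_time, ph.duration)
        if ph.state == "run":
            pos += frac * np.asarray(ph.velocity)
    return pos


def sample_on_grid(path: SamplePath, times):
    """Vectorised (x, y, state) of a sample path at the given times.

    Returns ``(x, y, state)`` arrays; ``state`` holds "run"/"rest" strings.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > path.t_end + 1e-9):
        raise ValueError("times outside the path's span")
    starts = np.array([ph.start_time for ph in path.phases])
    durs = np.array([ph.duration for ph in path.phases])
    vel = np.array([ph.velocity for ph in path.phases])
    is_run = np.array([ph.state == "run" for ph in path.phases])
    vrun = np.where(is_run[:, None], vel, 0.0)
    # cumulative displacement at each phase start
    disp = np.vstack([[0.0, 0.0], np.cumsum(vrun * durs[:, None], axis=0)])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 1)
    frac = np.clip(times - starts[idx], 0.0, durs[idx])
    pos = disp[idx] + vrun[idx] * frac[:, None] + np.asarray(path.origin)
    state = np.where(is_run[idx], "run", "rest")
    return pos[:, 0], pos[:, 1], state


def empirical_msd(ensemble, grid) -> np.ndarray:
    """Mean over paths of ||x(t) - x(0)||^2 at each grid time."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for path in ensemble:
        origin = np.asarray(path.origin)
        for i, t in enumerate(grid):
            d = position_at(path, t) - origin
            out[i] += d @ d
    return out / len(ensemble)


# ---------------------------------------------------------------------------
# vectorised ensembles
# ---------------------------------------------------------------------------

def ensemble_positions(cfg: SimConfig, grid, rng: np.random.Generator | None = None):
    """Positions of ``cfg.n_paths`` independent agents at the grid times.

    Returns arrays ``(X, Y)`` of shape (n_paths, n_grid).  All agents are
    advanced phase-by-phase in lockstep; each phase deposits its
    displacement onto every grid time it overlaps.  Output is bit-for-bit
    reproducible for a fixed config and seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > cfg.t_end:
        raise ValueError("grid must be non-empty and lie inside [0, t_end]")
    n = cfg.n_paths
    n_run0 = int(round(cfg.init_run_fraction * n))
    running = np.zeros(n, dtype=bool)
    running[:n_run0] = True  # deterministic split, matching stated fractions

    angle = rng.uniform(0.0, 2.0 * np.pi, size=n)
    speed = cfg.turning.speed_law.sample(rng, n)
    t_cur = np.zeros(n)
    X = np.zeros((n, grid.size))
    Y = np.zeros((n, grid.size))

    while t_cur.min() < cfg.t_end:
        dur = np.where(
            running,
            cfg.run_dist.sample(rng, n),
            cfg.rest_dist.sample(rng, n),
        )
        vx = np.where(running, speed * np.cos(angle), 0.0)
        vy = np.where(running, speed * np.sin(angle), 0.0)
        # overlap of [t_cur, t_cur + dur] with [0, g] for each grid time g
        frac = np.clip(grid[None, :] - t_cur[:, None], 0.0, dur[:, None])
        X += vx[:, None] * frac
        Y += vy[:, None] * frac
        t_cur += dur
        # reorient the agents that just finished a rest
        finishing_rest = ~running
        delta = rng.vonmises(cfg.turning.mu_angle, cfg.turning.kappa, size=n)
        new_speed = cfg.turning.speed_law.sample(rng, n)
        angle = np.where(finishing_rest, np.mod(angle + delta, 2.0 * np.pi), angle)
        speed = np.where(finishing_rest, new_speed, speed)
        running = ~running
    return X, Y


def ensemble_msd(cfg: SimConfig, grid, rng: np.random.Generator | None = None):
    """Ensemble MSD on a grid plus its Monte-Carlo standard error.

    Returns ``(msd, se)`` arrays over the grid, from ``cfg.n_paths`` agents.
    """
    X, Y = ensemble_positions(cfg, grid, rng=rng)
    r2 = X**2 + Y**2
    msd = r2.mean(axis=0)
    se = r2.std(axis=0, ddof=1) / np.sqrt(r2.shape[0])
    return msd, se
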