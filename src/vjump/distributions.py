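"""Run- and rest-duration distributions and their delay (renewal) kernels.

A two-state velocity-jump process is driven by the law ``f_tau`` of run
durations and ``f_omega`` of rest durations.  The memory these laws induce
in the transport equations enters through the delay kernel ``Phi``, defined
in Laplace space by

    Phibar(lambda) = lambda * fbar(lambda) / (1 - fbar(lambda)),

where ``fbar`` is the Laplace transform of the duration pdf.  ``Phibar`` is
lambda times the renewal-density transform, so in the time domain ``Phi``
splits into an impulse ``c * delta(t)`` with ``c = lim_{lambda->inf}
lambda * fbar(lambda)`` plus a regular part.  For an exponential law the
kernel is purely the impulse (rate * delta), recovering the Markovian
process; for inverse-Gaussian laws the impulse vanishes and the whole
kernel is regular.  Gamma laws with shape < 1 have a divergent impulse and
are rejected by the moment solver (the simulator handles them fine).

Supported families (positive parameters throughout):

* ``exponential(rate)`` -- mean 1/rate,
* ``gamma(shape, scale)`` -- mean shape*scale,
* ``inverse_gaussian(mean, shape)`` -- variance mean^3/shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .inversion import invert_laplace, InversionError

__all__ = [
    "TimeDistribution",
    "DelayKernel",
    "exponential",
    "gamma",
    "inverse_gaussian",
    "parse_distribution",
    "invert_laplace",
    "InversionError",
    "UnsupportedKernelError",
]

_FAMILIES = ("exponential", "gamma", "inverse_gaussian")


class UnsupportedKernelError(ValueError):
    """The delay kernel cannot be represented as impulse + regular part.

    Raised for duration laws whose renewal density diverges at t = 0
    (gamma with shape < 1).  Such laws are fully supported by the
    stochastic simulator and by the effective-diffusion formula; only the
    time-domain moment solver needs the impulse decomposition.
    """


@dataclass(frozen=True)
class TimeDistribution:
    """A positive duration law with analytic Laplace transform.

    Use the :func:`exponential`, :func:`gamma` and :func:`inverse_gaussian`
    constructors, or :func:`parse_distribution` for ``family:params`` strings.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if any(p <= 0 for p in self.params):
            raise ValueError("all distribution parameters must be strictly positive")
        n_expected = 1 if self.family == "exponential" else 2
        if len(self.params) != n_expected:
            raise ValueError(f"{self.family} takes {n_expected} parameter(s)")

    # -- scipy frozen distribution -------------------------------------
    @property
    def _frozen(self):
        if self.family == "exponential":
            return stats.expon(scale=1.0 / self.params[0])
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma(shape, scale=scale)
        mean, shape = self.params
        return stats.invgauss(mean / shape, scale=shape)

    # -- densities and moments -----------------------------------------
    def pdf(self, t):
        """Probability density f(t); domain error for negative t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("durations are non-negative; got t < 0")
        out = self._frozen.pdf(t)
        return float(out) if out.ndim == 0 else out

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("durations are non-negative; got t < 0")
        out = self._frozen.cdf(t)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> tuple[float, float]:
        """Closed-form (mean, variance)."""
        if self.family == "exponential":
            beta = self.params[0]
            return 1.0 / beta, 1.0 / beta**2
        if self.family == "gamma":
            k, theta = self.params
            return k * theta, k * theta**2
        mean, shape = self.params
        return mean, mean**3 / shape

    @property
    def mean(self) -> float:
        return self.moments()[0]

    @property
    def variance(self) -> float:
        return self.moments()[1]

    # -- Laplace transform ---------------------------------------------
    def laplace(self, lam):
        """Laplace transform fbar(lambda) of the pdf (principal branch)."""
        lam = np.asarray(lam, dtype=complex)
        if self.family == "exponential":
            beta = self.params[0]
            out = beta / (beta + lam)
        elif self.family == "gamma":
            k, theta = self.params
            out = (1.0 + theta * lam) ** (-k)
        else:
            mean, shape = self.params
            root = np.sqrt(1.0 + 2.0 * mean**2 * lam / shape)
            out = np.exp(shape / mean * (1.0 - root))
        return complex(out) if out.ndim == 0 else out

    def laplace_derivatives(self, lam):
        """(fbar, fbar', fbar'') at ``lam`` -- closed forms per family."""
        lam = np.asarray(lam, dtype=complex)
        if self.family == "exponential":
            beta = self.params[0]
            f = beta / (beta + lam)
            d1 = -beta / (beta + lam) ** 2
            d2 = 2.0 * beta / (beta + lam) ** 3
        elif self.family == "gamma":
            k, theta = self.params
            base = 1.0 + theta * lam
            f = base ** (-k)
            d1 = -k * theta * base ** (-k - 1.0)
            d2 = k * (k + 1.0) * theta**2 * base ** (-k - 2.0)
        else:
            mean, shape = self.params
            root = np.sqrt(1.0 + 2.0 * mean**2 * lam / shape)
            f = np.exp(shape / mean * (1.0 - root))
            d1 = -f * mean / root
            d2 = f * mean**2 / root**2 + f * mean**3 / (shape * root**3)
        return f, d1, d2

    # -- sampling --------------------------------------------------------
    def sample(self, rng: np.random.Generator, m: int) -> np.ndarray:
        """Draw ``m`` i.i.d. durations using the given generator."""
        if m < 0:
            raise ValueError("m must be >= 0")
        if m == 0:
            return np.empty(0)
        if self.family == "exponential":
            return rng.exponential(1.0 / self.params[0], size=m)
        if self.family == "gamma":
            k, theta = self.params
            return rng.gamma(k, theta, size=m)
        mean, shape = self.params
        return rng.wald(mean, shape, size=m)

    # -- misc ------------------------------------------------------------
    def spec_string(self) -> str:
        """Round-trippable ``family:params`` form (see parse_distribution)."""
        tag = {"exponential": "exp", "gamma": "gamma", "inverse_gaussian": "invgauss"}
        return tag[self.family] + ":" + ",".join(repr(p) for p in self.params)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"TimeDistribution({self.spec_string()!r})"


def exponential(rate: float) -> TimeDistribution:
    """Exponential law with the given rate (mean 1/rate)."""
    return TimeDistribution("exponential", (float(rate),))


def gamma(shape: float, scale: float) -> TimeDistribution:
    """Gamma law with shape k and scale theta (mean k*theta)."""
    return TimeDistribution("gamma", (float(shape), float(scale)))


def inverse_gaussian(mean: float, shape: float) -> TimeDistribution:
    """Inverse-Gaussian (Wald) law with the given mean and shape parameter."""
    return TimeDistribution("inverse_gaussian", (float(mean), float(shape)))


_TAGS = {
    "exp": ("exponential", 1),
    "exponential": ("exponential", 1),
    "gamma": ("gamma", 2),
    "invgauss": ("inverse_gaussian", 2),
    "inverse_gaussian": ("inverse_gaussian", 2),
}


def parse_distribution(spec: str) -> TimeDistribution:
    """Parse ``family:param1[,param2]`` strings, e.g. ``exp:2.30``.

    ``exp:a`` is rate a; ``gamma:a,b`` is shape a, scale b;
    ``invgauss:a,b`` is mean a, shape b.
    """
    try:
        tag, rest = spec.split(":", 1)
        family, nparams = _TAGS[tag.strip().lower()]
        params = tuple(float(x) for x in rest.split(","))
    except (ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse distribution spec {spec!r}") from exc
    if len(params) != nparams:
        raise ValueError(f"{tag} takes {nparams} parameter(s), got {len(params)}")
    return TimeDistribution(family, params)


# ---------------------------------------------------------------------------
# delay kernels
# ---------------------------------------------------------------------------

def kernel_laplace(dist: TimeDistribution, lam):
    """Delay-kernel transform Phibar(lambda) = lambda*fbar/(1 - fbar).

    The removable singularity at lambda = 0 is filled with the limit
    1/mean.  Values of fbar within ~1e-13 of 1 away from the origin signal
    a numerical pole and raise.
    """
    lam = np.asarray(lam, dtype=complex)
    scalar = lam.ndim == 0
    lamv = np.atleast_1d(lam)
    f = np.atleast_1d(dist.laplace(lamv))
    denom = 1.0 - f
    at_zero = lamv == 0
    bad = (np.abs(denom) < 1e-13) & ~at_zero
    if np.any(bad):
        raise ZeroDivisionError("kernel_laplace: fbar(lambda) is numerically 1 away from 0")
    out = np.empty_like(f)
    out[~at_zero] = lamv[~at_zero] * f[~at_zero] / denom[~at_zero]
    out[at_zero] = 1.0 / dist.mean
    return complex(out[0]) if scalar else out.reshape(lam.shape)


def kernel_moments(dist: TimeDistribution) -> tuple[float, float]:
    """Small-lambda kernel moments (Phibar(0), Phibar'(0)) = (1/mu, (sigma^2/mu^2 - 1)/2)."""
    mu, var = dist.moments()
    if not math.isfinite(var):
        raise ValueError("kernel moments require a finite variance")
    return 1.0 / mu, 0.5 * (var / mu**2 - 1.0)


def _impulse_weight(dist: TimeDistribution) -> float:
    """c = lim_{lambda->inf} lambda*fbar(lambda); the delta weight of Phi at t=0."""
    if dist.family == "exponential":
        return dist.params[0]
    if dist.family == "gamma":
        k, theta = dist.params
        if k < 1.0:
            return math.inf
        if k == 1.0:
            return 1.0 / theta
        return 0.0
    return 0.0  # inverse Gaussian: superexponential decay of fbar


@dataclass(frozen=True)
class DelayKernel:
    """The renewal kernel Phi of a duration law: impulse + regular part."""

    source: TimeDistribution
    impulse_weight: float = field(init=False)
    phi0: float = field(init=False)
    phi_prime0: float = field(init=False)

    def __post_init__(self):
        c = _impulse_weight(self.source)
        if not math.isfinite(c):
            raise UnsupportedKernelError(
                "delay kernel has a divergent impulse at t=0 (gamma shape < 1); "
                "use the stochastic simulator for this duration law"
            )
        p0, p1 = kernel_moments(self.source)
        object.__setattr__(self, "impulse_weight", c)
        object.__setattr__(self, "phi0", p0)
        object.__setattr__(self, "phi_prime0", p1)

    # Laplace-space evaluations -----------------------------------------
    def laplace(self, lam):
        return kernel_laplace(self.source, lam)

    def laplace_derivatives(self, lam):
        """(Phibar, Phibar', Phibar'') at complex ``lam`` (closed form).

        With u = lambda*fbar and v = 1 - fbar:  Phibar = u/v, and the
        quotient-rule derivatives follow from the analytic fbar derivatives.
        """
        lam = np.asarray(lam, dtype=complex)
        f, f1, f2 = self.source.laplace_derivatives(lam)
        u, v = lam * f, 1.0 - f
        u1, v1 = f + lam * f1, -f1
        u2, v2 = 2.0 * f1 + lam * f2, -f2
        phi = u / v
        phi1 = (u1 * v - u * v1) / v**2
        phi2 = (u2 * v - u * v2) / v**2 - 2.0 * v1 * (u1 * v - u * v1) / v**3
        return phi, phi1, phi2

    def regular_part(self, t, method: str = "talbot"):
        """Phi_reg(t) = Phi(t) minus the impulse, by numerical inversion.

        Talbot is the default: its deformed contour keeps full relative
        accuracy at small t, where the vertical-contour Euler scheme is
        limited by cancellation of large oscillatory terms.
        """
        c = self.impulse_weight
        if self.source.family == "exponential":
            return np.zeros_like(np.asarray(t, dtype=float))
        return invert_laplace(lambda lam: self.laplace(lam) - c, t, method=method)

    def on_grid(self, dt: float, n_steps: int, weight_power: int = 0):
        """Tabulate t^k * Phi_reg(t) on t = 0, dt, ..., n_steps*dt.

        Returns ``(impulse, grid)``: the impulse weight (0 for
        weight_power >= 1, since t^k * delta(t) = 0) and an array of
        length n_steps + 1.  The t = 0 entry of the regular part uses the
        small-time limit, which vanishes for the families supported here
        except gamma with shape in (1, 2), where the (integrable)
        singularity is truncated to 0 with a warning.
        """
        if weight_power not in (0, 1, 2):
            raise ValueError("weight_power must be 0, 1 or 2")
        if dt <= 0 or n_steps < 1:
            raise ValueError("need dt > 0 and n_steps >= 1")
        ts = dt * np.arange(1, n_steps + 1)
        grid = np.empty(n_steps + 1)
        grid[1:] = self.regular_part(ts)
        grid[0] = self._regular_at_zero(dt)
        if weight_power:
            grid *= (dt * np.arange(n_steps + 1)) ** weight_power
            return 0.0, grid
        return self.impulse_weight, grid

    def _regular_at_zero(self, dt: float) -> float:
        src = self.source
        if src.family == "exponential":
            return 0.0
        if src.family == "gamma":
            k, theta = src.params
            if k == 1.0:
                return 0.0
            if k < 2.0:
                warnings.warn(
                    "gamma shape in (1,2): the regular kernel has an integrable "
                    "singularity at t=0, truncated to 0 on the grid",
                    RuntimeWarning,
                )
                return 0.0
            if k == 2.0:
                return 1.0 / theta**2
            return 0.0
        return 0.0  # inverse Gaussian: Phi_reg(0+) = 0
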