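"""Synthetic movement-data scenarios with known ground truth.

No movement dataset ships with this package; instead every downstream
procedure is exercised on synthetic tracks whose generating parameters
are known exactly.  Five named scenarios lock the model parameters to the
values the package's worked examples use throughout:

* ``ecoli_like`` — seconds/micrometre scale: exponential runs (rate
  2.30 /s) and rests (rate 11.98 /s), persistence 0.46, mean squared
  speed 9.26; fine-sampled labelled tracks.
* ``gull_like`` — day/kilometre scale: inverse-Gaussian runs
  IG(1.26, 1.22) and rests IG(10.79, 7.42), persistence 0.42, mean
  squared speed 1.03e5; coarse GPS tracks around the Dutch Wadden coast.
* ``fig5_exp`` / ``fig5_gamma_var7`` / ``fig5_gamma_recover`` — unit-speed
  benchmark ensembles whose effective diffusion constants are 1/4, 1 and
  1/4 respectively.

Speed laws are lognormal with the prescribed mean square (the benchmark
scenarios use a fixed unit speed); real speed distributions are not
emulated beyond their second moment, which is the only property the
theory consumes.  Tracks live in a local planar frame; GPS output
projects it to latitude/longitude about a reference point, ignoring
coastlines, day-night cycles and other geography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import TimeDistribution, exponential, gamma, inverse_gaussian
from .estimation import EARTH_RADIUS_KM, GPSTrack, LabelledTrack
from .simulator import (
    DegenerateSpeed, LognormalSpeed, SimConfig, TurningKernel,
    kappa_from_psi, sample_on_grid, simulate_path,
)

__all__ = ["FixtureSpec", "SCENARIOS", "scenario_config", "ground_truth",
           "make_labelled_tracks", "make_gps_tracks"]

FIXTURE_VERSION = "1"

# reference point for the planar -> GPS projection (Wadden Sea coast)
_LAT0, _LON0 = 53.06, 4.79


@dataclass(frozen=True)
class _Scenario:
    run_dist: TimeDistribution
    rest_dist: TimeDistribution
    psi_d: float
    s_t2: float
    init_run_fraction: float
    track_length: float      # scenario time units (s or days)
    sample_dt: float         # labelled-track sampling interval
    unit_speed: bool = False
    time_unit: str = "day"

    def turning(self) -> TurningKernel:
        speed = DegenerateSpeed(1.0) if self.unit_speed else LognormalSpeed(self.s_t2)
        return TurningKernel(kappa_from_psi(self.psi_d), speed_law=speed)


SCENARIOS: dict[str, _Scenario] = {
    "ecoli_like": _Scenario(
        exponential(2.30), exponential(11.98), psi_d=0.46, s_t2=9.26,
        init_run_fraction=66.0 / 1868.0, track_length=10.0, sample_dt=0.002,
        time_unit="second",
    ),
    "gull_like": _Scenario(
        inverse_gaussian(1.26, 1.22), inverse_gaussian(10.79, 7.42),
        psi_d=0.42, s_t2=1.03e5,
        init_run_fraction=6.0 / 62.0, track_length=180.0, sample_dt=0.1,
    ),
    "fig5_exp": _Scenario(
        exponential(1.0), exponential(1.0), psi_d=0.0, s_t2=1.0,
        init_run_fraction=0.5, track_length=100.0, sample_dt=0.1,
        unit_speed=True, time_unit="1",
    ),
    "fig5_gamma_var7": _Scenario(
        gamma(1.0 / 7.0, 7.0), gamma(1.0 / 14.0, 14.0), psi_d=0.0, s_t2=1.0,
        init_run_fraction=0.5, track_length=100.0, sample_dt=0.1,
        unit_speed=True, time_unit="1",
    ),
    "fig5_gamma_recover": _Scenario(
        gamma(0.2, 2.5), exponential(1.0), psi_d=0.0, s_t2=1.0,
        init_run_fraction=2.0 / 3.0, track_length=100.0, sample_dt=0.1,
        unit_speed=True, time_unit="1",
    ),
}


@dataclass(frozen=True)
class FixtureSpec:
    scenario: str
    n_tracks: int = 10
    seed: int = 0
    gps_noise_km: float = 0.0
    fix_interval: float = 0.1        # days between GPS fixes (2.4 h)
    track_length: float | None = None
    sample_dt: float | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {sorted(SCENARIOS)}")
        if self.n_tracks < 0 or self.gps_noise_km < 0:
            raise ValueError("n_tracks and gps_noise_km must be >= 0")

    @property
    def _scn(self) -> _Scenario:
        return SCENARIOS[self.scenario]

    @property
    def length(self) -> float:
        return self.track_length if self.track_length is not None else self._scn.track_length

    @property
    def dt(self) -> float:
        return self.sample_dt if self.sample_dt is not None else self._scn.sample_dt


def scenario_config(spec: FixtureSpec, n_paths: int | None = None) -> SimConfig:
    """The simulator configuration a fixture spec corresponds to."""
    scn = spec._scn
    return SimConfig(
        run_dist=scn.run_dist, rest_dist=scn.rest_dist, turning=scn.turning(),
        t_end=spec.length, n_paths=n_paths or max(spec.n_tracks, 1),
        init_run_fraction=scn.init_run_fraction, seed=spec.seed,
    )


def ground_truth(spec: FixtureSpec) -> dict:
    """Sidecar record of the generating parameters of a fixture."""
    scn = spec._scn
    kern = scn.turning()
    return {
        "fixture_version": FIXTURE_VERSION,
        "scenario": spec.scenario,
        "seed": spec.seed,
        "n_tracks": spec.n_tracks,
        "run_dist": scn.run_dist.spec_string(),
        "rest_dist": scn.rest_dist.spec_string(),
        "run_mean": scn.run_dist.mean,
        "run_variance": scn.run_dist.variance,
        "rest_mean": scn.rest_dist.mean,
        "kappa": kern.kappa,
        "psi_d": scn.psi_d,
        "S_T2": scn.s_t2,
        "init_run_fraction": scn.init_run_fraction,
        "track_length": spec.length,
        "time_unit": scn.time_unit,
    }


def make_labelled_tracks(spec: FixtureSpec):
    """Yield (LabelledTrack, ...) with states sampled on a regular grid.

    Returns ``(tracks, truth)`` where ``tracks`` is a list and ``truth``
    the ground-truth record.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = scenario_config(spec)
    times = spec.dt * np.arange(int(round(spec.length / spec.dt)) + 1)
    tracks = []
    for k in range(spec.n_tracks):
        path = simulate_path(cfg, rng)
        x, y, state = sample_on_grid(path, times)
        tracks.append(LabelledTrack(times.copy(), x, y, state, track_id=str(k)))
    return tracks, ground_truth(spec)


def _destination(lat, lon, bearing, dist_km):
    """Great-circle destination point(s) from (lat, lon) in radians.

    ``bearing`` is the forward azimuth (clockwise from north); returns
    (lat2, lon2) in radians.  Vectorised in ``dist_km``.
    """
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    sin_lat2 = math.sin(lat) * np.cos(delta) + math.cos(lat) * np.sin(delta) * math.cos(bearing)
    lat2 = np.arcsin(np.clip(sin_lat2, -1.0, 1.0))
    lon2 = lon + np.arctan2(math.sin(bearing) * np.sin(delta) * math.cos(lat),
                            np.cos(delta) - math.sin(lat) * sin_lat2)
    return lat2, lon2


def make_gps_tracks(spec: FixtureSpec):
    """Great-circle run/rest tracks on the sphere, with optional GPS jitter.

    Each run advances the agent along a great circle at its drawn speed;
    turn angles are applied to the locally transported bearing, so the
    generating durations, speeds and angles are exactly the scenario's
    ground truth with no projection distortion.  Fixes are taken every
    ``spec.fix_interval`` days; Gaussian noise of standard deviation
    ``spec.gps_noise_km`` (per axis) perturbs the fixes.
    """
    rng = np.random.default_rng(spec.seed)
    scn = spec._scn
    kern = scn.turning()
    times = spec.fix_interval * np.arange(int(round(spec.length / spec.fix_interval)) + 1)
    tracks = []
    all_phases = []
    for k in range(spec.n_tracks):
        lat, lon = math.radians(_LAT0), math.radians(_LON0)
        bearing = rng.uniform(0.0, 2.0 * math.pi)
        speed = float(kern.speed_law.sample(rng, 1)[0])
        running = rng.random() < scn.init_run_fraction
        t_cur = 0.0
        fix_lat = np.empty(times.size)
        fix_lon = np.empty(times.size)
        phases = []
        i = 0
        while t_cur < spec.length:
            dur = float((scn.run_dist if running else scn.rest_dist).sample(rng, 1)[0])
            t_next = min(t_cur + dur, spec.length)
            phases.append(("run" if running else "rest", t_cur, t_next))
            j = int(np.searchsorted(times, t_next, side="right"))
            if running:
                d = speed * (times[i:j] - t_cur)
                fix_lat[i:j], fix_lon[i:j] = _destination(lat, lon, bearing, d)
                end_lat, end_lon = _destination(lat, lon, bearing, speed * dur)
                # transport the bearing along the great circle
                back = math.atan2(
                    math.sin(lon - end_lon) * math.cos(lat),
                    math.cos(end_lat) * math.sin(lat)
                    - math.sin(end_lat) * math.cos(lat) * math.cos(lon - end_lon),
                )
                bearing = (back + math.pi) % (2.0 * math.pi)
                lat, lon = float(end_lat), float(end_lon)
            else:
                fix_lat[i:j] = lat
                fix_lon[i:j] = lon
            i = j
            t_cur += dur
            if running:
                running = False
            else:  # fresh velocity on resuming a run
                bearing = (bearing + rng.vonmises(kern.mu_angle, kern.kappa)) % (2.0 * math.pi)
                speed = float(kern.speed_law.sample(rng, 1)[0])
                running = True
        lat_deg = np.degrees(fix_lat)
        lon_deg = np.degrees(fix_lon)
        if spec.gps_noise_km > 0:
            lat_deg = lat_deg + np.degrees(
                rng.normal(0.0, spec.gps_noise_km, size=times.size) / EARTH_RADIUS_KM)
            lon_deg = lon_deg + np.degrees(
                rng.normal(0.0, spec.gps_noise_km, size=times.size)
                / (EARTH_RADIUS_KM * np.cos(fix_lat)))
        lon_deg = (lon_deg + 180.0) % 360.0 - 180.0
        tracks.append(GPSTrack(times.copy(), lat_deg, lon_deg, track_id=str(k)))
        all_phases.append(phases)
    truth = ground_truth(spec)
    truth["track_phases"] = all_phases
    return tracks, truth
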