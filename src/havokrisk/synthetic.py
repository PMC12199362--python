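"""Synthetic patients and a Lorenz validation fixture.

Real long-term hourly interictal-epileptiform-activity (IEA) counts from
implanted responsive-neurostimulation devices are restricted data. The
generator here emulates their statistical structure instead: non-negative
hourly counts with a strong circadian component, one or two multidien
(multi-day) cycles whose amplitude is slowly modulated by a latent chaotic
driver, multiplicative gain discontinuities at clinician office visits, an
initial high-variability implant period, and sparse "long events" (LEs)
that concentrate on the rising phase of the slowest multidien cycle.

The Lorenz system is the canonical test bed for intermittently forced
linear (HAVOK) models: the forcing coordinate bursts just before the
trajectory switches attractor lobes, which gives an objective ground truth
for validating the decomposition.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .timeseries import EventSeries, HourlyCountSeries

__all__ = [
    "SyntheticPatientConfig",
    "LorenzConfig",
    "ConfigError",
    "IntegrationError",
    "generate_patient",
    "generate_lorenz",
    "lorenz_trajectory",
]

HOURS_PER_MONTH = 30.44 * 24.0


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


class IntegrationError(RuntimeError):
    """Raised when a simulated trajectory becomes non-finite."""


@dataclasses.dataclass(frozen=True)
class SyntheticPatientConfig:
    """Parameters of one synthetic patient record.

    The latent log-intensity is
    ``log(baseline_rate) + circadian + sum of multidien sinusoids`` with the
    multidien amplitudes slowly modulated by a standardized Lorenz driver
    (weight ``chaos_gain``). Counts are Gamma-mixed Poisson (negative-
    binomial-like) with variance ``mu + noise_dispersion * mu**2``.
    """

    duration_hours: int = 24 * 730
    baseline_rate: float = 20.0
    circadian_amplitude: float = 0.6
    multidien_periods: tuple[float, ...] = (7.0, 20.0)
    multidien_amplitudes: tuple[float, ...] = (0.35, 0.6)
    chaos_gain: float = 0.3
    noise_dispersion: float = 0.1
    visit_interval_days: float = 90.0
    visit_gain_jitter: float = 0.2
    event_base_rate: float = 0.01
    event_phase_odds: float = 4.0
    implant_period_months: float = 5.0
    seizure_report_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_hours <= 0:
            raise ConfigError("duration_hours must be positive")
        if len(self.multidien_periods) == 0:
            raise ConfigError("at least one multidien period is required")
        if not 1 <= len(self.multidien_periods) <= 2:
            raise ConfigError("one or two multidien periods are supported")
        if len(self.multidien_amplitudes) != len(self.multidien_periods):
            raise ConfigError("multidien_amplitudes must match multidien_periods")
        for p in self.multidien_periods:
            if not 3.0 < p < 45.0:
                raise ConfigError(f"multidien period {p} d outside the (3, 45) d band")
        for a in self.multidien_amplitudes:
            if a < 0:
                raise ConfigError("multidien_amplitudes must be >= 0")
        if self.circadian_amplitude < 0 or self.chaos_gain < 0:
            raise ConfigError("amplitudes/gains must be >= 0")
        if self.noise_dispersion <= 0:
            raise ConfigError("noise_dispersion must be > 0")
        if self.visit_interval_days <= 0:
            raise ConfigError("visit_interval_days must be positive")
        if self.visit_gain_jitter < 0:
            raise ConfigError("visit_gain_jitter must be >= 0")
        if not 0 < self.event_base_rate < 1:
            raise ConfigError("event_base_rate must be in (0, 1)")
        if self.event_phase_odds < 1:
            raise ConfigError("event_phase_odds must be >= 1")
        if not 0 <= self.seizure_report_prob <= 1:
            raise ConfigError("seizure_report_prob must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class LorenzConfig:
    """Lorenz-system fixture in the standard chaotic regime.

    ``n_steps * dt`` = 300 time units at the defaults, which covers several
    hundred lobe switches (sign changes of x), comfortably above the 50
    needed for switch statistics.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 0.002
    n_steps: int = 150_000
    seed: int = 0
    x0: tuple[float, float, float] = (-8.0, 8.0, 27.0)
    jitter: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.01:
            raise ConfigError("dt must be in (0, 0.01] for stable 4th-order stepping")
        if self.n_steps <= 0:
            raise ConfigError("n_steps must be positive")


def lorenz_trajectory(config: LorenzConfig) -> np.ndarray:
    """Integrate the Lorenz equations with fixed-step RK4.

    Returns the full (n_steps, 3) state trajectory sampled at ``dt``. The
    seed perturbs the initial condition by ``jitter``-scaled Gaussian noise,
    so different seeds give exponentially diverging trajectories.
    """
    rng = np.random.default_rng(config.seed)
    x, y, z = (v + config.jitter * e for v, e in zip(config.x0, rng.standard_normal(3)))
    s, r, b, dt = config.sigma, config.rho, config.beta, config.dt
    out = np.empty((config.n_steps, 3))

    def f(x: float, y: float, z: float) -> tuple[float, float, float]:
        return s * (y - x), x * (r - z) - y, x * y - b * z

    for i in range(config.n_steps):
        k1x, k1y, k1z = f(x, y, z)
        k2x, k2y, k2z = f(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, z + 0.5 * dt * k1z)
        k3x, k3y, k3z = f(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, z + 0.5 * dt * k2z)
        k4x, k4y, k4z = f(x + dt * k3x, y + dt * k3y, z + dt * k3z)
        x += dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y += dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        z += dt * (k1z + 2 * k2z + 2 * k3z + k4z) / 6.0
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise IntegrationError(f"trajectory became non-finite at step {i}")
        out[i] = (x, y, z)
    return out


def generate_lorenz(config: LorenzConfig | None = None) -> np.ndarray:
    """First Lorenz state variable sampled at ``dt`` (the HAVOK fixture)."""
    return lorenz_trajectory(config or LorenzConfig())[:, 0]


def _chaotic_driver(n: int, seed: int, dt_per_hour: float = 0.003) -> np.ndarray:
    """Standardized slow chaotic amplitude driver (Lorenz x, coarse steps).

    One hour advances the Lorenz clock by ``dt_per_hour`` time units, so
    lobe residences of ~1-2 units stretch over one to several weeks.
    """
    n_sub = 5  # keep the effective RK4 step small
    cfg = LorenzConfig(dt=dt_per_hour / n_sub, n_steps=n * n_sub, seed=seed)
    x = lorenz_trajectory(cfg)[::n_sub, 0]
    return (x - x.mean()) / x.std()


def generate_patient(
    config: SyntheticPatientConfig,
    return_latent: bool = False,
):
    """Draw one synthetic patient record.

    Returns ``(HourlyCountSeries, EventSeries)``; with ``return_latent=True``
    a third dict holds the noiseless latent intensity, per-cycle phases and
    the rising-phase indicator used as ground truth in validation.

    Long events occur with hourly probability
    ``event_base_rate * event_phase_odds**rising`` where ``rising`` indicates
    the slowest planted cycle's phase lying in (-pi, 0) (phase 0 at the
    cycle peak, analytic-signal convention). A ``seizure_report_prob``
    subsample of LE hours is additionally flagged as patient-labeled
    seizures, mimicking under-reporting.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.duration_hours)
    t = np.arange(n, dtype=float)

    phi_c = rng.uniform(0, 2 * np.pi)
    log_mu = math.log(config.baseline_rate) + config.circadian_amplitude * np.cos(
        2 * np.pi * t / 24.0 + phi_c
    )

    if config.chaos_gain > 0:
        z = _chaotic_driver(n, seed=int(rng.integers(2**31)))
        amp_mod = np.clip(1.0 + config.chaos_gain * z, 0.05, None)
    else:
        amp_mod = np.ones(n)

    phases = []
    slowest = int(np.argmax(config.multidien_periods))
    for period_days, amp in zip(config.multidien_periods, config.multidien_amplitudes):
        phi0 = rng.uniform(0, 2 * np.pi)
        theta = 2 * np.pi * t / (24.0 * period_days) + phi0
        log_mu = log_mu + amp * amp_mod * np.cos(theta)
        phases.append(np.angle(np.exp(1j * theta)))  # wrapped, 0 at the peak

    # per-block multiplicative gain jitter (detector retuning at office visits)
    block_len = int(round(config.visit_interval_days * 24))
    boundaries = np.arange(block_len, n, block_len, dtype=int)
    edges = [0, *boundaries.tolist(), n]
    for a, b in zip(edges[:-1], edges[1:]):
        log_mu[a:b] += rng.normal(0.0, config.visit_gain_jitter)

    intensity = np.exp(log_mu)

    disp = np.full(n, config.noise_dispersion)
    implant = int(round(config.implant_period_months * HOURS_PER_MONTH))
    disp[: min(implant, n)] *= 2.0  # early implant period is noisier
    gamma_mix = rng.gamma(shape=1.0 / disp, scale=disp)
    counts = rng.poisson(intensity * gamma_mix)

    slow_phase = phases[slowest]
    rising = (slow_phase > -np.pi) & (slow_phase < 0)
    p_event = np.minimum(
        config.event_base_rate * config.event_phase_odds ** rising.astype(float), 0.99
    )
    le = (rng.random(n) < p_event).astype(int)
    seizures = le.astype(bool) & (rng.random(n) < config.seizure_report_prob)

    series = HourlyCountSeries(
        counts.astype(float),
        gap_mask=np.zeros(n, dtype=bool),
        visit_boundaries=boundaries,
        patient_id=f"synthetic-{config.seed:04d}",
    )
    events = EventSeries(le, seizures)
    if not return_latent:
        return series, events
    latent = {
        "intensity": intensity,
        "log_intensity": log_mu,
        "phases": phases,
        "slow_phase": slow_phase,
        "rising": rising,
        "dispersion": disp,
        "event_probability": p_event,
    }
    return series, events, latent
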