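"""Photothermal conversion efficiency from heating-cooling traces.

A nanoparticle suspension irradiated at 808 nm heats toward a plateau and,
with the laser off, relaxes back to ambient.  The lumped (single
compartment) energy balance is

    m C dT/dt = eta * I * (1 - 10**-A) + Q_dis - hS * (T - T_surr)

with sample mass ``m`` (g), specific heat ``C`` (J/g/K), incident laser
power ``I`` (W), absorbance ``A`` at 808 nm, baseline dissipation
``Q_dis`` (W, e.g. solvent absorption), and heat-transfer product ``hS``
(W/K).  Three consequences drive the estimator:

* cooling (laser off, Q_dis = 0) is a single exponential with time
  constant ``tau_s = m C / hS``; plotting time against ``-ln theta`` with
  ``theta = (T - T_surr)/(T_max - T_surr)`` gives ``tau_s`` as the slope;
* the heating plateau satisfies ``hS * dT_max = eta * I * (1 - 10**-A) + Q_dis``;
* hence ``eta = (hS * dT_max - Q_dis) / (I * (1 - 10**-A))``.

:func:`estimate_eta` chains phase segmentation, plateau estimation, and
the cooling fit; :func:`predict_heating_curve` is the analytic forward
model used for round-trip validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ThermalTrace",
    "SystemConstants",
    "EtaEstimate",
    "PhaseError",
    "segment_phases",
    "fit_cooling_tau",
    "estimate_eta",
    "predict_heating_curve",
]

POOR_FIT_R2 = 0.99  # below this the cooling fit warns of non-exponential decay


class PhaseError(ValueError):
    """The trace lacks the laser phases an operation requires."""


@dataclass(frozen=True)
class ThermalTrace:
    """Time/temperature samples with a per-sample laser state."""

    time: np.ndarray  # s, strictly increasing
    temp: np.ndarray  # degrees C
    laser_on: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        temp = np.asarray(self.temp, dtype=float)
        on = np.asarray(self.laser_on, dtype=bool)
        if not (len(t) == len(temp) == len(on)):
            raise ValueError("time, temp, laser_on must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "temp", temp)
        object.__setattr__(self, "laser_on", on)

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SystemConstants:
    """Physical constants of the irradiated sample and optical setup.

    ``laser_power`` is the incident power I in watts (power density times
    irradiated spot area — the spot area must come from the setup, it is
    not implied by the density).  ``heat_transfer`` (hS, W/K) is a property
    of the cuvette geometry; it is required by the forward model and is
    measured, not assumed, by the cooling fit in :func:`estimate_eta`.
    ``ambient_temp`` of ``None`` means "take the first trace sample".
    """

    sample_mass: float = 1.0  # g
    specific_heat: float = 4.186  # J/g/K (water)
    laser_power: float = 0.65  # W
    absorbance_808: float | None = None
    ambient_temp: float | None = None
    dissipation_power: float = 0.0  # W
    heat_transfer: float | None = None  # hS, W/K (forward model only)

    def __post_init__(self) -> None:
        if self.sample_mass <= 0 or self.specific_heat <= 0 or self.laser_power <= 0:
            raise ValueError("mass, specific heat, and laser power must be positive")
        if self.dissipation_power < 0:
            raise ValueError("dissipation power must be >= 0")
        if self.absorbance_808 is not None and self.absorbance_808 <= 0:
            raise ValueError("absorbance must be positive")
        if self.heat_transfer is not None and self.heat_transfer <= 0:
            raise ValueError("heat_transfer must be positive")

    @classmethod
    def from_power_density(
        cls, power_density: float, spot_area_cm2: float, **kwargs
    ) -> "SystemConstants":
        """Build constants from a power density (W/cm**2) and spot area (cm**2)."""
        return cls(laser_power=power_density * spot_area_cm2, **kwargs)

    @property
    def tau_s(self) -> float:
        """Cooling time constant m*C/hS implied by ``heat_transfer``."""
        if self.heat_transfer is None:
            raise ValueError("heat_transfer (hS) is not set")
        return self.sample_mass * self.specific_heat / self.heat_transfer


@dataclass(frozen=True)
class EtaEstimate:
    """Photothermal conversion efficiency with its intermediates.

    ``eta`` is a fraction in [0, 1]; ``hS * tau_s == m * C`` by
    construction.  ``fit_r2`` is the r-squared of the cooling fit.
    """

    eta: float
    tau_s: float
    hS: float
    delta_T_max: float
    fit_r2: float


def segment_phases(
    trace: ThermalTrace,
) -> tuple[list[ThermalTrace], list[ThermalTrace]]:
    """Split a trace into maximal contiguous heating and cooling segments.

    Returns ``(heating, cooling)`` lists ordered in time.  Runs with fewer
    than 2 samples are rejected — a phase needs at least two points to say
    anything about the dynamics.
    """
    on = trace.laser_on
    heating: list[ThermalTrace] = []
    cooling: list[ThermalTrace] = []
    start = 0
    bounds = list(np.flatnonzero(np.diff(on)) + 1) + [len(on)]
    for end in bounds:
        seg = ThermalTrace(trace.time[start:end], trace.temp[start:end], on[start:end])
        if len(seg) < 2:
            raise PhaseError(
                f"laser phase starting at sample {start} has fewer than 2 samples"
            )
        (heating if on[start] else cooling).append(seg)
        start = end
    return heating, cooling


def fit_cooling_tau(
    segment: ThermalTrace,
    ambient: float,
    theta_window: tuple[float, float] = (0.1, 0.9),
) -> tuple[float, float]:
    """Cooling time constant tau_s (s) from a laser-off segment.

    Normalizes the decay as ``theta = (T - ambient)/(T_max - ambient)``
    with T_max the segment's first sample, keeps samples with theta inside
    ``theta_window`` (excluding the ln blow-up near ambient and transients
    near the plateau), and fits elapsed time against ``-ln theta`` by least
    squares.  Returns ``(tau_s, r_squared)``; warns when r**2 falls below
    0.99, the signature of a non-single-exponential decay.
    """
    t = segment.time - segment.time[0]
    t_max = segment.temp[0]
    if t_max <= ambient:
        raise PhaseError(
            f"cooling segment starts at {t_max} <= ambient {ambient}; cannot normalize"
        )
    theta = (segment.temp - ambient) / (t_max - ambient)
    lo, hi = theta_window
    keep = (theta > lo) & (theta < hi)
    if keep.sum() < 3:
        raise PhaseError(
            f"only {int(keep.sum())} cooling samples inside theta window {theta_window}"
        )
    x = -np.log(theta[keep])
    fit = stats.linregress(x, t[keep])
    r2 = float(fit.rvalue**2)
    if r2 < POOR_FIT_R2:
        warnings.warn(
            f"cooling fit r^2 = {r2:.4f} < {POOR_FIT_R2}: decay is not a clean "
            "single exponential; tau_s may be biased",
            stacklevel=2,
        )
    return float(fit.slope), r2


def estimate_eta(
    trace: ThermalTrace,
    constants: SystemConstants,
    plateau_fraction: float = 0.1,
    theta_window: tuple[float, float] = (0.1, 0.9),
) -> EtaEstimate:
    """Photothermal conversion efficiency from a heating-cooling trace.

    The plateau temperature is the mean of the last ``plateau_fraction`` of
    the hottest heating segment (robust to sensor noise, no curve fit);
    tau_s comes from the longest cooling segment via
    :func:`fit_cooling_tau`; then ``hS = m C / tau_s`` and

        eta = (hS * dT_max - Q_dis) / (I * (1 - 10**-A)).

    A negative numerator clips to 0 with a warning (blank solvent);
    eta > 1 also warns — it indicates inconsistent constants.
    """
    if constants.absorbance_808 is None:
        raise ValueError("absorbance_808 is required to estimate eta")
    ambient = (
        constants.ambient_temp
        if constants.ambient_temp is not None
        else float(trace.temp[0])
    )
    heating, cooling = segment_phases(trace)
    if not heating:
        raise PhaseError("no heating segment: cannot estimate the plateau")
    if not cooling:
        raise PhaseError("no cooling segment: cannot fit tau_s")

    hot = max(heating, key=lambda s: float(s.temp[-1]))
    n_tail = max(2, int(round(plateau_fraction * len(hot))))
    plateau = float(np.mean(hot.temp[-n_tail:]))
    delta_T_max = plateau - ambient
    if delta_T_max <= 0:
        raise PhaseError("heating plateau does not exceed ambient")

    cool = max(cooling, key=len)
    tau_s, r2 = fit_cooling_tau(cool, ambient, theta_window)
    if tau_s <= 0:
        raise PhaseError(f"cooling fit returned non-positive tau_s = {tau_s}")
    hS = constants.sample_mass * constants.specific_heat / tau_s

    absorbed = constants.laser_power * (1.0 - 10.0 ** (-constants.absorbance_808))
    eta = (hS * delta_T_max - constants.dissipation_power) / absorbed
    if eta < 0:
        warnings.warn(
            f"eta = {eta:.4f} < 0 (dissipation exceeds the plateau balance); "
            "clipping to 0",
            stacklevel=2,
        )
        eta = 0.0
    elif eta > 1:
        warnings.warn(
            f"eta = {eta:.4f} > 1: check laser power, absorbance, and mass",
            stacklevel=2,
        )
    return EtaEstimate(eta=float(eta), tau_s=tau_s, hS=hS,
                       delta_T_max=delta_T_max, fit_r2=r2)


def predict_heating_curve(
    constants: SystemConstants,
    eta: float,
    duration: float,
    dt: float = 1.0,
) -> ThermalTrace:
    """Analytic heating curve of the lumped energy-balance model.

    ``T(t) = T_surr + dT_eq * (1 - exp(-t/tau_s))`` with the equilibrium
    rise ``dT_eq = (eta * I * (1 - 10**-A) + Q_dis) / hS``.  Requires
    ``heat_transfer`` and ``absorbance_808`` in the constants; ambient
    defaults to 25 degrees C when unset.
    """
    if constants.absorbance_808 is None:
        raise ValueError("absorbance_808 is required by the forward model")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    tau = constants.tau_s
    ambient = constants.ambient_temp if constants.ambient_temp is not None else 25.0
    dT_eq = (
        eta * constants.laser_power * (1.0 - 10.0 ** (-constants.absorbance_808))
        + constants.dissipation_power
    ) / constants.heat_transfer
    t = np.arange(0.0, duration + dt / 2, dt)
    temp = ambient + dT_eq * (1.0 - np.exp(-t / tau))
    return ThermalTrace(t, temp, np.ones(len(t), dtype=bool))
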