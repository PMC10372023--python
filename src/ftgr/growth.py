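"""Caliper measurements, tumor volumes, and growth statistics.

Longitudinal preclinical studies measure subcutaneous tumors every few
days with a digital caliper and score them with three quantities:

* **Volume** — the ellipsoid approximation ``V = 0.5 * width**2 * length``
  (mm**3), with width the short axis.
* **FTGR** (fluctuation of tumor growth rate) — the difference between the
  forward and backward percent growth of the group-mean volume over the two
  intervals adjacent to a grid day ``t_n``::

      FTGR(t_n) = 100 * (V(t_n+h) - V(t_n)) / V(t_n)
                - 100 * (V(t_n) - V(t_n-h)) / V(t_n-h)

  FTGR < 0 means growth is decelerating (an ongoing treatment response);
  a crossing above 0 signals re-acceleration and is used to trigger a
  booster irradiation (:mod:`ftgr.regimen`).
* **TGI** (tumor growth inhibition) — one minus the ratio of treated to
  control volume fold-changes from the randomization baseline, in percent.

FTGR values can be labelled by either the *latest* day their triplet needs
(``t_n + h``; causal, the default, suitable for on-line decisions) or the
*middle* day ``t_n`` (centered, suitable for retrospective plots).  The two
conventions hold identical values shifted by one grid step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "CaliperRecord",
    "VolumeSeries",
    "FTGRTrace",
    "TGIResult",
    "InvalidMeasurementError",
    "GridError",
    "compute_volume",
    "group_mean_series",
    "animal_series",
    "compute_ftgr",
    "compute_tgi",
    "interval_growth_rate",
]

LabelConvention = Literal["latest", "middle"]


class InvalidMeasurementError(ValueError):
    """A caliper dimension or volume is non-positive or otherwise unusable."""


class GridError(ValueError):
    """Measurement days do not form the uniform grid an operation requires."""


def compute_volume(width: float, length: float) -> float:
    """Ellipsoid tumor volume (mm**3) from caliper width and length (mm).

    ``V = 0.5 * width**2 * length`` with width the short axis.  Accepts
    scalars or arrays; all dimensions must be strictly positive.
    """
    w = np.asarray(width, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise InvalidMeasurementError(
            f"caliper dimensions must be positive, got width={width!r} length={length!r}"
        )
    out = 0.5 * w**2 * l
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CaliperRecord:
    """One caliper measurement of one animal on one day.

    ``day`` counts from vaccination (day 0).  By caliper convention
    ``length >= width``; transposed entries are swapped with a warning
    because field data frequently has the columns reversed.
    """

    animal_id: str
    group_id: str
    day: int
    width: float
    length: float
    alive: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise InvalidMeasurementError(
                f"animal {self.animal_id} day {self.day}: non-positive dimension "
                f"(width={self.width}, length={self.length})"
            )
        if self.width > self.length:
            warnings.warn(
                f"animal {self.animal_id} day {self.day}: width {self.width} > "
                f"length {self.length}; swapping (caliper convention)",
                stacklevel=2,
            )
            w, l = self.width, self.length
            object.__setattr__(self, "width", l)
            object.__setattr__(self, "length", w)

    @property
    def volume(self) -> float:
        return compute_volume(self.width, self.length)


@dataclass(frozen=True)
class VolumeSeries:
    """Group-mean tumor volume on a uniform day grid.

    ``volumes[i]`` is the arithmetic mean over the ``n_animals[i]`` animals
    alive (still measured) at ``days[i]``.  The grid step must be constant;
    the default study design measures every 2 days.
    """

    group_id: str
    days: np.ndarray
    volumes: np.ndarray
    n_animals: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        vols = np.asarray(self.volumes, dtype=float)
        n = np.asarray(self.n_animals, dtype=int)
        if not (len(days) == len(vols) == len(n)):
            raise GridError("days, volumes, n_animals must have equal length")
        if len(days) >= 2:
            steps = np.diff(days)
            if np.any(steps <= 0):
                raise GridError(f"days must be strictly increasing, got {days.tolist()}")
            if len(set(steps.tolist())) > 1:
                raise GridError(
                    f"non-uniform grid {days.tolist()}; repair gaps before analysis"
                )
        if np.any(vols <= 0):
            raise InvalidMeasurementError("volumes must be positive")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "n_animals", n)

    @property
    def step(self) -> int:
        """Grid step h in days."""
        if len(self.days) < 2:
            raise GridError("step undefined for a single-day series")
        return int(self.days[1] - self.days[0])

    def value_at(self, day: int) -> float:
        idx = np.flatnonzero(self.days == day)
        if idx.size == 0:
            raise GridError(f"day {day} not on grid {self.days.tolist()}")
        return float(self.volumes[idx[0]])

    def truncated(self, day: int) -> "VolumeSeries":
        """The series restricted to days <= ``day``."""
        keep = self.days <= day
        return VolumeSeries(self.group_id, self.days[keep], self.volumes[keep],
                            self.n_animals[keep])


@dataclass(frozen=True)
class FTGRTrace:
    """Day-labelled FTGR values (percent) for one group.

    Under ``label_convention="latest"`` the value computed from the triplet
    ``(t_n-h, t_n, t_n+h)`` is reported at ``t_n+h`` — every value is known
    at its label day, so the trace can drive on-line decisions.  Under
    ``"middle"`` it is reported at ``t_n``.
    """

    group_id: str
    days: np.ndarray
    values: np.ndarray
    label_convention: LabelConvention = "latest"

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        vals = np.asarray(self.values, dtype=float)
        if len(days) != len(vals):
            raise GridError("days and values must have equal length")
        if self.label_convention not in ("latest", "middle"):
            raise ValueError(f"unknown label convention {self.label_convention!r}")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", vals)

    def truncated(self, day: int) -> "FTGRTrace":
        keep = self.days <= day
        return FTGRTrace(self.group_id, self.days[keep], self.values[keep],
                         self.label_convention)

    def value_at(self, day: int) -> float:
        idx = np.flatnonzero(self.days == day)
        if idx.size == 0:
            raise GridError(f"no FTGR value labelled at day {day}")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class TGIResult:
    """Tumor growth inhibition of a treated arm versus control, percent."""

    group_id: str
    eval_day: int
    tgi: float


def _volumes_by_animal(
    records: Iterable[CaliperRecord], group_id: str
) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for rec in records:
        if rec.group_id != group_id or not rec.alive:
            continue
        per = out.setdefault(rec.animal_id, {})
        if rec.day in per:
            raise GridError(
                f"duplicate measurement for animal {rec.animal_id} day {rec.day}"
            )
        per[rec.day] = rec.volume
    return out


def group_mean_series(
    records: Iterable[CaliperRecord],
    group_id: str,
    gap_policy: Literal["error", "interpolate"] = "error",
) -> VolumeSeries:
    """Mean tumor volume per day over the alive animals of one group.

    An animal contributes to the mean on every day it has an alive
    measurement; once its measurements stop (death/censoring) it drops out
    and ``n_animals`` shrinks.  Interior gaps in an animal's own series are
    a hard error by default; ``gap_policy="interpolate"`` repairs them by
    linear interpolation in log-volume (growth is multiplicative).  Silent
    interpolation is never done: it could fabricate trigger crossings.
    """
    per_animal = _volumes_by_animal(records, group_id)
    if not per_animal:
        raise ValueError(f"no alive records for group {group_id!r}")

    grid = np.array(sorted({d for per in per_animal.values() for d in per}), dtype=int)
    for animal, per in per_animal.items():
        days = sorted(per)
        span = grid[(grid >= days[0]) & (grid <= days[-1])]
        missing = [int(d) for d in span if d not in per]
        if missing:
            if gap_policy == "error":
                raise GridError(
                    f"animal {animal} is missing days {missing}; pass "
                    "gap_policy='interpolate' to repair in log-volume"
                )
            logv = np.interp(span, days, np.log([per[d] for d in days]))
            per_animal[animal] = {int(d): float(np.exp(lv)) for d, lv in zip(span, logv)}

    vols = []
    counts = []
    for d in grid:
        vals = [per[d] for per in per_animal.values() if d in per]
        vols.append(float(np.mean(vals)))
        counts.append(len(vals))
    return VolumeSeries(group_id, grid, np.array(vols), np.array(counts, dtype=int))


def animal_series(records: Iterable[CaliperRecord], animal_id: str) -> VolumeSeries:
    """Single-animal volume series — a per-animal FTGR diagnostic input.

    The headline FTGR is defined on the group-mean series; feeding the
    output of this helper to :func:`compute_ftgr` gives the per-animal
    variant for heterogeneity checks.
    """
    recs = [r for r in records if r.animal_id == animal_id and r.alive]
    if not recs:
        raise ValueError(f"no alive records for animal {animal_id!r}")
    recs.sort(key=lambda r: r.day)
    days = np.array([r.day for r in recs], dtype=int)
    vols = np.array([r.volume for r in recs])
    return VolumeSeries(f"{recs[0].group_id}:{animal_id}", days, vols,
                        np.ones(len(recs), dtype=int))


def interval_growth_rate(series: VolumeSeries, day: int) -> float:
    """Percent growth of the mean volume over the grid step ending at ``day``.

    ``100 * (V(day) - V(day - h)) / V(day - h)`` — the bracketed
    sub-expression of the FTGR definition, exposed for plots and tests.
    """
    h = series.step
    return 100.0 * (series.value_at(day) - series.value_at(day - h)) / series.value_at(day - h)


def compute_ftgr(
    series: VolumeSeries, label_convention: LabelConvention = "latest"
) -> FTGRTrace:
    """FTGR over every interior triplet of a uniform volume series.

    For each grid day ``t_n`` with both neighbours present::

        FTGR = 100*(V(t_n+h) - V(t_n))/V(t_n) - 100*(V(t_n) - V(t_n-h))/V(t_n-h)

    Values are percent and scale-invariant (multiplying all volumes by a
    positive constant leaves FTGR unchanged).  Requires at least 3 grid
    points and positive volumes.
    """
    v = series.volumes
    if len(v) < 3:
        raise GridError("FTGR needs at least 3 grid points")
    forward = 100.0 * (v[2:] - v[1:-1]) / v[1:-1]
    backward = 100.0 * (v[1:-1] - v[:-2]) / v[:-2]
    values = forward - backward
    days = series.days[2:] if label_convention == "latest" else series.days[1:-1]
    return FTGRTrace(series.group_id, days, values, label_convention)


def compute_tgi(
    treated: VolumeSeries,
    control: VolumeSeries,
    eval_day: int,
    baseline_day: int = 0,
) -> TGIResult:
    """Tumor growth inhibition at ``eval_day``, percent.

    ``TGI = [1 - (T_t/T_0) / (C_t/C_0)] * 100`` with T/C the treated and
    control mean volumes and the 0 subscript the post-randomization
    baseline (day 0 by default).  Equal fold-changes give 0%; a treated arm
    shrinking to nothing approaches 100%.
    """
    t0 = treated.value_at(baseline_day)
    tt = treated.value_at(eval_day)
    c0 = control.value_at(baseline_day)
    ct = control.value_at(eval_day)
    tgi = (1.0 - (tt / t0) / (ct / c0)) * 100.0
    return TGIResult(treated.group_id, eval_day, tgi)
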