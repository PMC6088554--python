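"""Drift-tube ion-mobility reduction via the Mason-Schamp relation.

Arrival-time distributions measured at several drift voltages are reduced to
a mobility K by ordinary least squares of the centroid arrival time against
inverse drift voltage (slope = L^2/K, intercept = non-drift time t0), and K
is converted to a collision cross section

    Omega = (3 z e) / (16 N) * sqrt(2 pi / (mu k_B T)) * 1 / K

with N the buffer-gas number density at the measurement pressure and
temperature and mu the ion-He reduced mass.  All physical constants come
from scipy.constants and every unit conversion lives in this module.

The regression is exposed statsmodels-style: ``ArrivalTimeModel(series)``
builds the design, ``.fit()`` returns a :class:`MobilityResult` carrying the
estimates, their uncertainties and a ``summary()`` table; the plain
:func:`fit_mobility` wrapper covers the common one-call use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

__all__ = [
    "MobilitySeries",
    "MobilityResult",
    "ArrivalTimeModel",
    "atd_centroid",
    "fit_mobility",
    "ccs_from_mobility",
    "mobility_from_ccs",
    "HE_MASS_DA",
    "BimodalATDWarning",
]

HE_MASS_DA = 4.0026
_DA_TO_KG = constants.atomic_mass
_TORR_TO_PA = constants.torr


class BimodalATDWarning(UserWarning):
    """An arrival-time distribution shows more than one resolved peak."""


def gas_number_density(pressure_torr: float, temperature_k: float) -> float:
    """Buffer-gas number density (m^-3) from the ideal-gas law."""
    return pressure_torr * _TORR_TO_PA / (constants.k * temperature_k)


@dataclass
class MobilitySeries:
    """Arrival-time distributions indexed by drift voltage, plus instrument state.

    ``records`` maps drift voltage (V) to either a 1-D array of raw arrival
    times (ms) or a (times, counts) histogram pair.
    """

    records: dict
    tube_length: float = 1.0  # m
    pressure: float = 15.0  # Torr
    temperature: float = 300.0  # K
    charge: int = 1
    ion_mass: float = 1000.0  # Da
    gas_mass: float = HE_MASS_DA  # Da

    def __post_init__(self):
        if len(self.records) < 3:
            raise ValueError("need arrival times at >= 3 distinct drift voltages")
        for name in ("tube_length", "pressure", "temperature", "ion_mass", "gas_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


def atd_centroid(arrival_times, counts=None) -> float:
    """Centroid (intensity-weighted mean, ms) of one arrival-time distribution.

    Accepts raw times or a (times, counts) histogram.  A distribution with
    more than one resolved mode triggers :class:`BimodalATDWarning`; the
    global centroid is still returned.
    """
    times = np.asarray(arrival_times, dtype=float)
    if times.size == 0:
        raise ValueError("empty arrival-time distribution")
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape != times.shape or counts.sum() <= 0:
            raise ValueError("histogram counts must match times and be non-trivial")
        centroid = float(np.average(times, weights=counts))
        _warn_if_bimodal(times, counts)
        return centroid
    if times.size >= 30:
        hist, edges = np.histogram(times, bins=max(5, int(np.sqrt(times.size))))
        _warn_if_bimodal(0.5 * (edges[:-1] + edges[1:]), hist.astype(float))
    return float(times.mean())


def _warn_if_bimodal(times, counts):
    """Flag distributions with two substantial peaks separated by a deep valley."""
    peak = counts.max()
    if peak <= 0:
        return
    # local maxima above 30% of the global maximum
    maxima = [
        i
        for i in range(len(counts))
        if counts[i] >= 0.3 * peak
        and (i == 0 or counts[i] > counts[i - 1])
        and (i == len(counts) - 1 or counts[i] >= counts[i + 1])
    ]
    modes = 0
    last_kept = None
    for i in maxima:
        if last_kept is None:
            modes = 1
            last_kept = i
            continue
        valley = counts[last_kept : i + 1].min()
        if valley < 0.4 * min(counts[last_kept], counts[i]):
            modes += 1
            last_kept = i
        elif counts[i] > counts[last_kept]:
            last_kept = i
    if modes > 1:
        warnings.warn(
            f"arrival-time distribution shows {modes} modes; returning the "
            "global centroid",
            BimodalATDWarning,
            stacklevel=3,
        )


def ccs_from_mobility(
    k_cm2, charge, temperature, pressure, ion_mass, gas_mass=HE_MASS_DA
) -> float:
    """Mason-Schamp CCS (A^2) from mobility K (cm^2 V^-1 s^-1)."""
    if k_cm2 <= 0:
        raise ValueError("mobility must be positive")
    n = gas_number_density(pressure, temperature)
    mu = ion_mass * gas_mass / (ion_mass + gas_mass) * _DA_TO_KG
    k_si = k_cm2 * 1e-4  # m^2 V^-1 s^-1
    omega_m2 = (
        (3.0 * charge * constants.e)
        / (16.0 * n)
        * np.sqrt(2.0 * np.pi / (mu * constants.k * temperature))
        / k_si
    )
    return float(omega_m2 * 1e20)


def mobility_from_ccs(
    ccs_a2, charge, temperature, pressure, ion_mass, gas_mass=HE_MASS_DA
) -> float:
    """Inverse Mason-Schamp: mobility K (cm^2 V^-1 s^-1) from CCS (A^2)."""
    if ccs_a2 <= 0:
        raise ValueError("CCS must be positive")
    # Omega ~ 1/K exactly, so invert by computing the CCS of unit mobility
    return ccs_from_mobility(1.0, charge, temperature, pressure, ion_mass, gas_mass) / ccs_a2


@dataclass(frozen=True)
class MobilityResult:
    """Fitted mobility and derived CCS with OLS diagnostics."""

    k: float  # cm^2 V^-1 s^-1
    k0: float  # reduced mobility (273.15 K, 760 Torr)
    ccs: float  # A^2
    t0: float  # ms, non-drift time intercept
    fit_r2: float
    k_stderr: float
    t0_stderr: float  # ms
    ccs_stderr: float
    n_voltages: int
    series: MobilitySeries = field(repr=False, compare=False, default=None)

    def summary(self) -> str:
        lines = [
            "Arrival time vs 1/V (Mason-Schamp reduction)",
            "=" * 46,
            f"{'voltages':<22}{self.n_voltages}",
            f"{'K (cm^2/Vs)':<22}{self.k:.6g} +/- {self.k_stderr:.2g}",
            f"{'K0 (cm^2/Vs)':<22}{self.k0:.6g}",
            f"{'CCS (A^2)':<22}{self.ccs:.6g} +/- {self.ccs_stderr:.2g}",
            f"{'t0 (ms)':<22}{self.t0:.6g} +/- {self.t0_stderr:.2g}",
            f"{'R^2':<22}{self.fit_r2:.6f}",
        ]
        if self.series is not None:
            lines.append(
                f"{'conditions':<22}L={self.series.tube_length} m, "
                f"P={self.series.pressure} Torr, T={self.series.temperature} K, "
                f"z={self.series.charge}"
            )
        return "\n".join(lines)


class ArrivalTimeModel:
    """OLS model of centroid arrival time against inverse drift voltage."""

    def __init__(self, series: MobilitySeries):
        self.series = series
        voltages = []
        centroids = []
        for v, atd in sorted(series.records.items()):
            if v <= 0:
                raise ValueError("drift voltages must be positive")
            if isinstance(atd, tuple):
                centroids.append(atd_centroid(atd[0], atd[1]))
            else:
                centroids.append(atd_centroid(atd))
            voltages.append(float(v))
        self.inv_v = 1.0 / np.array(voltages)
        self.t_ms = np.array(centroids)

    def fit(self) -> MobilityResult:
        s = self.series
        x = self.inv_v
        y = self.t_ms
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        slope_ms, t0 = float(coef[0]), float(coef[1])
        if slope_ms <= 0:
            raise ValueError("non-positive arrival-time slope: unphysical mobility")
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = len(x) - 2
        sigma2 = ss_res / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(design.T @ design)
        slope_se, t0_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        # slope (ms*V) = L^2/K with L in m -> cm: K = 1e4 L^2 / slope_s
        slope_s = slope_ms * 1e-3
        k_cm2 = 1e4 * s.tube_length**2 / slope_s
        k_se = k_cm2 * (slope_se / slope_ms)
        k0 = k_cm2 * (s.pressure / 760.0) * (273.15 / s.temperature)
        ccs = ccs_from_mobility(
            k_cm2, s.charge, s.temperature, s.pressure, s.ion_mass, s.gas_mass
        )
        ccs_se = ccs * (slope_se / slope_ms)  # Omega ~ 1/K ~ slope
        return MobilityResult(
            k=k_cm2,
            k0=k0,
            ccs=ccs,
            t0=t0,
            fit_r2=r2,
            k_stderr=k_se,
            t0_stderr=t0_se,
            ccs_stderr=ccs_se,
            n_voltages=len(x),
            series=s,
        )


def fit_mobility(series: MobilitySeries) -> MobilityResult:
    """One-call reduction: centroid per voltage, OLS vs 1/V, Mason-Schamp CCS."""
    return ArrivalTimeModel(series).fit()
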