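"""Forward generators for synthetic instrument data.

Inverse counterparts of the two reduction paths, used for closure testing
and for exercising the pipeline end-to-end:

* :func:`synth_spectra` builds paired 505/545 nm photofragment spectra whose
  expected raw yield ratio equals (true efficiency + acceptor
  direct-excitation ratio), with Poisson counting noise and pulse energies
  drawn from the experimental 1.0-4.5 mJ range;
* :func:`synth_atd_series` builds drift-tube arrival-time series from a true
  CCS via the inverse Mason-Schamp relation at the measurement conditions
  (1 m tube, 15 Torr He, 300 K), t = L^2/(K V) + t0 with Gaussian jitter.

The module's entire contract is reduce(generate(truth)) -> truth within the
propagated noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .action_fret import DEFAULT_CORRECTION, FragmentSpectrum
from .ims import HE_MASS_DA, MobilitySeries, mobility_from_ccs

__all__ = ["InstrumentTruth", "synth_spectra", "synth_atd_series"]

PULSE_ENERGY_RANGE = (1.0, 4.5)  # mJ, kept below saturation
# three acceptor-specific fragment channels below the precursor; the specific
# values are arbitrary but fixed (closure is mass-agnostic)
ACCEPTOR_FRAGMENT_MZS = (389.2, 512.7, 633.4)
_BASE_FRACTION_545 = 0.2  # mean fragment fraction of TIC in the reference channel
_MAX_FRACTION = 0.9


@dataclass(frozen=True)
class InstrumentTruth:
    """Ground truth and acquisition settings for the synthetic instrument."""

    true_efficiency: float = 0.4
    true_ccs: float = 450.0  # A^2
    charge: int = 4
    ion_mass: float = 3400.0  # Da
    direct_excitation_ratio: float = DEFAULT_CORRECTION
    counts_budget: int = 10**6  # total ion counts per spectrum
    seed: int = 0
    t0: float = 0.5  # ms, non-drift time
    tube_length: float = 1.0  # m
    pressure: float = 15.0  # Torr
    temperature: float = 300.0  # K
    gas_mass: float = HE_MASS_DA

    def __post_init__(self):
        if not 0.0 <= self.true_efficiency <= 1.0:
            raise ValueError("true_efficiency must be in [0, 1]")
        if self.true_ccs <= 0:
            raise ValueError("true_ccs must be positive")
        if self.counts_budget < 100:
            raise ValueError("counts budget must be at least 100")


def synth_spectra(truth: InstrumentTruth, n_repeats: int = 5):
    """Paired photofragment spectra lists: (five at 505 nm, five at 545 nm).

    The 545 nm fragment fraction is a * flux; the 505 nm fraction is
    a * (E + c) * flux, so the flux-normalised yield ratio is E + c exactly
    in expectation and the downstream reduction recovers E.
    """
    rng = np.random.default_rng(truth.seed)
    mean_flux_545 = np.mean(PULSE_ENERGY_RANGE) * 545.0
    a = _BASE_FRACTION_545 / mean_flux_545  # fragment fraction per unit flux
    ratio = truth.true_efficiency + truth.direct_excitation_ratio
    worst = a * ratio * PULSE_ENERGY_RANGE[1] * 505.0
    if worst > _MAX_FRACTION:
        raise ValueError(
            "true efficiency + direct-excitation ratio exceeds the maximum "
            f"fragment fraction ({_MAX_FRACTION}) at the highest pulse energy"
        )
    precursor_mz = truth.ion_mass / truth.charge

    def one(wavelength):
        pulse = float(rng.uniform(*PULSE_ENERGY_RANGE))
        flux = pulse * wavelength
        frac = a * flux * (ratio if wavelength == 505.0 else 1.0)
        n_frag = rng.poisson(frac * truth.counts_budget)
        n_prec = rng.poisson((1.0 - frac) * truth.counts_budget)
        split = rng.multinomial(n_frag, [1 / 3] * 3)
        return FragmentSpectrum(
            mz=np.array(list(ACCEPTOR_FRAGMENT_MZS) + [precursor_mz]),
            intensity=np.array(list(split) + [n_prec], dtype=float),
            wavelength=wavelength,
            pulse_energy=pulse,
            precursor_mz=precursor_mz,
            acceptor_fragment_mzs=ACCEPTOR_FRAGMENT_MZS,
        )

    spectra_505 = [one(505.0) for _ in range(n_repeats)]
    spectra_545 = [one(545.0) for _ in range(n_repeats)]
    return spectra_505, spectra_545


def synth_atd_series(
    truth: InstrumentTruth, voltages, noise_frac: float = 0.0, n_times: int = 50
) -> MobilitySeries:
    """Arrival-time series from a true CCS, with fractional Gaussian jitter.

    Each drift voltage yields an arrival-time *distribution* of ``n_times``
    ion arrivals (default 50, a typical per-voltage ion count at these signal
    levels), each jittered by ``noise_frac`` of the drift time; the centroid
    noise therefore shrinks as 1/sqrt(n_times).
    """
    voltages = [float(v) for v in voltages]
    if len(voltages) < 3:
        raise ValueError("need at least 3 drift voltages")
    if any(v <= 0 for v in voltages):
        raise ValueError("drift voltages must be positive")
    rng = np.random.default_rng(truth.seed)
    k_cm2 = mobility_from_ccs(
        truth.true_ccs,
        truth.charge,
        truth.temperature,
        truth.pressure,
        truth.ion_mass,
        truth.gas_mass,
    )
    records = {}
    for v in voltages:
        # t_s = (100 L)^2 / (K V) with K in cm^2/Vs; report in ms
        t_ms = 1e3 * (1e4 * truth.tube_length**2) / (k_cm2 * v) + truth.t0
        times = t_ms * (1.0 + noise_frac * rng.standard_normal(n_times))
        records[v] = times
    return MobilitySeries(
        records,
        tube_length=truth.tube_length,
        pressure=truth.pressure,
        temperature=truth.temperature,
        charge=truth.charge,
        ion_mass=truth.ion_mass,
        gas_mass=truth.gas_mass,
    )
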