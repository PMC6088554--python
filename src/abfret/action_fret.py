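"""Reduction of two-wavelength photofragment spectra to action-FRET efficiency.

The acceptor chromophore photo-fragments specifically; its fragment yield at
the donor absorption wavelength (505 nm) reports energy transfer, with the
yield at the acceptor wavelength (545 nm) as reference.  Per spectrum the
fragmentation yield is the acceptor-specific fragment fraction of the total
ion current, normalised to photon flux (proportional to pulse energy times
wavelength; the proportionality constant cancels in the ratio).  The
action-FRET efficiency is the ratio of the averaged 505 nm yield to the
averaged 545 nm yield minus a fixed correction (default 0.25) for direct
excitation of the acceptor at 505 nm, so an acceptor-only control reduces
to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FragmentSpectrum",
    "EfficiencyRecord",
    "fragmentation_yield",
    "action_fret_efficiency",
    "read_spectrum",
    "write_spectrum",
    "DEFAULT_CORRECTION",
    "MZ_TOLERANCE",
]

DEFAULT_CORRECTION = 0.25  # acceptor direct-excitation ratio at 505 vs 545 nm
MZ_TOLERANCE = 0.3  # Th, for matching acceptor-specific fragment peaks
MEASUREMENT_WAVELENGTHS = (505.0, 545.0)


@dataclass
class FragmentSpectrum:
    """One photofragment mass spectrum with its acquisition metadata."""

    mz: np.ndarray  # Th
    intensity: np.ndarray  # counts
    wavelength: float  # nm, 505 or 545
    pulse_energy: float  # mJ
    precursor_mz: float
    acceptor_fragment_mzs: tuple
    mz_tolerance: float = MZ_TOLERANCE

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if float(self.wavelength) not in MEASUREMENT_WAVELENGTHS:
            raise ValueError(
                f"wavelength must be one of {MEASUREMENT_WAVELENGTHS} nm"
            )
        if self.pulse_energy <= 0:
            raise ValueError("pulse energy must be positive")


def _photon_flux(spec: FragmentSpectrum) -> float:
    # photons per pulse ~ pulse_energy * wavelength; constant factor cancels
    return spec.pulse_energy * spec.wavelength


def fragmentation_yield(spec: FragmentSpectrum) -> float:
    """Photon-flux-normalised acceptor-specific fragmentation yield.

    yield = (sum of acceptor fragment intensities / total ion current)
            / (pulse_energy * wavelength).
    """
    total = float(spec.intensity.sum())
    if total <= 0:
        raise ValueError("empty spectrum")
    if not np.any(np.abs(spec.mz - spec.precursor_mz) <= spec.mz_tolerance):
        raise ValueError(
            f"no precursor peak within {spec.mz_tolerance} Th of {spec.precursor_mz}"
        )
    frag_mask = np.zeros(len(spec.mz), dtype=bool)
    for f in spec.acceptor_fragment_mzs:
        frag_mask |= np.abs(spec.mz - f) <= spec.mz_tolerance
    frag_sum = float(spec.intensity[frag_mask].sum())
    if frag_sum == 0.0:
        warnings.warn("no acceptor-specific fragment intensity found", stacklevel=2)
    return frag_sum / total / _photon_flux(spec)


@dataclass(frozen=True)
class EfficiencyRecord:
    """Reduced action-FRET efficiency with the quantities that produced it."""

    yield_505: float  # mean over repeats
    yield_545: float
    raw_ratio: float
    corrected_efficiency: float
    correction: float
    n_repeats_505: int
    n_repeats_545: int
    yield_definition: str = "fragment_fraction_per_photon"
    correction_applied: str = "after_averaging"  # to the ratio of mean yields


def action_fret_efficiency(
    yields_505, yields_545, correction: float = DEFAULT_CORRECTION
) -> EfficiencyRecord:
    """Corrected efficiency from repeat yields at the two wavelengths.

    raw_ratio = mean(yields_505) / mean(yields_545);
    corrected = raw_ratio - correction.  Negative results are reported with a
    warning (they signal sub-control transfer), never clipped.
    """
    y505 = np.asarray(list(yields_505), dtype=float)
    y545 = np.asarray(list(yields_545), dtype=float)
    if not len(y505) or not len(y545):
        raise ValueError("both repeat lists must be non-empty")
    m505 = float(y505.mean())
    m545 = float(y545.mean())
    if m545 == 0.0:
        raise ValueError("reference channel (545 nm) has zero mean yield")
    raw = m505 / m545
    corrected = raw - correction
    if corrected < 0:
        warnings.warn(
            f"corrected efficiency {corrected:.3f} is negative "
            "(below the acceptor-only control)",
            stacklevel=2,
        )
    return EfficiencyRecord(
        yield_505=m505,
        yield_545=m545,
        raw_ratio=raw,
        corrected_efficiency=corrected,
        correction=correction,
        n_repeats_505=len(y505),
        n_repeats_545=len(y545),
    )


# ---------------------------------------------------------------------------
# CSV dialect: spectrum as "mz,intensity" plus a YAML sidecar with metadata

def write_spectrum(spec: FragmentSpectrum, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity}).to_csv(
        csv_path, index=False
    )
    meta = {
        "wavelength_nm": float(spec.wavelength),
        "pulse_energy_mJ": float(spec.pulse_energy),
        "precursor_mz": float(spec.precursor_mz),
        "acceptor_fragment_mzs": [float(x) for x in spec.acceptor_fragment_mzs],
        "mz_tolerance": float(spec.mz_tolerance),
    }
    with open(csv_path.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_spectrum(csv_path) -> FragmentSpectrum:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    with open(csv_path.with_suffix(".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return FragmentSpectrum(
        mz=df["mz"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        wavelength=meta["wavelength_nm"],
        pulse_energy=meta["pulse_energy_mJ"],
        precursor_mz=meta["precursor_mz"],
        acceptor_fragment_mzs=tuple(meta["acceptor_fragment_mzs"]),
        mz_tolerance=meta.get("mz_tolerance", MZ_TOLERANCE),
    )
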