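"""Förster-theory FRET efficiency from chromophore geometry.

The donor/acceptor "optical units" are atom selections; R is the distance
between their unweighted geometric centres, and the orientation factor
kappa^2 is computed from declared transition-dipole axes:

    kappa = d_D . d_A - 3 (d_D . R_hat)(d_A . R_hat),   kappa^2 in [0, 4]

Efficiency uses the isotropically tabulated Förster radius R0 rescaled by
the explicit orientation factor:

    R0_eff^6 = R0^6 * kappa^2 / (2/3),   E = R0_eff^6 / (R0_eff^6 + R^6)

Below 15 A the point-dipole picture breaks down (Dexter transfer and
higher-multipole terms); such conformers are flagged, never modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .conformer_model import DIPOLE_AXIS_NAMES, SequenceSpec, TOKEN_ATOM_NAMES
from .structure_io import AtomSelection, Conformer, resolve_selection

__all__ = [
    "ChromophoreSpec",
    "FretResult",
    "chromophore_geometry",
    "forster_efficiency",
    "ensemble_fret",
    "default_chromophore_spec",
    "DEXTER_DISTANCE",
    "DEFAULT_R0",
]

DEXTER_DISTANCE = 15.0  # A; below this Förster theory is unreliable
# Placeholder isotropic Förster radius (A).  Deliberately uncalibrated: no
# spectral-overlap value is shipped, and every quantitative result in this
# package is expressed relative to R0.
DEFAULT_R0 = 49.0

ISOTROPIC_KAPPA2 = 2.0 / 3.0


@dataclass(frozen=True)
class ChromophoreSpec:
    """Optical-unit selections, dipole axes, and the isotropic Förster radius."""

    donor_unit: AtomSelection
    acceptor_unit: AtomSelection
    donor_axis: tuple  # ordered pair of (res_index, atom_name)
    acceptor_axis: tuple
    r0_iso: float = DEFAULT_R0

    def __post_init__(self):
        if self.r0_iso <= 0:
            raise ValueError("r0_iso must be positive")


def default_chromophore_spec(seq: SequenceSpec, r0_iso: float = DEFAULT_R0) -> ChromophoreSpec:
    """Spec for the packaged 7-atom chromophore tokens of a grafted sequence."""
    names = ",".join(TOKEN_ATOM_NAMES)
    a1, a2 = DIPOLE_AXIS_NAMES
    return ChromophoreSpec(
        donor_unit=AtomSelection(f"res {seq.donor_site} and name {names}"),
        acceptor_unit=AtomSelection(f"res {seq.acceptor_site} and name {names}"),
        donor_axis=((seq.donor_site, a1), (seq.donor_site, a2)),
        acceptor_axis=((seq.acceptor_site, a1), (seq.acceptor_site, a2)),
        r0_iso=r0_iso,
    )


def _axis_vector(conf: Conformer, axis) -> np.ndarray:
    (r1, n1), (r2, n2) = axis
    i = conf.atom_index(r1, n1)
    j = conf.atom_index(r2, n2)
    if i is None or j is None:
        raise ValueError(f"dipole-axis atoms {axis} not found")
    v = conf.coords[j] - conf.coords[i]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("zero-length dipole axis")
    return v / norm


def chromophore_geometry(conf: Conformer, spec: ChromophoreSpec):
    """(R, kappa^2) between the two optical units of one conformer."""
    don = resolve_selection(conf, spec.donor_unit)
    acc = resolve_selection(conf, spec.acceptor_unit)
    if set(don) & set(acc):
        raise ValueError("donor and acceptor selections overlap")
    c_d = conf.coords[don].mean(axis=0)
    c_a = conf.coords[acc].mean(axis=0)
    sep = c_a - c_d
    r = float(np.linalg.norm(sep))
    if r < 1e-9:
        raise ValueError("coincident optical-unit centres")
    r_hat = sep / r
    d_d = _axis_vector(conf, spec.donor_axis)
    d_a = _axis_vector(conf, spec.acceptor_axis)
    kappa = float(np.dot(d_d, d_a) - 3.0 * np.dot(d_d, r_hat) * np.dot(d_a, r_hat))
    return r, kappa**2


def forster_efficiency(r: float, kappa2: float, r0_iso: float) -> float:
    """Transfer efficiency for separation r at explicit orientation factor."""
    if r <= 0 or r0_iso <= 0 or kappa2 < 0:
        raise ValueError("r and r0_iso must be positive, kappa2 non-negative")
    if kappa2 == 0.0:
        return 0.0
    r0_eff6 = r0_iso**6 * kappa2 / ISOTROPIC_KAPPA2
    return float(r0_eff6 / (r0_eff6 + r**6))


@dataclass
class FretResult:
    """Per-conformer FRET geometry and the ensemble average."""

    r: np.ndarray  # A
    kappa2: np.ndarray
    efficiency: np.ndarray
    dexter_flag: np.ndarray  # bool, R < 15 A
    ensemble_mean_efficiency: float
    dexter_fraction: float
    n_failed: int = 0
    averaging: str = "static"  # per-conformer E averaged ("static") vs rate-averaged

    def __len__(self):
        return len(self.r)


def ensemble_fret(
    ensemble, spec: ChromophoreSpec, kappa2_mode: str = "explicit", averaging: str = "static"
) -> FretResult:
    """FRET efficiency over an ensemble.

    ``kappa2_mode``: "explicit" (per-structure orientation factor, default) or
    "isotropic" (kappa^2 = 2/3 for every structure).
    ``averaging``: "static" averages per-conformer efficiencies; "dynamic"
    averages the rate-like quantity R0_eff^6 / R^6 before forming E, the
    fast-orientation limit.
    """
    if kappa2_mode not in ("explicit", "isotropic"):
        raise ValueError("kappa2_mode must be 'explicit' or 'isotropic'")
    if averaging not in ("static", "dynamic"):
        raise ValueError("averaging must be 'static' or 'dynamic'")
    conformers = ensemble.conformers if hasattr(ensemble, "conformers") else ensemble
    if not conformers:
        raise ValueError("empty ensemble")
    rs, k2s = [], []
    n_failed = 0
    for k, conf in enumerate(conformers):
        try:
            r, k2 = chromophore_geometry(conf, spec)
        except ValueError as exc:
            n_failed += 1
            warnings.warn(f"conformer {k}: FRET geometry failed ({exc})", stacklevel=2)
            continue
        rs.append(r)
        k2s.append(k2 if kappa2_mode == "explicit" else ISOTROPIC_KAPPA2)
    if not rs:
        raise ValueError("FRET geometry failed for every conformer")
    rs = np.array(rs)
    k2s = np.array(k2s)
    eff = np.array([forster_efficiency(r, k2, spec.r0_iso) for r, k2 in zip(rs, k2s)])
    if averaging == "static":
        mean_e = float(eff.mean())
    else:
        ratio = (k2s / ISOTROPIC_KAPPA2) * (spec.r0_iso / rs) ** 6
        mean_ratio = float(ratio.mean())
        mean_e = mean_ratio / (1.0 + mean_ratio)
    flags = rs < DEXTER_DISTANCE
    return FretResult(
        r=rs,
        kappa2=k2s,
        efficiency=eff,
        dexter_flag=flags,
        ensemble_mean_efficiency=mean_e,
        dexter_fraction=float(flags.mean()),
        n_failed=n_failed,
        averaging=averaging,
    )
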