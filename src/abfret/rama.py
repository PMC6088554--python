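"""Ramachandran classification and structural-family summaries.

Backbone (phi, psi) pairs of the hydrophobic core (residues 17-21) are
assigned to named rectangular regions on the torus (alpha, beta, PPII,
left-handed alpha; everything else is "other"/random coil), ensembles are
summarised as per-region occupancies, and query dihedral sets are scored
against packaged reference dihedral sets by a toroidal nearest-neighbour
overlap fraction.  The overlap statistic is this package's quantification of
what is otherwise a visual comparison; it is labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .geometry import angular_difference, wrap_angle
from .structure_io import compute_dihedrals

__all__ = [
    "RegionMap",
    "ReferenceDihedralSet",
    "DEFAULT_REGIONS",
    "classify",
    "family_summary",
    "reference_overlap",
    "load_reference_set",
    "rama_plot",
    "CORE_RESIDUES",
]

CORE_RESIDUES = (17, 21)  # L17..A21, the hydrophobic core


def _in_range(value: float, lo: float, hi: float) -> bool:
    """Membership in a possibly wrapping interval on the circle (inclusive)."""
    v = wrap_angle(value)
    if lo <= hi:
        return lo <= v <= hi
    return v >= lo or v <= hi  # wraps through 180/-180


@dataclass(frozen=True)
class RegionMap:
    """Ordered named rectangles on the (phi, psi) torus; first match wins."""

    regions: tuple  # of (name, (phi_lo, phi_hi), (psi_lo, psi_hi))

    def __post_init__(self):
        names = [n for n, _, _ in self.regions]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")

    @property
    def names(self):
        return tuple(n for n, _, _ in self.regions)

    def to_yaml(self, path) -> None:
        data = {
            n: {"phi": list(p), "psi": list(s)} for n, p, s in self.regions
        }
        with open(path, "w") as fh:
            yaml.safe_dump({"regions": data, "order": list(self.names)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        regions = tuple(
            (name, tuple(data["regions"][name]["phi"]), tuple(data["regions"][name]["psi"]))
        for name in data["order"]
        )
        return cls(regions)


DEFAULT_REGIONS = RegionMap(
    (
        ("alpha", (-100.0, -30.0), (-67.0, -7.0)),
        ("beta", (-180.0, -90.0), (90.0, 180.0)),
        ("ppii", (-90.0, -55.0), (120.0, 180.0)),
        ("left_alpha", (30.0, 100.0), (7.0, 67.0)),
    )
)


def classify(phi: float, psi: float, regions: RegionMap = DEFAULT_REGIONS) -> str:
    """Region label for one (phi, psi) pair; total function, falls back to 'other'."""
    for name, (plo, phi_hi), (slo, shi) in regions.regions:
        if _in_range(phi, plo, phi_hi) and _in_range(psi, slo, shi):
            return name
    return "other"


def family_summary(
    ensemble, core_range=CORE_RESIDUES, regions: RegionMap = DEFAULT_REGIONS
):
    """Per-region occupancy of the core dihedrals over (structures x residues).

    Returns (fractions dict including "other", n_missing) where fractions sum
    to 1 over the observed dihedrals and n_missing counts residues excluded
    for incomplete backbones.
    """
    conformers = ensemble.conformers if hasattr(ensemble, "conformers") else ensemble
    if not conformers:
        raise ValueError("empty ensemble")
    lo, hi = core_range
    expected_per_conf = hi - lo + 1
    counts = {name: 0 for name in regions.names}
    counts["other"] = 0
    n = 0
    n_missing = 0
    for conf in conformers:
        records = compute_dihedrals(conf, (lo, hi))
        n_missing += expected_per_conf - len(records)
        for rec in records:
            counts[classify(rec.phi, rec.psi, regions)] += 1
            n += 1
    if n == 0:
        raise ValueError("no core dihedrals found")
    fractions = {k: v / n for k, v in counts.items()}
    return fractions, n_missing


@dataclass(frozen=True)
class ReferenceDihedralSet:
    """Labelled set of reference (phi, psi) points, degrees on (-180, 180]."""

    label: str
    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or not len(pts):
            raise ValueError("points must be a non-empty (n, 2) array")
        object.__setattr__(self, "points", wrap_angle(pts))


def load_reference_set(name: str) -> ReferenceDihedralSet:
    """Load a packaged reference dihedral set.

    Shipped sets are synthetic stand-ins for the core dihedrals of (a) a
    partially folded solution-phase monomer (helical core) and (b) amyloid
    fibril strands (beta core); see the data file headers.
    """
    fname = f"ref_dihedrals_{name}_synthetic.csv"
    with resources.files("abfret.data").joinpath(fname).open() as fh:
        pts = np.loadtxt(fh, delimiter=",", comments="#")
    return ReferenceDihedralSet(name, np.atleast_2d(pts))


def toroidal_distance(a, b) -> float:
    """Chebyshev distance on the torus between two (phi, psi) points."""
    return float(
        max(angular_difference(a[0], b[0]), angular_difference(a[1], b[1]))
    )


def reference_overlap(dihedrals, ref: ReferenceDihedralSet, delta: float = 30.0) -> float:
    """Fraction of query points within toroidal Chebyshev ``delta`` of the
    nearest reference point (boundary inclusive)."""
    pts = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    if not len(pts) or not len(ref.points):
        raise ValueError("query and reference sets must be non-empty")
    dphi = angular_difference(pts[:, 0][:, None], ref.points[None, :, 0])
    dpsi = angular_difference(pts[:, 1][:, None], ref.points[None, :, 1])
    nearest = np.maximum(dphi, dpsi).min(axis=1)
    return float((nearest <= delta + 1e-12).mean())


def rama_plot(dihedrals, path, references=(), title=""):
    """Ramachandran scatter of query dihedrals with optional reference sets."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pts[:, 0], pts[:, 1], s=6, c="black", marker="s", label="ensemble")
    colors = ["red", "blue", "green"]
    for k, ref in enumerate(references):
        ax.scatter(
            ref.points[:, 0], ref.points[:, 1], s=22, c=colors[k % 3],
            label=ref.label, zorder=3,
        )
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel(r"$\psi$ (deg)")
    ax.axhline(0, lw=0.3, c="grey")
    ax.axvline(0, lw=0.3, c="grey")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
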