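"""Coarse-grained gas-phase conformer model of doubly dye-grafted A-beta(12-28).

The peptide is represented in dihedral space: ideal backbone geometry
(omega fixed trans), one side-chain pseudo-atom (CB) per non-glycine residue,
and a rigid planar 7-atom chromophore token on each terminal cysteine,
attached through a linker pseudo-atom with two free torsions.  Residues are
numbered in the deposited-fragment convention: the grafted N-terminal
cysteine is 11, the peptide proper runs 12-28, the C-terminal cysteine is 29,
so the hydrophobic core is addressable as residues 17-21.

The energy model is a deliberately small surrogate for an all-atom force
field, in units of kT at 300 K: torsional basins for the alpha-helical, beta
and polyproline-II regions, a nearest-neighbour helix (and strand)
cooperativity bonus, vacuum Coulomb repulsion between the fixed chromophore
charges and the mobile protons on basic side chains, a short-range
hydrophobic contact attraction that stabilises compact globules at low
charge, and a soft-sphere overlap penalty.  The single physical driver it is
built to express is the competition between secondary-structure preferences
and inter-charge Coulomb repulsion as protons are added.

Sampling is replica-exchange Metropolis Monte Carlo over a geometric
temperature ladder with single-residue (phi, psi) pivot moves and
adjacent-pair exchange attempts on a fixed schedule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from ._kernels import nb_energy_batch, rotate_block, torsion_energy_batch
from .geometry import angular_difference, place_atom, wrap_angle
from .structure_io import Conformer, compute_dihedrals

__all__ = [
    "SequenceSpec",
    "ProtonationState",
    "ToyEnergyParams",
    "Ensemble",
    "wild_type",
    "f19p",
    "temperature_ladder",
    "build_conformer",
    "toy_energy",
    "assign_protons",
    "sample_ensemble",
    "radius_of_gyration",
    "SamplerWarning",
]

# ---------------------------------------------------------------------------
# sequence definitions

_WT_SEQ = "CVHHQKLVFFAEDVGSNKC"  # construct residues 11..29 (Ace/NH2 caps implicit)
_FIRST_RESIDUE = 11

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "K": "LYS", "L": "LEU", "N": "ASN", "P": "PRO", "Q": "GLN",
    "S": "SER", "V": "VAL",
}

_HYDROPHOBIC = set("AVLIFMP")
_CONTACT_MIN_SEP = 5  # residue separation for tertiary hydrophobic contacts


@dataclass(frozen=True)
class SequenceSpec:
    """Doubly grafted peptide sequence in fragment numbering (11..29)."""

    name: str
    residues: tuple  # of (res_index, one_letter_code)
    graft_sites: tuple = (11, 29)
    basic_sites: tuple = (13, 14, 16, 28)  # H13, H14, K16, K28
    proline_sites: frozenset = frozenset()
    donor_terminus: str = "C"  # which graft carries the donor dye ("C" or "N")

    def __post_init__(self):
        if len(self.graft_sites) != 2:
            raise ValueError("exactly two graft sites required")
        if self.donor_terminus not in ("C", "N"):
            raise ValueError("donor_terminus must be 'C' or 'N'")

    @property
    def res_indices(self):
        return tuple(r for r, _ in self.residues)

    def one_letter(self, res_index: int) -> str:
        return dict(self.residues)[res_index]

    @property
    def donor_site(self) -> int:
        return max(self.graft_sites) if self.donor_terminus == "C" else min(self.graft_sites)

    @property
    def acceptor_site(self) -> int:
        return min(self.graft_sites) if self.donor_terminus == "C" else max(self.graft_sites)


def wild_type(donor_terminus: str = "C") -> SequenceSpec:
    residues = tuple(
        (i + _FIRST_RESIDUE, aa) for i, aa in enumerate(_WT_SEQ)
    )
    return SequenceSpec("WT", residues, donor_terminus=donor_terminus)


def f19p(donor_terminus: str = "C") -> SequenceSpec:
    seq = list(_WT_SEQ)
    seq[19 - _FIRST_RESIDUE] = "P"
    residues = tuple((i + _FIRST_RESIDUE, aa) for i, aa in enumerate(seq))
    return SequenceSpec(
        "F19P", residues, proline_sites=frozenset({19}), donor_terminus=donor_terminus
    )


@dataclass(frozen=True)
class ProtonationState:
    """Number and placement of mobile protons; chromophores add a fixed +2."""

    n_protons: int
    proton_sites: tuple

    def __post_init__(self):
        if not 0 <= self.n_protons <= 4:
            raise ValueError("n_protons must be between 0 and 4")
        if len(self.proton_sites) != self.n_protons:
            raise ValueError("proton_sites length must equal n_protons")

    @property
    def total_charge(self) -> int:
        return self.n_protons + 2


# ---------------------------------------------------------------------------
# energy parameters

@dataclass(frozen=True)
class TorsionBasin:
    phi: float
    psi: float
    depth: float  # kT, positive = stabilising
    width: float  # degrees (isotropic Gaussian sigma)


@dataclass(frozen=True)
class ToyEnergyParams:
    """Tunable energy-model parameters (energies in kT at 300 K, lengths in A).

    Defaults are calibrated so that, with the shipped sampler settings, the
    charge-state series 3+ -> 6+ walks through compact-globular, helical,
    distorted-helical and extended ensembles, the qualitative sequence the
    model exists to express.
    """

    basins: tuple = (
        ("alpha", TorsionBasin(-63.0, -43.0, 3.1, 25.0)),
        ("beta", TorsionBasin(-135.0, 135.0, 1.2, 25.0)),
        ("ppii", TorsionBasin(-75.0, 145.0, 0.9, 25.0)),
    )
    coop_alpha: float = 1.8  # bonus per consecutive alpha-region pair
    coop_beta: float = 1.8  # bonus per consecutive beta-region pair (strand ladder)
    coop_ppii: float = 1.8  # bonus per consecutive PPII pair (proline-compatible)
    coop_delta: float = 40.0  # membership half-width (deg) around basin centre
    coulomb_k: float = 115.0  # kT*A per unit-charge pair (effective, see docs)
    chromophore_charge: float = 1.0
    soft_sigma: float = 3.2  # A, soft-sphere contact distance
    soft_k: float = 10.0  # kT/A^2
    contact_depth: float = 3.2  # kT per tertiary hydrophobic CB contact
    contact_r0: float = 6.2  # A
    contact_width: float = 2.0  # A
    proline_phi_range: tuple = (-90.0, -50.0)
    proline_k: float = 0.03  # kT/deg^2 outside the allowed phi interval

    def __post_init__(self):
        for _, b in self.basins:
            if b.width <= 0:
                raise ValueError("basin widths must be positive")

    def basin(self, name: str) -> TorsionBasin:
        return dict(self.basins)[name]


# ---------------------------------------------------------------------------
# topology and coordinate construction

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_OMEGA = 180.0
_BOND_CA_CB = 1.53
_ANG_N_CA_CB = 110.5
_TOR_C_N_CA_CB = 122.5  # constant offset fixing side-chain chirality
_BOND_CB_CL = 3.0  # coarse C5 linker
_ANG_CA_CB_CL = 109.5
_BOND_CL_X1 = 1.5
_ANG_CB_CL_X1 = 115.0

# planar 7-atom chromophore token, local frame anchored at X1
_TOKEN_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],   # X1 anchor (N-link side)
        [1.2, 0.9, 0.0],   # X2
        [2.4, 0.2, 0.0],   # X3
        [3.6, 0.9, 0.0],   # X4 carries the fixed +1 charge
        [4.8, 0.2, 0.0],   # X5 far end of the long axis
        [2.4, 1.6, 0.0],   # X6
        [2.4, -1.2, 0.0],  # X7
    ]
)
TOKEN_ATOM_NAMES = ("X1", "X2", "X3", "X4", "X5", "X6", "X7")
CHARGE_ATOM_NAME = "X4"
DIPOLE_AXIS_NAMES = ("X1", "X5")
# defaults point both tokens away from the chain in the canonical builds
DEFAULT_CHROMO_TORSIONS = (-150.0, -150.0, -150.0, -150.0)


@dataclass
class _Torsion:
    kind: str  # "phi" | "psi" | "chromo"
    res: int
    axis: tuple  # (atom_a, atom_b) indices, rotation about a->b
    block: tuple  # (start, stop) atom index slice that rotates
    slot: int  # index into the state vector for this torsion kind


class Topology:
    """Static atom layout and index tables for one sequence."""

    def __init__(self, seq: SequenceSpec):
        self.seq = seq
        names, elements, res_idx, res_names = [], [], [], []
        self.n_idx, self.ca_idx, self.c_idx, self.cb_idx = {}, {}, {}, {}
        self.chromo_atoms = {}  # graft residue -> dict(name -> atom index)
        for r, aa in seq.residues:
            rn = _THREE[aa]
            for nm, el in (("N", "N"), ("CA", "C"), ("C", "C")):
                idx = len(names)
                names.append(nm)
                elements.append(el)
                res_idx.append(r)
                res_names.append(rn)
                {"N": self.n_idx, "CA": self.ca_idx, "C": self.c_idx}[nm][r] = idx
            if aa != "G":
                self.cb_idx[r] = len(names)
                names.append("CB")
                elements.append("C")
                res_idx.append(r)
                res_names.append(rn)
            if r in seq.graft_sites:
                token = {}
                token["CL"] = len(names)
                names.append("CL")
                elements.append("C")
                res_idx.append(r)
                res_names.append(rn)
                for nm in TOKEN_ATOM_NAMES:
                    token[nm] = len(names)
                    names.append(nm)
                    elements.append("C")
                    res_idx.append(r)
                    res_names.append(rn)
                self.chromo_atoms[r] = token
        self.atom_names = names
        self.elements = elements
        self.res_indices = np.array(res_idx, dtype=int)
        self.res_names = res_names
        self.n_atoms = len(names)
        self._build_torsions()
        self._build_pairs()

    # -- torsion tables ----------------------------------------------------
    def _build_torsions(self):
        seq = self.seq
        rids = seq.res_indices
        self.torsions = []
        for k, r in enumerate(rids):
            if k > 0:  # phi defined (C of previous residue exists)
                self.torsions.append(
                    _Torsion(
                        "phi",
                        r,
                        (self.n_idx[r], self.ca_idx[r]),
                        (self.c_idx[r], self.n_atoms),
                        k,
                    )
                )
            if k < len(rids) - 1:  # psi rotates the next residue onward
                nxt = rids[k + 1]
                self.torsions.append(
                    _Torsion(
                        "psi",
                        r,
                        (self.ca_idx[r], self.c_idx[r]),
                        (self.n_idx[nxt], self.n_atoms),
                        k,
                    )
                )
        slot = 0
        for r in sorted(self.chromo_atoms):
            tok = self.chromo_atoms[r]
            first, last = tok["CL"], tok["X7"] + 1
            self.torsions.append(
                _Torsion("chromo", r, (self.ca_idx[r], self.cb_idx[r]), (first, last), slot)
            )
            self.torsions.append(
                _Torsion("chromo", r, (self.cb_idx[r], tok["CL"]), (tok["X1"], last), slot + 1)
            )
            slot += 2
        self.n_chromo_torsions = slot

    # -- nonbonded pair tables ---------------------------------------------
    def _build_pairs(self):
        seq = self.seq
        steric = []
        for r in seq.res_indices:
            steric.append(self.ca_idx[r])
            if r in self.cb_idx:
                steric.append(self.cb_idx[r])
        for r, tok in self.chromo_atoms.items():
            steric.extend(tok[nm] for nm in ("CL",) + TOKEN_ATOM_NAMES)
        steric = np.array(sorted(steric), dtype=int)
        ii, jj = [], []
        res_of = self.res_indices
        for a, b in itertools.combinations(steric, 2):
            if abs(int(res_of[a]) - int(res_of[b])) >= 2:
                ii.append(a)
                jj.append(b)
        self.steric_i = np.array(ii, dtype=int)
        self.steric_j = np.array(jj, dtype=int)

        hyd = [
            self.cb_idx[r]
            for r, aa in seq.residues
            if aa in _HYDROPHOBIC and r in self.cb_idx
        ]
        # tertiary contacts only: helix-local (i, i+3/i+4) pairs are excluded so
        # the contact term rewards globular packing, not helical structure
        ci, cj = [], []
        for a, b in itertools.combinations(hyd, 2):
            if abs(int(res_of[a]) - int(res_of[b])) >= _CONTACT_MIN_SEP:
                ci.append(a)
                cj.append(b)
        self.contact_i = np.array(ci, dtype=int)
        self.contact_j = np.array(cj, dtype=int)

    def charge_atoms(self, state: ProtonationState, params: ToyEnergyParams):
        """(atom indices, charges) of all charged sites for a protonation state."""
        idx, q = [], []
        for r in self.chromo_atoms:
            idx.append(self.chromo_atoms[r][CHARGE_ATOM_NAME])
            q.append(params.chromophore_charge)
        for r in state.proton_sites:
            if r not in self.cb_idx:
                raise ValueError(f"proton site {r} has no side-chain atom")
            idx.append(self.cb_idx[r])
            q.append(1.0)
        return np.array(idx, dtype=int), np.array(q, dtype=float)

    # -- geometry -----------------------------------------------------------
    def coords_from_state(self, phi, psi, chromo_torsions) -> np.ndarray:
        """Full NeRF reconstruction of coordinates from the torsion state."""
        seq = self.seq
        rids = seq.res_indices
        coords = np.zeros((self.n_atoms, 3))
        chromo_slot = 0
        for k, r in enumerate(rids):
            if k == 0:
                coords[self.n_idx[r]] = (0.0, 0.0, 0.0)
                coords[self.ca_idx[r]] = (_BOND_N_CA, 0.0, 0.0)
                coords[self.c_idx[r]] = place_atom(
                    (0.0, 1.0, 0.0),
                    coords[self.n_idx[r]],
                    coords[self.ca_idx[r]],
                    _BOND_CA_C,
                    _ANG_N_CA_C,
                    0.0,
                )
            if r in self.cb_idx:
                coords[self.cb_idx[r]] = place_atom(
                    coords[self.c_idx[r]],
                    coords[self.n_idx[r]],
                    coords[self.ca_idx[r]],
                    _BOND_CA_CB,
                    _ANG_N_CA_CB,
                    _TOR_C_N_CA_CB,
                )
            if r in self.chromo_atoms:
                tok = self.chromo_atoms[r]
                t1 = chromo_torsions[chromo_slot]
                t2 = chromo_torsions[chromo_slot + 1]
                chromo_slot += 2
                cl = place_atom(
                    coords[self.n_idx[r]],
                    coords[self.ca_idx[r]],
                    coords[self.cb_idx[r]],
                    _BOND_CB_CL,
                    _ANG_CA_CB_CL,
                    t1,
                )
                coords[tok["CL"]] = cl
                x1 = place_atom(
                    coords[self.ca_idx[r]],
                    coords[self.cb_idx[r]],
                    cl,
                    _BOND_CL_X1,
                    _ANG_CB_CL_X1,
                    t2,
                )
                coords[tok["X1"]] = x1
                e1 = x1 - cl
                e1 /= np.linalg.norm(e1)
                u = coords[self.cb_idx[r]] - cl
                e3 = np.cross(e1, u)
                e3 /= np.linalg.norm(e3)
                e2 = np.cross(e3, e1)
                frame = np.column_stack([e1, e2, e3])
                for t, nm in enumerate(TOKEN_ATOM_NAMES[1:], start=1):
                    coords[tok[nm]] = x1 + frame @ _TOKEN_TEMPLATE[t]
            if k < len(rids) - 1:
                nxt = rids[k + 1]
                n_next = place_atom(
                    coords[self.n_idx[r]],
                    coords[self.ca_idx[r]],
                    coords[self.c_idx[r]],
                    _BOND_C_N,
                    _ANG_CA_C_N,
                    psi[k],
                )
                coords[self.n_idx[nxt]] = n_next
                ca_next = place_atom(
                    coords[self.ca_idx[r]],
                    coords[self.c_idx[r]],
                    n_next,
                    _BOND_N_CA,
                    _ANG_C_N_CA,
                    _OMEGA,
                )
                coords[self.ca_idx[nxt]] = ca_next
                coords[self.c_idx[nxt]] = place_atom(
                    coords[self.c_idx[r]],
                    n_next,
                    ca_next,
                    _BOND_CA_C,
                    _ANG_N_CA_C,
                    phi[k + 1],
                )
        return coords

    def to_conformer(self, coords, label="") -> Conformer:
        return Conformer(
            list(self.atom_names),
            list(self.elements),
            self.res_indices.copy(),
            list(self.res_names),
            np.array(coords, dtype=float),
            label=label,
        )


# ---------------------------------------------------------------------------
# energy

class _EnergyModel:
    """Precomputed tables for fast repeated energy evaluation of one system."""

    def __init__(self, top: Topology, params: ToyEnergyParams, state: ProtonationState):
        self.top = top
        self.params = params
        seq = top.seq
        rids = np.array(seq.res_indices)
        self.interior = slice(1, len(rids) - 1)
        rr = rids[self.interior]
        names = [n for n, _ in params.basins]
        self.centres_phi = np.array([b.phi for _, b in params.basins])
        self.centres_psi = np.array([b.psi for _, b in params.basins])
        self.inv_two_w2 = np.array([1.0 / (2.0 * b.width**2) for _, b in params.basins])
        depths = np.tile([b.depth for _, b in params.basins], (len(rr), 1))
        self.alpha_col = names.index("alpha") if "alpha" in names else -1
        self.beta_col = names.index("beta") if "beta" in names else -1
        self.pro_mask = np.isin(rr, list(seq.proline_sites))
        if self.alpha_col >= 0:
            depths[self.pro_mask, self.alpha_col] = 0.0
        # proline is a strand breaker: it contributes no backbone NH to a
        # beta ladder and its ring constrains the preceding residue, so the
        # beta well and beta-run membership are removed for proline +/- 1
        self.strand_broken = np.isin(
            rr, [p + d for p in seq.proline_sites for d in (-1, 0, 1)]
        )
        if self.beta_col >= 0:
            depths[self.strand_broken, self.beta_col] = 0.0
        self.depths = depths
        coop_by_name = {
            "alpha": params.coop_alpha,
            "beta": params.coop_beta,
            "ppii": params.coop_ppii,
        }
        self.coop = np.array([coop_by_name.get(n, 0.0) for n in names])
        allowed = np.ones((len(rr), len(names)), dtype=np.uint8)
        if self.alpha_col >= 0:
            allowed[self.pro_mask, self.alpha_col] = 0
        if self.beta_col >= 0:
            allowed[self.strand_broken, self.beta_col] = 0
        self.allowed = allowed
        lo, hi = params.proline_phi_range
        self.pro_centre = wrap_angle((lo + hi) / 2.0)
        self.pro_half = angular_difference(hi, lo) / 2.0
        self.pro_mask_u8 = self.pro_mask.astype(np.uint8)
        # nonbonded: every distance needed lives inside one compact atom set, so
        # each evaluation does a single cdist plus flat gathers from its square
        self.charge_idx, self.charges = top.charge_atoms(state, params)
        self.qq = _pair_products(self.charges)
        self.sig2 = params.soft_sigma**2
        atoms = sorted(
            set(top.steric_i) | set(top.steric_j)
            | set(top.contact_i) | set(top.contact_j) | set(self.charge_idx)
        )
        self.nb_atoms = np.array(atoms, dtype=int)
        local = {a: k for k, a in enumerate(atoms)}
        n = len(atoms)

        def flat(ii, jj):
            return np.array([local[a] * n + local[b] for a, b in zip(ii, jj)], dtype=int)

        self.steric_flat = flat(top.steric_i, top.steric_j)
        self.contact_flat = flat(top.contact_i, top.contact_j)
        qpairs = list(itertools.combinations(self.charge_idx, 2))
        self.charge_flat = flat([a for a, _ in qpairs], [b for _, b in qpairs])
        # unified pair list (steric | contact | charge) for batched evaluation
        def loc(ii):
            return [local[a] for a in ii]

        self.pair_i = np.array(
            loc(top.steric_i) + loc(top.contact_i) + loc([a for a, _ in qpairs]), dtype=int
        )
        self.pair_j = np.array(
            loc(top.steric_j) + loc(top.contact_j) + loc([b for _, b in qpairs]), dtype=int
        )
        n_st, n_ct, n_q = len(top.steric_i), len(top.contact_i), len(qpairs)
        self.sl_steric = slice(0, n_st)
        self.sl_contact = slice(n_st, n_st + n_ct)
        self.sl_charge = slice(n_st + n_ct, n_st + n_ct + n_q)
        self.n_contact_pairs = n_ct
        self.n_charge_pairs = n_q
        # global-index pair tables for the compiled kernel
        self.gpair_i = np.concatenate(
            [top.steric_i, top.contact_i, [a for a, _ in qpairs]]
        ).astype(np.int64)
        self.gpair_j = np.concatenate(
            [top.steric_j, top.contact_j, [b for _, b in qpairs]]
        ).astype(np.int64)
        self.gpair_kind = np.concatenate(
            [np.zeros(n_st, int), np.ones(n_ct, int), np.full(n_q, 2)]
        ).astype(np.int64)
        self.gpair_q = np.concatenate([np.zeros(n_st + n_ct), self.qq]).astype(np.float64)

    def torsion_energy(self, phi, psi) -> float:
        p = self.params
        ph = np.asarray(phi)[self.interior, None]
        ps = np.asarray(psi)[self.interior, None]
        dph = np.abs(ph - self.centres_phi) % 360.0
        np.minimum(dph, 360.0 - dph, out=dph)
        dps = np.abs(ps - self.centres_psi) % 360.0
        np.minimum(dps, 360.0 - dps, out=dps)
        e = -float((self.depths * np.exp(-(dph**2 + dps**2) * self.inv_two_w2)).sum())
        member = (dph <= p.coop_delta) & (dps <= p.coop_delta) & self.allowed.astype(bool)
        e -= float((self.coop * (member[:-1] & member[1:]).sum(axis=0)).sum())
        if self.pro_mask.any():
            dev = (
                angular_difference(ph[self.pro_mask, 0], self.pro_centre) - self.pro_half
            )
            dev = np.clip(dev, 0.0, None)
            e += p.proline_k * float((dev**2).sum())
        return e

    def nonbonded_energy(self, coords) -> float:
        p = self.params
        e = 0.0
        pts = coords[self.nb_atoms]
        d2 = cdist(pts, pts, "sqeuclidean").ravel()
        if len(self.charge_flat):
            dq2 = d2[self.charge_flat]
            if dq2.min() < 1e-18:
                raise ValueError("coincident charge sites")
            e += p.coulomb_k * float((self.qq / np.sqrt(dq2)).sum())
        r2 = d2[self.steric_flat]
        close = r2 < self.sig2
        if close.any():
            overlap = p.soft_sigma - np.sqrt(r2[close])
            e += p.soft_k * float((overlap**2).sum())
        if p.contact_depth != 0.0 and len(self.contact_flat):
            rc = np.sqrt(d2[self.contact_flat])
            e -= p.contact_depth * float(
                np.exp(-((rc - p.contact_r0) ** 2) / (2.0 * p.contact_width**2)).sum()
            )
        return e

    def energy(self, coords, phi, psi) -> float:
        return self.torsion_energy(phi, psi) + self.nonbonded_energy(coords)

    # -- batched evaluation over replicas (compiled kernels) ----------------
    def batch_energy(self, coords3, phis, psis) -> np.ndarray:
        """Energies of a stack of systems: coords3 (R, n_atoms, 3), angles (R, n_res)."""
        p = self.params
        n_rep = len(coords3)
        e = np.empty(n_rep)
        torsion_energy_batch(
            np.ascontiguousarray(phis[:, self.interior]),
            np.ascontiguousarray(psis[:, self.interior]),
            self.centres_phi,
            self.centres_psi,
            self.inv_two_w2,
            self.depths,
            p.coop_delta,
            self.coop,
            self.allowed,
            self.pro_mask_u8,
            self.pro_centre,
            self.pro_half,
            p.proline_k,
            e,
        )
        e_nb = np.empty(n_rep)
        nb_energy_batch(
            np.ascontiguousarray(coords3),
            self.gpair_i,
            self.gpair_j,
            self.gpair_kind,
            self.gpair_q,
            p.soft_sigma,
            p.soft_k,
            p.contact_depth,
            p.contact_r0,
            p.contact_width,
            p.coulomb_k,
            e_nb,
        )
        if np.any(np.isinf(e_nb)):
            raise ValueError("coincident charge sites")
        return e + e_nb


def _pair_products(values) -> np.ndarray:
    """q_i * q_j for i < j, in pair-combination order."""
    v = np.asarray(values, dtype=float)
    return np.array([v[a] * v[b] for a, b in itertools.combinations(range(len(v)), 2)])


def toy_energy(conf: Conformer, state: ProtonationState, params: ToyEnergyParams, seq=None):
    """Energy (kT at 300 K) of a built conformer under a protonation state.

    The sequence is inferred from the conformer's residue names when not given.
    """
    if seq is None:
        is_f19p = any(
            rn == "PRO" and ri == 19
            for rn, ri in zip(conf.res_names, conf.res_indices)
        )
        seq = f19p() if is_f19p else wild_type()
    top = Topology(seq)
    if top.n_atoms != conf.n_atoms:
        raise ValueError("conformer does not match the sequence topology")
    records = compute_dihedrals(conf)
    rid_to_slot = {r: k for k, r in enumerate(seq.res_indices)}
    phi = np.zeros(len(seq.res_indices))
    psi = np.zeros(len(seq.res_indices))
    for rec in records:
        phi[rid_to_slot[rec.res_index]] = rec.phi
        psi[rid_to_slot[rec.res_index]] = rec.psi
    model = _EnergyModel(top, params, state)
    return model.energy(conf.coords, phi, psi)


# ---------------------------------------------------------------------------
# public construction helpers

def temperature_ladder(t_min: float, t_max: float, n: int):
    """Geometric temperature ladder T_k = t_min * (t_max/t_min)**(k/(n-1))."""
    if n < 2:
        raise ValueError("ladder needs at least 2 rungs")
    if not 0 < t_min < t_max:
        raise ValueError("require 0 < t_min < t_max")
    k = np.arange(n)
    return (t_min * (t_max / t_min) ** (k / (n - 1))).tolist()


def build_conformer(seq: SequenceSpec, dihedrals, chromo_torsions=None, label="") -> Conformer:
    """Deterministic conformer from one (phi, psi) pair per residue.

    ``dihedrals`` is a sequence of (phi, psi) in degrees, one per residue in
    chain order; phi of the first and psi of the last residue are ignored.
    """
    dihedrals = np.asarray(dihedrals, dtype=float)
    if dihedrals.shape != (len(seq.res_indices), 2):
        raise ValueError(
            f"expected {len(seq.res_indices)} (phi, psi) pairs, got {dihedrals.shape}"
        )
    top = Topology(seq)
    if chromo_torsions is None:
        chromo_torsions = DEFAULT_CHROMO_TORSIONS[: top.n_chromo_torsions]
    coords = top.coords_from_state(dihedrals[:, 0], dihedrals[:, 1], list(chromo_torsions))
    return top.to_conformer(coords, label=label)


def assign_protons(
    seq: SequenceSpec, n_protons: int, params: ToyEnergyParams | None = None
) -> ProtonationState:
    """Place protons on basic sites by minimum Coulomb energy.

    The assignment is evaluated on the idealised all-helical reference build
    (the motif the mid-charge states adopt), enumerating all subsets of the
    basic sites; an explicit ProtonationState can always be constructed
    directly to override this choice.
    """
    params = params or ToyEnergyParams()
    if n_protons == 0:
        return ProtonationState(0, ())
    top = Topology(seq)
    helix = [(-63.0, -43.0)] * len(seq.res_indices)
    coords = top.coords_from_state(
        [d[0] for d in helix], [d[1] for d in helix],
        list(DEFAULT_CHROMO_TORSIONS[: top.n_chromo_torsions]),
    )
    best, best_sites = None, None
    for sites in itertools.combinations(sorted(seq.basic_sites), n_protons):
        state = ProtonationState(n_protons, sites)
        idx, q = top.charge_atoms(state, params)
        pts = coords[idx]
        d = pdist(pts)
        qq = []
        for a, b in itertools.combinations(range(len(q)), 2):
            qq.append(q[a] * q[b])
        e = float(np.sum(np.array(qq) / d))
        if best is None or e < best:
            best, best_sites = e, sites
    return ProtonationState(n_protons, best_sites)


# ---------------------------------------------------------------------------
# replica-exchange sampler

class SamplerWarning(UserWarning):
    pass


@dataclass
class Ensemble:
    """Sampled conformers at the lowest ladder temperature, with provenance."""

    conformers: list
    alloform: str
    protonation: ProtonationState
    temperature: float
    seed: int
    sampler_stats: list  # exchange acceptance per adjacent ladder pair
    sequence: SequenceSpec | None = None

    def __len__(self):
        return len(self.conformers)


def radius_of_gyration(conf: Conformer) -> float:
    c = conf.coords - conf.coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c * c, axis=1))))


def sample_ensemble(
    seq: SequenceSpec,
    state: ProtonationState,
    params: ToyEnergyParams,
    ladder,
    n_steps: int,
    stride: int,
    seed: int,
    exchange_interval: int = 200,
    burn_in: int = 0,
    move_sigma: float = 25.0,
    p_jump: float = 0.3,
    sample_rung: int = 0,
) -> Ensemble:
    """Replica-exchange Metropolis sampling over a temperature ladder.

    One step is one pivot-move attempt in every replica (a random backbone
    residue's (phi, psi), or a chromophore linker torsion).  Adjacent-pair
    exchanges are attempted every ``exchange_interval`` steps.  Conformers of
    the replica at ladder rung ``sample_rung`` (default: the coldest) are
    recorded every ``stride`` steps after ``burn_in``.  Fully reproducible
    from ``seed``.
    """
    ladder = list(ladder)
    if sorted(ladder) != ladder:
        raise ValueError("temperature ladder must be sorted ascending")
    if n_steps < stride:
        raise ValueError("n_steps must be at least stride")
    rng = np.random.default_rng(seed)
    top = Topology(seq)
    model = _EnergyModel(top, params, state)
    n_res = len(seq.res_indices)
    n_rep = len(ladder)
    betas = np.array([300.0 / t for t in ladder])

    # torsion lookup tables
    phi_tors = {t.res: t for t in top.torsions if t.kind == "phi"}
    psi_tors = {t.res: t for t in top.torsions if t.kind == "psi"}
    chromo_tors = [t for t in top.torsions if t.kind == "chromo"]
    movable = list(seq.res_indices)  # termini contribute their single defined torsion
    n_ct = top.n_chromo_torsions
    p_chromo = 0.15 if n_ct else 0.0

    # replica state as stacked arrays; all moves are evaluated batched
    PHI = wrap_angle(rng.uniform(-180.0, 180.0, size=(n_rep, n_res)))
    PSI = wrap_angle(rng.uniform(-180.0, 180.0, size=(n_rep, n_res)))
    CHR = wrap_angle(rng.uniform(-180.0, 180.0, size=(n_rep, max(n_ct, 1))))
    C = np.stack(
        [top.coords_from_state(PHI[r], PSI[r], CHR[r][:n_ct]) for r in range(n_rep)]
    )
    E = model.batch_energy(C, PHI, PSI)

    exch_attempts = np.zeros(n_rep - 1)
    exch_accepts = np.zeros(n_rep - 1)
    samples = []
    window_attempts = window_accepts = 0

    def propose(old, jump, normal, uniform):
        return uniform if jump else old + normal

    def wrap(a):
        return -((-a + 180.0) % 360.0) + 180.0

    for step in range(1, n_steps + 1):
        kind_chromo = rng.random(n_rep) < p_chromo
        res_pick = rng.integers(len(movable), size=n_rep)
        chr_pick = rng.integers(len(chromo_tors), size=n_rep) if chromo_tors else None
        jumps = rng.random((n_rep, 2)) < p_jump
        normals = rng.normal(0.0, move_sigma, size=(n_rep, 2))
        uniforms = rng.uniform(-180.0, 180.0, size=(n_rep, 2))
        undo = []
        for r in range(n_rep):
            coords = C[r]
            if kind_chromo[r]:
                t = chromo_tors[chr_pick[r]]
                old = CHR[r, t.slot]
                new = propose(old, jumps[r, 0], normals[r, 0], uniforms[r, 0])
                saved = coords[t.block[0] : t.block[1]].copy()
                rotate_block(coords, t.block[0], t.block[1], coords[t.axis[0]],
                             coords[t.axis[1]] - coords[t.axis[0]], new - old)
                CHR[r, t.slot] = wrap(new)
                undo.append((t.block[0], t.block[1], saved, "chromo", t.slot, old))
            else:
                res = movable[res_pick[r]]
                tp = phi_tors.get(res)
                ts = psi_tors.get(res)
                k = (tp or ts).slot
                old_phi, old_psi = PHI[r, k], PSI[r, k]
                save_from = tp.block[0] if tp is not None else ts.block[0]
                saved = coords[save_from:].copy()
                if tp is not None:
                    new_phi = propose(old_phi, jumps[r, 0], normals[r, 0], uniforms[r, 0])
                    rotate_block(coords, tp.block[0], tp.block[1], coords[tp.axis[0]],
                                 coords[tp.axis[1]] - coords[tp.axis[0]],
                                 new_phi - old_phi)
                    PHI[r, k] = wrap(new_phi)
                if ts is not None:
                    new_psi = propose(old_psi, jumps[r, 1], normals[r, 1], uniforms[r, 1])
                    rotate_block(coords, ts.block[0], ts.block[1], coords[ts.axis[0]],
                                 coords[ts.axis[1]] - coords[ts.axis[0]],
                                 new_psi - old_psi)
                    PSI[r, k] = wrap(new_psi)
                undo.append((save_from, top.n_atoms, saved, "bb", k, (old_phi, old_psi)))

        E_new = model.batch_energy(C, PHI, PSI)
        d_e = E_new - E
        with np.errstate(over="ignore"):
            accept = (d_e <= 0.0) | (rng.random(n_rep) < np.exp(-betas * d_e))
        window_attempts += n_rep
        window_accepts += int(accept.sum())
        for r in range(n_rep):
            if accept[r]:
                E[r] = E_new[r]
            else:
                start, stop, saved, kind, k, old = undo[r]
                C[r, start:stop] = saved
                if kind == "chromo":
                    CHR[r, k] = old
                else:
                    PHI[r, k], PSI[r, k] = old

        if step % exchange_interval == 0:
            for p in range(n_rep - 1):
                exch_attempts[p] += 1
                arg = (betas[p] - betas[p + 1]) * (E[p] - E[p + 1])
                if arg >= 0 or rng.random() < np.exp(arg):
                    for arr in (PHI, PSI, CHR, C):
                        arr[[p, p + 1]] = arr[[p + 1, p]]
                    E[[p, p + 1]] = E[[p + 1, p]]
                    exch_accepts[p] += 1
            if window_attempts and window_accepts == 0:
                warnings.warn(
                    f"no moves accepted in the last {window_attempts} attempts",
                    SamplerWarning,
                    stacklevel=2,
                )
            window_attempts = window_accepts = 0
        if step > burn_in and step % stride == 0:
            samples.append(
                top.to_conformer(C[sample_rung].copy(), label=f"sample_{len(samples) + 1}")
            )

    acc = [
        float(exch_accepts[p] / exch_attempts[p]) if exch_attempts[p] else float("nan")
        for p in range(n_rep - 1)
    ]
    return Ensemble(
        conformers=samples,
        alloform=seq.name,
        protonation=state,
        temperature=float(ladder[sample_rung]),
        seed=seed,
        sampler_stats=acc,
        sequence=seq,
    )
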