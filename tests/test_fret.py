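"""Förster efficiency: closed forms, orientation factor, ensemble averaging."""

import numpy as np
import pytest

from abfret.fret import (
    chromophore_geometry,
    default_chromophore_spec,
    ensemble_fret,
    forster_efficiency,
)
from abfret.structure_io import AtomSelection, Conformer


def dipole_fixture(r_sep, donor_axis, acceptor_axis):
    """Two 2-atom 'optical units' with prescribed separation and dipole axes."""
    donor_axis = np.asarray(donor_axis, dtype=float)
    acceptor_axis = np.asarray(acceptor_axis, dtype=float)
    donor_axis /= np.linalg.norm(donor_axis)
    acceptor_axis /= np.linalg.norm(acceptor_axis)
    # centre donor at origin, acceptor displaced along +x
    d1 = -0.5 * donor_axis
    d2 = +0.5 * donor_axis
    a1 = np.array([r_sep, 0.0, 0.0]) - 0.5 * acceptor_axis
    a2 = np.array([r_sep, 0.0, 0.0]) + 0.5 * acceptor_axis
    conf = Conformer(
        atom_names=["D1", "D2", "A1", "A2"],
        elements=["C"] * 4,
        res_indices=np.array([1, 1, 2, 2]),
        res_names=["DNR", "DNR", "ACC", "ACC"],
        coords=np.array([d1, d2, a1, a2]),
    )
    from abfret.fret import ChromophoreSpec

    spec = ChromophoreSpec(
        donor_unit=AtomSelection("res 1"),
        acceptor_unit=AtomSelection("res 2"),
        donor_axis=((1, "D1"), (1, "D2")),
        acceptor_axis=((2, "A1"), (2, "A2")),
        r0_iso=20.0,
    )
    return conf, spec


class TestKappaSquared:
    def test_parallel_perpendicular_dipoles_give_one(self):
        conf, spec = dipole_fixture(10.0, [0, 0, 1], [0, 0, 1])
        r, k2 = chromophore_geometry(conf, spec)
        assert r == pytest.approx(10.0)
        assert k2 == pytest.approx(1.0, abs=1e-12)

    def test_collinear_head_to_tail_dipoles_give_four(self):
        conf, spec = dipole_fixture(10.0, [1, 0, 0], [1, 0, 0])
        _, k2 = chromophore_geometry(conf, spec)
        assert k2 == pytest.approx(4.0, abs=1e-12)

    def test_mutually_orthogonal_arrangement_gives_zero(self):
        conf, spec = dipole_fixture(10.0, [0, 0, 1], [0, 1, 0])
        _, k2 = chromophore_geometry(conf, spec)
        assert k2 == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_average_is_two_thirds(self, rng):
        """Brute-force average over random mutual orientations."""
        n = 100_000
        def unit(v):
            return v / np.linalg.norm(v, axis=1, keepdims=True)
        d = unit(rng.normal(size=(n, 3)))
        a = unit(rng.normal(size=(n, 3)))
        rhat = unit(rng.normal(size=(n, 3)))
        kappa = (d * a).sum(1) - 3.0 * (d * rhat).sum(1) * (a * rhat).sum(1)
        k2 = kappa**2
        se = k2.std(ddof=1) / np.sqrt(n)
        assert abs(k2.mean() - 2.0 / 3.0) < 3 * se
        assert k2.max() <= 4.0 and k2.min() >= 0.0


class TestEfficiencyClosedForms:
    def test_midpoint_at_forster_radius(self):
        assert forster_efficiency(20.0, 2.0 / 3.0, 20.0) == pytest.approx(0.5)

    def test_double_distance_gives_one_sixty_fifth(self):
        assert forster_efficiency(40.0, 2.0 / 3.0, 20.0) == pytest.approx(1.0 / 65.0)

    def test_forbidden_orientation_gives_zero(self):
        assert forster_efficiency(5.0, 0.0, 20.0) == 0.0

    def test_strictly_decreasing_in_distance(self):
        rs = np.linspace(1.0, 100.0, 60)
        es = [forster_efficiency(r, 2.0 / 3.0, 20.0) for r in rs]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert es[0] > 0.999 and es[-1] < 1e-3

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            forster_efficiency(-1.0, 0.6, 20.0)
        with pytest.raises(ValueError):
            forster_efficiency(10.0, -0.1, 20.0)


class TestEnsembleFret:
    def test_identical_conformers_average_to_single_value(self):
        conf, spec = dipole_fixture(20.0, [0, 0, 1], [0, 0, 1])
        res = ensemble_fret([conf] * 3, spec)
        assert res.ensemble_mean_efficiency == pytest.approx(res.efficiency[0])

    def test_two_conformer_mean_is_arithmetic(self):
        # distances chosen so per-conformer efficiencies bracket the midpoint
        near, spec = dipole_fixture(12.0, [0, 0, 1], [0, 0, 1])
        far, _ = dipole_fixture(35.0, [0, 0, 1], [0, 0, 1])
        res = ensemble_fret([near, far], spec)
        assert res.ensemble_mean_efficiency == pytest.approx(res.efficiency.mean())

    def test_isotropic_orientation_ensemble_at_r0(self, rng):
        """Random mutual dipole orientations at fixed R = R0: mean kappa^2 is
        2/3 and the mean efficiency is below the isotropic-kappa2 0.5
        (averaging E over orientations loses to E at the average because the
        zero-transfer orientations cost more than the enhanced ones gain)."""
        confs = []
        spec = None
        for _ in range(4000):
            conf, spec = dipole_fixture(
                20.0, rng.normal(size=3), rng.normal(size=3)
            )
            confs.append(conf)
        res = ensemble_fret(confs, spec)
        se = res.kappa2.std(ddof=1) / np.sqrt(len(confs))
        assert abs(res.kappa2.mean() - 2.0 / 3.0) < 3 * se
        # independent brute-force check of the mean efficiency
        direct = np.mean(
            [
                (k2 / (2 / 3) * 1.0) / (k2 / (2 / 3) + 1.0)
                for k2 in res.kappa2
            ]
        )
        assert res.ensemble_mean_efficiency == pytest.approx(direct, abs=1e-9)
        assert res.ensemble_mean_efficiency < 0.5

    def test_dexter_flag_below_fifteen_angstrom(self):
        near, spec = dipole_fixture(12.0, [0, 0, 1], [0, 0, 1])
        far, _ = dipole_fixture(30.0, [0, 0, 1], [0, 0, 1])
        res = ensemble_fret([near, far], spec)
        assert list(res.dexter_flag) == [True, False]
        assert res.dexter_fraction == pytest.approx(0.5)

    def test_isotropic_mode_overrides_geometry(self):
        conf, spec = dipole_fixture(20.0, [0, 0, 1], [0, 1, 0])  # kappa2 = 0
        res = ensemble_fret([conf], spec, kappa2_mode="isotropic")
        assert res.ensemble_mean_efficiency == pytest.approx(0.5)

    def test_compact_ensemble_transfers_more_than_extended(
        self, wt_seq, helix_conformer, extended_conformer
    ):
        spec = default_chromophore_spec(wt_seq, r0_iso=49.0)
        compact = ensemble_fret([helix_conformer], spec)
        extended = ensemble_fret([extended_conformer], spec)
        assert compact.ensemble_mean_efficiency > extended.ensemble_mean_efficiency
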