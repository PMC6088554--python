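"""Collision cross-section estimators against analytic and geometric oracles."""

import numpy as np
import pytest

from abfret.ccs import (
    CCSSettings,
    CollisionRadiiTable,
    ccs_ehss,
    ccs_pa,
    ensemble_ccs,
)

SPHERE_AREA = np.pi * 3.0**2  # single collision sphere, r = 3 A


def sphere(radius=3.0, centre=(0.0, 0.0, 0.0)):
    return np.array([centre], dtype=float), np.array([radius])


# three spheres forming a cup plus one offset above: re-entrant geometry
POCKET = (
    np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [2.5, 4.3, 0.0], [2.5, 1.4, 4.5]]),
    np.full(4, 3.0),
)


class TestAnalyticCases:
    def test_single_sphere_pa_is_disc_area(self):
        res = ccs_pa(sphere(), n_orientations=100, n_points=2000, seed=1)
        # the bounding disc equals the shadow disc, so this case is exact
        assert res.mean == pytest.approx(SPHERE_AREA, abs=1e-9)

    def test_single_sphere_ehss_matches_geometric_cross_section(self):
        res = ccs_ehss(sphere(), n_orientations=200, n_trajectories=2000, seed=2)
        assert abs(res.mean - SPHERE_AREA) < 3 * max(res.mc_standard_error, 1e-3)

    def test_coincident_spheres_degenerate_to_one(self):
        coords = np.zeros((2, 3))
        radii = np.full(2, 3.0)
        res = ccs_pa((coords, radii), n_orientations=50, n_points=1500, seed=3)
        assert res.mean == pytest.approx(SPHERE_AREA, abs=1e-9)

    def test_two_distant_spheres_add(self):
        coords = np.array([[0.0, 0.0, 0.0], [150.0, 0.0, 0.0]])  # d = 50 r
        radii = np.full(2, 3.0)
        res = ccs_pa((coords, radii), n_orientations=600, n_points=4000, seed=4)
        assert abs(res.mean - 2 * SPHERE_AREA) < 3 * res.mc_standard_error


class TestEhssVsPa:
    def test_convex_single_sphere_estimators_agree(self):
        pa = ccs_pa(sphere(), n_orientations=100, n_points=3000, seed=5)
        eh = ccs_ehss(sphere(), n_orientations=200, n_trajectories=3000, seed=6)
        comb = np.hypot(pa.mc_standard_error, max(eh.mc_standard_error, 1e-3))
        assert abs(eh.mean - pa.mean) < 3 * comb

    def test_concave_pocket_scatters_more_than_it_shadows(self):
        pa = ccs_pa(POCKET, n_orientations=400, n_points=4000, seed=7)
        eh = ccs_ehss(POCKET, n_orientations=400, n_trajectories=4000, seed=8)
        comb = np.hypot(pa.mc_standard_error, eh.mc_standard_error)
        assert eh.mean - pa.mean > 3 * comb


class TestInvariants:
    def test_scale_law_quadruples_at_double_size(self):
        base = ccs_ehss(POCKET, n_orientations=300, n_trajectories=2000, seed=9)
        coords, radii = POCKET
        big = ccs_ehss(
            (coords * 2.0, radii * 2.0), n_orientations=300, n_trajectories=2000, seed=10
        )
        comb = np.hypot(4 * base.mc_standard_error, big.mc_standard_error)
        assert abs(big.mean - 4 * base.mean) < 3 * comb

    def test_rigid_motion_invariance(self, rng):
        from abfret.geometry import random_rotation_matrix

        coords, radii = POCKET
        rot = random_rotation_matrix(rng)
        moved = coords @ rot.T + rng.normal(size=3) * 30
        a = ccs_ehss(POCKET, n_orientations=400, n_trajectories=2000, seed=11)
        b = ccs_ehss((moved, radii), n_orientations=400, n_trajectories=2000, seed=12)
        assert abs(a.mean - b.mean) < 3 * np.hypot(a.mc_standard_error, b.mc_standard_error)

    def test_mc_error_shrinks_like_root_n(self):
        small = ccs_ehss(POCKET, n_orientations=150, n_trajectories=400, seed=13)
        large = ccs_ehss(POCKET, n_orientations=600, n_trajectories=400, seed=14)
        # 4x orientations should roughly halve the standard error (30% slack)
        ratio = small.mc_standard_error / large.mc_standard_error
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3

    def test_unknown_element_is_an_error(self, helix_conformer):
        with pytest.raises(KeyError):
            ccs_pa(helix_conformer, CollisionRadiiTable({"H": 2.2}), 5, 50, seed=0)

    def test_invalid_sampling_sizes_raise(self):
        with pytest.raises(ValueError):
            ccs_pa(sphere(), n_orientations=0, n_points=10, seed=0)
        with pytest.raises(ValueError):
            ccs_ehss(sphere(), n_orientations=10, n_trajectories=0, seed=0)


class TestEnsemble:
    def test_identical_conformers_have_sd_below_mc_error(self, helix_conformer):
        settings = CCSSettings(method="ehss", n_orientations=60, n_trajectories=300)
        results, (mean, sd) = ensemble_ccs([helix_conformer] * 4, settings=settings)
        typical_se = np.mean([r.mc_standard_error for r in results])
        assert sd <= 3 * typical_se

    def test_two_conformer_mean_is_midpoint(self, helix_conformer, extended_conformer):
        settings = CCSSettings(method="ehss", n_orientations=60, n_trajectories=300)
        results, (mean, _) = ensemble_ccs(
            [helix_conformer, extended_conformer], settings=settings
        )
        mid = 0.5 * (results[0].mean + results[1].mean)
        assert mean == pytest.approx(mid, rel=1e-12)

    def test_extended_build_exceeds_helical_build(
        self, helix_conformer, extended_conformer
    ):
        """Chain extension increases the cross section well beyond MC error,
        the geometric face of the compact-to-extended transition."""
        eh_h = ccs_ehss(helix_conformer, n_orientations=150, n_trajectories=800, seed=20)
        eh_e = ccs_ehss(extended_conformer, n_orientations=150, n_trajectories=800, seed=21)
        comb = np.hypot(eh_h.mc_standard_error, eh_e.mc_standard_error)
        assert eh_e.mean - eh_h.mean > 3 * comb

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            ensemble_ccs([])
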