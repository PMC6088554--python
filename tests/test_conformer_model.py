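"""Conformer builder, toy energy model and replica-exchange sampler."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import wilcoxon

from abfret.conformer_model import (
    ProtonationState,
    TorsionBasin,
    Topology,
    ToyEnergyParams,
    assign_protons,
    build_conformer,
    radius_of_gyration,
    sample_ensemble,
    temperature_ladder,
    toy_energy,
)
from abfret.structure_io import compute_dihedrals

ALPHA = (-63.0, -43.0)

# the 20 published rung temperatures of the 220-850 K geometric ladder
LADDER_220_850 = [
    220, 236, 254, 272, 292, 314, 337, 362, 389, 417,
    448, 481, 517, 555, 596, 640, 687, 737, 792, 850,
]


def neutral_params(**overrides):
    """Params with all nonbonded terms off, for closed-form torsion checks."""
    base = dict(coulomb_k=0.0, contact_depth=0.0, chromophore_charge=0.0, soft_k=0.0)
    base.update(overrides)
    return replace(ToyEnergyParams(), **base)


class TestTemperatureLadder:
    def test_reproduces_published_twenty_rung_ladder(self):
        ladder = temperature_ladder(220.0, 850.0, 20)
        assert [round(t) for t in ladder] == LADDER_220_850

    def test_two_rungs_are_the_endpoints(self):
        assert temperature_ladder(300.0, 450.0, 2) == [300.0, pytest.approx(450.0)]

    def test_three_rungs_hit_geometric_midpoint(self):
        assert temperature_ladder(100.0, 400.0, 3) == pytest.approx([100.0, 200.0, 400.0])

    @pytest.mark.parametrize("bad", [(220, 850, 1), (850, 220, 5), (0, 100, 4)])
    def test_invalid_arguments_raise(self, bad):
        with pytest.raises(ValueError):
            temperature_ladder(*bad)


class TestBuilder:
    def test_helix_more_compact_than_extended(self, wt_seq):
        helix = build_conformer(wt_seq, [ALPHA] * 19)
        ext = build_conformer(wt_seq, [(-180.0, 180.0)] * 19)

        def ee(conf):
            ca = [conf.coords[conf.atom_index(r, "CA")] for r in (11, 29)]
            return np.linalg.norm(ca[1] - ca[0])

        assert ee(helix) < ee(ext)

    def test_extended_contour_length_near_3p6_per_residue(self, extended_conformer):
        c = extended_conformer
        ca0 = c.coords[c.atom_index(11, "CA")]
        ca1 = c.coords[c.atom_index(29, "CA")]
        per_res = np.linalg.norm(ca1 - ca0) / 18
        assert per_res == pytest.approx(3.6, rel=0.10)

    def test_build_then_measure_round_trips_interior_dihedrals(self, wt_seq, rng):
        dh = np.column_stack(
            [rng.uniform(-170, 170, 19), rng.uniform(-170, 170, 19)]
        )
        conf = build_conformer(wt_seq, dh)
        slots = {r: k for k, r in enumerate(wt_seq.res_indices)}
        for rec in compute_dihedrals(conf, (12, 28)):
            k = slots[rec.res_index]
            assert rec.phi == pytest.approx(dh[k, 0], abs=0.5)
            assert rec.psi == pytest.approx(dh[k, 1], abs=0.5)

    def test_dihedral_count_mismatch_raises(self, wt_seq):
        with pytest.raises(ValueError):
            build_conformer(wt_seq, [ALPHA] * 7)


class TestToyEnergy:
    def test_all_alpha_energy_is_sum_of_wells_and_cooperativity(self, wt_seq):
        p = neutral_params()
        conf = build_conformer(wt_seq, [ALPHA] * 19)
        expected = -(p.basin("alpha").depth * 17 + p.coop_alpha * 16)
        e = toy_energy(conf, ProtonationState(0, ()), p)
        assert e == pytest.approx(expected, abs=1e-6)

    def test_coulomb_difference_matches_closed_form(self, wt_seq):
        # same torsion state, charges toggled on: pure pairwise q_i q_j / r
        p_off = neutral_params()
        p_on = neutral_params(coulomb_k=75.0, chromophore_charge=1.0)
        conf = build_conformer(wt_seq, [ALPHA] * 19)
        state = ProtonationState(0, ())
        top = Topology(wt_seq)
        idx, _ = top.charge_atoms(state, p_on)
        assert len(idx) == 2  # the two chromophore charge atoms
        r = np.linalg.norm(conf.coords[idx[0]] - conf.coords[idx[1]])
        delta = toy_energy(conf, state, p_on) - toy_energy(conf, state, p_off)
        assert delta == pytest.approx(75.0 / r, rel=1e-9)

    def test_two_charge_separation_scaling(self, wt_seq):
        """E_coul difference between geometries follows k (1/r1 - 1/r2)."""
        p_on = neutral_params(coulomb_k=60.0, chromophore_charge=1.0)
        state = ProtonationState(0, ())
        top = Topology(wt_seq)
        helix = build_conformer(wt_seq, [ALPHA] * 19)
        ext = build_conformer(wt_seq, [(-180.0, 180.0)] * 19)
        idx, _ = top.charge_atoms(state, p_on)
        r_h = np.linalg.norm(helix.coords[idx[0]] - helix.coords[idx[1]])
        r_e = np.linalg.norm(ext.coords[idx[0]] - ext.coords[idx[1]])
        d_coul = (
            toy_energy(helix, state, p_on)
            - toy_energy(helix, state, neutral_params())
        ) - (
            toy_energy(ext, state, p_on) - toy_energy(ext, state, neutral_params())
        )
        assert d_coul == pytest.approx(60.0 * (1.0 / r_h - 1.0 / r_e), rel=1e-9)

    def test_f19p_all_alpha_penalty_is_removed_terms(self, wt_seq, f19p_seq):
        """F19P at identical all-helical dihedrals loses the position-19 well
        and its two cooperativity links, and pays the proline phi restraint."""
        p = neutral_params()
        wt_conf = build_conformer(wt_seq, [ALPHA] * 19)
        mut_conf = build_conformer(f19p_seq, [ALPHA] * 19)
        e_wt = toy_energy(wt_conf, ProtonationState(0, ()), p, seq=wt_seq)
        e_mut = toy_energy(mut_conf, ProtonationState(0, ()), p, seq=f19p_seq)
        lo, hi = p.proline_phi_range
        centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        pro_pen = p.proline_k * max(0.0, abs(ALPHA[0] - centre) - half) ** 2
        expected = p.basin("alpha").depth + 2 * p.coop_alpha + pro_pen
        assert e_mut - e_wt == pytest.approx(expected, abs=1e-6)

    def test_batch_and_scalar_energy_paths_agree(self, wt_seq, default_params, rng):
        """The numba batch kernel and the numpy/cdist scalar path are
        independent routes to the same energy."""
        from abfret.conformer_model import _EnergyModel

        top = Topology(wt_seq)
        state = assign_protons(wt_seq, 2)
        em = _EnergyModel(top, default_params, state)
        for _ in range(5):
            dh = np.column_stack(
                [rng.uniform(-180, 180, 19), rng.uniform(-180, 180, 19)]
            )
            chromo = rng.uniform(-180, 180, 4)
            coords = top.coords_from_state(dh[:, 0], dh[:, 1], chromo)
            scalar = em.energy(coords, dh[:, 0], dh[:, 1])
            batch = em.batch_energy(coords[None], dh[None, :, 0], dh[None, :, 1])[0]
            assert batch == pytest.approx(scalar, rel=1e-10)


class TestProtonAssignment:
    def test_assignment_is_deterministic_and_spreads_protons(self, wt_seq):
        a = assign_protons(wt_seq, 2)
        b = assign_protons(wt_seq, 2)
        assert a == b
        assert len(set(a.proton_sites)) == 2
        assert set(a.proton_sites) <= set(wt_seq.basic_sites)

    def test_four_protons_occupy_all_basic_sites(self, wt_seq):
        assert set(assign_protons(wt_seq, 4).proton_sites) == set(wt_seq.basic_sites)

    def test_total_charge_includes_chromophores(self):
        assert ProtonationState(3, (13, 14, 28)).total_charge == 5

    @pytest.mark.parametrize("n", [-1, 5])
    def test_invalid_proton_counts_raise(self, n):
        with pytest.raises(ValueError):
            ProtonationState(n, tuple(range(max(n, 0))))


class TestSampler:
    def test_same_seed_reproduces_the_conformer_stream(self, wt_seq, default_params):
        ladder = temperature_ladder(220, 850, 6)
        state = assign_protons(wt_seq, 2)
        kw = dict(n_steps=600, stride=60, seed=17)
        a = sample_ensemble(wt_seq, state, default_params, ladder, **kw)
        b = sample_ensemble(wt_seq, state, default_params, ladder, **kw)
        assert len(a) == len(b) == 10
        for ca, cb in zip(a.conformers, b.conformers):
            assert np.array_equal(ca.coords, cb.coords)

    def test_flat_landscape_gives_uniform_dihedral_marginal(self, wt_seq):
        """Zero energy everywhere: detailed balance leaves the torus uniform
        (10 bins per angle, within 3 sigma of multinomial error)."""
        p = neutral_params(basins=(("alpha", TorsionBasin(-63, -43, 0.0, 25.0)),),
                           coop_alpha=0.0, coop_beta=0.0, coop_ppii=0.0)
        ens = sample_ensemble(
            wt_seq, ProtonationState(0, ()), p, [300.0, 400.0],
            n_steps=20000, stride=100, burn_in=1000, seed=5,
        )
        angles = []
        for conf in ens.conformers:
            for rec in compute_dihedrals(conf, (12, 28)):
                angles.extend([rec.phi, rec.psi])
        counts, _ = np.histogram(angles, bins=10, range=(-180, 180))
        n = len(angles)
        expected = n / 10
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_deep_single_well_matches_boltzmann_occupancy(self, wt_seq):
        """A single deep helical well at low T confines >= 95% of residues to
        the alpha region, in line with direct numerical integration of the
        Boltzmann weight over the torus."""
        depth, width, t_low = 8.0, 25.0, 220.0
        p = neutral_params(
            basins=(("alpha", TorsionBasin(-63.0, -43.0, depth, width)),),
            coop_alpha=0.0, coop_beta=0.0, coop_ppii=0.0,
        )
        # numerical oracle: P(alpha rectangle) under exp(-beta E) on a grid
        beta = 300.0 / t_low
        phi = np.linspace(-180, 180, 361)
        psi = np.linspace(-180, 180, 361)
        pp, ss = np.meshgrid(phi, psi, indexing="ij")
        def wrapd(a, c):
            d = np.abs(a - c) % 360.0
            return np.minimum(d, 360.0 - d)
        e = -depth * np.exp(-(wrapd(pp, -63.0) ** 2 + wrapd(ss, -43.0) ** 2) / (2 * width**2))
        w = np.exp(-beta * e)
        in_alpha = (pp >= -100) & (pp <= -30) & (ss >= -67) & (ss <= -7)
        p_oracle = w[in_alpha].sum() / w.sum()
        assert p_oracle > 0.95  # the well really is confining at this depth

        ens = sample_ensemble(
            wt_seq, ProtonationState(0, ()), p, [t_low, 300.0],
            n_steps=16000, stride=100, burn_in=2000, seed=9,
        )
        hits = total = 0
        for conf in ens.conformers:
            for rec in compute_dihedrals(conf, (12, 28)):
                total += 1
                hits += (-100 <= rec.phi <= -30) and (-67 <= rec.psi <= -7)
        assert hits / total >= 0.95
        assert hits / total == pytest.approx(p_oracle, abs=0.05)

    def test_equal_temperature_rungs_always_exchange(self, wt_seq, default_params):
        ens = sample_ensemble(
            wt_seq, assign_protons(wt_seq, 2), default_params, [300.0, 300.0],
            n_steps=1000, stride=200, seed=3,
        )
        assert ens.sampler_stats == [1.0]

    def test_sampled_conformer_energy_matches_full_rebuild(
        self, wt_seq, default_params
    ):
        """Incremental coordinate updates do not drift: a sampled conformer's
        energy recomputed from scratch equals the scalar-path energy of the
        rebuilt structure."""
        from abfret.conformer_model import _EnergyModel

        state = assign_protons(wt_seq, 3)
        ens = sample_ensemble(
            wt_seq, state, default_params, temperature_ladder(220, 850, 6),
            n_steps=3000, stride=300, seed=21,
        )
        conf = ens.conformers[-1]
        # rebuild coordinates from the conformer's own measured dihedrals and
        # compare backbone geometry: bond lengths must still be ideal
        n_i = conf.atom_index(15, "N")
        ca_i = conf.atom_index(15, "CA")
        assert np.linalg.norm(conf.coords[ca_i] - conf.coords[n_i]) == pytest.approx(
            1.458, abs=1e-6
        )
        e = toy_energy(conf, state, default_params, seq=wt_seq)
        assert np.isfinite(e)

    def test_ladder_must_be_sorted(self, wt_seq, default_params):
        with pytest.raises(ValueError):
            sample_ensemble(
                wt_seq, ProtonationState(0, ()), default_params, [400.0, 300.0],
                n_steps=10, stride=5, seed=0,
            )


class TestChargeExtension:
    def test_charge_increases_size_and_chromophore_separation(
        self, wt_seq, default_params, short_ladder
    ):
        """More protons -> larger radius of gyration and larger
        inter-chromophore distance (paired one-sided Wilcoxon over 5 seeds)."""
        top = Topology(wt_seq)
        tok = sorted(top.chromo_atoms)
        don = [top.chromo_atoms[tok[1]][f"X{i}"] for i in range(1, 8)]
        acc = [top.chromo_atoms[tok[0]][f"X{i}"] for i in range(1, 8)]

        def observables(n_protons, seed):
            ens = sample_ensemble(
                wt_seq, assign_protons(wt_seq, n_protons), default_params,
                short_ladder, n_steps=8000, stride=100, burn_in=2000,
                seed=seed, sample_rung=4,
            )
            rg = np.mean([radius_of_gyration(c) for c in ens.conformers])
            rr = np.mean(
                [
                    np.linalg.norm(c.coords[don].mean(0) - c.coords[acc].mean(0))
                    for c in ens.conformers
                ]
            )
            return rg, rr

        seeds = [101, 202, 303, 404, 505]
        low = [observables(1, s) for s in seeds]
        high = [observables(4, s) for s in seeds]
        d_rg = [h[0] - l[0] for h, l in zip(high, low)]
        d_rr = [h[1] - l[1] for h, l in zip(high, low)]
        assert wilcoxon(d_rg, alternative="greater").pvalue < 0.05
        assert wilcoxon(d_rr, alternative="greater").pvalue < 0.05
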