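import math
from dataclasses import replace

import numpy as np
import pytest

import reference as ref
from miecsvm.energy import (
    BornRadiusError,
    EnergyParams,
    MinimizationProtocol,
    SingularGeometryError,
    born_radii,
    decompose,
    electrostatic_component,
    gb_component,
    hct_integrals,
    minimize,
    rescore_pose,
    sa_component,
    sasa,
    select_pose,
    sphere_points,
    vdw_component,
)
from miecsvm.io import AtomRecord, ReceptorLigandComplex
from miecsvm.synthetic import make_pose_set


def _rotate_translate(complex_, seed=3):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(0, 5, size=3)
    coords = np.array([a.xyz for a in complex_.all_atoms()]) @ Q.T + t
    return complex_.with_all_coords(coords)


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------


class TestElectrostatics:
    def test_hand_evaluated_pair(self, pair_complex_factory, params):
        cx = pair_complex_factory(r=3.32, q_rec=1.0, q_lig=-1.0)
        e = electrostatic_component(cx, params)
        assert e[0] == pytest.approx(332.0637 * -1.0 / (4.0 * 3.32), abs=1e-9)
        assert e[0] == pytest.approx(-25.005, abs=1e-3)

    def test_zero_charge_contributes_nothing(self, pair_complex_factory, params):
        cx = pair_complex_factory(q_lig=0.0)
        assert electrostatic_component(cx, params)[0] == 0.0

    def test_dielectric_scaling(self, toy_complex, params):
        e4 = electrostatic_component(toy_complex, params)
        e8 = electrostatic_component(toy_complex, replace(params, eps_in=8.0))
        assert np.allclose(e8, e4 / 2.0, atol=1e-12)

    def test_coincident_atoms_rejected(self, pair_complex_factory, params):
        cx = pair_complex_factory(r=0.0)
        with pytest.raises(SingularGeometryError):
            electrostatic_component(cx, params)

    def test_matches_bruteforce(self, toy_complex, params):
        got = electrostatic_component(toy_complex, params)
        want = ref.coulomb_per_residue(toy_complex, params)
        for k, (ri, _) in enumerate(toy_complex.residue_order):
            assert got[k] == pytest.approx(want[ri], abs=1e-9)


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------


class TestVanDerWaals:
    def test_minimum_identity(self, pair_complex_factory, params):
        # at r = Rmin_ij the well depth is exactly -eps_ij
        cx = pair_complex_factory(r=3.6, rmin_half=1.8, eps=0.2)
        assert vdw_component(cx, params)[0] == pytest.approx(-0.2, abs=1e-12)

    def test_zero_epsilon_contributes_nothing(self, pair_complex_factory, params):
        cx = pair_complex_factory(eps=0.0)
        assert vdw_component(cx, params)[0] == 0.0

    def test_zero_crossing_at_sigma(self, pair_complex_factory, params):
        # the 12-6 form crosses zero at r = Rmin / 2^(1/6)
        r0 = 3.6 / 2 ** (1 / 6)
        cx = pair_complex_factory(r=r0, rmin_half=1.8, eps=0.2)
        assert vdw_component(cx, params)[0] == pytest.approx(0.0, abs=1e-9)
        just_in = pair_complex_factory(r=r0 * 0.99, rmin_half=1.8, eps=0.2)
        assert vdw_component(just_in, params)[0] > 0

    def test_matches_bruteforce(self, toy_complex, params):
        got = vdw_component(toy_complex, params)
        want = ref.lj_per_residue(toy_complex, params)
        for k, (ri, _) in enumerate(toy_complex.residue_order):
            assert got[k] == pytest.approx(want[ri], abs=1e-9)


# ---------------------------------------------------------------------------
# Born radii
# ---------------------------------------------------------------------------


def _atom(i, xyz, rho=1.7):
    return AtomRecord(i, f"A{i}", 0, "RES", "A", xyz, 0.1, rho, 1.8, 0.1)


class TestBornRadii:
    def test_isolated_atom_limit(self, params):
        r = born_radii([_atom(1, [0, 0, 0], rho=1.7)], params)
        assert r[0] == pytest.approx(1.7 - 0.09, abs=1e-12)

    def test_radius_never_below_reduced_radius(self, toy_complex, params):
        atoms = toy_complex.all_atoms()
        r = born_radii(atoms, params)
        rho_t = np.array([a.gb_radius for a in atoms]) - params.gb_offset
        assert np.all(r >= rho_t - 1e-12)

    def test_descreening_monotonicity(self, params):
        prev = None
        for d in [50.0, 20.0, 10.0, 6.0, 4.0]:
            r = born_radii([_atom(1, [0, 0, 0]), _atom(2, [d, 0, 0])], params)
            if prev is not None:
                assert np.all(r > prev)
            prev = r

    def test_integral_matches_numerical_quadrature(self, params):
        # non-overlapping two-atom case vs direct quadrature of r^-4
        rho_i, rho_j = 1.7, 1.5
        for d in [4.0, 6.0, 10.0]:
            atoms = [
                _atom(1, [0, 0, 0], rho=rho_i + params.gb_offset),
                _atom(2, [d, 0, 0], rho=rho_j + params.gb_offset),
            ]
            got = hct_integrals(atoms, params)[0]
            want = ref.descreening_integral_pair(d, rho_i, rho_j)
            assert got == pytest.approx(want, rel=1e-8)

    def test_order_invariance(self, toy_complex, params):
        atoms = toy_complex.all_atoms()
        r = born_radii(atoms, params)
        perm = np.random.default_rng(1).permutation(len(atoms))
        r_perm = born_radii([atoms[i] for i in perm], params)
        assert np.allclose(r[perm], r_perm, atol=1e-12)

    def test_radius_below_offset_rejected(self, params):
        with pytest.raises(BornRadiusError, match="atom 1"):
            born_radii([_atom(1, [0, 0, 0], rho=0.05)], params)


# ---------------------------------------------------------------------------
# generalized Born cross-term
# ---------------------------------------------------------------------------


class TestGBComponent:
    def test_hand_evaluated_coincident_pair(self, params):
        # f_gb(0) = sqrt(R_i R_j); with R = 2 both, energy = -pref q^2 / 2
        a = _atom(1, [0, 0, 0])
        b = AtomRecord(2, "L1", 0, "LIG", "L", [0, 0, 0], 1.0, 1.7, 1.8, 0.1)
        a = replace(a, charge=1.0)
        cx = ReceptorLigandComplex([a], [b], [(0, "RES")])
        e = gb_component(cx, np.array([2.0, 2.0]), params)
        assert e[0] == pytest.approx(-(1 / 4 - 1 / 80) * 332.0637 / 2.0, abs=1e-9)
        assert e[0] == pytest.approx(-39.43, abs=5e-3)

    def test_vanishes_when_dielectrics_match(self, toy_complex):
        p = EnergyParams(eps_in=4.0, eps_out=4.0 + 1e-9)
        radii = born_radii(toy_complex.all_atoms(), p)
        assert np.all(np.abs(gb_component(toy_complex, radii, p)) < 1e-6)

    def test_coulomb_screening_limit(self, pair_complex_factory, params):
        r = 100.0
        cx = pair_complex_factory(r=r, q_rec=1.0, q_lig=-1.0)
        radii = born_radii(cx.all_atoms(), params)
        e = gb_component(cx, radii, params)[0]
        limit = -(1 / params.eps_in - 1 / params.eps_out) * 332.0637 * -1.0 / r
        assert e == pytest.approx(limit, rel=1e-6)

    def test_matches_bruteforce(self, toy_complex, params):
        radii = born_radii(toy_complex.all_atoms(), params)
        got = gb_component(toy_complex, radii, params)
        want = ref.gb_per_residue(toy_complex, radii, params)
        for k, (ri, _) in enumerate(toy_complex.residue_order):
            assert got[k] == pytest.approx(want[ri], abs=1e-9)

    def test_radius_count_checked(self, toy_complex, params):
        with pytest.raises(ValueError, match="Born radius"):
            gb_component(toy_complex, np.ones(3), params)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


class TestSASA:
    def test_isolated_atom_analytic_area(self, params):
        a = _atom(1, [0, 0, 0], rho=1.7)
        area = sasa([a], params)[0]
        exact = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_fully_buried_atom(self, params):
        small = _atom(1, [0, 0, 0], rho=1.0)
        big = _atom(2, [0, 0, 0.1], rho=6.0)
        areas = sasa([small, big], params)
        assert areas[0] == 0.0

    def test_burial_monotone_with_approach(self, params):
        # against a high-density reference run at 10x the points
        dense = replace(params, sasa_points=5120)
        prev = None
        for d in [10.0, 6.0, 4.0, 3.0]:
            pair = [_atom(1, [0, 0, 0]), _atom(2, [d, 0, 0])]
            total = sasa(pair, dense).sum()
            if prev is not None:
                assert total < prev
            prev = total

    def test_matches_matched_point_oracle(self, toy_complex, params):
        atoms = toy_complex.all_atoms()
        pts = sphere_points(params.sasa_points)
        got = sasa(atoms, params)
        want = ref.sasa_per_atom(atoms, params, pts)
        assert np.allclose(got, want, atol=1e-6)

    def test_icosphere_point_counts(self):
        assert len(sphere_points(20)) == 20
        assert len(sphere_points(320)) == 320
        assert len(sphere_points(1280)) == 1280
        assert len(sphere_points(500)) == 500  # Fibonacci fallback
        with pytest.raises(ValueError):
            sphere_points(4)

    def test_points_lie_on_unit_sphere(self):
        for n in (320, 500):
            pts = sphere_points(n)
            assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestSAComponent:
    def test_distant_ligand_no_burial(self, toy_complex, params):
        far = toy_complex.with_ligand_coords(toy_complex.ligand_coords() + 100.0)
        assert np.all(sa_component(far, params) == 0.0)

    def test_burial_is_never_favourable_to_expose(self, toy_complex, params):
        assert np.all(sa_component(toy_complex, params) <= 1e-12)

    def test_contact_pair_matches_high_density_reference(self, params):
        a = _atom(1, [0, 0, 0], rho=1.7)
        b = AtomRecord(2, "L1", 0, "LIG", "L", [3.0, 0, 0], 0.0, 1.7, 1.8, 0.1)
        cx = ReceptorLigandComplex([a], [b], [(0, "RES")])
        dense = replace(params, sasa_points=10240)
        got = sa_component(cx, dense)[0]
        pts = sphere_points(dense.sasa_points)
        sasa_cx = ref.sasa_per_atom([a, b], dense, pts)[0]
        sasa_alone = ref.sasa_per_atom([a], dense, pts)[0]
        want = dense.sasa_gamma * (sasa_cx - sasa_alone)
        assert got == pytest.approx(want, abs=1e-9)
        assert got < 0


# ---------------------------------------------------------------------------
# decomposition / rescoring / pose selection
# ---------------------------------------------------------------------------


class TestDecompose:
    def test_additivity_by_construction(self, toy_complex, params):
        table = decompose(toy_complex, params)
        radii = born_radii(toy_complex.all_atoms(), params)
        assert np.allclose(
            table.rows["dG_ele"], electrostatic_component(toy_complex, params), atol=1e-9
        )
        assert np.allclose(
            table.rows["dG_gb"], gb_component(toy_complex, radii, params), atol=1e-9
        )
        comp_sum = table.rows[["dG_vdw", "dG_ele", "dG_gb", "dG_sa"]].sum(axis=1)
        assert np.allclose(comp_sum, table.rows["dG_total"], atol=1e-9)

    def test_infinite_separation_all_zero(self, toy_complex, params):
        far = toy_complex.with_ligand_coords(toy_complex.ligand_coords() + 1e7)
        table = decompose(far, params)
        assert np.all(np.abs(table.rows["dG_total"]) < 1e-6)

    def test_contact_residues_dominate_distal(self, toy_complex, params):
        table = decompose(toy_complex, params)
        lig = toy_complex.ligand_coords()
        strength = {}
        for k, (ri, _) in enumerate(toy_complex.residue_order):
            atoms = [a for a in toy_complex.receptor_atoms if a.residue_index == ri]
            dmin = min(np.linalg.norm(a.xyz - lig, axis=1).min() for a in atoms)
            strength[ri] = (dmin, abs(table.rows["dG_total"][k]))
        near = [s for d, s in strength.values() if d <= 5.0]
        far = [s for d, s in strength.values() if d > 12.0]
        if near and far:
            assert min(near) > max(far)

    def test_translation_invariance(self, toy_complex, params):
        coords = np.array([a.xyz for a in toy_complex.all_atoms()]) + [7.0, -3.0, 11.0]
        t0 = decompose(toy_complex, params)
        t1 = decompose(toy_complex.with_all_coords(coords), params)
        for col in ("dG_vdw", "dG_ele", "dG_gb", "dG_sa"):
            assert np.allclose(t0.rows[col], t1.rows[col], atol=1e-6)

    def test_rotation_invariance(self, toy_complex, params):
        # analytic terms are exactly rotation invariant; the point-sampled
        # surface term only up to the sampling resolution (the sphere point
        # lattice does not rotate with the molecule)
        t0 = decompose(toy_complex, params)
        t1 = decompose(_rotate_translate(toy_complex), params)
        for col in ("dG_vdw", "dG_ele", "dG_gb"):
            assert np.allclose(t0.rows[col], t1.rows[col], atol=1e-6)
        assert np.allclose(t0.rows["dG_sa"], t1.rows["dG_sa"], atol=2e-2)

    def test_two_atom_components_symmetric_under_label_swap(
        self, pair_complex_factory, params
    ):
        cx = pair_complex_factory(r=3.0, q_rec=0.5, q_lig=-0.3)
        swapped = ReceptorLigandComplex(
            [replace(cx.ligand_atoms[0], residue_name="RES", residue_index=0)],
            [replace(cx.receptor_atoms[0], residue_name="LIG")],
            [(0, "RES")],
        )
        assert electrostatic_component(cx, params)[0] == pytest.approx(
            electrostatic_component(swapped, params)[0], abs=1e-12
        )
        assert vdw_component(cx, params)[0] == pytest.approx(
            vdw_component(swapped, params)[0], abs=1e-12
        )
        radii = born_radii(cx.all_atoms(), params)
        radii_sw = born_radii(swapped.all_atoms(), params)
        assert gb_component(cx, radii, params)[0] == pytest.approx(
            gb_component(swapped, radii_sw, params)[0], abs=1e-12
        )


class TestPoseSelection:
    def test_rescore_equals_total_column_sum(self, toy_complex, params):
        score = rescore_pose(toy_complex, toy_complex.ligand_coords(), params)
        table = decompose(toy_complex, params)
        assert score == pytest.approx(table.rows["dG_total"].sum(), abs=1e-9)

    def test_far_pose_scores_near_zero(self, toy_complex, params):
        s = rescore_pose(toy_complex, toy_complex.ligand_coords() + 1e7, params)
        assert abs(s) < 1e-6

    def test_clashed_pose_scores_worse(self, toy_complex, params):
        base = rescore_pose(toy_complex, toy_complex.ligand_coords(), params)
        # drive the ligand into the nearest receptor atom
        rec0 = toy_complex.receptor_atoms[0].xyz
        lig = toy_complex.ligand_coords()
        shift = rec0 - lig[0]
        clashed = rescore_pose(toy_complex, lig + shift * 0.98, params)
        assert clashed > base

    def test_top1_always_rank_one(self, toy_complex, params):
        ps = make_pose_set(toy_complex, 3, jitter_sd=0.5, seed=4, params=params)
        assert select_pose(ps, toy_complex, params, "top1") == 1

    def test_best_of_top3_is_argmin(self, toy_complex, params):
        ps = make_pose_set(toy_complex, 3, jitter_sd=1.0, seed=4, params=params)
        best = select_pose(ps, toy_complex, params, "best_of_top3")
        scores = [
            rescore_pose(toy_complex, p.ligand_coordinates, params) for p in ps.poses
        ]
        assert best == int(np.argmin(scores)) + 1

    def test_single_pose_degenerate(self, toy_complex, params):
        ps = make_pose_set(toy_complex, 1, jitter_sd=0.0, seed=1, params=params)
        assert select_pose(ps, toy_complex, params, "best_of_top3") == 1

    def test_empty_pose_set_rejected(self, toy_complex, params):
        from miecsvm.io import PoseSet

        with pytest.raises(ValueError, match="empty"):
            select_pose(PoseSet("x", []), toy_complex, params)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def _diatomic(r, k=10.0, r0=1.5):
    a = AtomRecord(1, "A1", 0, "RES", "A", [0.0, 0.0, 0.0], 0.0, 1.5, 0.0, 0.0, True)
    b = AtomRecord(2, "L1", 0, "LIG", "L", [r, 0.0, 0.0], 0.0, 1.5, 0.0, 0.0)
    cx = ReceptorLigandComplex([a], [b], [(0, "RES")])
    return cx, [(1, 2, k, r0)]


class TestMinimize:
    def test_at_minimum_coordinates_unchanged(self, params):
        cx, bonds = _diatomic(1.5)
        res = minimize(cx, MinimizationProtocol([(0.0, 50, 50)]), params, bonds)
        moved = np.abs(
            np.array([a.xyz for a in res.complex.all_atoms()])
            - np.array([a.xyz for a in cx.all_atoms()])
        )
        assert moved.max() < 1e-6

    def test_stretched_bond_relaxes_to_length(self, params):
        cx, bonds = _diatomic(3.0)
        res = minimize(cx, MinimizationProtocol([(0.0, 200, 200)]), params, bonds)
        d = np.linalg.norm(
            res.complex.ligand_atoms[0].xyz - res.complex.receptor_atoms[0].xyz
        )
        assert d == pytest.approx(1.5, abs=1e-4)
        assert res.final_energy == pytest.approx(0.0, abs=1e-8)

    def test_energy_trajectory_non_increasing(self, toy_complex, params):
        res = minimize(
            toy_complex,
            MinimizationProtocol([(50.0, 30, 30), (10.0, 30, 30), (0.0, 60, 60)]),
            params,
        )
        for phase in res.energy_trajectory:
            assert np.all(np.diff(phase) <= 1e-10)
        assert res.final_energy <= res.initial_energy + 1e-10

    def test_stiffer_restraint_moves_backbone_less(self, toy_complex, params):
        start = np.array(
            [a.xyz for a in toy_complex.all_atoms() if a.is_backbone]
        )

        def backbone_shift(k):
            res = minimize(
                toy_complex, MinimizationProtocol([(k, 100, 100)]), params
            )
            end = np.array(
                [a.xyz for a in res.complex.all_atoms() if a.is_backbone]
            )
            return np.linalg.norm(end - start, axis=1).mean()

        assert backbone_shift(50.0) <= backbone_shift(10.0) + 1e-9

    def test_restraint_k_must_not_increase(self):
        with pytest.raises(ValueError, match="non-increasing"):
            MinimizationProtocol([(10.0, 10, 10), (50.0, 10, 10)])
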