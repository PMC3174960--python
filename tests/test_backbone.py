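"""NeRF placement, build/extract inverse pair, ensemble generator,
omega idealization and Kabsch superposition."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pepgeom import backbone as bb
from pepgeom import geometry as g
from pepgeom import survey as sv
from pepgeom import trends as tr
from pepgeom.geometry import wrap

from conftest import make_chain, random_ic_chain


def nerf_oracle(a, b, c, bond_length, bond_angle, torsion):
    """Independent atom placement via axis-angle rotations (scipy Rotation):
    start from the extension of b->c, bend in the abc plane, then twist
    about the b->c axis by the torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n_hat = np.cross(b - a, bc)
    n_hat = n_hat / np.linalg.norm(n_hat)
    d0 = bc_hat * bond_length
    bend = Rotation.from_rotvec(np.radians(180.0 - bond_angle) * n_hat)
    twist = Rotation.from_rotvec(np.radians(torsion) * bc_hat)
    return c + twist.apply(bend.apply(d0))


def ic_equal(ic1, ic2, tol=1e-6):
    torsion_fields = ("phi", "psi", "omega", "omega3", "o_torsion_terminal")
    scalar_fields = ("len_n_ca", "len_ca_c", "len_c_o", "len_c_n",
                     "ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca", "ang_o")
    assert len(ic1.residues) == len(ic2.residues)
    for r1, r2 in zip(ic1.residues, ic2.residues):
        for f in torsion_fields:
            v1, v2 = getattr(r1, f), getattr(r2, f)
            assert (v1 is None) == (v2 is None), f
            if v1 is not None:
                assert abs(wrap(v1 - v2)) < tol, f
        for f in scalar_fields:
            v1, v2 = getattr(r1, f), getattr(r2, f)
            assert (v1 is None) == (v2 is None), f
            if v1 is not None:
                assert abs(v1 - v2) < tol, f


class TestPlaceAtom:
    def test_planar_constructions(self):
        d = bb.place_atom((0, 0, 0), (1, 0, 0), (1, 1, 0), 1.0, 90.0, 180.0)
        assert np.allclose(d, (2, 1, 0), atol=1e-9)
        d = bb.place_atom((0, 0, 0), (1, 0, 0), (1, 1, 0), 1.0, 90.0, 0.0)
        assert np.allclose(d, (0, 1, 0), atol=1e-9)

    def test_defining_constraints_random(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3)) * 3
            if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
                continue
            r = rng.uniform(0.8, 2.0)
            ang = rng.uniform(30, 150)
            tor = rng.uniform(-180, 180)
            d = bb.place_atom(a, b, c, r, ang, tor)
            assert np.linalg.norm(d - c) == pytest.approx(r, abs=1e-9)
            assert g.bond_angle(b, c, d) == pytest.approx(ang, abs=1e-9)
            assert abs(wrap(g.dihedral(a, b, c, d) - tor)) < 1e-9
            # cross-check against the independently coded placement
            assert np.allclose(d, nerf_oracle(a, b, c, r, ang, tor), atol=1e-9)

    def test_collinear_frame_raises(self):
        with pytest.raises(g.DegenerateGeometryError):
            bb.place_atom((0, 0, 0), (1, 0, 0), (2, 0, 0), 1.0, 90.0, 0.0)


class TestInversePair:
    def test_helix_round_trip(self):
        m = make_chain(10)
        recs = [r for r in sv.extract_records(m) if r.included]
        for r in recs:
            assert r.phi == pytest.approx(-60.0, abs=1e-6)
            assert r.psi == pytest.approx(-45.0, abs=1e-6)
            assert r.omega == pytest.approx(180.0, abs=1e-6)
            assert r.theta_c == pytest.approx(0.0, abs=1e-6)

    def test_single_bond_delta_omega(self):
        m = make_chain(4, omega=170.0)
        recs = [r for r in sv.extract_records(m) if r.omega is not None]
        assert recs[0].delta_omega == pytest.approx(-10.0, abs=1e-6)

    def test_extract_build_identity_randomized(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            ic = random_ic_chain(rng, n=int(rng.integers(4, 12)))
            model = bb.build_backbone(ic)
            ic2 = bb.extract_internal(model)
            ic_equal(ic, ic2)
            model2 = bb.build_backbone(ic2)
            for r1, r2 in zip(model.residues(), model2.residues()):
                for a1, a2 in zip(r1.atoms, r2.atoms):
                    assert np.linalg.norm(a1.coord - a2.coord) < 1e-6

    def test_extract_missing_atom_names_residue(self):
        m = make_chain(5)
        m.chains["A"][2].atoms = [a for a in m.chains["A"][2].atoms if a.name != "O"]
        with pytest.raises(bb.ExtractionError, match="3"):
            bb.extract_internal(m)

    def test_extract_refuses_chain_break(self):
        m = make_chain(6)
        for res in m.chains["A"][3:]:
            for a in res.atoms:
                a.coord = a.coord + 40.0
        with pytest.raises(bb.ExtractionError, match="break"):
            bb.extract_internal(m)


class TestSynthesizeEnsemble:
    def test_noiseless_zero_amplitude(self):
        spec = bb.EnsembleSpec(n_chains=2, chain_length=8, amplitude_A=0.0,
                               noise_omega_sd=0.0, noise_thetaC_sd=0.0,
                               thetaC_intercept=1.5, seed=1)
        res = bb.synthesize_ensemble(spec)
        for m in res.models:
            for r in sv.extract_records(m):
                if r.omega is not None:
                    assert r.omega == pytest.approx(180.0, abs=1e-6)
                    assert r.theta_c == pytest.approx(1.5, abs=1e-6)

    def test_fixed_psi_evaluates_generator(self):
        spec = bb.EnsembleSpec(n_chains=1, chain_length=6, amplitude_A=2.0,
                               phase=0.0, noise_omega_sd=0.0, noise_thetaC_sd=0.0,
                               phipsi_sampler=("fixed", -60.0, 30.0), seed=1)
        res = bb.synthesize_ensemble(spec)
        recs = [r for r in sv.extract_records(res.models[0]) if r.included]
        for r in recs:
            assert r.delta_omega == pytest.approx(2.0 * math.sin(math.radians(90.0)),
                                                  abs=1e-6)

    def test_reproducible_under_seed(self):
        r1 = bb.synthesize_ensemble(bb.EnsembleSpec(n_chains=2, chain_length=10, seed=5))
        r2 = bb.synthesize_ensemble(bb.EnsembleSpec(n_chains=2, chain_length=10, seed=5))
        assert r1.truth.equals(r2.truth)
        a1 = np.array([a.coord for m in r1.models for r in m.residues() for a in r.atoms])
        a2 = np.array([a.coord for m in r2.models for r in m.residues() for a in r.atoms])
        np.testing.assert_array_equal(a1, a2)

    def test_survey_matches_truth(self, default_ensemble, default_ensemble_records):
        """Measured delta_omega/theta_C on rebuilt coordinates equal the
        generating values recorded in the truth table."""
        truth = default_ensemble.truth.set_index(["entry_id", "seq_number"])
        for rec in default_ensemble_records[:200]:
            row = truth.loc[(rec.entry_id, rec.seq_number)]
            assert rec.psi == pytest.approx(row.psi, abs=1e-6)
            assert rec.delta_omega == pytest.approx(row.delta_omega, abs=1e-6)
            assert rec.theta_c == pytest.approx(row.theta_c, abs=1e-6)

    def test_full_recovery_loop(self, default_ensemble_records):
        recs = default_ensemble_records
        assert len(recs) == 2000
        hfit = tr.fit_harmonic([r.psi for r in recs], [r.delta_omega for r in recs])
        assert 1.9 <= hfit.amplitude <= 2.1
        lfit = tr.fit_linear([r.delta_omega for r in recs], [r.theta_c for r in recs])
        assert 0.55 <= lfit.slope <= 0.65
        phase_dist = min(hfit.phase % 120.0, 120.0 - hfit.phase % 120.0)
        assert phase_dist < 3.0


class TestIdealizeOmega:
    def test_fixed_point(self):
        m = make_chain(12, omega=180.0)
        rebuilt, rep = bb.idealize_omega(m)
        assert rep.max_displacement < 1e-6
        assert rep.kabsch_rmsd < 1e-6

    def test_lever_arm_structure(self):
        """A single perturbed central bond: zero displacement upstream,
        nondecreasing displacement downstream."""
        ics = []
        n = 20
        for i in range(n):
            r = bb.ResidueIC(phi=(-120.0 if i > 0 else None))
            if i < n - 1:
                r.psi, r.omega, r.omega3 = 130.0, 180.0, 0.0
            else:
                r.o_torsion_terminal = 180.0
            ics.append(r)
        ics[10].omega = 170.0  # delta_omega = -10 on bond 10->11
        m = bb.build_backbone(bb.InternalCoordinateChain(residues=ics))
        _, rep = bb.idealize_omega(m)
        d = rep.per_residue_ca_displacement
        assert all(x < 1e-9 for x in d[:11])
        assert d[11] > 1e-3
        for i in range(11, n - 1):
            assert d[i + 1] >= d[i] - 1e-9

    def test_idempotent(self):
        res = bb.synthesize_ensemble(
            bb.EnsembleSpec(n_chains=1, chain_length=30, noise_omega_sd=4.0, seed=3))
        once, rep1 = bb.idealize_omega(res.models[0])
        twice, rep2 = bb.idealize_omega(once)
        assert rep2.max_displacement < 1e-6
        for r1, r2 in zip(once.residues(), twice.residues()):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.linalg.norm(a1.coord - a2.coord) < 1e-6

    def test_cis_bonds_untouched(self):
        ics = []
        n = 8
        for i in range(n):
            r = bb.ResidueIC(phi=(-80.0 if i > 0 else None))
            if i < n - 1:
                r.psi, r.omega, r.omega3 = 140.0, 175.0, -5.0
            else:
                r.o_torsion_terminal = 180.0
            ics.append(r)
        ics[3].omega = 5.0  # a cis bond
        m = bb.build_backbone(bb.InternalCoordinateChain(residues=ics))
        rebuilt, _ = bb.idealize_omega(m)
        ic2 = bb.extract_internal(rebuilt)
        assert ic2.residues[3].omega == pytest.approx(5.0, abs=1e-6)
        assert ic2.residues[2].omega == pytest.approx(180.0, abs=1e-6)

    def test_displacement_monotone_in_perturbation(self):
        """Terminal CA displacement grows with |delta_omega| of one bond."""
        last = []
        for d_omega in (0.0, 5.0, 10.0, 15.0, 20.0):
            m = make_chain(15, omega=wrap(180.0 - d_omega))
            ic = bb.extract_internal(m)
            for r in ic.residues:
                if r.omega is not None:
                    r.omega = 180.0
            # perturb only the central bond back
            ic.residues[7].omega = wrap(180.0 - d_omega)
            m2 = bb.build_backbone(ic)
            _, rep = bb.idealize_omega(m2)
            last.append(rep.per_residue_ca_displacement[-1])
        assert all(b >= a - 1e-9 for a, b in zip(last, last[1:]))

    def test_agrees_with_independent_rebuild(self):
        """Idealized coordinates match a from-scratch rebuild using the
        independent NeRF oracle."""
        res = bb.synthesize_ensemble(
            bb.EnsembleSpec(n_chains=1, chain_length=25, noise_omega_sd=6.8, seed=9))
        model = res.models[0]
        rebuilt, rep = bb.idealize_omega(model)
        ic = bb.extract_internal(model)
        for r in ic.residues:
            if r.omega is not None and g.classify_isomer(r.omega) == "trans":
                r.omega = 180.0
        # oracle rebuild, atom by atom
        n = len(ic.residues)
        N = [ic.anchor_n]
        CA = [ic.anchor_ca]
        C = [ic.anchor_c]
        for i in range(n - 1):
            r, rn = ic.residues[i], ic.residues[i + 1]
            N.append(nerf_oracle(N[i], CA[i], C[i], r.len_c_n, r.ang_ca_c_n, r.psi))
            CA.append(nerf_oracle(CA[i], C[i], N[i + 1], rn.len_n_ca, r.ang_c_n_ca, r.omega))
            C.append(nerf_oracle(C[i], N[i + 1], CA[i + 1], rn.len_ca_c, rn.ang_n_ca_c, rn.phi))
        for i, resid in enumerate(rebuilt.chains["A"]):
            assert np.linalg.norm(resid.atom("N").coord - N[i]) < 1e-6
            assert np.linalg.norm(resid.atom("CA").coord - CA[i]) < 1e-6
            assert np.linalg.norm(resid.atom("C").coord - C[i]) < 1e-6

    def test_kabsch_bound(self):
        res = bb.synthesize_ensemble(
            bb.EnsembleSpec(n_chains=1, chain_length=40, noise_omega_sd=6.8, seed=2))
        _, rep = bb.idealize_omega(res.models[0])
        assert rep.kabsch_rmsd <= rep.unsuperposed_rms + 1e-9
        assert rep.mean_displacement > 0


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(1).normal(size=(10, 3))
        _, _, rmsd = bb.kabsch_superpose(P, P)
        assert rmsd < 1e-9

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(12, 3))
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 5
        Rhat, that, rmsd = bb.kabsch_superpose(P, (P @ R.T) + t)
        assert rmsd < 1e-7
        assert np.linalg.det(Rhat) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[3] += np.array([1.0, 0.0, 0.0])
        _, _, rmsd = bb.kabsch_superpose(P, Q)

        def objective(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            diff = (Q @ R.T + x[3:]) - P
            return np.sqrt(np.mean(np.sum(diff**2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for x0 in [np.zeros(6), np.r_[0.3, -0.2, 0.1, 1.0, -1.0, 0.5]]
        )
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            bb.kabsch_superpose(np.zeros((5, 3)), np.zeros((4, 3)))


class TestAmideHydrogens:
    def test_in_plane_hydrogens_give_zero_theta_n(self):
        m = make_chain(6)
        bb.add_amide_hydrogens(m)
        recs = sv.extract_records(m)
        for r in recs:
            if r.omega is not None:
                assert r.theta_n == pytest.approx(0.0, abs=1e-6)
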