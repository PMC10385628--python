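"""Superposition, RMSD/RMSF analytics and B-factor conversions."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from contactzones import synthetic as syn
from contactzones.flucts import (
    Ensemble,
    FluctuationProfile,
    b_from_rmstd,
    correlate_profiles,
    kabsch_superpose,
    rmsd_series,
    rmsf,
    rmstd_from_b,
    rmstd_profile,
)


def random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-5, 5, 3)
    return rot, trans


class TestKabsch:
    def test_self_superposition_zero(self, rng):
        x = rng.uniform(-3, 3, (10, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self, rng):
        x = rng.uniform(-3, 3, (10, 3))
        rot, trans = random_rigid(rng)
        _, _, rmsd = kabsch_superpose(x @ rot.T + trans, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_independent_scipy_alignment(self, rng):
        x = rng.uniform(-3, 3, (12, 3))
        y = x + rng.normal(0, 0.4, x.shape)
        _, _, rmsd = kabsch_superpose(x, y)
        rot, rssd = Rotation.align_vectors(
            y - y.mean(axis=0), x - x.mean(axis=0)
        )
        assert rmsd == pytest.approx(rssd / np.sqrt(len(x)), abs=1e-9)

    def test_four_point_fixture_matches_rotation_search_oracle(self):
        x = np.array(
            [[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]]
        )
        y = x.copy()
        y[0] += [0.0, 0.0, 1.0]  # one point displaced by 1 A

        def objective(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            xm = (x - x.mean(axis=0)) @ r.T
            ym = y - y.mean(axis=0)
            return np.sqrt(((xm - ym) ** 2).sum(axis=1).mean())

        # numeric search over rotations, independent of the SVD solution
        best = min(
            (
                minimize(objective, v0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12})
                for v0 in ([0, 0, 0], [0.3, 0, 0], [0, 0.4, 0.2])
            ),
            key=lambda res: res.fun,
        )
        _, _, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(best.fun, abs=1e-3)

    def test_reflection_case_resolved_to_proper_rotation(self, rng):
        x = rng.uniform(-2, 2, (6, 3))
        y = x.copy()
        y[:, 2] *= -1  # mirrored target
        rot, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_shape_errors(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.uniform(size=(4, 3)), rng.uniform(size=(5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(rng.uniform(size=(2, 3)), rng.uniform(size=(2, 3)))


class TestRmsdSeries:
    def _ensemble(self, base, frames):
        return Ensemble(np.array(frames))

    def test_identical_frames_zero(self, rng):
        base = rng.uniform(-3, 3, (8, 3))
        ens = self._ensemble(base, [base] * 5)
        out = rmsd_series(ens, base, np.arange(8))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_noise_scaling_doubles_mean(self, rng):
        base = rng.uniform(-5, 5, (40, 3))
        n1 = rng.normal(0, 0.1, (50, 40, 3))
        e1 = self._ensemble(base, base[None] + n1)
        e2 = self._ensemble(base, base[None] + 2 * n1)
        m1 = rmsd_series(e1, base, np.arange(40)).mean()
        m2 = rmsd_series(e2, base, np.arange(40)).mean()
        assert m2 / m1 == pytest.approx(2.0, rel=0.02)

    def test_mean_matches_direct_simulation_oracle(self, rng):
        base = rng.uniform(-5, 5, (30, 3))
        sigma = 0.2
        ens = self._ensemble(
            base, base[None] + rng.normal(0, sigma, (200, 30, 3))
        )
        got = rmsd_series(ens, base, np.arange(30)).mean()
        # independent oracle: scipy alignment on freshly drawn frames
        vals = []
        for _ in range(200):
            noisy = base + rng.normal(0, sigma, base.shape)
            rot, rssd = Rotation.align_vectors(
                base - base.mean(axis=0), noisy - noisy.mean(axis=0)
            )
            vals.append(rssd / np.sqrt(len(base)))
        assert got == pytest.approx(np.mean(vals), rel=0.05)

    def test_empty_selection(self, rng):
        base = rng.uniform(size=(5, 3))
        with pytest.raises(ValueError):
            rmsd_series(self._ensemble(base, [base] * 3), base, np.array([]))


class TestRmsf:
    def test_static_ensemble_zero(self, rng):
        base = rng.uniform(-3, 3, (6, 3))
        ens = Ensemble(np.repeat(base[None], 4, axis=0))
        prof = rmsf(ens, align=False)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_isotropic_sigma_recovery(self):
        a, b = syn.make_two_atom_complex("C", 40.0)
        atoms = [a.atoms[0], b.atoms[0]] * 10  # 20-atom roster
        atoms = [
            syn._atom(i + 1, "C", np.asarray(at.position) + [0, 2.0 * i, 0])
            for i, at in enumerate(atoms)
        ]
        ens = syn.make_gaussian_ensemble(atoms, 0.2, 2000, seed=5)
        prof = rmsf(ens, align=False)
        assert prof.values.mean() == pytest.approx(0.2 * np.sqrt(3), rel=0.05)

    def test_two_sigma_groups_ratio(self):
        atoms = [syn._atom(i + 1, "C", (3.0 * i, 0, 0)) for i in range(40)]
        sigma = np.array([0.1] * 20 + [0.3] * 20)
        ens = syn.make_gaussian_ensemble(atoms, sigma, 1500, seed=9)
        prof = rmsf(ens, align=False)
        ratio = prof.values[20:].mean() / prof.values[:20].mean()
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_alignment_removes_rigid_motion(self, rng):
        base = rng.uniform(-4, 4, (12, 3))
        frames = []
        for _ in range(30):
            rot, trans = random_rigid(rng)
            frames.append(base @ rot.T + trans)
        ens = Ensemble(np.array(frames))
        prof = rmsf(ens, align=True)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            rmsf(Ensemble(rng.uniform(size=(1, 4, 3))))

    def test_about_reference_at_least_about_mean(self):
        atoms = [syn._atom(i + 1, "C", (3.0 * i, 0, 0)) for i in range(10)]
        ens = syn.make_gaussian_ensemble(atoms, 0.25, 400, seed=2)
        about_mean = rmsf(ens, align=False, about="mean").values
        about_ref = rmsf(ens, align=False, about="reference").values
        assert np.all(about_ref >= about_mean - 1e-12)


class TestBfactorConversions:
    def test_forced_by_formula(self):
        assert rmstd_from_b(8 * np.pi**2) == pytest.approx(1.0)
        assert rmstd_from_b(0.0) == 0.0

    def test_published_average_b(self):
        # average refined B of 25.55 A^2 corresponds to ~0.57 A displacement
        assert rmstd_from_b(25.55) == pytest.approx(0.569, abs=0.001)

    def test_roundtrip_identity(self, rng):
        b = rng.uniform(0, 100, 50)
        np.testing.assert_allclose(b_from_rmstd(rmstd_from_b(b)), b, rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rmstd_from_b(-1.0)

    def test_profile_from_calpha_bfactors(self):
        atoms = [
            syn._atom(i + 1, "C", (3.0 * i, 0, 0), name="CA", resnum=i + 1,
                      b=10.0 + i)
            for i in range(5)
        ]
        prof = rmstd_profile(atoms)
        assert prof.kind == "RMSTD" and len(prof.values) == 5
        np.testing.assert_allclose(
            prof.values, rmstd_from_b(np.array([10.0, 11, 12, 13, 14]))
        )


class TestCorrelation:
    def test_affine_transform_perfect(self, rng):
        v = rng.uniform(0, 2, 20)
        p1 = FluctuationProfile(v, kind="RMSF")
        p2 = FluctuationProfile(2 * v + 1, kind="RMSTD")
        assert correlate_profiles(p1, p2) == pytest.approx(1.0)

    def test_anticorrelated(self, rng):
        v = rng.uniform(0, 2, 20)
        assert correlate_profiles(v, v.max() - v) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0, 1, 30)
        got = correlate_profiles(x, y)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert got == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_profiles(np.ones(5), np.arange(5.0))


class TestEnsembleRoster:
    def test_roster_mismatch_reports_first_difference(self, glycine_atoms):
        from contactzones.structure_io import StructureModel

        m1 = StructureModel({"A": glycine_atoms})
        renamed = list(glycine_atoms)
        bad = syn._atom(99, "C", (9, 9, 9), name="CB")
        renamed[3] = bad
        m2 = StructureModel({"A": renamed})
        with pytest.raises(ValueError, match="atom 3"):
            Ensemble.from_models([m1, m2])
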