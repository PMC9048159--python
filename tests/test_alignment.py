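"""Rigid point-set registration and the sphere-phantom alignment pipeline."""

import numpy as np
import pytest
from scipy.optimize import minimize

from petmr_qa.alignment import align_session, detect_spheres, kabsch, midpoints, register
from petmr_qa.core import QAError, RigidTransform
from petmr_qa.phantoms import VQCPhantomSpec, gen_vqc_phantom


def random_points(rng, n=5, scale=60.0):
    return rng.uniform(-scale, scale, (n, 3))


class TestKabsch:
    def test_identity(self, rng):
        pts = random_points(rng)
        r, t, rms = kabsch(pts, pts)
        assert r == pytest.approx(np.eye(3), abs=1e-12)
        assert t == pytest.approx(np.zeros(3), abs=1e-10)
        assert rms == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation_recovered_exactly(self, rng):
        pts = random_points(rng)
        res = register(pts, pts + np.array([1.0, 2.0, 3.0]))
        assert res.transform.translation == pytest.approx([1.0, 2.0, 3.0], abs=1e-9)
        assert res.transform.as_params()[3:] == pytest.approx(np.zeros(3), abs=1e-9)

    def test_random_rigid_recovery_to_1e6(self, rng):
        for _ in range(25):
            truth = RigidTransform(*rng.uniform(-5, 5, 3), *rng.uniform(-2, 2, 3))
            pts = random_points(rng)
            res = register(pts, truth.apply(pts))
            assert res.transform.as_params() == pytest.approx(truth.as_params(), abs=1e-6)
            assert res.residual_rms < 1e-9

    def test_equivalence_with_numeric_least_squares(self, rng):
        # the closed form must match brute-force minimisation of the
        # sum of squared distances over the six parameters
        for _ in range(3):
            src = random_points(rng)
            tgt = random_points(rng)  # unrelated clouds: non-trivial optimum

            def cost(params):
                t = RigidTransform(*params)
                return np.sum((t.apply(src) - tgt) ** 2)

            r, t, rms = kabsch(src, tgt)
            closed = RigidTransform.from_matrix(r, t)
            num = minimize(cost, closed.as_params() + 0.05, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            assert cost(closed.as_params()) <= num.fun + 1e-8

    def test_rotation_determinant_always_plus_one(self, rng):
        for _ in range(50):
            src = random_points(rng)
            tgt = random_points(rng)
            r, _, _ = kabsch(src, tgt)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        # near-reflection case
        src = random_points(rng)
        r, _, _ = kabsch(src, -src)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_swap_invariance_up_to_inversion(self, rng):
        truth = RigidTransform(1.0, -2.0, 0.5, 1.0, -0.5, 0.8)
        src = random_points(rng)
        tgt = truth.apply(src) + rng.normal(0, 0.1, src.shape)
        fwd = register(src, tgt)
        bwd = register(tgt, src)
        assert bwd.transform.as_params() == pytest.approx(
            fwd.transform.inverse().as_params(), abs=1e-6
        )
        assert bwd.residual_rms == pytest.approx(fwd.residual_rms, abs=1e-9)

    def test_collinear_points_rejected(self):
        src = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(QAError, match="collinear"):
            kabsch(src, src)

    def test_too_few_points_rejected(self):
        with pytest.raises(QAError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_translation_noise_scaling_monte_carlo(self, rng):
        # with centroid noise SD s on k spheres centred at the origin the
        # recovered translation component SD is s / sqrt(k)
        s, k, reps = 0.05, 5, 1000
        src = np.asarray(VQCPhantomSpec().pet_sphere_positions, dtype=float)
        assert src.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)
        trans = np.empty((reps, 3))
        for i in range(reps):
            tgt = src + rng.normal(0.0, s, src.shape)
            trans[i] = register(src, tgt).transform.translation
        measured = trans.std(axis=0, ddof=1)
        assert measured == pytest.approx(np.full(3, s / np.sqrt(k)), rel=0.2)


class TestSphereDetection:
    def test_pet_centroids_within_tenth_mm(self):
        spec = VQCPhantomSpec(seed=2)
        _, pet, _ = gen_vqc_phantom(spec)
        det = detect_spheres(pet, expected_count=5)
        truth = np.asarray(spec.pet_sphere_positions, dtype=float)
        d = np.linalg.norm(det.centroids[:, None, :] - truth[None, :, :], axis=2)
        assert d.min(axis=1).max() < 0.1  # every detection near one truth sphere
        assert len(set(d.argmin(axis=1))) == 5  # one-to-one

    def test_mr_count_is_ten(self):
        mr, _, _ = gen_vqc_phantom(VQCPhantomSpec(seed=2))
        assert len(detect_spheres(mr, expected_count=10)) == 10

    def test_wrong_count_is_error(self):
        _, pet, _ = gen_vqc_phantom(VQCPhantomSpec(seed=2))
        with pytest.raises(QAError, match="expected 4 spheres"):
            detect_spheres(pet, expected_count=4)


class TestMidpoints:
    def test_symmetric_pair_midpoint_at_zero(self):
        from petmr_qa.alignment import SphereDetections
        from petmr_qa.core import Modality

        pts = np.array([[0, 0, 10.0], [0, 0, -10.0], [30, 0, 12.0], [30, 0, -8.0]])
        det = SphereDetections(Modality.MR, pts)
        mids = midpoints(det)
        mids = mids[np.argsort(mids[:, 0])]
        assert mids[0] == pytest.approx([0, 0, 0])
        assert mids[1] == pytest.approx([30, 0, 2.0])

    def test_pairing_matches_exhaustive_oracle(self, rng):
        from petmr_qa.alignment import SphereDetections
        from petmr_qa.core import Modality

        centres = random_points(rng, n=5, scale=50.0)
        off = np.array([0.0, 0.0, 15.0])
        pts = np.vstack([centres + off, centres - off]) + rng.normal(0, 0.1, (10, 3))
        mids = midpoints(SphereDetections(Modality.MR, pts))
        # oracle: the midpoint set must equal {mean of the two spheres of
        # each constructed pair}, found by exhaustive matching
        expected = 0.5 * (pts[:5] + pts[5:])
        d = np.linalg.norm(mids[:, None, :] - expected[None, :, :], axis=2)
        assert (d.min(axis=1) < 1e-9).all()

    def test_ambiguous_pairing_fails(self):
        from petmr_qa.alignment import SphereDetections
        from petmr_qa.core import Modality

        pts = np.array([[0, 0, 10.0], [0, 0, -10.0], [0, 0, 30.0], [200, 0, 0.0]])
        with pytest.raises(QAError):
            midpoints(SphereDetections(Modality.MR, pts))


class TestFullPipeline:
    def test_recovers_true_misalignment(self):
        truth = RigidTransform(t_rl=0.5, t_ap=0.3, t_si=0.2, pitch=0.1)
        mr, pet, _ = gen_vqc_phantom(VQCPhantomSpec(true_misalignment=truth, seed=21))
        res = align_session(mr, pet)
        assert res.transform.translation == pytest.approx(truth.translation, abs=0.05)
        assert res.transform.as_params()[3:] == pytest.approx([0.1, 0.0, 0.0], abs=0.05)
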