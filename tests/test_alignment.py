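import itertools
import math

import numpy as np
import pytest

from pocketkernel import (
    KernelParams,
    OptimizerConfig,
    Pocket,
    RigidMotion,
    apply_motion,
    centroid,
    ck_kernel,
    initial_motions,
    kernel_gradient,
    sup_ck,
)
from pocketkernel.alignment import _Objective, _batch_euler


def geodesic_angle(R1, R2):
    c = (np.trace(R1 @ R2.T) - 1) / 2
    return math.acos(min(1.0, max(-1.0, c)))


class TestKernelGradient:
    def test_stationary_at_coincident_single_atoms(self):
        p = Pocket(np.zeros((1, 3)))
        g = kernel_gradient(p, p, KernelParams(), RigidMotion())
        assert np.allclose(g, 0, atol=1e-12)

    def test_matches_finite_differences(self, rng, random_motion):
        params = KernelParams(sigma=1.0, lam=0.5)
        for _ in range(5):
            p1 = Pocket(rng.normal(size=(6, 3)), labels=rng.normal(size=6))
            p2 = Pocket(rng.normal(size=(6, 3)), labels=rng.normal(size=6))
            m = random_motion(rng, tmax=1.0)
            g = kernel_gradient(p1, p2, params, m)
            obj = _Objective(p1, p2, params)
            v, h = m.as_vector(), 1e-5
            fd = np.empty(6)
            for k in range(6):
                vp, vm = v.copy(), v.copy()
                vp[k] += h
                vm[k] -= h
                fd[k] = (obj.value(vp[None])[0] - obj.value(vm[None])[0]) / (2 * h)
            assert np.linalg.norm(g - fd) <= 1e-5 * max(np.linalg.norm(fd), 1e-3)

    def test_translation_gradient_zero_at_matched_centroids(self):
        p1 = Pocket(np.array([[1.0, 2, 3]]))
        p2 = Pocket(np.array([[-4.0, 0, 1]]))
        t = p1.coords[0] - p2.coords[0]
        g = kernel_gradient(p1, p2, KernelParams(), RigidMotion(translation=t))
        assert np.allclose(g[:3], 0, atol=1e-12)


class TestInitialMotions:
    def test_exact_translate_recovered(self, rng):
        p1 = Pocket(rng.normal(size=(12, 3)) * [3, 2, 1])
        p2 = apply_motion(p1, RigidMotion(translation=np.array([7.0, -2, 4])))
        best = max(
            ck_kernel(p1, apply_motion(p2, m)) for m in initial_motions(p1, p2)
        )
        assert best >= ck_kernel(p1, p1) - 1e-9

    def test_eight_starts_for_generic_clouds(self, rng):
        p1 = Pocket(rng.normal(size=(15, 3)) * [5, 2.5, 1])
        p2 = Pocket(rng.normal(size=(15, 3)) * [5, 2.5, 1])
        motions = initial_motions(p1, p2, permit_axis_permutations=False)
        assert len(motions) == 8

    def test_rotations_proper_and_axis_aligned(self, rng):
        from pocketkernel import principal_frame

        p1 = Pocket(rng.normal(size=(18, 3)) * [4, 2, 1])
        p2 = Pocket(rng.normal(size=(14, 3)) * [4, 2, 1])
        a1 = principal_frame(p1).axes[:, 0]
        a2 = principal_frame(p2).axes[:, 0]
        for m in initial_motions(p1, p2, permit_axis_permutations=False):
            R = m.rotation
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert abs(abs((R @ a2) @ a1) - 1) < 1e-9

    def test_degenerate_cloud_falls_back(self):
        p1 = Pocket(np.zeros((3, 3)))
        p2 = Pocket(np.ones((3, 3)))
        motions = initial_motions(p1, p2)
        assert len(motions) >= 1
        moved = apply_motion(p2, motions[0])
        assert np.allclose(centroid(moved), centroid(p1), atol=1e-9)


class TestSupCk:
    def test_recovers_rigid_copy(self, rng, random_motion):
        p1 = Pocket(rng.normal(size=(20, 3)) * 3)
        m = random_motion(rng)
        p2 = apply_motion(p1, m)
        res = sup_ck(p1, p2)
        assert res.score >= 0.99 * ck_kernel(p1, p1)
        back = apply_motion(p2, res.motion)
        rmsd = np.sqrt(((back.coords - p1.coords) ** 2).sum(axis=1).mean())
        assert rmsd < 0.1

    def test_single_atom_exact(self):
        p1 = Pocket(np.array([[1.0, 2, 3]]))
        p2 = Pocket(np.array([[-5.0, 8, 0]]))
        res = sup_ck(p1, p2)
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_beats_euler_grid_oracle(self, rng):
        params = KernelParams(1.0)
        p1 = Pocket(rng.normal(size=(8, 3)) * 2)
        p2 = Pocket(rng.normal(size=(8, 3)) * 2)
        best = grid_search_oracle(p1, p2, params)
        assert sup_ck(p1, p2, params).score >= best - 1e-6

    def test_approximate_symmetry(self, rng):
        # anisotropic clouds: the principal-axis starts make the optimum
        # reproducible from either side, up to optimizer noise
        p1 = Pocket(rng.normal(size=(10, 3)) * [4, 2, 1])
        p2 = Pocket(rng.normal(size=(12, 3)) * [4, 2, 1])
        s12 = sup_ck(p1, p2).score
        s21 = sup_ck(p2, p1).score
        assert abs(s12 - s21) / max(s12, s21) < 1e-3

    def test_rigid_motion_invariance_of_score(
        self, rng, random_pocket, random_motion
    ):
        p1, p2 = random_pocket(rng, 10), random_pocket(rng, 9)
        base = sup_ck(p1, p2).score
        moved = sup_ck(p1, apply_motion(p2, random_motion(rng))).score
        assert moved == pytest.approx(base, rel=1e-6)

    def test_improves_on_centroid_matched_start(self, rng, random_pocket):
        p1, p2 = random_pocket(rng, 9), random_pocket(rng, 9)
        t = centroid(p1) - centroid(p2)
        baseline = ck_kernel(p1, apply_motion(p2, RigidMotion(translation=t)))
        assert sup_ck(p1, p2).score >= baseline - 1e-12

    def test_improves_on_every_initial_motion(self, rng, random_pocket):
        # maximization can only improve on its starting poses
        p1, p2 = random_pocket(rng, 8), random_pocket(rng, 10)
        best_init = max(
            ck_kernel(p1, apply_motion(p2, m)) for m in initial_motions(p1, p2)
        )
        assert sup_ck(p1, p2).score >= best_init - 1e-12

    def test_deterministic_given_seed(self, rng, random_pocket):
        p1, p2 = random_pocket(rng, 8), random_pocket(rng, 8)
        cfg = OptimizerConfig(seed=3)
        a = sup_ck(p1, p2, cfg=cfg)
        b = sup_ck(p1, p2, cfg=cfg)
        assert a.score == b.score
        assert np.array_equal(a.motion.as_vector(), b.motion.as_vector())


def grid_search_oracle(p1, p2, params, step_deg=10.0):
    """Exhaustive centroid-matched search over a Euler-angle grid."""
    angs = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    combos = np.array(list(itertools.product(angs, angs, angs)))
    c1, c2 = centroid(p1), centroid(p2)
    X, x2 = p1.coords, (p1.coords**2).sum(axis=1)
    inv2s2 = 1.0 / (2.0 * params.sigma**2)
    best = -np.inf
    for chunk in np.array_split(combos, 32):
        Rzf, Rxt, Rzp = _batch_euler(chunk)
        R = Rzf @ Rxt @ Rzp
        t = c1[None, :] - np.einsum("sab,b->sa", R, c2)
        Q = np.einsum("sab,jb->sja", R, p2.coords) + t[:, None, :]
        sq = (
            x2[None, :, None]
            + (Q * Q).sum(axis=2)[:, None, :]
            - 2.0 * (X @ Q.transpose(0, 2, 1))
        )
        best = max(best, float(np.exp(-sq * inv2s2).sum(axis=(1, 2)).max()))
    return best
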