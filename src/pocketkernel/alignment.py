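"""sup-CK: maximization of the convolution kernel over rigid motions.

The fixed-pose kernel is not invariant under rotation/translation of a
pocket, so the similarity used in practice is

    sup-CK(P1, P2) = max over (R, t) of K(P1, R·P2 + t),

a non-concave maximization over SE(3) with many local maxima.  We follow the
standard recipe for this problem: gradient ascent in the Euler-angle /
translation parameterization, restarted from a set of informed initial
poses — the translation matching the two geometric centers, and the rotation
superposing the principal axes of P2 onto those of P1 for all 2³ = 8 sign
assignments of the axes (principal directions are defined up to sign).  When
two axis lengths are close the axis correspondence itself is ambiguous, so
starts with those axes swapped are added; a few seeded random-rotation
starts guard against the remaining local maxima.

All starts are ascended simultaneously (vectorized over the start axis) with
a backtracking line search; each start's objective sequence is nondecreasing.
The Z-X-Z Euler chart loses a degree of freedom at theta in {0, pi}; starts
that converge on that locus are re-seeded once with a small seeded angular
perturbation and continued, keeping the re-seeded result only if it improves.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .kernel import KernelParams, ck_kernel, pair_weights
from .pocket import (
    Pocket,
    PrincipalFrame,
    RigidMotion,
    centroid,
    euler_from_matrix,
    euler_to_matrix,
    principal_frame,
)

__all__ = [
    "OptimizerConfig",
    "AlignmentResult",
    "kernel_gradient",
    "initial_motions",
    "sup_ck",
]

# Generators of z- and x-axis rotations: dRz(a)/da = Lz·Rz(a), likewise Lx.
_LZ = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
_LX = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


@dataclasses.dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the multi-start gradient ascent."""

    max_iterations: int = 500
    tol: float = 1e-7  # relative improvement stopping threshold
    initial_step: float = 0.1
    permit_axis_permutations: bool = True
    axis_close_fraction: float = 0.2  # axes "close" if lengths within 20%
    random_extra_starts: int = 4
    exploration_iterations: int = 30  # budget for every start before pruning
    refine_top: int = 2  # starts kept for full-budget refinement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.tol > 0:
            raise ValueError("tolerance must be positive")


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a sup-CK maximization.

    ``motion`` is the rigid motion applied to the *second* pocket; ``score``
    is the kernel value at that motion (the best over all starts).
    """

    score: float
    motion: RigidMotion
    n_starts: int
    iterations_per_start: np.ndarray
    converged: np.ndarray


# ---------------------------------------------------------------------------
# Batched objective and gradient over motion vectors (tx,ty,tz,phi,theta,psi)
# ---------------------------------------------------------------------------

def _batch_euler(angles: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-factor Z-X-Z rotation matrices for a batch of (phi, theta, psi)."""
    S = angles.shape[0]
    phi, theta, psi = angles[:, 0], angles[:, 1], angles[:, 2]
    Rzf = np.zeros((S, 3, 3))
    Rxt = np.zeros((S, 3, 3))
    Rzp = np.zeros((S, 3, 3))
    cf, sf = np.cos(phi), np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    Rzf[:, 0, 0], Rzf[:, 0, 1], Rzf[:, 1, 0], Rzf[:, 1, 1], Rzf[:, 2, 2] = (
        cf, -sf, sf, cf, 1.0,
    )
    Rxt[:, 0, 0], Rxt[:, 1, 1], Rxt[:, 1, 2], Rxt[:, 2, 1], Rxt[:, 2, 2] = (
        1.0, ct, -st, st, ct,
    )
    Rzp[:, 0, 0], Rzp[:, 0, 1], Rzp[:, 1, 0], Rzp[:, 1, 1], Rzp[:, 2, 2] = (
        cp, -sp, sp, cp, 1.0,
    )
    return Rzf, Rxt, Rzp


class _Objective:
    """K(P1, R·P2 + t) and its gradient, vectorized over a batch of motions.

    Squared distances use the Gram expansion ||x-q||² = ||x||² + ||q||² - 2x·q
    so neither value nor gradient ever materializes the (S, N1, N2, 3)
    displacement tensor: the P1-sum of E_ij·(x_i - q_j) needed by the
    gradient is EᵀX - colsum(E)·q.
    """

    def __init__(self, p1: Pocket, p2: Pocket, params: KernelParams) -> None:
        self.X = p1.coords
        self.Y = p2.coords
        self.W = pair_weights(p1, p2, params)
        self.x2 = (self.X * self.X).sum(axis=1)
        self.inv2s2 = 1.0 / (2.0 * params.sigma**2)
        self.inv_s2 = 1.0 / params.sigma**2

    def _weighted_gauss(self, M: np.ndarray, R: np.ndarray):
        Q = np.einsum("sab,jb->sja", R, self.Y) + M[:, None, :3]
        q2 = (Q * Q).sum(axis=2)  # (S, N2)
        cross = self.X @ Q.transpose(0, 2, 1)  # (S, N1, N2)
        sq = self.x2[None, :, None] + q2[:, None, :] - 2.0 * cross
        E = np.exp(-sq * self.inv2s2)
        if self.W is not None:
            E = E * self.W[None, :, :]
        return Q, E

    def value(self, M: np.ndarray) -> np.ndarray:
        Rzf, Rxt, Rzp = _batch_euler(M[:, 3:])
        _, E = self._weighted_gauss(M, Rzf @ Rxt @ Rzp)
        return E.sum(axis=(1, 2))

    def value_and_grad(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Rzf, Rxt, Rzp = _batch_euler(M[:, 3:])
        R = Rzf @ Rxt @ Rzp
        Q, E = self._weighted_gauss(M, R)
        f = E.sum(axis=(1, 2))
        colsum = E.sum(axis=1)  # (S, N2)
        Sj = E.transpose(0, 2, 1) @ self.X - colsum[:, :, None] * Q
        g = np.empty((M.shape[0], 6))
        g[:, :3] = Sj.sum(axis=1) * self.inv_s2
        dRs = (_LZ @ R, Rzf @ (_LX @ Rxt) @ Rzp, R @ _LZ)
        for k, dR in enumerate(dRs):
            V = np.einsum("sab,jb->sja", dR, self.Y)
            g[:, 3 + k] = np.einsum("sjc,sjc->s", Sj, V) * self.inv_s2
        return f, g


def kernel_gradient(
    p1: Pocket, p2: Pocket, params: KernelParams, m: RigidMotion
) -> np.ndarray:
    """Analytic gradient of K(P1, R·P2 + t) at motion m.

    Returns the 6-vector (d/dtx, d/dty, d/dtz, d/dphi, d/dtheta, d/dpsi).
    """
    obj = _Objective(p1, p2, params)
    _, g = obj.value_and_grad(m.as_vector()[None, :])
    return g[0]


# ---------------------------------------------------------------------------
# Initial poses
# ---------------------------------------------------------------------------

def _axis_permutations(
    f1: PrincipalFrame, f2: PrincipalFrame, close_fraction: float
) -> list[tuple[int, int, int]]:
    perms: list[tuple[int, int, int]] = [(0, 1, 2)]

    def close(lengths: np.ndarray, i: int, j: int) -> bool:
        big, small = max(lengths[i], lengths[j]), min(lengths[i], lengths[j])
        return big <= 0 or small >= (1.0 - close_fraction) * big

    if close(f1.semi_axis_lengths, 0, 1) or close(f2.semi_axis_lengths, 0, 1):
        perms.append((1, 0, 2))
    if close(f1.semi_axis_lengths, 1, 2) or close(f2.semi_axis_lengths, 1, 2):
        perms.append((0, 2, 1))
    return perms


def initial_motions(
    p1: Pocket,
    p2: Pocket,
    permit_axis_permutations: bool = True,
    axis_close_fraction: float = 0.2,
    seed: int = 0,
) -> list[RigidMotion]:
    """Principal-axis initial poses for the sup-CK ascent.

    The translation carries the geometric center of P2 onto that of P1; the
    rotations superpose the principal axes of P2 onto those of P1 under all
    2³ = 8 sign assignments.  Sign assignments with negative determinant are
    made proper by flipping the third axis, so all 8 orientation hypotheses
    are covered by proper rotations.  If axis lengths are close (and
    permitted), axis-swap variants are added.  Degenerate clouds fall back to
    a centroid-matching translation with the identity plus seeded random
    rotations.
    """
    c1, c2 = centroid(p1), centroid(p2)
    try:
        f1, f2 = principal_frame(p1), principal_frame(p2)
    except ValueError:
        rng = np.random.default_rng(seed)
        rots = [np.eye(3)] + [_random_rotation(rng) for _ in range(7)]
        return [RigidMotion.from_matrix(R, c1 - R @ c2) for R in rots]

    perms = (
        _axis_permutations(f1, f2, axis_close_fraction)
        if permit_axis_permutations
        else [(0, 1, 2)]
    )
    motions: list[RigidMotion] = []
    for perm in perms:
        A2 = f2.axes[:, perm]
        for s1 in (1.0, -1.0):
            for s2 in (1.0, -1.0):
                for s3 in (1.0, -1.0):
                    signs = np.array([s1, s2, s3])
                    if s1 * s2 * s3 * np.linalg.det(A2) * np.linalg.det(f1.axes) < 0:
                        signs[2] = -signs[2]  # restore det = +1
                    R = (f1.axes * signs) @ A2.T
                    motions.append(RigidMotion.from_matrix(R, c1 - R @ c2))
    return motions


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation on SO(3) via a random unit quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# Multi-start ascent
# ---------------------------------------------------------------------------

def _ascend(
    obj: _Objective, M: np.ndarray, cfg: OptimizerConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched gradient ascent with backtracking; monotone per start.

    Returns final motions, values, iteration counts and convergence flags.
    """
    S = M.shape[0]
    f = obj.value(M)
    step = np.full(S, cfg.initial_step)
    iters = np.zeros(S, dtype=int)
    converged = np.zeros(S, dtype=bool)
    active = np.ones(S, dtype=bool)
    Mprev = np.full_like(M, np.nan)
    Gprev = np.full_like(M, np.nan)
    tiny = 1e-300
    for _ in range(cfg.max_iterations):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        _, g = obj.value_and_grad(M[idx])
        # Barzilai–Borwein spectral step (backtracked below): tames the
        # zig-zag of plain gradient steps under anisotropic curvature
        dm = M[idx] - Mprev[idx]
        dg = g - Gprev[idx]
        denom = np.einsum("sk,sk->s", dg, dg)
        num = np.abs(np.einsum("sk,sk->s", dm, dg))
        ok = np.isfinite(denom) & (denom > tiny) & (num > tiny)
        step[idx[ok]] = np.clip(num[ok] / denom[ok], 1e-8, 1e3)
        Mprev[idx] = M[idx]
        Gprev[idx] = g
        trial = M[idx] + step[idx, None] * g
        ftrial = obj.value(trial)
        fail = ftrial <= f[idx]
        for _half in range(40):
            if not fail.any():
                break
            step[idx[fail]] *= 0.5
            trial[fail] = M[idx[fail]] + step[idx[fail], None] * g[fail]
            ftrial[fail] = obj.value(trial[fail])
            fail = ftrial <= f[idx]
        improved = ~fail
        rel = (ftrial - f[idx]) / np.maximum(np.abs(f[idx]), tiny)
        M[idx[improved]] = trial[improved]
        f[idx[improved]] = ftrial[improved]
        iters[idx] += 1
        done = rel < cfg.tol  # includes exhausted backtracking (rel <= 0)
        converged[idx[done]] = True
        active[idx[done]] = False
    return M, f, iters, converged


def sup_ck(
    p1: Pocket,
    p2: Pocket,
    params: KernelParams = KernelParams(),
    cfg: OptimizerConfig = OptimizerConfig(),
) -> AlignmentResult:
    """Maximize the convolution kernel over rigid motions of the second pocket.

    Deterministic given ``cfg.seed``.  If no start converges within the
    iteration budget the best iterate is still returned with its
    ``converged`` flag false.
    """
    rng = np.random.default_rng(cfg.seed)
    motions = initial_motions(
        p1,
        p2,
        permit_axis_permutations=cfg.permit_axis_permutations,
        axis_close_fraction=cfg.axis_close_fraction,
        seed=cfg.seed,
    )
    c1, c2 = centroid(p1), centroid(p2)
    for _ in range(cfg.random_extra_starts):
        R = _random_rotation(rng)
        motions.append(RigidMotion.from_matrix(R, c1 - R @ c2))

    M = np.stack([m.as_vector() for m in motions])
    # the 8 sign hypotheses collapse pairwise onto 4 proper rotations;
    # ascend each distinct pose only once
    M = np.unique(np.round(M, 12), axis=0)
    # avoid starting exactly on the Euler chart's gimbal locus
    on_gimbal = np.abs(np.sin(M[:, 4])) < 1e-9
    M[on_gimbal, 3:] += rng.uniform(-1e-3, 1e-3, size=(int(on_gimbal.sum()), 3))

    obj = _Objective(p1, p2, params)
    # phase 1: every start gets the exploration budget; phase 2: only the
    # most promising starts are refined to full convergence
    explore = dataclasses.replace(
        cfg, max_iterations=min(cfg.exploration_iterations, cfg.max_iterations)
    )
    M, f, iters, converged = _ascend(obj, M, explore)
    if cfg.max_iterations > explore.max_iterations:
        from scipy.optimize import minimize

        def neg(v: np.ndarray) -> tuple[float, np.ndarray]:
            fv, gv = obj.value_and_grad(v[None])
            return -fv[0], -gv[0]

        for i in np.argsort(-f)[: max(1, cfg.refine_top)]:
            if converged[i]:
                continue
            r = minimize(
                neg, M[i], jac=True, method="L-BFGS-B",
                options={
                    "maxiter": cfg.max_iterations - explore.max_iterations,
                    "ftol": cfg.tol,
                },
            )
            iters[i] += r.nit
            converged[i] = bool(r.success)
            if -r.fun > f[i]:  # quasi-Newton polish accepted only on improvement
                M[i], f[i] = r.x, -r.fun

    # one re-seed pass for starts that stopped on the gimbal locus
    stuck = converged & (np.abs(np.sin(M[:, 4])) < 1e-6)
    if stuck.any():
        M2 = M[stuck].copy()
        M2[:, 3:] += rng.normal(scale=1e-2, size=M2[:, 3:].shape)
        M2, f2, it2, _ = _ascend(obj, M2, cfg)
        better = f2 > f[stuck]
        sub = np.flatnonzero(stuck)[better]
        M[sub] = M2[better]
        f[sub] = f2[better]
        iters[sub] += it2[better]

    best = int(np.argmax(f))
    score = float(f[best])
    if params.normalize:
        raw = dataclasses.replace(params, normalize=False)
        score /= math.sqrt(ck_kernel(p1, p1, raw) * ck_kernel(p2, p2, raw))
    return AlignmentResult(
        score=score,
        motion=RigidMotion.from_vector(M[best]),
        n_starts=M.shape[0],
        iterations_per_start=iters,
        converged=converged,
    )
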