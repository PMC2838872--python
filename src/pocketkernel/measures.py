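"""Baseline and combined pocket similarity measures.

Alongside sup-CK itself this module implements the simple ellipsoid
baselines and the overlap-count similarity it is compared against:

* ``Vol`` — absolute difference of the principal-axis ellipsoid volumes
  (a dissimilarity, Å³);
* ``Princ-Axis`` — L1 distance between the descending-sorted ellipsoid
  semi-axis lengths (a dissimilarity, Å);
* ``sup-PI`` — Poisson index: the normalized count of one-to-one atom pairs
  within a distance tolerance (1 Å by default) after sup-CK superposition
  and a local refinement of the pose that maximizes the count;
* ``sup-CK-Vol`` — a linear combination of z-standardized sup-CK and Vol
  scores, with the combination weight learned like any other
  hyperparameter.

The Poisson-index normalization is pluggable; the default is the
union-style L / (#P1 + #P2 - L).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .alignment import AlignmentResult, OptimizerConfig, sup_ck
from .kernel import KernelParams
from .pocket import Pocket, RigidMotion, apply_motion, ellipsoid_volume, principal_frame

__all__ = [
    "MeasureSpec",
    "MEASURE_NAMES",
    "vol_score",
    "princ_axis_score",
    "count_overlaps",
    "optimal_count_overlaps",
    "sup_pi",
    "CombinationContext",
    "supck_vol_score",
    "pairwise_scores",
]

MEASURE_NAMES = (
    "sup-CK",
    "sup-CK_L",
    "Vol",
    "Princ-Axis",
    "sup-PI",
    "sup-CK-Vol",
    "sup-CK_L-Vol",
)
_DISSIMILARITIES = {"Vol", "Princ-Axis"}


@dataclasses.dataclass(frozen=True)
class MeasureSpec:
    """A named similarity measure plus its parameters.

    ``orientation`` is derived from the name: Vol and Princ-Axis are
    dissimilarities (smaller = more similar), everything else a similarity.
    """

    name: str
    params: KernelParams = KernelParams()
    weight: float = 1.0  # combination weight w for the -Vol variants
    overlap_tol: float = 1.0  # Å, sup-PI only

    def __post_init__(self) -> None:
        if self.name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.name!r}")
        if self.name in ("sup-CK_L", "sup-CK_L-Vol") and math.isinf(self.params.lam):
            raise ValueError(f"{self.name} requires a finite lambda")
        if self.weight < 0:
            raise ValueError("combination weight must be >= 0")

    @property
    def orientation(self) -> str:
        return "dissimilarity" if self.name in _DISSIMILARITIES else "similarity"


def vol_score(p1: Pocket, p2: Pocket) -> float:
    """|Vol(P1) - Vol(P2)|: absolute ellipsoid-volume difference (Å³)."""
    return abs(ellipsoid_volume(p1) - ellipsoid_volume(p2))


def princ_axis_score(p1: Pocket, p2: Pocket) -> float:
    """L1 distance between descending-sorted ellipsoid semi-axis lengths (Å)."""
    a = principal_frame(p1).semi_axis_lengths
    b = principal_frame(p2).semi_axis_lengths
    return float(np.abs(a - b).sum())


def count_overlaps(p1: Pocket, p2_moved: Pocket, tol: float = 1.0) -> int:
    """Greedy one-to-one count of atom pairs within ``tol`` Å.

    Pairs are matched greedily by ascending distance so no atom is used
    twice; ``p2_moved`` must already be superposed onto P1's frame.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    d = cdist(p1.coords, p2_moved.coords)
    ii, jj = np.nonzero(d <= tol)
    if ii.size == 0:
        return 0
    order = np.argsort(d[ii, jj], kind="stable")
    used1 = np.zeros(p1.n_atoms, dtype=bool)
    used2 = np.zeros(p2_moved.n_atoms, dtype=bool)
    count = 0
    for k in order:
        i, j = ii[k], jj[k]
        if not used1[i] and not used2[j]:
            used1[i] = used2[j] = True
            count += 1
    return count


def optimal_count_overlaps(p1: Pocket, p2_moved: Pocket, tol: float = 1.0) -> int:
    """Maximum one-to-one overlap count, via optimal assignment (test oracle)."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    within = cdist(p1.coords, p2_moved.coords) <= tol
    rows, cols = linear_sum_assignment(within.astype(float), maximize=True)
    return int(within[rows, cols].sum())


def union_normalizer(L: int, n1: int, n2: int) -> float:
    """Tanimoto-style Poisson-index normalization L / (#P1 + #P2 - L)."""
    return L / (n1 + n2 - L)


def min_normalizer(L: int, n1: int, n2: int) -> float:
    """Alternative normalization L / min(#P1, #P2)."""
    return L / min(n1, n2)


def _refine_overlaps(
    p1: Pocket,
    p2: Pocket,
    motion: RigidMotion,
    tol: float,
    max_moves: int = 100,
) -> tuple[RigidMotion, int]:
    """Coordinate-wise local search on the 6 pose parameters maximizing L.

    Steps of 0.2 Å / 2 degrees, halved twice; a move is accepted only if the
    overlap count strictly increases.
    """
    v = motion.as_vector()
    best = count_overlaps(p1, apply_motion(p2, motion), tol)
    moves = 0
    for scale in (1.0, 0.5, 0.25):
        steps = np.array([0.2, 0.2, 0.2, *(math.radians(2.0),) * 3]) * scale
        improved = True
        while improved and moves < max_moves:
            improved = False
            for k in range(6):
                for sign in (1.0, -1.0):
                    trial = v.copy()
                    trial[k] += sign * steps[k]
                    L = count_overlaps(
                        p1, apply_motion(p2, RigidMotion.from_vector(trial)), tol
                    )
                    moves += 1
                    if L > best:
                        best, v, improved = L, trial, True
                        break
                    if moves >= max_moves:
                        break
                if moves >= max_moves:
                    break
    return RigidMotion.from_vector(v), best


def sup_pi(
    p1: Pocket,
    p2: Pocket,
    params: KernelParams = KernelParams(),
    cfg: OptimizerConfig = OptimizerConfig(),
    tol: float = 1.0,
    normalizer: Callable[[int, int, int], float] = union_normalizer,
) -> float:
    """Poisson index after sup-CK superposition with overlap-count refinement.

    Returns the normalized number of one-to-one overlapping atoms in [0, 1]
    (1 exactly when every atom is matched and the pockets have equal size).
    """
    res: AlignmentResult = sup_ck(p1, p2, params, cfg)
    _, L = _refine_overlaps(p1, p2, res.motion, tol)
    return normalizer(L, p1.n_atoms, p2.n_atoms)


@dataclasses.dataclass(frozen=True)
class CombinationContext:
    """Training-set standardization statistics for the sup-CK-Vol combination."""

    supck_mean: float
    supck_sd: float
    vol_mean: float
    vol_sd: float

    @classmethod
    def fit(
        cls, supck_scores: Sequence[float], vol_scores: Sequence[float]
    ) -> "CombinationContext":
        s = np.asarray(supck_scores, dtype=float)
        v = np.asarray(vol_scores, dtype=float)
        return cls(
            supck_mean=float(s.mean()),
            supck_sd=float(s.std()) or 1.0,
            vol_mean=float(v.mean()),
            vol_sd=float(v.std()) or 1.0,
        )

    def combine(self, supck: float, vol: float, w: float) -> float:
        """z(sup-CK) - w·z(Vol); larger = more similar."""
        zs = (supck - self.supck_mean) / self.supck_sd
        zv = (vol - self.vol_mean) / self.vol_sd
        return zs - w * zv


def supck_vol_score(
    p1: Pocket,
    p2: Pocket,
    params: KernelParams = KernelParams(),
    w: float = 1.0,
    context: CombinationContext | None = None,
    cfg: OptimizerConfig = OptimizerConfig(),
) -> float:
    """Linear combination of standardized sup-CK and Vol scores.

    Requires a :class:`CombinationContext` fitted on training-set raw scores
    (the two raw scores live on incommensurate scales).
    """
    if context is None:
        raise ValueError("unfitted combination: a CombinationContext is required")
    return context.combine(sup_ck(p1, p2, params, cfg).score, vol_score(p1, p2), w)


def pairwise_scores(
    pockets: Sequence[Pocket],
    spec: MeasureSpec,
    cfg: OptimizerConfig = OptimizerConfig(),
) -> np.ndarray:
    """Symmetric N×N raw-score matrix for a measure over a pocket collection.

    For the combined sup-CK-Vol measures this returns the *sup-CK* component
    only; combination with Vol is done downstream with fold-specific
    standardization (see evaluation.double_cv_loo).
    """
    n = len(pockets)
    out = np.zeros((n, n))
    if spec.name in ("Vol", "Princ-Axis"):
        fn = vol_score if spec.name == "Vol" else princ_axis_score
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = fn(pockets[i], pockets[j])
        return out
    if spec.name == "sup-PI":
        for i in range(n):
            out[i, i] = 1.0
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = sup_pi(
                    pockets[i], pockets[j], spec.params, cfg, spec.overlap_tol
                )
        return out
    # sup-CK / sup-CK_L (also the kernel part of the -Vol combinations)
    from .kernel import ck_kernel

    for i in range(n):
        out[i, i] = ck_kernel(pockets[i], pockets[i], spec.params)
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = sup_ck(pockets[i], pockets[j], spec.params, cfg).score
    return out
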