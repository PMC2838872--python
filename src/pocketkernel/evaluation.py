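"""Ligand-prediction quality scores for pocket similarity measures.

Two complementary criteria are implemented.

*Per-pocket AUC*: for a query pocket, all other pockets are ranked by their
similarity to it and the ROC area is computed with pockets binding the same
ligand as positives.  An ideal measure ranks all same-ligand pockets first
(AUC 1.0); random ranking gives 0.5.  The overall score is the mean over
query pockets.  The AUC can be misleading for ligand prediction when pockets
binding one ligand form several well-separated clusters — ranking the far
cluster low hurts AUC even though nearest-neighbor prediction is unaffected.

*Classification error*: leave-one-out K-nearest-neighbor ligand prediction
under a double (nested) cross-validation in which the hyperparameters
(σ, λ, K, combination weight w) are selected per held-out pocket by an inner
leave-one-out on the remaining pockets, then used to predict the held-out
pocket.  With C balanced classes a random predictor has error 1 - 1/C
(0.9 for ten ligands).

Kernel PCA on the (indefinite) sup-CK similarity matrix is provided for
visualization: the double-centered matrix is eigendecomposed and only
components with positive eigenvalues are kept; the discarded negative
eigenvalue mass is reported.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .kernel import KernelParams
from .measures import CombinationContext, MeasureSpec, pairwise_scores
from .alignment import OptimizerConfig
from .pocket import Pocket

__all__ = [
    "SimilarityMatrix",
    "ParameterGrid",
    "CVResult",
    "KPCAResult",
    "pocket_auc",
    "mean_auc",
    "knn_predict",
    "double_cv_loo",
    "kernel_pca",
]


@dataclasses.dataclass(frozen=True)
class SimilarityMatrix:
    """Square pairwise score table with per-pocket ligand-class annotations."""

    scores: np.ndarray
    ids: tuple[str, ...]
    classes: tuple[str, ...]
    orientation: str = "similarity"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        n = s.shape[0]
        if s.ndim != 2 or s.shape[1] != n:
            raise ValueError("scores must be square")
        if len(self.ids) != n or len(self.classes) != n:
            raise ValueError("ids/classes must match the matrix size")
        scale = max(np.abs(s).max(), 1e-30)
        if np.abs(s - s.T).max() > 1e-6 * scale:
            raise ValueError("matrix not symmetric within tolerance")
        if self.orientation not in ("similarity", "dissimilarity"):
            raise ValueError("orientation must be similarity|dissimilarity")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def oriented(self) -> np.ndarray:
        """Scores with larger-is-more-similar orientation."""
        return self.scores if self.orientation == "similarity" else -self.scores

    @classmethod
    def from_pockets(
        cls,
        pockets: Sequence[Pocket],
        spec: MeasureSpec,
        cfg: OptimizerConfig = OptimizerConfig(),
    ) -> "SimilarityMatrix":
        scores = pairwise_scores(pockets, spec, cfg)
        return cls(
            scores=scores,
            ids=tuple(p.id for p in pockets),
            classes=tuple(p.ligand_class or "?" for p in pockets),
            orientation=spec.orientation,
        )


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """Hyperparameter candidates explored by the double cross-validation.

    Defaults follow the values that work well in practice: σ around 1 for
    the purely geometric kernel (2–4 when charges are used), λ around 0.25,
    K between 3 and 5.  The extraction radius R is fixed at pocket-extraction
    time and not re-optimized here.
    """

    sigmas: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    lams: tuple[float, ...] = (0.125, 0.25, 0.5, math.inf)
    ks: tuple[int, ...] = (1, 3, 5)
    ws: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)

    def points(self, measure: str) -> list[dict]:
        """Grid points for a measure, in declared order (ties go to the first)."""
        if measure in ("Vol", "Princ-Axis"):
            return [{"k": k} for k in self.ks]
        lams = self.lams if measure in ("sup-CK_L", "sup-CK_L-Vol") else (math.inf,)
        ws = self.ws if measure.endswith("-Vol") else (None,)
        out = []
        for s, l, w, k in itertools.product(self.sigmas, lams, ws, self.ks):
            pt = {"sigma": s, "lam": l, "k": k}
            if w is not None:
                pt["w"] = w
            out.append(pt)
        return out


@dataclasses.dataclass(frozen=True)
class CVResult:
    """Outcome of the leave-one-out double cross-validation."""

    predictions: tuple[str, ...]
    classification_error: float
    chosen_params: tuple[dict, ...]


def pocket_auc(sm: SimilarityMatrix, i: int) -> float:
    """ROC AUC of ranking all other pockets by similarity to pocket i.

    Positives are the pockets binding the same ligand; ties between a
    positive and a negative score get 0.5 credit (Mann-Whitney convention).
    """
    mask = np.arange(sm.n) != i
    y = np.array([c == sm.classes[i] for c in sm.classes])[mask]
    if y.all() or not y.any():
        raise ValueError(
            f"pocket {i}: AUC undefined without both same- and different-class pockets"
        )
    return float(roc_auc_score(y, sm.oriented()[i, mask]))


def mean_auc(sm: SimilarityMatrix) -> tuple[float, np.ndarray]:
    """Mean per-pocket AUC and the per-pocket vector (NaN where undefined)."""
    per = np.full(sm.n, np.nan)
    for i in range(sm.n):
        try:
            per[i] = pocket_auc(sm, i)
        except ValueError:
            warnings.warn(
                f"pocket {sm.ids[i]}: single-member class, excluded from mean AUC"
            )
    if np.isnan(per).all():
        raise ValueError("no evaluable pockets")
    return float(np.nanmean(per)), per


def _knn_vote(
    oriented: np.ndarray,
    classes: Sequence[str],
    candidates: np.ndarray,
    target: int,
    k: int,
) -> str:
    """Majority vote among the k most similar candidates to ``target``.

    Ties are broken by the larger summed similarity of each tied class's
    neighbors, then by lexicographic class order.
    """
    scores = oriented[target, candidates]
    k = min(k, scores.size)
    top = candidates[np.argsort(-scores, kind="stable")[:k]]
    votes: dict[str, int] = {}
    sums: dict[str, float] = {}
    for j in top:
        c = classes[j]
        votes[c] = votes.get(c, 0) + 1
        sums[c] = sums.get(c, 0.0) + oriented[target, j]
    return min(votes, key=lambda c: (-votes[c], -sums[c], c))


def knn_predict(sm: SimilarityMatrix, i: int, k: int) -> str:
    """Predict pocket i's ligand from its K most similar other pockets."""
    if k > sm.n - 1:
        raise ValueError("K must be at most N-1")
    candidates = np.flatnonzero(np.arange(sm.n) != i)
    return _knn_vote(sm.oriented(), sm.classes, candidates, i, k)


def _oriented_matrices(
    pockets: Sequence[Pocket],
    measure: MeasureSpec,
    grid: ParameterGrid,
    cfg: OptimizerConfig,
    score_cache: dict | None = None,
) -> tuple[dict, np.ndarray | None]:
    """Cache raw score matrices per (σ, λ); the score between two training
    pockets does not depend on the held-out pocket, so each matrix is
    computed once and sliced per fold (an identity, not an approximation).
    ``score_cache`` may supply already-computed matrices under (σ, λ) keys
    ("vol" for the volume matrix)."""
    cache: dict = dict(score_cache or {})
    volmat = cache.pop("vol", None)
    name = measure.name
    if name in ("Vol", "Princ-Axis"):
        if None not in cache:
            cache[None] = pairwise_scores(pockets, measure, cfg)
        return cache, None
    if name.endswith("-Vol") and volmat is None:
        volmat = pairwise_scores(pockets, MeasureSpec("Vol"), cfg)
    for pt in grid.points(name):
        key = (pt["sigma"], pt["lam"])
        if key not in cache:
            params = KernelParams(sigma=pt["sigma"], lam=pt["lam"])
            # λ = ∞ in a labeled grid degrades gracefully to the unlabeled kernel
            kernel_name = (
                "sup-CK_L"
                if name.startswith("sup-CK_L") and math.isfinite(pt["lam"])
                else "sup-CK"
            )
            cache[key] = pairwise_scores(
                pockets, dataclasses.replace(measure, name=kernel_name, params=params), cfg
            )
    return cache, volmat


def double_cv_loo(
    pockets: Sequence[Pocket],
    measure: MeasureSpec,
    grid: ParameterGrid = ParameterGrid(),
    cfg: OptimizerConfig = OptimizerConfig(),
    score_cache: dict | None = None,
) -> CVResult:
    """Leave-one-out double cross-validation classification error.

    Each pocket is held out in turn; an inner leave-one-out over the
    remaining pockets scores every grid point, the point with the highest
    inner accuracy (first in declared order on ties) is selected, and the
    held-out pocket is predicted with it.
    """
    n = len(pockets)
    if n < 3:
        raise ValueError("need at least 3 pockets")
    classes = [p.ligand_class or "?" for p in pockets]
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    bad = sorted(c for c, m in counts.items() if m < 2)
    if bad:
        raise ValueError(f"classes with fewer than 2 pockets: {', '.join(bad)}")

    points = grid.points(measure.name)
    if not points:
        raise ValueError("empty parameter grid")
    cache, volmat = _oriented_matrices(pockets, measure, grid, cfg, score_cache)
    sign = -1.0 if measure.orientation == "dissimilarity" else 1.0

    def oriented_for(pt: dict, train: np.ndarray) -> np.ndarray:
        key = None if measure.name in ("Vol", "Princ-Axis") else (pt["sigma"], pt["lam"])
        raw = cache[key]
        if volmat is None:
            return sign * raw
        off = ~np.eye(len(train), dtype=bool)
        ctx = CombinationContext.fit(
            raw[np.ix_(train, train)][off], volmat[np.ix_(train, train)][off]
        )
        zs = (raw - ctx.supck_mean) / ctx.supck_sd
        zv = (volmat - ctx.vol_mean) / ctx.vol_sd
        return zs - pt["w"] * zv

    predictions: list[str] = []
    chosen: list[dict] = []
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        best_pt, best_acc = None, -1.0
        for pt in points:
            om = oriented_for(pt, train)
            hits = 0
            for j in train:
                inner = train[train != j]
                if _knn_vote(om, classes, inner, j, pt["k"]) == classes[j]:
                    hits += 1
            acc = hits / train.size
            if acc > best_acc:
                best_pt, best_acc = pt, acc
        om = oriented_for(best_pt, train)
        predictions.append(_knn_vote(om, classes, train, i, best_pt["k"]))
        chosen.append(dict(best_pt))

    err = float(np.mean([p != c for p, c in zip(predictions, classes)]))
    return CVResult(
        predictions=tuple(predictions),
        classification_error=err,
        chosen_params=tuple(chosen),
    )


@dataclasses.dataclass(frozen=True)
class KPCAResult:
    """Kernel PCA projection of a similarity matrix."""

    coords: np.ndarray  # (N, n_components), scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # kept (positive) eigenvalues, descending
    dropped_negative_mass: float  # |negative eigenvalues| / total |eigenvalues|


def kernel_pca(sm: SimilarityMatrix, n_components: int = 2) -> KPCAResult:
    """Project pockets onto the leading positive components of the matrix.

    The similarity matrix is double-centered and eigendecomposed; only the
    ``n_components`` largest *positive* eigenvalues are kept (sup-CK is not
    positive definite, so negative directions can occur and are dropped).
    """
    K = sm.scores
    n = K.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    evals, evecs = np.linalg.eigh(J @ K @ J)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12 * max(abs(evals[0]), 1.0)
    if not pos.any():
        raise ValueError("no positive eigenvalues")
    keep = min(n_components, int(pos.sum()))
    lam = evals[:keep]
    coords = evecs[:, :keep] * np.sqrt(lam)
    total = np.abs(evals).sum()
    neg_mass = float(np.abs(evals[evals < 0]).sum() / total) if total > 0 else 0.0
    return KPCAResult(coords=coords, eigenvalues=lam, dropped_negative_mass=neg_mass)
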