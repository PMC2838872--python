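import math

import numpy as np
import pytest

from pocketkernel import (
    GeneratorConfig,
    KernelParams,
    MeasureSpec,
    ParameterGrid,
    SimilarityMatrix,
    double_cv_loo,
    kernel_pca,
    knn_predict,
    make_benchmark,
    mean_auc,
    pocket_auc,
)


def sm_from(scores, classes, orientation="similarity"):
    n = len(classes)
    return SimilarityMatrix(
        scores=np.asarray(scores, float),
        ids=tuple(f"p{i}" for i in range(n)),
        classes=tuple(classes),
        orientation=orientation,
    )


class TestSimilarityMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            sm_from([[1, 2], [3, 1]], ["A", "B"])

    def test_oriented_flips_dissimilarity(self):
        sm = sm_from([[0, 2], [2, 0]], ["A", "B"], orientation="dissimilarity")
        assert sm.oriented()[0, 1] == -2


class TestPocketAuc:
    def test_perfect_ranking_gives_one(self):
        # same-class pockets rank above all others for every query
        classes = ["A", "A", "A", "B", "B", "B"]
        scores = np.array([[10 if a == b else 1 for b in classes] for a in classes], float)
        sm = sm_from(scores, classes)
        assert pocket_auc(sm, 0) == 1.0
        assert mean_auc(sm)[0] == 1.0

    def test_two_positives_at_ranks_one_and_three(self):
        # query 0; others ranked: pos, neg, pos, neg -> 3 of 4 pairs concordant
        classes = ["A", "A", "B", "A", "B"]
        row = [0.0, 4.0, 3.0, 2.0, 1.0]
        scores = np.zeros((5, 5))
        scores[0, :] = row
        scores[:, 0] = row
        assert pocket_auc(sm_from(scores, classes), 0) == pytest.approx(0.75)

    def test_random_scores_average_half(self, rng):
        classes = ["A"] * 5 + ["B"] * 5
        aucs = []
        for _ in range(300):
            x = rng.normal(size=(10, 10))
            sm = sm_from((x + x.T) / 2, classes)
            aucs.append(pocket_auc(sm, 0))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        classes = ["A", "A", "B", "B", "A"]
        x = rng.normal(size=(5, 5))
        s = (x + x.T) / 2
        a0 = [pocket_auc(sm_from(s, classes), i) for i in range(5)]
        a1 = [pocket_auc(sm_from(np.exp(s), classes), i) for i in range(5)]
        assert a0 == a1

    def test_dissimilarity_orientation(self):
        classes = ["A", "A", "B"]
        d = np.array([[0.0, 1.0, 9.0], [1.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        sm = sm_from(d, classes, orientation="dissimilarity")
        assert pocket_auc(sm, 0) == 1.0

    def test_single_member_class_excluded_with_warning(self):
        classes = ["A", "A", "B"]
        s = np.ones((3, 3))
        sm = sm_from(s, classes)
        with pytest.warns(UserWarning, match="single-member"):
            mean, per = mean_auc(sm)
        assert np.isnan(per[2]) and not np.isnan(per[0])

    def test_all_singletons_error(self):
        sm = sm_from(np.eye(3), ["A", "B", "C"])
        with pytest.raises(ValueError, match="no evaluable pockets"):
            mean_auc(sm)


class TestKnnPredict:
    def test_hand_built_matrix(self):
        classes = ["A", "A", "B", "B", "B"]
        s = np.array(
            [
                [9, 5, 4, 1, 1],
                [5, 9, 1, 1, 1],
                [4, 1, 9, 3, 2],
                [1, 1, 3, 9, 2],
                [1, 1, 2, 2, 9],
            ],
            float,
        )
        sm = sm_from(s, classes)
        assert knn_predict(sm, 0, 1) == "A"  # nearest is p1 (A)
        assert knn_predict(sm, 0, 3) == "B"  # neighbors p1(A,5), p2(B,4), p3(B,1)
        assert knn_predict(sm, 1, 1) == "A"
        assert knn_predict(sm, 4, 3) == "B"

    def test_majority_vote(self):
        classes = ["X", "A", "A", "B"]
        s = np.array(
            [[9, 5, 4, 6], [5, 9, 0, 0], [4, 0, 9, 0], [6, 0, 0, 9]], float
        )
        sm = sm_from(s, classes)
        assert knn_predict(sm, 0, 3) == "A"  # A beats B 2:1 despite B nearer

    def test_never_uses_own_diagonal(self):
        classes = ["A", "B", "B"]
        s = np.array([[100, 1, 2], [1, 100, 3], [2, 3, 100]], float)
        sm = sm_from(s, classes)
        assert knn_predict(sm, 0, 1) == "B"

    def test_k_bounds(self):
        sm = sm_from(np.eye(3), ["A", "A", "B"])
        with pytest.raises(ValueError):
            knn_predict(sm, 0, 3)


@pytest.fixture(scope="module")
def small_bench():
    cfg = GeneratorConfig(
        n_classes=3, pockets_per_class=4, atoms_per_template=(12, 20), seed=7
    )
    return make_benchmark(cfg)


class TestDoubleCv:
    def test_perfectly_separated_data_zero_error(self, small_bench):
        grid = ParameterGrid(sigmas=(1.0,), lams=(math.inf,), ks=(1, 3))
        cv = double_cv_loo(list(small_bench.pockets), MeasureSpec("sup-CK"), grid)
        assert cv.classification_error == 0.0

    def test_single_grid_point_reduces_to_plain_loo(self, small_bench):
        pockets = list(small_bench.pockets)
        grid = ParameterGrid(sigmas=(1.0,), lams=(math.inf,), ks=(3,))
        cv = double_cv_loo(pockets, MeasureSpec("sup-CK"), grid)
        sm = SimilarityMatrix.from_pockets(pockets, MeasureSpec("sup-CK"))
        plain = [knn_predict(sm, i, 3) for i in range(sm.n)]
        assert list(cv.predictions) == plain

    def test_planted_sigma_is_selected(self, small_bench):
        # a huge sigma makes every pair score ~N1*N2, destroying the signal;
        # the inner CV should therefore pick the informative sigma
        pockets = list(small_bench.pockets)
        grid = ParameterGrid(sigmas=(1.0, 1e4), lams=(math.inf,), ks=(3,))
        cv = double_cv_loo(pockets, MeasureSpec("sup-CK"), grid)
        picked = [p["sigma"] for p in cv.chosen_params]
        assert sum(s == 1.0 for s in picked) >= 10  # >= 10 of 12 outer folds

    def test_degenerate_classes_rejected(self, small_bench):
        pockets = list(small_bench.pockets)[:5]  # class 2 has a single member
        with pytest.raises(ValueError, match="fewer than 2"):
            double_cv_loo(pockets, MeasureSpec("sup-CK"), ParameterGrid())

    def test_random_labels_near_chance(self, rng):
        # label-free scores: prediction cannot beat chance over many classes
        n, n_cls = 40, 10
        classes = [f"C{i % n_cls}" for i in range(n)]
        x = rng.normal(size=(n, n))
        sm = sm_from((x + x.T) / 2, classes)
        errs = np.mean(
            [knn_predict(sm, i, 3) != classes[i] for i in range(n)]
        )
        assert errs > 0.6  # chance error is 0.9


class TestKernelPca:
    def test_points_on_a_line(self):
        x = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        G = np.outer(x, x)
        sm = sm_from(G, ["A"] * 5)
        res = kernel_pca(sm, n_components=3)
        assert res.coords.shape[1] == 1  # a line has one positive direction
        order = np.argsort(res.coords[:, 0])
        assert list(order) == list(range(5)) or list(order) == list(range(4, -1, -1))

    def test_reconstructs_known_2d_points(self, rng):
        pts = rng.normal(size=(8, 2))
        pts -= pts.mean(axis=0)
        G = pts @ pts.T
        res = kernel_pca(sm_from(G, ["A"] * 8), n_components=2)
        # projections match the points up to an orthogonal transform
        U, _, Vt = np.linalg.svd(res.coords.T @ pts)
        aligned = res.coords @ (U @ Vt)
        assert np.abs(aligned - pts).max() < 1e-8

    def test_negative_directions_dropped_and_reported(self):
        Q = np.linalg.qr(np.arange(16.0).reshape(4, 4) + np.eye(4))[0]
        K = Q @ np.diag([2.0, 1.0, 0.5, -0.5]) @ Q.T
        # double-centering changes eigenvalues; check via an uncentered Gram
        sm = sm_from((K + K.T) / 2, ["A"] * 4)
        res = kernel_pca(sm, n_components=4)
        assert (res.eigenvalues > 0).all()
        assert res.dropped_negative_mass >= 0.0

    def test_no_positive_eigenvalues(self):
        sm = sm_from(-np.eye(3) + 0.0, ["A"] * 3)
        with pytest.raises(ValueError, match="no positive"):
            kernel_pca(sm, 2)
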