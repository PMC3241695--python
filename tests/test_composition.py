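import dataclasses

import numpy as np
import pytest
from scipy.stats import chi2

from dicistro import composition_nca as nca
from dicistro.errors import (
    DataError,
    DimensionError,
    InsufficientSequenceError,
    LabelError,
    UndefinedRatioError,
)


def brute_profile(seq):
    """Dictionary-based counting oracle, independent of the numpy path."""
    bases = "ACGT"
    mono = {b: 0 for b in bases}
    for ch in seq:
        if ch in mono:
            mono[ch] += 1
    n_mono = sum(mono.values())
    dinuc = {a + b: 0 for a in bases for b in bases}
    n_di = 0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair[0] in bases and pair[1] in bases:
            dinuc[pair] += 1
            n_di += 1
    fm = np.array([mono[b] / n_mono for b in bases])
    fd = np.array([dinuc[a + b] / n_di for a in bases for b in bases]).reshape(4, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = fd / np.outer(fm, fm)
    return fm, fd, oe


class TestCompositionProfile:
    def test_homopolymer(self):
        p = nca.composition_profile("AAAA")
        assert p.mono[0] == 1.0
        assert p.dinuc[0, 0] == 1.0
        assert p.oe[0, 0] == 1.0

    def test_alternating_hand_count(self):
        # windows AC,CA,AC,CA,AC: observed(AC)=3/5, expected 0.25 -> rho 2.4
        p = nca.composition_profile("ACACAC")
        assert p.mono[0] == p.mono[1] == 0.5
        assert p.dinuc[0, 1] == pytest.approx(0.6)
        assert p.oe[0, 1] == pytest.approx(2.4)

    def test_n_positions_excluded(self):
        p = nca.composition_profile("ANAC")
        assert p.n_mono == 3  # N not counted
        assert p.n_dinuc == 1  # only the AC window has two non-N bases

    def test_insufficient_sequence(self):
        with pytest.raises(InsufficientSequenceError):
            nca.composition_profile("NNNNN")

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            seq = "".join(
                rng.choice(list("ACGTN"), size=rng.integers(10, 400),
                           p=[0.24, 0.24, 0.24, 0.24, 0.04])
            )
            if sum(c in "ACGT" for c in seq) < 2:
                continue
            p = nca.composition_profile(seq)
            fm, fd, oe = brute_profile(seq)
            np.testing.assert_allclose(p.mono, fm, atol=1e-12)
            np.testing.assert_allclose(p.dinuc, fd, atol=1e-12)
            np.testing.assert_allclose(
                p.oe[p.oe_defined], oe[p.oe_defined], atol=1e-12
            )

    def test_iid_sequence_has_unit_ratios(self):
        from dicistro import synthetic_data as sd

        spec = sd.host_spec("iid", (0.3, 0.25, 0.2, 0.25), {})
        seq = sd.sample_sequence(sd.markov_from_profile(spec), 100_000, seed=5)
        p = nca.composition_profile(seq)
        assert np.abs(p.oe - 1.0).max() <= 0.05


class TestGcAu:
    def test_reported_base_composition(self):
        # 1000-nt sequence with exactly 26.6% A, 27.4% C, 20.3% G, 25.7% T
        seq = "A" * 266 + "C" * 274 + "G" * 203 + "T" * 257
        p = nca.composition_profile(seq)
        assert nca.gc_content(p) == 47.7
        assert nca.au_content(p) == 52.3

    def test_uniform(self):
        assert nca.gc_content(nca.composition_profile("ACGT" * 10)) == 50.0

    def test_conservation(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            p = nca.composition_profile(seq)
            assert nca.gc_content(p) + nca.au_content(p) == pytest.approx(100.0, abs=0.11)


class TestFeatures:
    def test_homopolymer_vector(self):
        v = nca.build_features(nca.composition_profile("AAAA"))
        expected = np.zeros(20)
        expected[0] = 1.0  # f(A)
        expected[4] = 1.0  # AA frequency
        np.testing.assert_allclose(v, expected)

    def test_frequency_vector_sums_to_two(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            v = nca.build_features(nca.composition_profile(seq))
            assert v.sum() == pytest.approx(2.0, abs=1e-9)

    def test_oe_mode_undefined_pairs_rejected(self):
        with pytest.raises(UndefinedRatioError) as exc:
            nca.build_features(nca.composition_profile("AAAA"), mode="oe")
        assert "CG" in exc.value.pairs

    def test_ordering_stable(self):
        seq = "ACGTTGCAACGT"
        v1 = nca.build_features(nca.composition_profile(seq))
        v2 = nca.build_features(nca.composition_profile(seq))
        np.testing.assert_array_equal(v1, v2)


def _random_problem(rng, n_per=15, p=6, classes=4, spread=4.0):
    X, y = [], []
    for c in range(classes):
        center = rng.normal(scale=spread, size=p)
        X.append(center + rng.normal(size=(n_per, p)))
        y += [f"c{c}"] * n_per
    return np.vstack(X), np.asarray(y)


class TestFitCda:
    def test_separable_two_class_geometry(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        y = ["a", "a", "b", "b"]
        model = nca.fit_cda(X, y)
        assert model.n_factors == 1
        direction = model.scalings[:, 0]
        assert abs(direction[1]) < 1e-6 * abs(direction[0])  # parallel to x-axis
        assert (nca.predict_labels(model, X) == y).all()

    def test_two_class_reduces_to_fisher_direction(self):
        rng = np.random.default_rng(41)
        X, y = _random_problem(rng, classes=2)
        model = nca.fit_cda(X, y, ridge=1e-10)
        m1 = X[y == "c0"].mean(axis=0)
        m2 = X[y == "c1"].mean(axis=0)
        W = sum(
            (X[y == c] - X[y == c].mean(axis=0)).T @ (X[y == c] - X[y == c].mean(axis=0))
            for c in ("c0", "c1")
        )
        fisher = np.linalg.solve(W, m1 - m2)
        v = model.scalings[:, 0]
        cos = abs(fisher @ v) / (np.linalg.norm(fisher) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_matches_dense_generalized_eigen_oracle(self):
        rng = np.random.default_rng(43)
        X, y = _random_problem(rng)
        ridge = 1e-6
        model = nca.fit_cda(X, y, ridge=ridge)
        # oracle: explicit scatter loops + dense non-symmetric eigensolve
        classes = sorted(set(y))
        means = {c: X[y == c].mean(axis=0) for c in classes}
        grand = X.mean(axis=0)
        p = X.shape[1]
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        for xi, yi in zip(X, y):
            d = xi - means[yi]
            W += np.outer(d, d)
        for c in classes:
            d = means[c] - grand
            B += (y == c).sum() * np.outer(d, d)
        Wr = W + ridge * np.trace(W) / p * np.eye(p)
        evals, evecs = np.linalg.eig(np.linalg.solve(Wr, B))
        order = np.argsort(evals.real)[::-1][: len(classes) - 1]
        np.testing.assert_allclose(
            model.eigenvalues, evals.real[order], rtol=1e-8, atol=1e-8
        )
        for k, idx in enumerate(order):
            u = evecs[:, idx].real
            v = model.scalings[:, k]
            cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_eigenvalues_affine_invariant(self):
        rng = np.random.default_rng(47)
        X, y = _random_problem(rng)
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        b = rng.normal(size=6)
        e1 = nca.fit_cda(X, y, ridge=1e-12).eigenvalues
        e2 = nca.fit_cda(X @ A + b, y, ridge=1e-12).eigenvalues
        np.testing.assert_allclose(e1, e2, rtol=1e-5)

    def test_agrees_with_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(53)
        X, y = _random_problem(rng, n_per=30, spread=5.0)
        model = nca.fit_cda(X, y)
        lda = LinearDiscriminantAnalysis(
            solver="eigen", priors=np.full(4, 0.25)
        ).fit(X, y)
        agree = (nca.predict_labels(model, X) == lda.predict(X)).mean()
        assert agree == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(LabelError):
            nca.fit_cda(np.zeros((3, 2)), ["a", "a", "a"])

    def test_non_finite_rejected(self):
        X = np.zeros((6, 2))
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            nca.fit_cda(X, ["a", "a", "a", "b", "b", "b"])


class TestClassify:
    def test_centroid_classifies_to_own_class_with_zero_distance(self):
        rng = np.random.default_rng(59)
        X, y = _random_problem(rng)
        model = nca.fit_cda(X, y)
        for i, c in enumerate(model.classes):
            pred = nca.classify(model, model.class_means[i])
            assert pred.predicted == c
            assert pred.scores[c] == pytest.approx(0.0, abs=1e-9)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(61)
        X, y = _random_problem(rng)
        model = nca.fit_cda(X, y)
        with pytest.raises(DimensionError):
            nca.classify(model, np.zeros(7))

    def test_invariant_under_rigid_transform_of_canonical_space(self):
        rng = np.random.default_rng(67)
        X, y = _random_problem(rng)
        model = nca.fit_cda(X, y)
        k = model.n_factors
        Q, _ = np.linalg.qr(rng.normal(size=(k, k)))  # random rotation
        rotated = dataclasses.replace(
            model,
            scalings=model.scalings @ Q,
            centroids_canonical=model.centroids_canonical @ Q,
        )
        queries = rng.normal(size=(20, X.shape[1])) + X.mean(axis=0)
        np.testing.assert_array_equal(
            nca.predict_labels(model, queries), nca.predict_labels(rotated, queries)
        )


class TestConcordance:
    def test_separable_toy_is_perfect(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 10])
        X += np.random.default_rng(71).normal(scale=0.1, size=X.shape)
        y = ["a"] * 5 + ["b"] * 5
        assert nca.concordance(X, y) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(73)
        X = rng.normal(size=(80, 6))
        y = rng.permutation(["a", "b"] * 40)
        assert 0.25 <= nca.concordance(X, y, scheme="loo") <= 0.75

    def test_loo_not_above_resubstitution_on_average(self):
        rng = np.random.default_rng(79)
        diffs = []
        for _ in range(20):
            X, y = _random_problem(rng, n_per=10, p=4, classes=3, spread=1.0)
            diffs.append(
                nca.concordance(X, y) - nca.concordance(X, y, scheme="loo")
            )
        assert np.mean(diffs) >= 0.0


class TestConfidenceEllipse:
    def test_circle_is_round(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.c_[np.cos(theta), np.sin(theta)] * 3.0
        ell = nca.confidence_ellipse(pts)
        np.testing.assert_allclose(ell.center, [0, 0], atol=1e-12)
        assert ell.axes[0] == pytest.approx(ell.axes[1], rel=1e-9)

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(83)
        train = rng.multivariate_normal([1, -2], [[2.0, 0.8], [0.8, 1.0]], size=800)
        test = rng.multivariate_normal([1, -2], [[2.0, 0.8], [0.8, 1.0]], size=4000)
        ell = nca.confidence_ellipse(train, 0.95)
        # map points into the ellipse frame and test the quadratic form
        R = np.array(
            [[np.cos(ell.angle), np.sin(ell.angle)],
             [-np.sin(ell.angle), np.cos(ell.angle)]]
        )
        z = (test - ell.center) @ R.T
        inside = ((z / ell.axes) ** 2).sum(axis=1) <= 1.0
        assert inside.mean() == pytest.approx(0.95, abs=0.03)

    def test_levels_nest(self):
        rng = np.random.default_rng(89)
        pts = rng.normal(size=(100, 2))
        inner = nca.confidence_ellipse(pts, 0.5)
        outer = nca.confidence_ellipse(pts, 0.95)
        assert (inner.axes < outer.axes).all()

    def test_degenerate_covariance_flagged(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert nca.confidence_ellipse(pts).degenerate


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(97)
        X, y = _random_problem(rng)
        model = nca.fit_cda(X, y, feature_mode="frequencies")
        path = tmp_path / "model.json"
        nca.save_model(model, path)
        back = nca.load_model(path)
        assert back.classes == model.classes
        np.testing.assert_allclose(back.scalings, model.scalings)
        queries = rng.normal(size=(10, X.shape[1]))
        np.testing.assert_array_equal(
            nca.predict_labels(model, queries), nca.predict_labels(back, queries)
        )
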