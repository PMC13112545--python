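"""Attribution correctness: LIME surrogate recovery, kernel-SHAP
exactness against brute-force Shapley enumeration, and the axiomatic
properties (additivity, symmetry, null player)."""

import itertools
from math import factorial

import numpy as np
import pytest

from ecgxai.records import EcgRecord, Rhythm
from ecgxai.xai import ImportanceVector, SegmentPartition, lime_explain, shap_explain

FS = 300.0


def _record(n=1200, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    # fs low enough that even short synthetic vectors span >= 2 s
    fs = min(fs, n / 2.5)
    return EcgRecord("x", rng.normal(size=n), fs=fs)


def _segment_mean_model(weights, seg_len):
    """Probability linear (through a bounded affine map) in segment means."""
    weights = np.asarray(weights, dtype=float)

    def f(X):
        edges = np.arange(0, X.shape[1], seg_len)
        means = np.add.reduceat(X, edges, axis=1) / seg_len
        raw = means @ weights
        p1 = 0.5 + 0.04 * raw  # keep strictly inside (0, 1)
        p1 = np.clip(p1, 1e-6, 1 - 1e-6)
        return np.column_stack([1 - p1, p1])

    return f


def _brute_force_shapley(f, x, seg_len, bg):
    m = x.size // seg_len
    def value(subset):
        sig = bg.copy()
        for j in subset:
            sig[j * seg_len : (j + 1) * seg_len] = x[j * seg_len : (j + 1) * seg_len]
        return f(sig[None, :])[0, 1]
    phi = np.zeros(m)
    for j in range(m):
        others = [i for i in range(m) if i != j]
        for size in range(m):
            for s in itertools.combinations(others, size):
                w = factorial(size) * factorial(m - size - 1) / factorial(m)
                phi[j] += w * (value(s + (j,)) - value(s))
    return phi


class TestSegmentPartition:
    def test_partition_exhaustive_and_disjoint(self):
        part = SegmentPartition(n_samples=95, segment_length=30)
        assert part.n_segments == 4
        np.testing.assert_array_equal(part.bounds, [0, 30, 60, 90, 95])
        np.testing.assert_array_equal(part.lengths(), [30, 30, 30, 5])

    def test_spread_preserves_segment_mass(self):
        part = SegmentPartition(n_samples=100, segment_length=30)
        vals = np.array([1.0, -2.0, 0.5, 3.0])
        per_sample = part.spread(vals)
        np.testing.assert_allclose(part.segment_sums(per_sample), vals, atol=1e-12)


class TestLime:
    def test_constant_model_gives_zero_importance(self):
        record = _record()
        def constant(X):
            return np.tile([0.3, 0.7], (X.shape[0], 1))
        with pytest.warns(UserWarning, match="degenerate"):
            imp = lime_explain(constant, record, n_perturb=60, seed=0)
        np.testing.assert_allclose(imp.values, 0.0, atol=1e-8)

    def test_deterministic_under_seed(self):
        record = _record()
        model = _segment_mean_model(np.linspace(-1, 1, 40), 30)
        a = lime_explain(model, record, n_perturb=100, seed=4, segment_length=30)
        b = lime_explain(model, record, n_perturb=100, seed=4, segment_length=30)
        np.testing.assert_array_equal(a.values, b.values)

    def test_closed_form_wls_oracle(self):
        """The internal ridge solution matches an independently computed
        weighted least-squares fit on the same perturbation design."""
        record = _record(n=600, seed=3)
        model = _segment_mean_model(np.linspace(-2, 2, 20), 30)
        n_perturb, kernel_width, seed = 200, 0.25, 9
        imp = lime_explain(
            model, record, n_perturb=n_perturb, kernel_width=kernel_width,
            seed=seed, segment_length=30, link="identity",
        )
        part = SegmentPartition(record.n_samples, 30)
        seg_imp = part.segment_sums(imp.values)

        # independent reconstruction of the same design
        rng = np.random.default_rng(seed)
        masks = rng.random((n_perturb, part.n_segments)) < 0.5
        noise_sd = 0.2 * record.samples.std()
        noise = rng.normal(0.0, noise_sd, size=(n_perturb, record.n_samples))
        sample_mask = np.repeat(masks, part.lengths(), axis=1)
        probs = model(record.samples[None, :] + noise * sample_mask)[:, 1]
        w = np.exp(-(masks.mean(axis=1) ** 2) / kernel_width**2)
        z = np.column_stack([np.ones(n_perturb), masks.astype(float)])
        ridge = 1e-3 * np.eye(part.n_segments + 1)
        ridge[0, 0] = 0.0
        beta = np.linalg.solve(z.T @ (z * w[:, None]) + ridge, (z * w[:, None]).T @ probs)
        np.testing.assert_allclose(seg_imp, -beta[1:], atol=1e-10)

    def test_recovers_known_segment_importances(self):
        """A model whose response is linear in segment perturbation
        energies is recovered with r >= 0.99."""
        seg_len = 30
        record = _record(n=600, seed=5)
        reference = record.samples.copy()
        rng = np.random.default_rng(8)
        coeffs = rng.uniform(0.1, 2.0, size=20)  # importance of each segment

        def model(X):
            dev = (X - reference[None, :]) ** 2
            edges = np.arange(0, X.shape[1], seg_len)
            seg_energy = np.add.reduceat(dev, edges, axis=1) / seg_len
            p1 = np.clip(1.0 - 0.8 * seg_energy @ coeffs, 1e-6, 1 - 1e-6)
            return np.column_stack([1 - p1, p1])

        imp = lime_explain(
            model, record, n_perturb=2000, seed=2, segment_length=30, link="identity"
        )
        seg_imp = SegmentPartition(600, seg_len).segment_sums(imp.values)
        r = np.corrcoef(seg_imp, coeffs)[0, 1]
        assert r >= 0.99

    def test_too_few_perturbations_rejected(self):
        with pytest.raises(ValueError):
            lime_explain(lambda X: None, _record(), n_perturb=10)


class TestShap:
    def test_matches_brute_force_enumeration(self):
        """Exhaustive kernel SHAP equals the factorial-form Shapley value."""
        seg_len = 100
        record = _record(n=800, seed=1)
        rng = np.random.default_rng(2)
        weights = rng.normal(size=8)

        def f(X):
            edges = np.arange(0, X.shape[1], seg_len)
            means = np.add.reduceat(X, edges, axis=1) / seg_len
            s = np.tanh(means @ weights)
            return np.column_stack([(1 - s) / 2, (1 + s) / 2])

        imp = shap_explain(
            f, record, n_coalitions=300, seed=0, segment_length=seg_len,
            link="identity",
        )
        assert imp.meta["exhaustive"]
        phi_kernel = SegmentPartition(800, seg_len).segment_sums(imp.values)
        phi_exact = _brute_force_shapley(
            f, record.samples, seg_len, np.zeros(800)
        )
        np.testing.assert_allclose(phi_kernel, phi_exact, atol=1e-6)

    def test_local_accuracy(self):
        record = _record(n=900, seed=2)
        model = _segment_mean_model(np.linspace(-1, 1, 30), 30)
        imp = shap_explain(model, record, n_coalitions=500, seed=1, segment_length=30, link="identity")
        delta = imp.meta["f_x"] - imp.meta["f_background"]
        assert imp.values.sum() == pytest.approx(delta, abs=1e-3)

    def test_linear_model_exact_solution(self):
        """For f linear in segment means with zero background, the Shapley
        value of a segment is its own contribution c_j * mean_j."""
        seg_len = 50
        record = _record(n=500, seed=6)
        w = np.linspace(-1.5, 1.5, 10)
        model = _segment_mean_model(w, seg_len)
        imp = shap_explain(
            model, record, n_coalitions=1100, seed=0, segment_length=seg_len,
            link="identity",
        )
        phi = SegmentPartition(500, seg_len).segment_sums(imp.values)
        means = np.add.reduceat(record.samples, np.arange(0, 500, seg_len)) / seg_len
        np.testing.assert_allclose(phi, 0.04 * w * means, atol=1e-6)

    def test_symmetry_of_identical_segments(self):
        """Segments with identical content and identical marginal effect
        receive equal values."""
        seg_len = 40
        x = np.zeros(240)
        x[0:40] = 0.5
        x[40:80] = 0.5  # identical twin segments
        x[80:] = np.random.default_rng(3).normal(size=160)
        record = EcgRecord("sym", x, fs=80.0)
        model = _segment_mean_model(np.array([1.0, 1.0, 0.3, -0.4, 0.8, 0.0]), seg_len)
        imp = shap_explain(
            model, record, n_coalitions=200, seed=0, segment_length=seg_len,
            link="identity",
        )
        phi = SegmentPartition(240, seg_len).segment_sums(imp.values)
        assert phi[0] == pytest.approx(phi[1], abs=1e-6)

    def test_null_player_gets_nothing(self):
        seg_len = 40
        record = _record(n=240, seed=7)
        weights = np.array([1.0, -0.7, 0.0, 0.5, -0.2, 0.9])  # segment 2 ignored
        model = _segment_mean_model(weights, seg_len)
        imp = shap_explain(
            model, record, n_coalitions=200, seed=0, segment_length=seg_len,
            link="identity",
        )
        phi = SegmentPartition(240, seg_len).segment_sums(imp.values)
        assert abs(phi[2]) < 1e-3

    def test_insufficient_coalitions_rejected(self):
        with pytest.raises(ValueError):
            shap_explain(lambda X: None, _record(), n_coalitions=5)

    def test_deterministic_under_seed(self):
        record = _record(n=3000, seed=4)
        model = _segment_mean_model(np.linspace(-1, 1, 100), 30)
        a = shap_explain(model, record, n_coalitions=150, seed=5, segment_length=30)
        b = shap_explain(model, record, n_coalitions=150, seed=5, segment_length=30)
        np.testing.assert_array_equal(a.values, b.values)


class TestImportanceVector:
    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError):
            ImportanceVector(np.array([1.0, np.nan]), Rhythm.AFIB, "lime")
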