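"""Feature extraction, LORETA, evidence and BMA tests."""

import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from erpsource.headmodel import build_source_space
from erpsource.inverse import (BmaSourceModel, CompartmentModel, FeatureVector,
                               PeakSpec, WindowSpec, bma_solve,
                               enumerate_models, extract_feature,
                               graph_laplacian, log_evidence, loreta_solve,
                               _ModelOperator)
from erpsource.simulate import ErpSet


def make_erps(data, fs=250.0, baseline=200.0):
    data = np.asarray(data, float)
    names = tuple(f"ch{i}" for i in range(data.shape[2]))
    return ErpSet(data=data, fs=fs, baseline_ms=baseline, channel_names=names)


@pytest.fixture(scope="module")
def tiny_space():
    return build_source_space(150, 5, seed=9)


@pytest.fixture(scope="module")
def tiny_lf(head, montage, tiny_space):
    from erpsource.headmodel import compute_lead_field
    return compute_lead_field(head, montage, tiny_space)


class TestExtractFeature:
    def test_constant_signal_window_mean(self):
        data = np.full((2, 4, 3, 256), 5.0)
        out = extract_feature(make_erps(data), WindowSpec("N400", 330, 440))
        assert len(out) == 2 * 4
        for f in out:
            assert np.allclose(f.values, 5.0)

    def test_window_bounds_inclusive(self):
        """330-440 ms covers exactly the samples with latency in [330, 440]."""
        data = np.zeros((1, 4, 2, 256))
        erps = make_erps(data)
        t = erps.times_ms
        inside = (t >= 330) & (t <= 440)
        data[0, :, :, inside] = 1.0
        out = extract_feature(erps, WindowSpec("N400", 330, 440))
        assert all(np.allclose(f.values, 1.0) for f in out)
        # one sample outside the window dilutes the mean
        data[0, :, :, np.flatnonzero(inside)[0] - 1] = 1.0
        out2 = extract_feature(erps, WindowSpec("N400", 330, 440))
        assert all(np.allclose(f.values, 1.0) for f in out2)

    def test_planted_peak_latency_recovered(self):
        rng = np.random.default_rng(0)
        data = rng.normal(scale=0.01, size=(3, 4, 4, 256))
        erps = make_erps(data)
        t = erps.times_ms
        data -= 3.0 * np.exp(-0.5 * ((t - 170.0) / 15.0) ** 2)
        out = extract_feature(erps, PeakSpec("N170", -1, 130, 200,
                                             channel_group=("ch0", "ch1")))
        assert len(out) == 12
        for f in out:
            assert abs(f.peak_latency_ms - 170.0) <= 8.0

    def test_no_extremum_excludes_subject_with_warning(self):
        data = np.zeros((1, 4, 2, 256))
        erps = make_erps(data)
        t = erps.times_ms
        data[..., :] = t            # monotone: no interior maximum
        with pytest.warns(UserWarning, match="no interior"):
            out = extract_feature(
                erps, PeakSpec("P", 1, 130, 200, channel_group=("ch0",),
                               conditions=("intra_match",)))
        assert out == []


class TestGraphLaplacian:
    def test_isolated_generator_yields_zero_operator(self, tiny_space):
        # a subset with one generator has no internal edges
        lbl = tiny_space.compartment_labels[0]
        idx = tiny_space.generators_in(lbl)[:1]
        import scipy.sparse as sp
        sub = tiny_space.neighbor_graph[np.ix_(idx, idx)]
        from scipy.sparse.csgraph import laplacian
        L = laplacian(sub)
        assert L.shape == (1, 1)
        assert L.toarray()[0, 0] == 0.0

    def test_row_sums_zero_and_symmetric(self, tiny_space):
        L = graph_laplacian(tiny_space, [0, 1])
        arr = L.toarray()
        assert np.abs(arr.sum(axis=1)).max() < 1e-12
        assert np.allclose(arr, arr.T)

    def test_constant_field_in_nullspace(self, tiny_space):
        L = graph_laplacian(tiny_space, [2])
        ones = np.ones(L.shape[0])
        assert np.abs(L @ ones).max() < 1e-12

    def test_empty_subset_rejected(self, tiny_space):
        with pytest.raises(ValueError, match="no generators"):
            graph_laplacian(tiny_space, [99])


class TestEnumerateModels:
    def test_counts(self, tiny_space):
        space12 = build_source_space(300, 12, seed=4)
        space4 = build_source_space(100, 4, seed=4)
        assert len(enumerate_models(space4, 1)) == 4
        assert len(enumerate_models(space4, 2)) == 10
        assert len(enumerate_models(space12, 3)) == 298
        with pytest.raises(ValueError, match="cap"):
            enumerate_models(space12, 6, cap=100)

    def test_deterministic_order_and_support(self, tiny_space):
        models = enumerate_models(tiny_space, 2)
        assert models[0].compartments == (0,)
        for m in models:
            expect = tiny_space.generators_in(list(m.compartments))
            assert np.array_equal(m.generator_index, expect)


class TestLoreta:
    def test_zero_data_zero_solution(self, tiny_lf, tiny_space):
        model = enumerate_models(tiny_space, 1)[0]
        f = FeatureVector(np.zeros(60), 0, "intra_mismatch", "N400")
        j, resid = loreta_solve(f, tiny_lf, tiny_space, model, 1.0, 1.0)
        assert np.all(j == 0.0)
        assert np.all(resid == 0.0)

    def test_normal_equations_satisfied(self, tiny_lf, tiny_space):
        """(beta K'K + alpha P) j = beta K' v with P the jittered squared
        Laplacian prior, checked against explicit dense algebra."""
        model = enumerate_models(tiny_space, 2)[7]
        rng = np.random.default_rng(5)
        v = rng.normal(size=60)
        alpha, beta = 2.7, 0.9
        f = FeatureVector(v, 0, "intra_mismatch", "N400")
        j, _ = loreta_solve(f, tiny_lf, tiny_space, model, alpha, beta)
        K = tiny_lf.columns(model.generator_index)
        L = graph_laplacian(tiny_space, list(model.compartments)).toarray()
        P1 = L.T @ L
        P = np.kron(P1, np.eye(3))
        eps = 1e-8 * np.trace(P) / P.shape[0]
        P[np.diag_indices_from(P)] += eps
        lhs = (beta * K.T @ K + alpha * P) @ j
        rhs = beta * K.T @ v
        assert np.linalg.norm(lhs - rhs) < 1e-8 * np.linalg.norm(rhs)

    def test_noiseless_source_localized_within_graph_distance_2(
            self, tiny_lf, tiny_space):
        label = 3
        model = CompartmentModel(
            compartments=(label,),
            generator_index=tiny_space.generators_in(label))
        gi = model.generator_index
        g = gi[len(gi) // 2]
        jtrue = np.zeros(3 * tiny_space.n_generators)
        jtrue[3 * g: 3 * g + 3] = tiny_space.positions[g]
        v = tiny_lf.matrix @ jtrue
        f = FeatureVector(v, 0, "intra_mismatch", "N400")
        j, _ = loreta_solve(f, tiny_lf, tiny_space, model, 1e-3, 1e3)
        mags = np.linalg.norm(j.reshape(-1, 3), axis=1)
        peak = gi[np.argmax(mags)]
        D = shortest_path(tiny_space.neighbor_graph, indices=[g],
                          unweighted=True)[0]
        assert D[peak] <= 2


class TestEvidence:
    def test_duplicate_model_identical_evidence(self, tiny_lf, tiny_space):
        rng = np.random.default_rng(6)
        v = rng.normal(size=60)
        f = FeatureVector(v, 0, "intra_mismatch", "N400")
        m1 = enumerate_models(tiny_space, 1)[2]
        m2 = enumerate_models(tiny_space, 1)[2]
        assert log_evidence(f, tiny_lf, tiny_space, m1) == \
            log_evidence(f, tiny_lf, tiny_space, m2)

    def test_generating_compartment_wins(self, tiny_lf, tiny_space):
        """High-SNR data from compartment A: evidence(A) > evidence(B
        disjoint) in nearly all replicates."""
        models = enumerate_models(tiny_space, 1)
        opA = _ModelOperator(tiny_lf, tiny_space, models[0])
        opB = _ModelOperator(tiny_lf, tiny_space, models[1])
        rng = np.random.default_rng(7)
        giA = models[0].generator_index
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            g = rng.choice(giA)
            j = np.zeros(3 * tiny_space.n_generators)
            j[3 * g: 3 * g + 3] = rng.normal(size=3)
            v = tiny_lf.matrix @ j
            v += rng.normal(scale=0.01 * np.abs(v).max(), size=60)
            wins += opA.optimize(v)[2] > opB.optimize(v)[2]
        assert wins >= 0.95 * n_rep

    def test_occam_penalty_for_superfluous_compartment(self, tiny_lf,
                                                       tiny_space):
        """Appending an inactive compartment to the generating model lowers
        the evidence in the majority of high-SNR replicates."""
        single = enumerate_models(tiny_space, 1)[0]
        double = next(m for m in enumerate_models(tiny_space, 2)
                      if m.compartments == (0, 1))
        op1 = _ModelOperator(tiny_lf, tiny_space, single)
        op2 = _ModelOperator(tiny_lf, tiny_space, double)
        rng = np.random.default_rng(8)
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            g = rng.choice(single.generator_index)
            j = np.zeros(3 * tiny_space.n_generators)
            j[3 * g: 3 * g + 3] = rng.normal(size=3)
            v = tiny_lf.matrix @ j
            v += rng.normal(scale=0.01 * np.abs(v).max(), size=60)
            wins += op1.optimize(v)[2] > op2.optimize(v)[2]
        assert wins > n_rep / 2


class TestBma:
    def test_single_model_equals_loreta_solution(self, tiny_lf, tiny_space):
        rng = np.random.default_rng(9)
        v = rng.normal(size=60)
        f = FeatureVector(v, 0, "intra_mismatch", "N400")
        model = enumerate_models(tiny_space, 1)[1]
        ism, post = bma_solve(f, tiny_lf, tiny_space, [model])
        assert np.allclose(post.weights, [1.0])
        j, _ = loreta_solve(f, tiny_lf, tiny_space, model,
                            model.alpha, model.beta)
        mags = np.zeros(tiny_space.n_generators)
        mags[model.generator_index] = np.linalg.norm(j.reshape(-1, 3), axis=1)
        assert np.allclose(ism.magnitudes, mags, atol=1e-12)

    def test_weights_normalized(self, tiny_lf, tiny_space):
        rng = np.random.default_rng(10)
        f = FeatureVector(rng.normal(size=60), 0, "intra_mismatch", "N400")
        _, post = bma_solve(f, tiny_lf, tiny_space,
                            enumerate_models(tiny_space, 1))
        assert abs(post.weights.sum() - 1.0) < 1e-12
        assert np.all(post.weights >= 0)

    def test_matches_brute_force_oracle(self, tiny_lf, tiny_space):
        """<= 20-model space: BMA equals an independently coded
        evidence-weighted average of dense normal-equation solutions."""
        models = enumerate_models(tiny_space, 2)
        assert len(models) == 15
        rng = np.random.default_rng(11)
        g = tiny_space.generators_in(2)[0]
        j = np.zeros(3 * tiny_space.n_generators)
        j[3 * g: 3 * g + 3] = rng.normal(size=3)
        v = tiny_lf.matrix @ j + rng.normal(scale=0.05, size=60)
        f = FeatureVector(v, 0, "intra_mismatch", "N400")
        occam = 0.05
        ism, post = bma_solve(f, tiny_lf, tiny_space, models,
                              occam_window=occam)

        # --- independent oracle: dense algebra from the stored (alpha, beta)
        les = np.array([m.log_evidence for m in models])
        w = np.exp(les - les.max())
        w /= w.sum()
        w[w / w.max() < occam] = 0.0
        w /= w.sum()
        vectors = np.zeros((tiny_space.n_generators, 3))
        for m, wi in zip(models, w):
            if wi == 0.0:
                continue
            K = tiny_lf.columns(m.generator_index)
            L = graph_laplacian(tiny_space, list(m.compartments)).toarray()
            P = np.kron(L.T @ L, np.eye(3))
            eps = 1e-8 * np.trace(P) / P.shape[0]
            P[np.diag_indices_from(P)] += eps
            A = m.beta * K.T @ K + m.alpha * P
            b = m.beta * K.T @ v
            jm = np.linalg.solve(A, b)
            jm += np.linalg.solve(A, b - A @ jm)   # iterative refinement
            vectors[m.generator_index] += wi * jm.reshape(-1, 3)
        oracle = np.linalg.norm(vectors, axis=1)
        assert np.max(np.abs(ism.magnitudes - oracle)) < 1e-10

    def test_pruning_brackets(self, tiny_lf, tiny_space):
        """Occam window 0 keeps all models; window near 1 keeps only the
        best, whose map equals the LORETA solution of the argmax-evidence
        model."""
        models = enumerate_models(tiny_space, 1)
        rng = np.random.default_rng(12)
        g = tiny_space.generators_in(1)[3]
        j = np.zeros(3 * tiny_space.n_generators)
        j[3 * g: 3 * g + 3] = rng.normal(size=3)
        v = tiny_lf.matrix @ j + rng.normal(scale=0.02, size=60)
        f = FeatureVector(v, 0, "intra_mismatch", "N400")
        _, post_all = bma_solve(f, tiny_lf, tiny_space, models,
                                occam_window=0.0)
        assert len(post_all.models) == len(models)
        ism_best, post_best = bma_solve(f, tiny_lf, tiny_space, models,
                                        occam_window=1.0 - 1e-12)
        assert len(post_best.models) == 1
        best = max(models, key=lambda m: m.log_evidence)
        assert post_best.models[0].compartments == best.compartments
        jb, _ = loreta_solve(f, tiny_lf, tiny_space, best, best.alpha,
                             best.beta)
        mags = np.zeros(tiny_space.n_generators)
        mags[best.generator_index] = np.linalg.norm(jb.reshape(-1, 3), axis=1)
        assert np.allclose(ism_best.magnitudes, mags, atol=1e-12)

    def test_scale_covariance(self, tiny_lf, tiny_space):
        """Scaling the feature by c scales every magnitude by c (1e-6 rel)."""
        models = enumerate_models(tiny_space, 1)
        rng = np.random.default_rng(13)
        g = tiny_space.generators_in(0)[5]
        j = np.zeros(3 * tiny_space.n_generators)
        j[3 * g: 3 * g + 3] = rng.normal(size=3)
        v = tiny_lf.matrix @ j + rng.normal(scale=0.02, size=60)
        c = 7.3
        f1 = FeatureVector(v, 0, "intra_mismatch", "N400")
        f2 = FeatureVector(c * v, 0, "intra_mismatch", "N400")
        ism1, _ = bma_solve(f1, tiny_lf, tiny_space, models)
        models2 = enumerate_models(tiny_space, 1)
        ism2, _ = bma_solve(f2, tiny_lf, tiny_space, models2)
        nz = ism1.magnitudes > 1e-12 * ism1.magnitudes.max()
        rel = np.abs(ism2.magnitudes[nz] / ism1.magnitudes[nz] - c) / c
        assert rel.max() < 1e-6

    def test_source_recovery_on_paper_batch(self, paper_batch):
        """Grand-average N400 mismatch inversion attributes the largest
        summed magnitude to the planted compartment in >= 90% of seeds."""
        hits = sum(r["recovery_argmax"] == r["n400_intra_label"]
                   for r in paper_batch)
        assert hits >= 0.9 * len(paper_batch)


def test_bma_results_summary(tiny_lf, tiny_space):
    rng = np.random.default_rng(14)
    f = FeatureVector(rng.normal(size=60), 3, "intra_mismatch", "N400")
    res = BmaSourceModel(tiny_lf, tiny_space, max_size=1).fit(f)
    text = res.summary()
    assert "Occam window" in text and "N400" in text
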