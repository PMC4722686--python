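import numpy as np
import pytest

from hierpred import kernels as kn
from hierpred import ontology as onto
from hierpred import structpred as sp
from tests.conftest import random_dag

TERMS4 = ["t1", "t2", "t3", "t4"]


def consistent_random_labels(dag, n, seed):
    """Random true-path-consistent term sets on a DAG (below the root)."""
    rng = np.random.default_rng(seed)
    terms = sorted(dag.terms - {dag.root})
    labels = []
    for _ in range(n):
        k = int(rng.integers(1, 4))
        picked = {terms[int(j)] for j in rng.choice(len(terms), size=k)}
        full = set(picked)
        for t in picked:
            full |= set(dag.ancestors(t)) - {dag.root}
        labels.append(frozenset(full))
    return labels


def random_model(seed, n_train=6, n_terms=5, density=0.5, normalize_ky=False):
    """A StructuredModel with arbitrary alpha for oracle comparisons."""
    rng = np.random.default_rng(seed)
    term_order = [f"t{j}" for j in range(n_terms)]
    # distinct non-empty binary labels, capped by the size of the label space
    n_labels = min(n_train, 2**n_terms - 1)
    labels: set[tuple] = set()
    for _ in range(200):
        if len(labels) >= n_labels:
            break
        cand = tuple(int(b) for b in rng.integers(0, 2, size=n_terms))
        if any(cand):
            labels.add(cand)
    cat = sp.CandidateCatalog(term_order, np.array(sorted(labels), dtype=float))
    true_idx = rng.integers(0, len(cat), size=n_train)
    alpha = np.where(rng.random((n_train, len(cat))) < density, rng.random((n_train, len(cat))), 0.0)
    return sp.StructuredModel(
        train_genes=[f"g{i}" for i in range(n_train)],
        catalog=cat,
        alpha=alpha,
        true_idx=true_idx,
        normalize_ky=normalize_ky,
    )


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


class TestBuildCatalog:
    def test_dedup(self):
        labels = [{"t1"}, {"t1"}, {"t1", "t2"}]
        cat = sp.build_catalog(labels, TERMS4)
        assert len(cat) == 2

    def test_all_identical(self):
        cat = sp.build_catalog([{"t1", "t2"}] * 5, TERMS4)
        assert len(cat) == 1

    def test_set_dedup_oracle(self):
        dag = random_dag(20, seed=2)
        labels = consistent_random_labels(dag, 50, seed=2)
        term_order = sorted(dag.terms - {dag.root})
        cat = sp.build_catalog(labels, term_order)
        assert len(cat) == len({frozenset(l) for l in labels})

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sp.build_catalog([], TERMS4)

    def test_order_deterministic(self):
        labels = [{"t2"}, {"t1"}, {"t3", "t4"}]
        c1 = sp.build_catalog(labels, TERMS4)
        c2 = sp.build_catalog(list(reversed(labels)), TERMS4)
        np.testing.assert_array_equal(c1.labels, c2.labels)

    def test_duplicate_catalog_rejected(self):
        with pytest.raises(ValueError):
            sp.CandidateCatalog(TERMS4, np.array([[1, 0, 0, 0], [1, 0, 0, 0]]))


# ---------------------------------------------------------------------------
# compatibility
# ---------------------------------------------------------------------------


class TestCompatibility:
    def test_zero_alpha_gives_zero(self):
        m = random_model(0)
        m.alpha[:] = 0
        m = sp.StructuredModel(m.train_genes, m.catalog, m.alpha, m.true_idx, normalize_ky=False)
        kx = np.ones(len(m.train_genes))
        for row in m.catalog.labels:
            assert sp.compatibility(m, kx, row) == 0.0

    def test_single_support_pair_hand_check(self):
        cat = sp.CandidateCatalog(["a", "b"], np.array([[1.0, 0.0], [1.0, 1.0]]))
        alpha = np.array([[0.0, 0.7]])  # one training gene, mass on label 1
        m = sp.StructuredModel(["g0"], cat, alpha, np.array([0]), normalize_ky=False)
        kx = np.array([2.0])
        # f(x, y) = 0.7 * 2 * (K_Y(y_0, y) - K_Y(cat_1, y)); y_0 = [1,0]
        y = np.array([1.0, 0.0])
        assert sp.compatibility(m, kx, y) == pytest.approx(0.7 * 2 * (1.0 - 1.0))
        y = np.array([1.0, 1.0])
        assert sp.compatibility(m, kx, y) == pytest.approx(0.7 * 2 * (1.0 - 2.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_primal_dual_equivalence(self, seed):
        """Dual expansion equals explicit tensor-product primal weights."""
        rng = np.random.default_rng(seed + 100)
        n, dx, dy = 5, int(rng.integers(2, 7)), int(rng.integers(2, 6))
        m = random_model(seed, n_train=n, n_terms=dy, normalize_ky=False)
        X = rng.normal(size=(n, dx))
        Y_train = m.catalog.labels[m.true_idx]
        w = np.zeros(dx * dy)
        for i in range(n):
            for c in range(len(m.catalog)):
                if m.alpha[i, c]:
                    w += m.alpha[i, c] * (
                        np.outer(X[i], Y_train[i]).ravel()
                        - np.outer(X[i], m.catalog.labels[c]).ravel()
                    )
        x_query = rng.normal(size=dx)
        kx_col = X @ x_query
        for row in m.catalog.labels:
            primal = float(w @ np.outer(x_query, row).ravel())
            dual = sp.compatibility(m, kx_col, row)
            assert dual == pytest.approx(primal, abs=1e-8)

    def test_dimension_mismatch_errors(self):
        m = random_model(1)
        with pytest.raises(ValueError):
            m.compatibility(np.ones(len(m.train_genes) + 1), m.catalog.labels[0])
        with pytest.raises(ValueError):
            m.compatibility(np.ones(len(m.train_genes)), np.ones(99))

    def test_accepts_term_sets(self):
        m = random_model(2)
        kx = np.ones(len(m.train_genes))
        row = m.catalog.labels[0]
        terms = [t for t, b in zip(m.catalog.term_order, row) if b]
        assert m.compatibility(kx, frozenset(terms)) == pytest.approx(
            m.compatibility(kx, row)
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def audit_constraints(model, Kx_train, Y, epsilon, tol=1e-9):
    """Brute-force margin-constraint scan over the full catalog."""
    cat = model.catalog.labels
    Delta = (Y[:, None, :] != cat[None, :, :]).sum(axis=2)
    for i in range(len(Y)):
        scores = np.array(
            [model.compatibility(Kx_train[i], cat[c]) for c in range(len(cat))]
        )
        f_true = scores[model.true_idx[i]]
        xi = max(
            0.0,
            max(Delta[i, c] - (f_true - scores[c]) for c in model.working_sets[i]),
        )
        worst = (Delta[i] - (f_true - scores)).max()
        assert worst <= xi + epsilon + tol, f"gene {i}: {worst} > {xi} + {epsilon}"


class TestTrain:
    def test_single_gene_single_label(self):
        cat = sp.build_catalog([{"t1", "t2"}], TERMS4)
        m = sp.train(np.array([[1.0]]), [{"t1", "t2"}], cat)
        pred = m.predict(np.array([1.0]))
        np.testing.assert_array_equal(pred.label, cat.labels[0])
        assert sp.slacks(m, np.array([[1.0]]))[0] == pytest.approx(0.0)

    def test_two_orthogonal_genes_separable(self):
        labels = [{"t1"}, {"t2"}]
        cat = sp.build_catalog(labels, TERMS4)
        Kx = np.eye(2) * 4.0
        m = sp.train(Kx, labels, cat, C=10.0)
        Y = sp.label_matrix(labels, TERMS4)
        for i in range(2):
            scores = np.array([m.compatibility(Kx[i], c) for c in cat.labels])
            assert int(np.argmax(scores)) == m.true_idx[i]
        assert sp.slacks(m, Kx).max() <= 0.02
        audit_constraints(m, Kx, Y, epsilon=0.01)

    def test_forty_gene_separable_constraint_audit(self):
        rng = np.random.default_rng(17)
        dag = random_dag(15, seed=17)
        labels = consistent_random_labels(dag, 40, seed=17)
        term_order = sorted(dag.terms - {dag.root})
        cat = sp.build_catalog(labels, term_order)
        Y = sp.label_matrix(labels, term_order)
        # one-hot per distinct label -> orthogonal inputs, separable
        X = np.eye(len(cat))[[cat.index_of(y) for y in Y]]
        Kx = X @ X.T
        m = sp.train(Kx, Y, cat, C=100.0, epsilon=0.01)
        audit_constraints(m, Kx, Y, epsilon=0.01)

    def test_separable_exact_match_and_zero_slack(self):
        dag = random_dag(15, seed=23)
        labels = consistent_random_labels(dag, 40, seed=23)
        term_order = sorted(dag.terms - {dag.root})
        cat = sp.build_catalog(labels, term_order)
        Y = sp.label_matrix(labels, term_order)
        X = np.eye(len(cat))[[cat.index_of(y) for y in Y]]
        Kx = X @ X.T
        m = sp.train(Kx, Y, cat, C=100.0, epsilon=0.01)
        hits = sum((m.predict(Kx[i]).label == Y[i]).all() for i in range(len(Y)))
        assert hits == len(Y)
        assert sp.slacks(m, Kx).mean() < 0.5

    def test_bad_parameters(self):
        cat = sp.build_catalog([{"t1"}], TERMS4)
        with pytest.raises(ValueError):
            sp.train(np.eye(1), [{"t1"}], cat, C=0.0)
        with pytest.raises(ValueError):
            sp.train(np.eye(1), [{"t1"}], cat, epsilon=-1.0)

    def test_alpha_invariants(self):
        dag = random_dag(12, seed=31)
        labels = consistent_random_labels(dag, 15, seed=31)
        term_order = sorted(dag.terms - {dag.root})
        cat = sp.build_catalog(labels, term_order)
        rng = np.random.default_rng(31)
        X = rng.normal(size=(15, 6))
        Kx = kn.normalize_kernel(
            kn.KernelMatrix([f"g{i}" for i in range(15)], X @ X.T)
        ).values
        m = sp.train(Kx, labels, cat, C=2.0)
        assert (m.alpha >= 0).all()
        np.testing.assert_allclose(m.alpha.sum(axis=1), 2.0, atol=1e-9)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


class TestPredict:
    def test_catalog_of_one(self):
        cat = sp.build_catalog([{"t1"}], TERMS4)
        m = sp.train(np.eye(3), [{"t1"}] * 3, cat)
        for kx in (np.zeros(3), np.ones(3)):
            np.testing.assert_array_equal(m.predict(kx).label, cat.labels[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_argmax_matches_exhaustive_oracle(self, seed):
        m = random_model(seed, n_train=8, n_terms=5)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            kx = rng.normal(size=8)
            pred = m.predict(kx)
            scores = [m.compatibility(kx, row) for row in m.catalog.labels]
            assert pred.catalog_index == int(np.argmax(scores))

    def test_predictions_hierarchically_consistent(self):
        dag = random_dag(15, seed=41)
        labels = consistent_random_labels(dag, 20, seed=41)
        term_order = sorted(dag.terms - {dag.root})
        cat = sp.build_catalog(labels, term_order)
        rng = np.random.default_rng(41)
        X = rng.normal(size=(20, 5))
        m = sp.train(X @ X.T, labels, cat, C=1.0)
        terms = np.array(term_order)
        for _ in range(10):
            kx = X @ rng.normal(size=5)
            pred = m.predict(kx)
            label = set(terms[pred.label > 0])
            assert onto.is_consistent(label, dag)


# ---------------------------------------------------------------------------
# term confidence
# ---------------------------------------------------------------------------


def confidence_oracle(model, kx):
    """Brute-force contrastive per-term score via compatibility calls."""
    scores = np.array([model.compatibility(kx, row) for row in model.catalog.labels])
    out = np.empty(len(model.catalog.term_order))
    for j in range(len(out)):
        has = model.catalog.labels[:, j] > 0
        if not has.any():
            out[j] = -np.inf
            continue
        ref = scores[~has].max() if (~has).any() else scores.min()
        out[j] = scores[has].max() - ref
    return out


class TestTermConfidence:
    def test_absent_term_neg_inf(self):
        cat = sp.CandidateCatalog(TERMS4, np.array([[1.0, 0, 0, 0], [1.0, 1, 0, 0]]))
        m = sp.StructuredModel(["g0"], cat, np.zeros((1, 2)), np.array([0]))
        conf = m.term_confidence(np.ones(1))
        assert conf[2] == -np.inf and conf[3] == -np.inf

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        m = random_model(seed + 50, n_train=7, n_terms=5)
        rng = np.random.default_rng(seed)
        kx = rng.normal(size=7)
        np.testing.assert_allclose(
            m.term_confidence(kx), confidence_oracle(m, kx), atol=1e-10
        )

    def test_hierarchy_monotone(self):
        dag = random_dag(15, seed=55)
        labels = consistent_random_labels(dag, 25, seed=55)
        term_order = sorted(dag.terms - {dag.root})
        cat = sp.build_catalog(labels, term_order)
        rng = np.random.default_rng(55)
        X = rng.normal(size=(25, 6))
        m = sp.train(X @ X.T, labels, cat, C=1.0)
        idx = {t: j for j, t in enumerate(term_order)}
        for _ in range(10):
            conf = m.term_confidence(X @ rng.normal(size=6))
            for t in term_order:
                for p in dag.ancestors(t) - {dag.root}:
                    assert conf[idx[p]] >= conf[idx[t]] - 1e-9


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_model_round_trip(tmp_path):
    dag = random_dag(12, seed=61)
    labels = consistent_random_labels(dag, 12, seed=61)
    term_order = sorted(dag.terms - {dag.root})
    cat = sp.build_catalog(labels, term_order)
    rng = np.random.default_rng(61)
    X = rng.normal(size=(12, 5))
    m = sp.train(X @ X.T, labels, cat, C=3.0)
    path = tmp_path / "model.json"
    sp.save_model(str(path), m)
    back = sp.load_model(str(path))
    assert back.train_genes == m.train_genes
    assert back.catalog.term_order == m.catalog.term_order
    np.testing.assert_array_equal(back.catalog.labels, m.catalog.labels)
    np.testing.assert_allclose(back.alpha, m.alpha)
    kx = X @ rng.normal(size=5)
    np.testing.assert_allclose(back.catalog_scores(kx), m.catalog_scores(kx))
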