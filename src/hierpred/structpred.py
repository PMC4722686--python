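"""Structured SVM over a joint input-output product kernel.

The model scores a gene/label pair with a compatibility function expressed
in the dual:

    f(x, y) = sum over stored (i, c) pairs of
              alpha[i, c] * K_X(x_i, x) * (K_Y(y_i, y) - K_Y(cat_c, y))

Training is n-slack cutting-plane optimization of the margin-rescaling
objective with Hamming loss; loss-augmented inference is an exhaustive
scan over a finite candidate catalog (the distinct training label
vectors), which makes the cutting-plane procedure exact.  Prediction is
the argmax of f over the catalog, so every prediction is hierarchically
consistent by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass
class CandidateCatalog:
    """Deduplicated binary label vectors over a fixed term order."""

    term_order: list[str]
    labels: np.ndarray  # (n_labels, n_terms), 0/1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.ndim != 2 or self.labels.shape[1] != len(self.term_order):
            raise ValueError("catalog shape does not match term order")
        self._index = {tuple(row.astype(int)): c for c, row in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("catalog contains duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label_vec: np.ndarray) -> int:
        key = tuple(np.asarray(label_vec).astype(int))
        if key not in self._index:
            raise KeyError("label vector not in catalog")
        return self._index[key]

    def to_term_sets(self) -> list[frozenset[str]]:
        terms = np.array(self.term_order)
        return [frozenset(terms[row > 0]) for row in self.labels]


def label_matrix(term_sets: Sequence[Iterable[str]], term_order: Sequence[str]) -> np.ndarray:
    """Binary (genes x terms) matrix for term sets over a fixed term order."""
    index = {t: j for j, t in enumerate(term_order)}
    Y = np.zeros((len(term_sets), len(term_order)))
    for i, terms in enumerate(term_sets):
        for t in terms:
            if t in index:
                Y[i, index[t]] = 1.0
    return Y


def build_catalog(
    train_labels: Sequence[Iterable[str]], term_order: Sequence[str]
) -> CandidateCatalog:
    """Distinct training label vectors in lexicographic (bit-tuple) order."""
    if not len(train_labels):
        raise ValueError("cannot build a catalog from an empty training set")
    Y = label_matrix(train_labels, term_order)
    distinct = sorted({tuple(row.astype(int)) for row in Y})
    return CandidateCatalog(list(term_order), np.array(distinct, dtype=float))


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    norms = np.sqrt((M * M).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    return M / safe[:, None]


@dataclass
class StructuredModel:
    """Dual weights over (training gene, catalog label) pairs."""

    train_genes: list[str]
    catalog: CandidateCatalog
    alpha: np.ndarray  # (n_train, n_catalog), >= 0
    true_idx: np.ndarray  # catalog index of each training gene's label
    C: float = 1.0
    epsilon: float = 0.01
    normalize_ky: bool = True
    working_sets: list[set[int]] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.true_idx = np.asarray(self.true_idx, dtype=int)
        n, m = len(self.train_genes), len(self.catalog)
        if self.alpha.shape != (n, m):
            raise ValueError(f"alpha shape {self.alpha.shape} != ({n}, {m})")
        if (self.alpha < -1e-12).any():
            raise ValueError("alpha must be non-negative")
        cat = self.catalog.labels
        self._cat_n = _normalize_rows(cat) if self.normalize_ky else cat
        # training label rows are catalog rows picked out by true_idx
        self._Yn = self._cat_n[self.true_idx]
        self._KY_cc = self._cat_n @ self._cat_n.T
        self._KY_tc = self._Yn @ self._cat_n.T

    # -- scoring ---------------------------------------------------------

    def _label_vec(self, y: np.ndarray | Iterable[str]) -> np.ndarray:
        if isinstance(y, np.ndarray):
            v = np.asarray(y, dtype=float)
        else:
            v = label_matrix([y], self.catalog.term_order)[0]
        if v.shape != (len(self.catalog.term_order),):
            raise ValueError("label vector does not match the model's term order")
        return v

    def compatibility(self, kx_col: np.ndarray, y: np.ndarray | Iterable[str]) -> float:
        """f(x, y) for a query gene given its kernel column vs. train genes."""
        kx_col = np.asarray(kx_col, dtype=float)
        if kx_col.shape != (len(self.train_genes),):
            raise ValueError("kernel column length does not match training genes")
        v = self._label_vec(y)
        if self.normalize_ky:
            nrm = np.sqrt(v @ v)
            if nrm > 0:
                v = v / nrm
        ky_t = self._Yn @ v
        ky_c = self._cat_n @ v
        s = self.alpha.sum(axis=1)
        return float(kx_col @ (s * ky_t - self.alpha @ ky_c))

    def catalog_scores(self, kx_col: np.ndarray) -> np.ndarray:
        """f(x, y) for every catalog label at once."""
        kx_col = np.asarray(kx_col, dtype=float)
        if kx_col.shape != (len(self.train_genes),):
            raise ValueError("kernel column length does not match training genes")
        s = self.alpha.sum(axis=1)
        return kx_col @ (s[:, None] * self._KY_tc - self.alpha @ self._KY_cc)

    def predict(self, kx_col: np.ndarray) -> "Prediction":
        scores = self.catalog_scores(kx_col)
        c = int(np.argmax(scores))  # argmax breaks ties at the lowest index
        return Prediction(
            label=self.catalog.labels[c].copy(),
            catalog_index=c,
            term_scores=self.term_confidence(kx_col, _scores=scores),
        )

    def term_confidence(
        self, kx_col: np.ndarray, _scores: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-term contrastive confidence from the compatibility function.

        score(t) = max f over catalog labels containing t, minus max f over
        labels lacking t (or the overall minimum when every label contains
        t).  The subtraction cancels the per-gene offset of raw
        compatibility values, so scores are comparable across genes; terms
        absent from every catalog label get -inf.  Ancestor scores never
        fall below descendant scores.
        """
        scores = self.catalog_scores(kx_col) if _scores is None else _scores
        cat = self.catalog.labels
        inmax = np.where(cat > 0, scores[:, None], NEG_INF).max(axis=0)
        outmax = np.where(cat == 0, scores[:, None], NEG_INF).max(axis=0)
        ref = np.where(np.isfinite(outmax), outmax, scores.min())
        return np.where(np.isfinite(inmax), inmax - ref, NEG_INF)


@dataclass
class Prediction:
    label: np.ndarray
    catalog_index: int
    term_scores: np.ndarray
    gene: str | None = None


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def compatibility(model: StructuredModel, kx_col: np.ndarray, y) -> float:
    return model.compatibility(kx_col, y)


def predict(model: StructuredModel, kx_col: np.ndarray) -> Prediction:
    return model.predict(kx_col)


def term_confidence(model: StructuredModel, kx_col: np.ndarray) -> np.ndarray:
    return model.term_confidence(kx_col)


def train(
    Kx: np.ndarray,
    train_labels: Sequence[Iterable[str]] | np.ndarray,
    catalog: CandidateCatalog,
    *,
    train_genes: Sequence[str] | None = None,
    C: float = 10.0,
    epsilon: float = 0.01,
    max_passes: int = 100,
    normalize_ky: bool = True,
) -> StructuredModel:
    """Cutting-plane training of the margin-rescaling structured SVM.

    Constraints are generated by exhaustive loss-augmented inference over
    the catalog; the restricted dual is re-optimized with SMO-style
    pairwise updates inside each example's simplex block.  Terminates when
    no candidate violates its margin constraint by more than ``epsilon``.
    """
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    Kx = np.asarray(Kx, dtype=float)
    if isinstance(train_labels, np.ndarray):
        Y = np.asarray(train_labels, dtype=float)
    else:
        Y = label_matrix(train_labels, catalog.term_order)
    n = Y.shape[0]
    if Kx.shape != (n, n):
        raise ValueError("kernel and label matrix sizes disagree")
    if train_genes is None:
        train_genes = [f"g{i}" for i in range(n)]

    true_idx = np.array([catalog.index_of(row) for row in Y], dtype=int)
    cat = catalog.labels
    m = len(cat)
    cat_n = _normalize_rows(cat) if normalize_ky else cat
    KY_cc = cat_n @ cat_n.T
    # Hamming loss between each training label and each catalog label
    Delta = (Y[:, None, :] != cat[None, :, :]).sum(axis=2).astype(float)

    A = np.zeros((n, m))
    A[np.arange(n), true_idx] = C  # all mass on the zero-cost true label
    G = np.zeros((n, m))  # G[i, c] = f(x_i, cat_c); zero at the start
    work: list[set[int]] = [{int(t)} for t in true_idx]
    inner_tol = min(epsilon / 10.0, 1e-4)

    def optimize_working_set(max_sweeps: int = 200) -> None:
        for _ in range(max_sweeps):
            worst = 0.0
            for i in range(n):
                w = sorted(work[i])
                if len(w) < 2:
                    continue
                g = Delta[i, w] - (G[i, true_idx[i]] - G[i, w])
                a = A[i, w]
                iu = int(np.argmax(g))
                support = np.flatnonzero(a > 1e-14)
                if support.size == 0:
                    continue
                iv = int(support[np.argmin(g[support])])
                gap = g[iu] - g[iv]
                if gap <= inner_tol:
                    continue
                worst = max(worst, gap)
                u, v = w[iu], w[iv]
                eta = Kx[i, i] * (KY_cc[u, u] + KY_cc[v, v] - 2.0 * KY_cc[u, v])
                t = a[iv] if eta <= 1e-14 else min(gap / eta, a[iv])
                if t <= 0:
                    continue
                A[i, u] += t
                A[i, v] -= t
                G[:, :] += t * np.outer(Kx[:, i], KY_cc[v] - KY_cc[u])
            if worst <= inner_tol:
                return
        logger.debug("inner SMO sweep cap reached")

    converged = False
    for _ in range(max_passes):
        added = 0
        for i in range(n):
            viol = Delta[i] - (G[i, true_idx[i]] - G[i])
            xi = max(0.0, max(viol[c] for c in work[i]))
            c_star = int(np.argmax(viol))
            if viol[c_star] > xi + epsilon:
                work[i].add(c_star)
                added += 1
        if added == 0:
            converged = True
            break
        optimize_working_set()
    if not converged:
        # the final pass may have added constraints without re-optimizing
        optimize_working_set()
        final_ok = True
        for i in range(n):
            viol = Delta[i] - (G[i, true_idx[i]] - G[i])
            xi = max(0.0, max(viol[c] for c in work[i]))
            if viol.max() > xi + epsilon:
                final_ok = False
                break
        converged = final_ok
        if not converged:
            warnings.warn(
                f"structured SVM did not converge within {max_passes} passes; "
                "returning best-so-far model",
                RuntimeWarning,
                stacklevel=2,
            )

    return StructuredModel(
        train_genes=list(train_genes),
        catalog=catalog,
        alpha=A,
        true_idx=true_idx,
        C=C,
        epsilon=epsilon,
        normalize_ky=normalize_ky,
        working_sets=work,
        converged=converged,
    )


def slacks(model: StructuredModel, Kx_train: np.ndarray) -> np.ndarray:
    """Per-example slack over the model's working-set constraints."""
    n = len(model.train_genes)
    out = np.zeros(n)
    Y = model.catalog.labels[model.true_idx]
    Delta = (Y[:, None, :] != model.catalog.labels[None, :, :]).sum(axis=2)
    for i in range(n):
        scores = model.catalog_scores(Kx_train[i])
        f_true = scores[model.true_idx[i]]
        out[i] = max(
            0.0,
            max(Delta[i, c] - (f_true - scores[c]) for c in model.working_sets[i]),
        )
    return out


# ---------------------------------------------------------------------------
# text serialization
# ---------------------------------------------------------------------------


def save_model(path: str, model: StructuredModel) -> None:
    rows, cols = np.nonzero(model.alpha)
    payload = {
        "term_order": model.catalog.term_order,
        "catalog": [
            "".join(str(int(b)) for b in row) for row in model.catalog.labels
        ],
        "train_genes": model.train_genes,
        "true_idx": model.true_idx.tolist(),
        "C": model.C,
        "epsilon": model.epsilon,
        "normalize_ky": model.normalize_ky,
        "converged": model.converged,
        "working_sets": [sorted(w) for w in model.working_sets],
        "alpha": [
            [int(i), int(c), float(model.alpha[i, c])] for i, c in zip(rows, cols)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_model(path: str) -> StructuredModel:
    with open(path) as fh:
        payload = json.load(fh)
    cat = CandidateCatalog(
        payload["term_order"],
        np.array([[int(ch) for ch in row] for row in payload["catalog"]], dtype=float),
    )
    alpha = np.zeros((len(payload["train_genes"]), len(cat)))
    for i, c, v in payload["alpha"]:
        alpha[i, c] = v
    return StructuredModel(
        train_genes=payload["train_genes"],
        catalog=cat,
        alpha=alpha,
        true_idx=np.array(payload["true_idx"], dtype=int),
        C=payload["C"],
        epsilon=payload["epsilon"],
        normalize_ky=payload["normalize_ky"],
        working_sets=[set(w) for w in payload["working_sets"]],
        converged=payload["converged"],
    )
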