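"""Binary-SVM baseline, term-centric and protein-centric metrics,
cross-validation folds, source ablation, and paired significance tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Genes x terms confidence scores with the matching binary truth grid."""

    genes: list[str]
    terms: list[str]
    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truth = np.asarray(self.truth, dtype=float)
        shape = (len(self.genes), len(self.terms))
        if self.scores.shape != shape or self.truth.shape != shape:
            raise ValueError("score/truth shapes do not match gene/term lists")


@dataclass(frozen=True)
class FoldPlan:
    """Seeded, size-balanced assignment of genes to cross-validation folds."""

    fold_of: dict[str, int]
    n_folds: int
    seed: int

    def test_genes(self, fold: int) -> list[str]:
        return [g for g, f in self.fold_of.items() if f == fold]

    def train_genes(self, fold: int) -> list[str]:
        return [g for g, f in self.fold_of.items() if f != fold]


def make_folds(genes: Sequence[str], k: int = 5, seed: int = 0) -> FoldPlan:
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if len(genes) < k:
        raise ValueError(f"{len(genes)} genes cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    fold_of: dict[str, int] = {}
    for pos, idx in enumerate(order):
        fold_of[genes[idx]] = pos % k
    return FoldPlan(fold_of, k, seed)


# ---------------------------------------------------------------------------
# binary SVM baseline
# ---------------------------------------------------------------------------


def train_binary_svms(
    Kx: np.ndarray,
    truth: np.ndarray,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    C: float = 1.0,
) -> np.ndarray:
    """Per-term kernel SVM decision values for held-out genes.

    Terms whose training fold is single-class are skipped (NaN columns).
    Uses the same precomputed combined kernel as the structured model.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    K_tr = Kx[np.ix_(train_idx, train_idx)]
    K_te = Kx[np.ix_(test_idx, train_idx)]
    n_terms = truth.shape[1]
    out = np.full((len(test_idx), n_terms), np.nan)
    skipped = 0
    for t in range(n_terms):
        y = truth[train_idx, t]
        if y.min() == y.max():
            skipped += 1
            continue
        clf = SVC(kernel="precomputed", C=C, tol=1e-7)
        clf.fit(K_tr, y)
        out[:, t] = clf.decision_function(K_te)
    if skipped:
        logger.info("train_binary_svms: skipped %d single-class terms", skipped)
    return out


# ---------------------------------------------------------------------------
# term-centric metrics
# ---------------------------------------------------------------------------


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties contribute 1/2.

    Returns NaN for single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def macro_auc(table: ScoreTable) -> float:
    """Unweighted mean of per-term AUCs over terms with a defined AUC."""
    vals = per_term_auc(table)
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        raise ValueError("no term has both positives and negatives")
    return float(finite.mean())


def per_term_auc(table: ScoreTable) -> np.ndarray:
    vals = np.full(len(table.terms), np.nan)
    for t in range(len(table.terms)):
        col = table.scores[:, t]
        ok = ~np.isnan(col)
        if ok.any():
            vals[t] = auc(col[ok], table.truth[ok, t])
    return vals


# ---------------------------------------------------------------------------
# protein-centric metrics
# ---------------------------------------------------------------------------


def protein_centric_pr(
    pred: Mapping[str, Iterable[str]], truth: Mapping[str, Iterable[str]]
) -> dict[str, tuple[float, float]]:
    """Per-gene (precision, recall) over predicted vs. true term sets.

    Genes with empty truth are excluded; empty predictions give NaN
    precision.
    """
    out: dict[str, tuple[float, float]] = {}
    excluded = 0
    for gene, true_terms in truth.items():
        ts = set(true_terms)
        if not ts:
            excluded += 1
            continue
        ps = set(pred.get(gene, ()))
        hit = len(ps & ts)
        precision = hit / len(ps) if ps else float("nan")
        out[gene] = (precision, hit / len(ts))
    if excluded:
        logger.info("protein_centric_pr: excluded %d genes with empty truth", excluded)
    return out


def fmax(table: ScoreTable, thresholds: Sequence[float] | None = None) -> float:
    """CAFA-style protein-centric F-max over a threshold grid.

    At each threshold, precision is averaged over genes with at least one
    prediction and recall over all genes (with non-empty truth); F-max is
    the best harmonic mean across the grid.
    """
    keep = table.truth.sum(axis=1) > 0
    scores, truth = table.scores[keep], table.truth[keep]
    if scores.size == 0:
        return float("nan")
    finite = scores[np.isfinite(scores)]
    if thresholds is None:
        if finite.size == 0:
            thresholds = [0.0]
        else:
            lo, hi = float(finite.min()), float(finite.max())
            thresholds = np.linspace(lo, hi, 101) if hi > lo else [lo]
    best = 0.0
    for tau in thresholds:
        pred = scores >= tau
        n_pred = pred.sum(axis=1)
        hits = (pred * (truth > 0)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            has_pred = n_pred > 0
            precision = (hits[has_pred] / n_pred[has_pred]).mean() if has_pred.any() else 0.0
            recall = (hits / truth.sum(axis=1)).mean()
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return float(best)


# ---------------------------------------------------------------------------
# protocol helpers
# ---------------------------------------------------------------------------


def exclude_grouping_terms(table: ScoreTable, grouping: Iterable[str]) -> ScoreTable:
    """Drop listed grouping-only term columns before metric computation."""
    grouping = set(grouping)
    unknown = grouping - set(table.terms)
    if unknown:
        logger.warning("exclude_grouping_terms: unknown terms ignored: %s", sorted(unknown))
    keep = [j for j, t in enumerate(table.terms) if t not in grouping]
    return ScoreTable(
        list(table.genes),
        [table.terms[j] for j in keep],
        table.scores[:, keep],
        table.truth[:, keep],
    )


def leave_one_source_out(
    sources: Sequence[str], evaluate: Callable[[Sequence[str]], float]
) -> dict[str, float]:
    """Percent change in macro AUC from dropping each source in turn.

    ``evaluate`` maps a source subset to a macro AUC; the all-sources run
    is the reference.
    """
    if len(sources) < 2:
        raise ValueError("leave-one-source-out needs at least 2 sources")
    auc_all = evaluate(list(sources))
    if auc_all == 0:
        raise ValueError("reference macro AUC is zero")
    out: dict[str, float] = {}
    for s in sources:
        rest = [x for x in sources if x != s]
        out[s] = 100.0 * (evaluate(rest) - auc_all) / auc_all
    return out


def paired_ttest(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value; NaN when differences have zero
    variance."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 pairs")
    d = a - b
    if np.ptp(d) == 0:  # exactly constant differences -> zero variance
        return float("nan")
    return float(stats.ttest_rel(a, b).pvalue)
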