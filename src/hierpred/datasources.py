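"""Per-gene feature construction from the four heterogeneous source families.

Sources: interaction networks (binary interactor indicators over the union
of edge lists, plus optional per-network blocks), curated GO annotations
(GAF 2.x with evidence-code exclusion), literature sentence co-occurrence
counts (raw or document-frequency-normalized bag of words), and genetic
variants reached through a gene -> disease -> variant two-hop join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Genes x features numeric grid for one source."""

    genes: list[str]
    feature_names: list[str]
    values: np.ndarray
    source_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.feature_names)} features"
            )


@dataclass(frozen=True)
class EdgeSet:
    """Undirected gene-pair set for one named network (no self-loops)."""

    name: str
    pairs: frozenset[tuple[str, str]]

    @staticmethod
    def from_pairs(name: str, pairs: Iterable[tuple[str, str]]) -> "EdgeSet":
        norm = set()
        for a, b in pairs:
            if a == b:
                continue  # self-similarity is carried by the kernel diagonal
            norm.add((a, b) if a < b else (b, a))
        return EdgeSet(name, frozenset(norm))


def _drop_zero_columns(values: np.ndarray, names: list[str], tag: str) -> tuple[np.ndarray, list[str]]:
    keep = np.flatnonzero(values.any(axis=0))
    dropped = values.shape[1] - keep.size
    if dropped:
        logger.info("%s: dropped %d all-zero feature columns", tag, dropped)
    return values[:, keep], [names[i] for i in keep]


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def load_edge_list(
    path: str,
    name: str | None = None,
    min_score: float | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> EdgeSet:
    """Read `gene_a<TAB>gene_b[<TAB>score]` lines into an :class:`EdgeSet`.

    With ``min_score`` set, rows whose third column falls below it are
    skipped (confidence binarization); otherwise any listed edge counts.
    """
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            a, b = parts[0], parts[1]
            if min_score is not None and len(parts) >= 3 and float(parts[2]) < min_score:
                continue
            if gene_map is not None:
                a, b = gene_map.get(a, a), gene_map.get(b, b)
            pairs.append((a, b))
    return EdgeSet.from_pairs(name, pairs)


def build_network_features(
    edge_sets: Sequence[EdgeSet],
    genes: Sequence[str],
    tagged_sets: Sequence[EdgeSet] = (),
) -> FeatureMatrix:
    """Binary interactor-indicator features from the union network.

    ``edge_sets`` are merged into a single union network contributing one
    binary column per interactor gene; each entry of ``tagged_sets`` adds
    its own per-network indicator block (per-evidence-channel networks).
    """
    gene_index = {g: i for i, g in enumerate(genes)}

    def adjacency(pairs: frozenset[tuple[str, str]], tag: str) -> np.ndarray:
        adj = np.zeros((len(genes), len(genes)))
        skipped = 0
        for a, b in sorted(pairs):
            ia, ib = gene_index.get(a), gene_index.get(b)
            if ia is None or ib is None:
                skipped += 1
                continue
            adj[ia, ib] = adj[ib, ia] = 1.0
        if skipped:
            logger.info("%s: skipped %d edges touching unknown genes", tag, skipped)
        return adj

    union: set[tuple[str, str]] = set()
    for es in edge_sets:
        union |= es.pairs
    blocks: list[np.ndarray] = []
    names: list[str] = []
    adj = adjacency(frozenset(union), "union")
    if not adj.any():
        raise ValueError("union network is empty after gene harmonization")
    blocks.append(adj)
    names.extend(f"ppi:{g}" for g in genes)
    for es in tagged_sets:
        blocks.append(adjacency(es.pairs, es.name))
        names.extend(f"{es.name}:{g}" for g in genes)
    values = np.hstack(blocks)
    values, names = _drop_zero_columns(values, names, "network")
    return FeatureMatrix(list(genes), names, values, "network")


# ---------------------------------------------------------------------------
# GO (GAF 2.x)
# ---------------------------------------------------------------------------

DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})


def read_gaf(path: str) -> list[tuple[str, str, str]]:
    """Parse GAF 2.x rows into (gene, go_term, evidence_code) triples."""
    rows: list[tuple[str, str, str]] = []
    bad = 0
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 7 or not parts[4]:
                bad += 1
                continue
            rows.append((parts[1], parts[4], parts[6]))
    if bad:
        logger.info("read_gaf: skipped %d malformed rows in %s", bad, path)
    return rows


def build_go_features(
    gaf_rows: Iterable[tuple[str, str, str]],
    genes: Sequence[str],
    excluded_evidence: frozenset[str] = DEFAULT_EXCLUDED_EVIDENCE,
) -> FeatureMatrix:
    """Binary gene x GO-term indicators, excluding computational evidence."""
    gene_index = {g: i for i, g in enumerate(genes)}
    kept = [
        (g, t)
        for g, t, ev in gaf_rows
        if ev not in excluded_evidence and g in gene_index
    ]
    terms = sorted({t for _, t in kept})
    term_index = {t: j for j, t in enumerate(terms)}
    values = np.zeros((len(genes), len(terms)))
    for g, t in kept:
        values[gene_index[g], term_index[t]] = 1.0
    values, terms = _drop_zero_columns(values, terms, "go")
    return FeatureMatrix(list(genes), terms, values, "go")


# ---------------------------------------------------------------------------
# literature bag-of-words
# ---------------------------------------------------------------------------


def read_cooccurrence(path: str) -> list[tuple[str, str, float]]:
    """Parse `gene<TAB>word<TAB>count` triples."""
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            rows.append((parts[0], parts[1], float(parts[2])))
    return rows


def _bow_counts(
    cooccur: Iterable[tuple[str, str, float]],
    genes: Sequence[str],
    max_doc_freq: float,
    stopwords: frozenset[str],
) -> tuple[np.ndarray, list[str], np.ndarray]:
    if not (0 < max_doc_freq <= 1):
        raise ValueError(f"max_doc_freq must lie in (0, 1], got {max_doc_freq}")
    gene_index = {g: i for i, g in enumerate(genes)}
    counts: dict[str, dict[int, float]] = {}
    for gene, word, count in cooccur:
        if count < 0:
            raise ValueError(f"negative co-occurrence count for {gene!r}/{word!r}")
        w = word.lower()
        if w in stopwords:
            continue
        i = gene_index.get(gene)
        if i is None:
            continue
        col = counts.setdefault(w, {})
        col[i] = col.get(i, 0.0) + count
    n = len(genes)
    # strict "<" document-frequency comparison
    words = sorted(
        w
        for w, col in counts.items()
        if 0 < sum(1 for v in col.values() if v > 0) / n < max_doc_freq
    )
    values = np.zeros((n, len(words)))
    doc_freq = np.zeros(len(words))
    for j, w in enumerate(words):
        for i, v in counts[w].items():
            values[i, j] = v
        doc_freq[j] = sum(1 for v in counts[w].values() if v > 0)
    return values, words, doc_freq


def build_bow_features(
    cooccur: Iterable[tuple[str, str, float]],
    genes: Sequence[str],
    max_doc_freq: float = 0.01,
    stopwords: frozenset[str] = frozenset(),
) -> FeatureMatrix:
    """Raw low-document-frequency word co-occurrence counts per gene."""
    values, words, _ = _bow_counts(cooccur, genes, max_doc_freq, stopwords)
    values, words = _drop_zero_columns(values, words, "literature")
    return FeatureMatrix(list(genes), words, values, "literature")


def build_bow_normalized(
    cooccur: Iterable[tuple[str, str, float]],
    genes: Sequence[str],
    max_doc_freq: float = 0.01,
    stopwords: frozenset[str] = frozenset(),
) -> FeatureMatrix:
    """TFIDF-like variant: counts divided by per-word distinct-gene counts."""
    values, words, doc_freq = _bow_counts(cooccur, genes, max_doc_freq, stopwords)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(doc_freq > 0, values / doc_freq, 0.0)
    values, words = _drop_zero_columns(values, words, "literature")
    return FeatureMatrix(list(genes), words, values, "literature")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def read_pairs(path: str) -> list[tuple[str, str]]:
    """Parse a two-column TSV of (left_id, right_id) pairs."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            rows.append((parts[0], parts[1]))
    return rows


def build_variant_features(
    gene_disease: Iterable[tuple[str, str]],
    disease_variant: Iterable[tuple[str, str]],
    genes: Sequence[str],
) -> FeatureMatrix:
    """Binary gene x variant matrix via the gene -> disease -> variant join."""
    disease_to_variants: dict[str, set[str]] = {}
    for d, v in disease_variant:
        disease_to_variants.setdefault(d, set()).add(v)
    gene_to_variants: dict[str, set[str]] = {g: set() for g in genes}
    for g, d in gene_disease:
        if g in gene_to_variants:
            gene_to_variants[g] |= disease_to_variants.get(d, set())
    variants = sorted({v for vs in gene_to_variants.values() for v in vs})
    var_index = {v: j for j, v in enumerate(variants)}
    values = np.zeros((len(genes), len(variants)))
    for i, g in enumerate(genes):
        for v in gene_to_variants[g]:
            values[i, var_index[v]] = 1.0
    values, variants = _drop_zero_columns(values, variants, "variant")
    return FeatureMatrix(list(genes), variants, values, "variant")


# ---------------------------------------------------------------------------
# id mapping
# ---------------------------------------------------------------------------


def load_gene_map(path: str) -> dict[str, str]:
    """Two-column `from<TAB>to` identifier mapping (identity by default)."""
    return dict(read_pairs(path))
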