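"""Ontology DAG handling: OBO parsing, true-path propagation, term filtering.

Only ``is_a`` relationships are treated as edges; every other OBO
relationship type is ignored.  Obsolete terms are skipped at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown terms."""


class OntologyDAG:
    """A rooted, acyclic is-a hierarchy over term identifiers.

    Parameters
    ----------
    parents:
        Mapping from term identifier to the set of its direct is-a parents.
        Exactly one term must have no parents; it becomes the root.
    names:
        Optional human-readable name per term.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.parents: dict[str, frozenset[str]] = {
            term: frozenset(ps) for term, ps in parents.items()
        }
        known = set(self.parents)
        for term, ps in self.parents.items():
            missing = ps - known
            if missing:
                raise OntologyError(
                    f"term {term!r} references unknown parent {sorted(missing)[0]!r}"
                )
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root term, found {len(roots)}: {roots[:5]}"
            )
        self.root: str = roots[0]
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for term, ps in self.parents.items():
            g.add_edges_from((term, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            edge = nx.find_cycle(g)[0]
            raise OntologyError(f"cycle detected involving edge {edge[0]!r} -> {edge[1]!r}")
        self._graph = g
        self.names: dict[str, str] = dict(names or {})
        self._ancestors: dict[str, frozenset[str]] = {}
        self._depth: dict[str, int] = {}

    # -- basic accessors -------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def children(self, term: str) -> frozenset[str]:
        self._check(term)
        return frozenset(self._graph.predecessors(term))

    def leaves(self) -> list[str]:
        """Terms with no children, sorted."""
        return sorted(t for t in self.parents if self._graph.in_degree(t) == 0)

    def _check(self, term: str) -> None:
        if term not in self.parents:
            raise OntologyError(f"unknown term {term!r}")

    # -- derived structure ----------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms on any directed path to the root, excluding ``term``."""
        self._check(term)
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        acc: set[str] = set()
        for p in self.parents[term]:
            acc.add(p)
            acc |= self.ancestors(p)
        result = frozenset(acc)
        self._ancestors[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """All terms from which ``term`` is reachable, excluding ``term``."""
        self._check(term)
        return frozenset(nx.ancestors(self._graph, term))

    def depth(self, term: str) -> int:
        """Shortest-path distance to the root (root has depth 0)."""
        self._check(term)
        cached = self._depth.get(term)
        if cached is not None:
            return cached
        d = 0 if term == self.root else 1 + min(self.depth(p) for p in self.parents[term])
        self._depth[term] = d
        return d


@dataclass(frozen=True)
class AnnotationSet:
    """Gene -> term-set map, optionally true-path-expanded."""

    annotations: dict[str, frozenset[str]]
    expanded: bool = False

    @property
    def genes(self) -> list[str]:
        return sorted(self.annotations)

    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return frozenset(out)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def parse_obo(stream: TextIO | Iterable[str]) -> OntologyDAG:
    """Parse OBO 1.2 text into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas are considered; ``is_a`` lines become edges,
    stanzas with ``is_obsolete: true`` are skipped.
    """
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    cur_id: str | None = None
    cur_name: str | None = None
    cur_parents: set[str] = set()
    obsolete = False
    in_term = False

    def flush() -> None:
        nonlocal cur_id, cur_name, cur_parents, obsolete
        if in_term and cur_id is not None and not obsolete:
            parents.setdefault(cur_id, set()).update(cur_parents)
            if cur_name is not None:
                names[cur_id] = cur_name
        cur_id, cur_name, cur_parents, obsolete = None, None, set(), False

    for raw in stream:
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            continue
        if not in_term or not line:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        if key == "id":
            cur_id = value
        elif key == "name":
            cur_name = value
        elif key == "is_a":
            cur_parents.add(value.split("!")[0].strip())
        elif key == "is_obsolete" and value.startswith("true"):
            obsolete = True
    flush()
    return OntologyDAG(parents, names)


def write_obo(path: str, dag: OntologyDAG) -> None:
    """Write the DAG back out as minimal OBO 1.2 text (is_a edges only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            name = dag.names.get(term)
            if name:
                fh.write(f"name: {name}\n")
            for p in sorted(dag.parents[term]):
                fh.write(f"is_a: {p}\n")


def subontology(dag: OntologyDAG, root: str) -> OntologyDAG:
    """Induced DAG on ``root`` and all of its descendants."""
    dag._check(root)
    keep = set(dag.descendants(root)) | {root}
    parents = {
        t: (dag.parents[t] & keep if t != root else frozenset()) for t in keep
    }
    return OntologyDAG(parents, {t: n for t, n in dag.names.items() if t in keep})


def ancestors(dag: OntologyDAG, term: str) -> frozenset[str]:
    return dag.ancestors(term)


def propagate_true_path(ann: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Expand each gene's term set with all ancestors (true-path rule)."""
    out: dict[str, frozenset[str]] = {}
    for gene, terms in ann.annotations.items():
        acc = set(terms)
        for t in terms:
            if t not in dag:
                raise OntologyError(f"annotated term {t!r} not in ontology")
            acc |= dag.ancestors(t)
        out[gene] = frozenset(acc)
    return AnnotationSet(out, expanded=True)


def filter_terms(
    ann: AnnotationSet,
    dag: OntologyDAG,
    min_genes: int = 10,
    drop_roots: Iterable[str] = (),
) -> tuple[AnnotationSet, list[str]]:
    """Drop rare terms and listed root terms; prune genes left empty.

    Returns the filtered annotation set together with the retained terms in
    lexicographic order (the canonical term order for label vectors).
    """
    if min_genes < 1:
        raise ValueError(f"min_genes must be >= 1, got {min_genes}")
    if not ann.expanded:
        raise ValueError("filter_terms requires a true-path-expanded AnnotationSet")
    drop = set(drop_roots)
    counts: dict[str, int] = {}
    for terms in ann.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    retained = sorted(
        t for t, c in counts.items() if c >= min_genes and t not in drop
    )
    keep = set(retained)
    out: dict[str, frozenset[str]] = {}
    dropped_genes = 0
    for gene, terms in ann.annotations.items():
        kept = terms & keep
        if kept:
            out[gene] = frozenset(kept)
        else:
            dropped_genes += 1
    if dropped_genes:
        logger.info("filter_terms: dropped %d genes with empty label sets", dropped_genes)
    return AnnotationSet(out, expanded=True), retained


def is_consistent(
    label: Iterable[str], dag: OntologyDAG, ignore: Iterable[str] = ()
) -> bool:
    """True iff every term's ancestors (below the root) are in the label.

    The DAG root (and any terms in ``ignore``, e.g. dropped subontology
    roots or filtered-out rare terms) are exempt from the check.
    """
    label_set = set(label)
    exempt = {dag.root} | set(ignore)
    for t in label_set:
        dag._check(t)
        if (dag.ancestors(t) - exempt) - label_set:
            return False
    return True


# ---------------------------------------------------------------------------
# annotation TSV I/O: `gene_id<TAB>term_id`, one pair per line, # comments
# ---------------------------------------------------------------------------


def read_annotations(path: str, expanded: bool = False) -> AnnotationSet:
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            gene, term = parts
            ann.setdefault(gene, set()).add(term)
    return AnnotationSet({g: frozenset(ts) for g, ts in ann.items()}, expanded=expanded)


def write_annotations(path: str, ann: AnnotationSet) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.annotations):
            for term in sorted(ann.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
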