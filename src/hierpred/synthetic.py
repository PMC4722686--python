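"""Desk-scale synthetic fixture: a random is-a DAG, hierarchically
consistent gene annotations, and four feature sources whose informativeness
about the labels is tunable, written in the exact dialects the loaders
consume."""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationSet, OntologyDAG, propagate_true_path, write_annotations, write_obo

SOURCES = ("network", "go", "literature", "variant")


@dataclass
class SimConfig:
    n_terms: int = 40
    max_parents: int = 2
    n_genes: int = 120
    mean_leaf_annotations: float = 1.0
    signal_strength: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SOURCES}
    )
    noise: float = 0.05
    vocabulary_size: int = 150
    n_go_features: int = 60
    n_diseases: int = 15
    n_variants: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.signal_strength, (int, float)):
            self.signal_strength = {s: float(self.signal_strength) for s in SOURCES}
        if self.n_terms < 3:
            raise ValueError("need at least 3 terms")
        for k, v in self.signal_strength.items():
            if not 0 <= v <= 1:
                raise ValueError(f"signal_strength[{k}] outside [0, 1]")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise flip-rate outside [0, 1]")
        for name in ("n_genes", "vocabulary_size", "n_go_features", "n_diseases", "n_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def generate_dag(cfg: SimConfig, rng: np.random.Generator | None = None) -> OntologyDAG:
    """Single-root random DAG: node i > 0 draws 1..max_parents parents among
    earlier nodes, so a topological order exists by construction."""
    rng = rng or np.random.default_rng(cfg.seed)
    parents: dict[str, set[str]] = {_term_id(0): set()}
    window = max(2, cfg.n_terms // 4)  # recent-parent bias gives depth ~5
    for i in range(1, cfg.n_terms):
        k = int(rng.integers(1, cfg.max_parents + 1))
        lo = max(0, i - window)
        k = min(k, i - lo)
        choice = rng.choice(np.arange(lo, i), size=k, replace=False)
        parents[_term_id(i)] = {_term_id(int(j)) for j in choice}
    names = {_term_id(i): f"synthetic term {i}" for i in range(cfg.n_terms)}
    return OntologyDAG(parents, names)


def generate_annotations(
    dag: OntologyDAG, cfg: SimConfig, rng: np.random.Generator | None = None
) -> AnnotationSet:
    """Each gene samples >=1 Poisson-many leaf terms, then true-path
    expansion makes the label consistent by construction."""
    rng = rng or np.random.default_rng(cfg.seed)
    leaves = dag.leaves()
    raw: dict[str, frozenset[str]] = {}
    for g in range(cfg.n_genes):
        k = max(1, int(rng.poisson(cfg.mean_leaf_annotations)))
        k = min(k, len(leaves))
        picked = rng.choice(len(leaves), size=k, replace=False)
        raw[f"G{g:04d}"] = frozenset(leaves[int(j)] for j in picked)
    return propagate_true_path(AnnotationSet(raw, expanded=False), dag)


def _label_sets(ann: AnnotationSet) -> dict[str, frozenset[str]]:
    return {g: ann.annotations[g] for g in ann.genes}


def generate_features(
    ann: AnnotationSet, dag: OntologyDAG, cfg: SimConfig, rng: np.random.Generator | None = None
) -> dict:
    """Raw feature-source tables keyed by source name.

    network: two edge lists whose union's edge probability grows with the
    Jaccard similarity of the endpoint label sets, scaled by the source
    signal.  go: indicator features tied to latent terms, flipped at the
    noise rate.  literature: per-term signal words with Poisson counts plus
    background words.  variant: diseases anchored at latent leaf terms,
    variants hanging off diseases.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genes = ann.genes
    labels = _label_sets(ann)
    sig = cfg.signal_strength

    # -- network ---------------------------------------------------------
    edges: list[tuple[str, str]] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            inter = len(labels[a] & labels[b])
            union = len(labels[a] | labels[b])
            jac = inter / union if union else 0.0
            p = 0.03 + 0.85 * sig["network"] * jac
            if rng.random() < p:
                edges.append((a, b))
    half = rng.random(len(edges)) < 0.5
    net_a = [e for e, h in zip(edges, half) if h]
    net_b = [e for e, h in zip(edges, half) if not h]

    # -- go-like indicators ----------------------------------------------
    terms = sorted(dag.terms - {dag.root})
    go_rows: list[tuple[str, str, str]] = []
    s = sig["go"]
    for j in range(cfg.n_go_features):
        t = terms[j % len(terms)]  # cover every term before repeating any
        go_id = f"GO:{j:07d}"
        for g in genes:
            has = t in labels[g]
            p = (1 - s) * 0.08 + s * (1.0 if has else 0.0)
            on = rng.random() < p
            if rng.random() < cfg.noise:
                on = not on
            if on:
                go_rows.append((g, go_id, "EXP"))
        # decoy computational-evidence rows that the loader must exclude
        decoy = genes[int(rng.integers(len(genes)))]
        go_rows.append((decoy, go_id, "IEA"))

    # -- literature ------------------------------------------------------
    lit_rows: list[tuple[str, str, int]] = []
    s = sig["literature"]
    n_signal_words = min(2 * len(terms), cfg.vocabulary_size)
    for j in range(n_signal_words):
        t = terms[j % len(terms)]
        word = f"word{j:04d}"
        for g in genes:
            lam = 6.0 * s * (1.0 if t in labels[g] else 0.0) + 0.15
            c = int(rng.poisson(lam))
            if c > 0:
                lit_rows.append((g, word, c))
    for j in range(cfg.vocabulary_size - n_signal_words):
        word = f"bg{j:04d}"
        for g in genes:
            c = int(rng.poisson(0.3))
            if c > 0:
                lit_rows.append((g, word, c))

    # -- variants --------------------------------------------------------
    leaves = dag.leaves()
    s = sig["variant"]
    gene_disease: list[tuple[str, str]] = []
    disease_variant: list[tuple[str, str]] = []
    per_disease = max(1, cfg.n_variants // cfg.n_diseases)
    for d in range(cfg.n_diseases):
        did = f"D{d:04d}"
        anchor = leaves[int(rng.integers(len(leaves)))]
        for g in genes:
            p = 0.9 * s * (1.0 if anchor in labels[g] else 0.0) + 0.02
            if rng.random() < p:
                gene_disease.append((g, did))
        for v in range(per_disease):
            disease_variant.append((did, f"V{d * per_disease + v:05d}"))

    return {
        "network": {"network_a": net_a, "network_b": net_b},
        "go": go_rows,
        "literature": lit_rows,
        "variant": {"gene_disease": gene_disease, "disease_variant": disease_variant},
    }


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------


def write_fixture(out_dir: str, cfg: SimConfig) -> dict:
    """Generate and write the full fixture; returns the manifest dict.

    Identical config + seed produce byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    dag = generate_dag(cfg, rng)
    ann = generate_annotations(dag, cfg, rng)
    tables = generate_features(ann, dag, cfg, rng)

    os.makedirs(out_dir, exist_ok=True)
    write_obo(os.path.join(out_dir, "ontology.obo"), dag)
    write_annotations(os.path.join(out_dir, "annotations.tsv"), ann)
    for name in ("network_a", "network_b"):
        with open(os.path.join(out_dir, f"{name}.tsv"), "w") as fh:
            for a, b in tables["network"][name]:
                fh.write(f"{a}\t{b}\n")
    with open(os.path.join(out_dir, "go.gaf"), "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for g, go_id, ev in tables["go"]:
            fh.write(f"DB\t{g}\t{g}\t\t{go_id}\tREF\t{ev}\t\tP\t\t\tprotein\ttaxon:9606\t0\tsrc\t\t\n")
    with open(os.path.join(out_dir, "literature.tsv"), "w") as fh:
        for g, w, c in tables["literature"]:
            fh.write(f"{g}\t{w}\t{c}\n")
    with open(os.path.join(out_dir, "gene_disease.tsv"), "w") as fh:
        for g, d in tables["variant"]["gene_disease"]:
            fh.write(f"{g}\t{d}\n")
    with open(os.path.join(out_dir, "disease_variant.tsv"), "w") as fh:
        for d, v in tables["variant"]["disease_variant"]:
            fh.write(f"{d}\t{v}\n")

    manifest = {
        "config": cfg.to_dict(),
        "files": [
            "ontology.obo",
            "annotations.tsv",
            "network_a.tsv",
            "network_b.tsv",
            "go.gaf",
            "literature.tsv",
            "gene_disease.tsv",
            "disease_variant.tsv",
        ],
        "root": dag.root,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
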