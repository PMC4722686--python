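"""End-to-end run orchestration: load inputs, propagate and filter
annotations, build per-source kernels, cross-validate the structured model
and the binary-SVM baseline, compute metrics, and write reports."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import baselines_eval as ev
from . import datasources as ds
from . import kernels as kn
from . import ontology as onto
from . import structpred as sp

logger = logging.getLogger(__name__)

VERSION = "0.1.0"
ALL_SOURCES = ("network", "go", "literature", "variant")


class DataError(ValueError):
    """Raised for unusable or inconsistent input data."""


@dataclass
class RunConfig:
    fixture_dir: str
    sources: list[str] = field(default_factory=lambda: list(ALL_SOURCES))
    subontology_root: str | None = None
    min_genes: int = 10
    folds: int = 5
    seed: int = 0
    C: float = 10.0
    epsilon: float = 0.01
    bow_max_doc_freq: float = 1.0
    grouping_terms: list[str] = field(default_factory=list)
    ablation: bool = True
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        return RunConfig(**{k: v for k, v in d.items() if k in known})


@dataclass
class Dataset:
    """Filtered, label-vectorized problem instance plus per-source kernels."""

    genes: list[str]
    terms: list[str]
    Y: np.ndarray
    dag: onto.OntologyDAG
    kernels: dict[str, kn.KernelMatrix]
    label_sets: dict[str, frozenset[str]]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_fixture(cfg: RunConfig) -> Dataset:
    d = cfg.fixture_dir
    try:
        with open(os.path.join(d, "ontology.obo")) as fh:
            dag = onto.parse_obo(fh)
        ann = onto.read_annotations(os.path.join(d, "annotations.tsv"))
    except (OSError, onto.OntologyError, ValueError) as exc:
        raise DataError(str(exc)) from exc
    if cfg.subontology_root is not None:
        dag = onto.subontology(dag, cfg.subontology_root)
        ann = onto.AnnotationSet(
            {g: ts & dag.terms for g, ts in ann.annotations.items()}, ann.expanded
        )
    ann = onto.propagate_true_path(ann, dag)
    ann, terms = onto.filter_terms(ann, dag, cfg.min_genes, drop_roots=[dag.root])
    if not terms:
        raise DataError("no terms survive filtering; lower min_genes")
    genes = ann.genes
    Y = sp.label_matrix([ann.annotations[g] for g in genes], terms)

    feats = build_feature_matrices(cfg, genes)
    kernels = {
        s: kn.normalize_kernel(kn.linear_kernel(fm)) for s, fm in feats.items()
    }
    return Dataset(genes, terms, Y, dag, kernels, dict(ann.annotations))


def build_feature_matrices(cfg: RunConfig, genes: Sequence[str]) -> dict[str, ds.FeatureMatrix]:
    d = cfg.fixture_dir
    out: dict[str, ds.FeatureMatrix] = {}
    try:
        for source in cfg.sources:
            if source == "network":
                import glob

                files = sorted(glob.glob(os.path.join(d, "network_*.tsv")))
                edge_sets = [ds.load_edge_list(p) for p in files]
                out[source] = ds.build_network_features(edge_sets, genes)
            elif source == "go":
                out[source] = ds.build_go_features(
                    ds.read_gaf(os.path.join(d, "go.gaf")), genes
                )
            elif source == "literature":
                out[source] = ds.build_bow_features(
                    ds.read_cooccurrence(os.path.join(d, "literature.tsv")),
                    genes,
                    max_doc_freq=cfg.bow_max_doc_freq,
                )
            elif source == "variant":
                out[source] = ds.build_variant_features(
                    ds.read_pairs(os.path.join(d, "gene_disease.tsv")),
                    ds.read_pairs(os.path.join(d, "disease_variant.tsv")),
                    genes,
                )
            else:
                raise DataError(f"unknown source {source!r}")
    except (OSError, ValueError) as exc:
        raise DataError(str(exc)) from exc
    return out


def combined_kernel(data: Dataset, sources: Sequence[str]) -> np.ndarray:
    Ks = [data.kernels[s] for s in sources]
    return kn.normalize_kernel(kn.combine_kernels(Ks)).values


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    data: Dataset,
    cfg: RunConfig,
    sources: Sequence[str] | None = None,
    methods: Sequence[str] = ("structured", "binary"),
) -> dict[str, ev.ScoreTable]:
    """Pooled held-out score tables per method over a seeded fold plan."""
    sources = list(sources or cfg.sources)
    Kx = combined_kernel(data, sources)
    genes, Y = data.genes, data.Y
    idx = {g: i for i, g in enumerate(genes)}
    plan = ev.make_folds(genes, cfg.folds, cfg.seed)
    tables = {
        m: np.full(Y.shape, np.nan) for m in methods
    }
    for fold in range(plan.n_folds):
        tr = np.array([idx[g] for g in plan.train_genes(fold)])
        te = np.array([idx[g] for g in plan.test_genes(fold)])
        if "structured" in methods:
            catalog = sp.build_catalog(
                [data.label_sets[genes[i]] for i in tr], data.terms
            )
            model = sp.train(
                Kx[np.ix_(tr, tr)],
                Y[tr],
                catalog,
                train_genes=[genes[i] for i in tr],
                C=cfg.C,
                epsilon=cfg.epsilon,
            )
            for row, i in enumerate(te):
                tables["structured"][i] = model.term_confidence(Kx[i, tr])
        if "binary" in methods:
            tables["binary"][te] = ev.train_binary_svms(Kx, Y, tr, te, C=cfg.C)
    out = {}
    for m in methods:
        table = ev.ScoreTable(genes, list(data.terms), tables[m], Y)
        if cfg.grouping_terms:
            table = ev.exclude_grouping_terms(table, cfg.grouping_terms)
        out[m] = table
    return out


# ---------------------------------------------------------------------------
# full evaluation run
# ---------------------------------------------------------------------------


def evaluate_run(cfg: RunConfig) -> dict:
    """Run the full protocol and return (and optionally write) the report."""
    data = load_fixture(cfg)
    tables = cross_validate(data, cfg)

    aucs = {m: ev.per_term_auc(t) for m, t in tables.items()}
    terms = tables["structured"].terms
    freq = tables["structured"].truth.sum(axis=0).astype(int)
    summary: dict = {
        "version": VERSION,
        "config": cfg.to_dict(),
        "n_genes": len(data.genes),
        "n_terms": len(terms),
        "macro_auc": {m: ev.macro_auc(t) for m, t in tables.items()},
        "fmax": {m: ev.fmax(t) for m, t in tables.items()},
    }
    both = ~np.isnan(aucs["structured"]) & ~np.isnan(aucs["binary"])
    if both.sum() >= 2:
        p = ev.paired_ttest(aucs["structured"][both], aucs["binary"][both])
        summary["paired_ttest_p"] = None if np.isnan(p) else p

    if cfg.ablation and len(cfg.sources) >= 2:
        def eval_subset(subset: Sequence[str]) -> float:
            t = cross_validate(data, cfg, sources=subset, methods=("structured",))
            return ev.macro_auc(t["structured"])

        summary["ablation_pct_change"] = ev.leave_one_source_out(
            cfg.sources, eval_subset
        )

    rows = []
    for j, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "name": data.dag.names.get(t, ""),
                "freq": int(freq[j]),
                "depth": data.dag.depth(t),
                "auc_structured": aucs["structured"][j],
                "auc_binary": aucs["binary"][j],
            }
        )
    report = {"summary": summary, "per_term": rows}

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        write_report(cfg.out_dir, report)
    return report


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(out_dir: str, report: dict) -> None:
    cols = ["term", "name", "freq", "depth", "auc_structured", "auc_binary"]
    with open(os.path.join(out_dir, "per_term.tsv"), "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in report["per_term"]:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(report["summary"], fh, indent=1, sort_keys=True, default=float)
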