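# hierpred

Hierarchically consistent ontology-term prediction for genes.

`hierpred` predicts, for each gene, a whole *set* of ontology terms that is
guaranteed to respect the ontology's is-a hierarchy.  It does so with a
structured SVM over a joint input–output kernel: the input-space kernel is
the sum of cosine-normalized linear kernels over heterogeneous feature
sources (interaction networks, curated functional annotations, literature
sentence co-occurrence counts, and genetic variants), the output-space
kernel is a normalized linear kernel between binary label vectors, and the
joint kernel is their product.  Training uses n-slack cutting-plane
optimization of the margin-rescaling objective with Hamming loss;
inference is an exact argmax over the catalog of distinct training label
vectors, so every prediction is hierarchically consistent by construction.
A per-term binary-SVM baseline, term-centric (macro AUC) and
protein-centric (precision/recall/F-max) metrics, cross-validation,
leave-one-source-out ablation, and a tunable synthetic fixture generator
are included, so the full protocol runs end to end with no downloads.

## Layout

| module | role |
| --- | --- |
| `hierpred.ontology` | OBO parsing, subontology extraction, true-path propagation, term filters, consistency checks |
| `hierpred.datasources` | per-gene feature construction from edge lists, GAF, co-occurrence counts, and gene–disease–variant tables |
| `hierpred.kernels` | linear kernels, cosine normalization, additive combination, joint product kernel |
| `hierpred.structpred` | candidate catalog, compatibility function, cutting-plane training, argmax inference, per-term confidence |
| `hierpred.baselines_eval` | binary-SVM baseline, AUC / macro AUC / F-max, folds, ablation, paired t-tests |
| `hierpred.synthetic` | seeded fixture generator (ontology + annotations + four feature sources) |
| `hierpred.pipeline`, `hierpred.cli` | run orchestration, reports, command-line interface |

## CLI

```bash
# write a synthetic fixture (ontology.obo, annotations.tsv, network_*.tsv,
# go.gaf, literature.tsv, gene_disease.tsv, disease_variant.tsv, manifest)
hierpred simulate --out fx/ --seed 1

# cross-validated evaluation of the structured model vs. binary SVMs,
# with per-source ablation; writes per_term.tsv and summary.json
hierpred evaluate --fixture fx/ --out report/ --seed 1

# individual stages
hierpred build-features --fixture fx/ --out feats/
hierpred train --fixture fx/ --out model.json
hierpred predict --fixture fx/ --model model.json --out preds.tsv
```

`evaluate` also accepts a YAML config file (`--config run.yaml`) whose keys
mirror the flags; flags override the file.  Exit codes: 0 success, 1 usage
error, 2 data error.

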