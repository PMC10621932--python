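# hmlfsm

Two-phase hybrid feature selection for tumour/normal classification of
high-dimensional gene-expression data, with a multi-classifier evaluation
harness and a synthetic-data generator with planted ground truth.

Microarray-style expression matrices have thousands of genes measured on a
few dozen biopsies, so classifiers overfit unless the gene set is cut down
aggressively. `hmlfsm` implements a two-phase hybrid selector:

1. **Phase 1 — information gain + genetic algorithm.** Each gene is
   discretized by supervised MDL (Fayyad–Irani) binning and scored by its
   information gain *IG(g) = H(y) − Σ_b (n_b/n) H(y | b)* against the class
   label; genes with zero gain are eliminated. A genetic algorithm then
   searches binary masks over the survivors, scoring each mask by the pooled
   cross-validated accuracy of a 1-NN classifier trained on the masked genes.
2. **Phase 2 — mRMR + binary particle swarm.** Surviving genes are ranked by
   greedy minimum-redundancy-maximum-relevance: the pick at step *t*
   maximises *MI(g; y) − mean_{s∈S} MI(g; s)* (difference form; the quotient
   form is available). Near-duplicates — genes sharing more information with
   a higher-ranked gene than they carry about the class — are screened out,
   and a binary PSO (velocity update *v ← wv + c1 r1 (pbest−x) + c2 r2
   (gbest−x)*, bits resampled with probability *sigmoid(v)*) refines the
   remaining pool for cross-validated accuracy.

The evaluation harness trains six classifier families (SVM, naive Bayes,
decision tree, random forest, k-NN, and a small MLP standing in for a deep
network) and reports precision, recall, F1 = 2PR/(P+R), ROC area (rank
statistic) and accuracy from the confusion matrix, with tumour as the
positive class.

## Worked example

```python
from hmlfsm.pipeline import RunConfig, run_full

cfg = RunConfig.model_validate({
    "io": {"synthetic": {"n_samples": 62, "n_genes": 2000,
                         "n_informative": 20, "n_redundant": 40,
                         "effect_size": 2.0, "class_balance": 40/62}},
    "seed": 0,
    "out_dir": "example_run",
})
report = run_full(cfg)
print(report.stage_counts)   # {'input': 2000, 'preprocessed': 2000,
                             #  'ig_filter': 74, 'phase1': 74, 'phase2': 23}
print(report.reductions)     # {'phase1_vs_input': 96.3, 'phase2_vs_input': 98.9}
```

This simulates a 62-sample × 2000-gene dataset shaped like the classic
colon-cancer benchmark (40 tumour / 22 normal biopsies, 20 planted
informative genes plus 40 noisy copies). Phase 1 keeps 74 genes (a 96.3 %
reduction: the zero-gain filter removes nearly all pure-noise genes), and
phase 2's redundancy screen plus swarm refinement cuts those to 23 (98.9 %),
discarding the noisy copies while keeping the planted parents. The
`example_run/` directory holds per-stage gene lists, the IG and mRMR score
tables, and per-classifier metric tables such as:

```
Classifier	Precision	Recall	F-Measure	ROC Area	Accuracy
svm	1.000	1.000	1.000	1.000	100.0%
dt	0.857	1.000	0.923	0.857	89.5%
```

The same pipeline runs from the shell on real data:

```bash
hmlfsm run --config config.yaml --seed 0 --out run/
hmlfsm simulate --seed 0 --out sim/          # synthetic data + ground truth
hmlfsm phase1 --data expr.csv --label-column label --out p1/
hmlfsm phase2 --data p1/phase1_dataset.csv --out p2/
hmlfsm evaluate --data p2/phase2_dataset.csv --out eval/
```

Input tables are delimited text in either orientation (samples in rows with
a label column, or genes in rows with a separate sample→label file).

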