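# braingut

A tested, reusable implementation of a brain–gut machine-learning pipeline
that discriminates **obese** (BMI > 30) from **overweight**
(25 ≤ BMI < 30) adults using two data blocks:

* **structural connectomes** — per-subject DTI streamline-count matrices
  over a parcellated brain, volume-corrected into connection weights
  `w_ij = c_ij / (v_i + v_j)`, summarized as nodal graph metrics
  (strength, betweenness centrality, eigenvector centrality, nodal
  average path length);
* **fecal metabolomics** — a subjects × metabolites abundance table,
  modeled on the log scale.

The analysis core is **SVM-based recursive feature elimination** with a
leave-one-out cross-validated search for the optimal subset size k and a
ten-fold **voting** aggregation: each stratified fold runs RFE-to-k on its
training portion, every selected feature gains a vote, and the final
subset is the top k by votes. Final linear models (linear-kernel SVM,
ridge classifier, logistic regression; covariates age + sex, plus diet for
metabolite-bearing designs) are evaluated by leave-one-out
cross-validation; a **combined** model merges the top 90% of each block's
features by |weight|; a **label-permutation test** (R shuffles, ten-fold
CV accuracy per shuffle, empirical p) provides the null reference.

The cohorts the original analysis was run on are not publicly deposited,
so the package includes a first-class **synthetic cohort generator**
(117 subjects split 64 obese / 53 overweight, 165 regions, up to 987
metabolites, clinical-table covariate composition) that plants
group-discriminative effects of configurable size in both blocks. All
pipeline stages are deterministic given a seed. See `docs/methods.md` for
the model, its assumptions, and what the synthetic results do and do not
show.

## Worked example

```python
from braingut.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(elimination_step=5, permutation_R=49, seed=11)
manifest = run_pipeline(cfg, "runs/demo")
```

This generates the demonstration cohort (165 regions, 200 metabolites,
signal planted in 8 regions at edge-scaling 1.25 and 10 metabolites at
d = 0.8), computes nodal metric features, selects features per block,
trains and evaluates the three model families, builds the combined model
and runs the permutation test. Selected numbers from `runs/demo`:

| report | value | meaning |
|---|---|---|
| `selection_brain.json` → `optimal_k` | 2 | LOO accuracy peaked at 2 brain features (both betweenness of planted regions) |
| `evaluation_brain_svm.json` → `accuracy` | 0.9915 | brain-block SVM, leave-one-out |
| `evaluation_metabolite_svm.json` → `accuracy` | 0.8462 | metabolite-block SVM, leave-one-out |
| `evaluation_combined_svm.json` → `accuracy` | 0.9658 | combined model (tp 62, fp 2, fn 2, tn 51 of 117) |
| `evaluation_combined_svm.json` → `precision` | 0.97 / 0.96 | obese / overweight class precision |
| `permutation_combined.json` → `mean_permuted_accuracy` | 0.5067 | label-shuffled ten-fold CV accuracy collapses to chance |
| `permutation_combined.json` → `empirical_p` | 0.02 | 0 of 49 shuffles reached the observed accuracy, p = 1/50 |

Every evaluation report carries a `selection_inherited` note: the feature
subset was selected using all subjects, so these LOO accuracies inherit
that selection, exactly as in the protocol being reimplemented; the
permutation test is the check that the signal is real, and
`braingut.rfe.nested_loo_accuracy` provides the fully split-nested
estimator.

The same stages are scriptable from the shell:

```bash
braingut synth --spec cohort.yaml --out data/ --seed 7
braingut connectome-metrics --matrices data/connectomes --volumes data/volumes.tsv \
    --metrics nodebwcent,avpathlength --out features.tsv
braingut select --features features.tsv --labels data/covariates.tsv \
    --grid auto --folds 10 --seed 7 --out selection.json
braingut evaluate --features features.tsv --labels data/covariates.tsv \
    --selection selection.json --family svm --block brain --out report.json
braingut table1 --cohort data/covariates.tsv --out table1.tsv
braingut run --out runs/full --seed 7
```

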