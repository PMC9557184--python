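# momcrad

Multi-objective, multi-classifier radiomics for predicting **local
persistence/recurrence (P/R)** of head and neck squamous cell carcinoma
after definitive radiotherapy, from post-treatment PET/CT and clinical
data.

Post-treatment FDG-PET/CT surveillance is confounded by radiation-induced
inflammation: recurrent tumour and inflamed tissue show similar uptake,
so early reads are error-prone.  `momcrad` addresses this as a
quantitative-imaging problem.  From the contoured gross tumour volume it
extracts a 257-feature radiomic signature per imaging modality
(8 geometry + 9 intensity + 240 gray-level co-occurrence texture
features), pre-selects the 50 most relevant and least redundant features
by mRMR, and then trains, per modality, an ensemble of candidate models —
each a triple (f, β, ω) of feature-selection vector, classifier
hyperparameters (logistic regression, discriminant analysis, RBF SVM) and
classifier-fusion weights — with an **iterative multi-objective immune
algorithm** that simultaneously maximizes

* sensitivity on the training cohort,
* specificity on the training cohort,
* feature sparsity, defined as 1 / (number of selected features).

The Pareto-optimal solutions are retained and their probability outputs
combined by **evidential reasoning (ER)**, weighting each solution by
`[(sens+spec)/2] · [1 − |sens − spec|]` so balanced solutions dominate.
Per-modality outputs (CT, PET, clinical) are ER-fused again with weights
proportional to training AUC; probability ≥ 0.5 flags a patient high-risk.
Evaluation covers sensitivity/specificity/accuracy/AUC, DeLong ROC
comparisons, and Kaplan-Meier/log-rank risk-group separation.

No dataset of this kind is publicly deposited, so the package includes a
first-class synthetic-data module: PET/CT lesion phantoms for the
extractor, and study-sized cohorts (328 patients, 21% positive, 262/66
stratified split) with planted signal of known Bayes-optimal AUC for the
modelling stack.  See `docs/methods.md` for the model details and what
the synthetic conditions do and do not demonstrate.

## Worked example

`examples/03_train_fuse_evaluate.py` runs the whole study on the default
synthetic cohort:

```text
validation cohort, threshold 0.5
modality    sens  spec   acc    AUC  DeLong p vs fused
CT          0.79  0.79  0.79  0.879  0.177
PET         0.86  0.56  0.62  0.805  0.061
clinical    0.71  0.58  0.61  0.698  0.001
fused       0.86  0.88  0.88  0.930
modality weights: {'CT': 0.36, 'PET': 0.343, 'clinical': 0.297}
log-rank, predicted low vs high risk: chi2 32.6, p 1.13e-08
artifacts (model.json, predictions.csv, report.json) in run_artifacts/
```

Each row is one modality's model evaluated on the held-out 66 patients;
the fused row is the three-modality ER combination, which here dominates
every single modality (AUC 0.930 against a planted per-modality
Bayes-optimal AUC of 0.9 — fusing three noisy views can exceed each
view's own ceiling).  The DeLong column tests each single-modality ROC
against the fused one; only the weak clinical model differs
significantly.  The log-rank line shows that patients the model calls
high-risk have far shorter local-P/R-free survival.

The other examples cover the extractor on a phantom
(`01_phantom_features.py`), mRMR pre-selection behaviour
(`02_mrmr_preselection.py`) and the sparsity-objective ablation
(`04_sparsity_ablation.py`).  A thin CLI mirrors the pipeline stages:

```bash
momcrad simulate --out-dir data/ --seed 1
momcrad run-full --seed 1 --out-dir run/
momcrad extract --ct ct.nii.gz --pet pet.nii.gz --mask gtv.nii.gz --out features.csv
```

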