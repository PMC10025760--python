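# encodeaudit

Auditing whether a disease-detection model **encodes** protected
characteristics — and whether it actually **uses** them.

Deep image classifiers can recognize a patient's racial identity or sex
from a medical scan with high accuracy.  That raises a concrete question
for anyone deploying such a model: if race is recoverable from the model's
internal representation, is it influencing the disease predictions?  The
two are not the same.  A linear probe on the penultimate layer (the
*supervised prediction layer information test*, SPLIT: freeze the backbone,
train a fresh linear head for the attribute, measure its AUC) detects
*encoding* — but a positive probe is only a necessary condition for *use*,
because shared features with orthogonal decision boundaries yield perfect
probes for attributes the prediction layer ignores.

`encodeaudit` is a toolkit for resolving that ambiguity with converging
evidence on one cohort:

1. **Subgroup operating points** — per-group AUC, TPR, FPR and Youden's
   J = TPR − FPR at a single decision threshold calibrated to a population
   false positive rate of 0.20, with 95% CIs from a stratified bootstrap
   (2000 resamples).
2. **Test-set resampling** — balanced test sets drawn with replacement to
   equalize group proportions, age histograms and disease prevalence across
   groups; disparities that survive the correction point at the model, not
   the test-set composition.
3. **SPLIT panel** — the probe run over four backbones (random-init,
   generically pretrained, all-data disease, subgroup-only disease) next to
   direct single-task and multitask attribute classifiers.
4. **Multitask comparison and feature inspection** — disease/sex/race heads
   on one shared representation, plus PCA (first four modes), t-SNE and
   paired focal-label logits with per-axis two-sample Kolmogorov–Smirnov
   tests, Benjamini–Yekutieli-adjusted per table.

Everything runs on synthetic cohorts generated by the package itself: three
unbalanced demographic groups (majority ≈78%), group-dependent sex ratios,
ages and prevalences of two mutually exclusive focal labels (`no_finding`,
`condition_x`), and a switch controlling whether the group attribute enters
the latent features not at all (`none`), orthogonally to the disease
direction (`orthogonal`), or entangled with it (`entangled`) — the three
canonical task-relationship regimes.  No data download, no GPU; the neural
components are compact NumPy networks.  User-supplied prediction tables
(CSV) can be audited directly in place of the built-in models.

## Worked example

```python
from encodeaudit import (CohortConfig, EvalConfig, calibrate_threshold,
                         make_cohort, subgroup_performance)
from encodeaudit.models import build_backbone, freeze, predict_proba, train_single_task
from encodeaudit.split import run_split

cohort = make_cohort(CohortConfig(n=10_000), seed=0)
backbone = build_backbone("mlp", {"input_dim": cohort.features.shape[1]}, seed=0)
model = train_single_task(backbone, cohort, epochs=30, seed=0)

test = cohort.split("test")
scores = predict_proba(model, test)[:, cohort.label_names.index("no_finding")]
labels = test.attr("no_finding").astype(int)

threshold = calibrate_threshold(scores, labels, target_fpr=0.20)
report = subgroup_performance(scores, labels, test.attr("group"), threshold,
                              EvalConfig(n_boot=2000, boot_seed=0))
print(report.table[["group", "n", "auc", "tpr", "fpr", "youden_j"]].round(3))

probe = run_split(freeze(model.backbone), cohort.split("train"), test, "race",
                  seed=0, eval_cfg=EvalConfig(n_boot=200))
print(probe.table[["class", "auc", "auc_lo", "auc_hi"]].round(3))
```

Output:

```
group    n   auc   tpr   fpr  youden_j
   g0 2252 0.879 0.779 0.189     0.589
   g1  460 0.892 0.897 0.228     0.669
   g2  201 0.932 0.913 0.253     0.660

class   auc  auc_lo  auc_hi
   g0 0.729   0.709   0.752
   g1 0.734   0.713   0.759
   g2 0.744   0.711   0.772
```

Reading it: at the shared threshold (population FPR 0.20) the minority
groups sit at elevated FPRs (0.228, 0.253) for the rule-out label — the
under-diagnosis-style shift the audit is built to investigate — while the
probe reads the group attribute out of the disease model's features well
above chance (AUC ≈ 0.73).  Whether that encoding is *used* is then settled
by the resampled evaluation, the multitask comparison and the logit-space
KS tests (`encodeaudit run-all` produces all of them together, plus a
scenario verdict with the raw evidence attached).

## Command line

```bash
encodeaudit make-cohort --seed 1 --out cohort/          # generate + population summary
encodeaudit train --cohort cohort/ --task multi --out run/
encodeaudit resample --cohort cohort/ --seed 1 --out balanced/
encodeaudit split-panel --cohort cohort/ --attribute race --out panel.csv
encodeaudit evaluate --predictions preds.csv --label condition_x --out report.csv
encodeaudit run-all --seed 1 --out audit_out/           # full report bundle
```

## Layout

| Module | Contents |
| --- | --- |
| `encodeaudit.synthetic` | scenario toys, cohort generator, image renderer, population summary |
| `encodeaudit.models` | backbones (MLP / CNN / DenseNet-121 / random / external), single-task and multitask training, freezing, feature/logit extraction |
| `encodeaudit.metrics` | ROC/AUC, threshold calibration, subgroup reports, Youden thresholds, one-vs-rest AUC, stratified bootstrap |
| `encodeaudit.resampling` | balanced test-set construction, shift diagnosis |
| `encodeaudit.split` | SPLIT probe, toy feature maps, four-backbone panel |
| `encodeaudit.inspection` | PCA/t-SNE/logit views, KS tables with BY adjustment, mode-attribution summary |
| `encodeaudit.audit`, `encodeaudit.cli` | end-to-end orchestration, prediction-table ingestion, `encodeaudit` CLI |

See `docs/methods.md` for the statistical conventions, generator design and
known limitations.
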