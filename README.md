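# mirforest

Random-forest classification of miRNA binding-site alignments.

Animal miRNAs repress target mRNAs through partial, seed-anchored base
pairing, so complementarity-based screens (miRanda-style alignment with
score and energy thresholds) produce many false positives. `mirforest`
refines such screens: it aligns candidate miRNA–mRNA pairs with the miRanda
scoring scheme (+5 G:C, +5 A:U, +2 G:U wobble, −3 otherwise, affine gaps,
four empirical seed/site rules, ΔG threshold), summarizes each accepted
duplex in 34 features — alignment score and length, duplex ΔG, per-category
column counts, the pairing category at positions 1–20, and seed-window
(positions 2–8) energy and counts — and trains a random forest (500 bagged
trees, per-split `mtry` feature sampling) to separate functional targets
from pseudo-targets. A site is called a target when the fraction of trees
voting TARGET strictly exceeds 0.5.

The evaluation machinery implements the full published protocol: ACC/SEN/SPE
as percentages and MCC from (possibly fractional, fold-averaged) confusion
matrices,

    ACC = (TP+TN)/(TP+TN+FP+FN) · 100        SEN = TP/(TP+FN) · 100
    SPE = TN/(TN+FP) · 100
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

ROC/AUC by threshold sweep (AUC = P(random positive outscores random
negative), ties ½), stratified 10×5 repeated cross-validation,
Gini-importance ranking with restricted forward feature selection
(recommended size maximizes out-of-bag MCC), partial dependence profiles,
and a 2000-fold label-permutation significance test. A synthetic-data
module plants seed-biased binding sites in random targets so the whole
pipeline is testable without downloads.

Intended users: bioinformaticians post-processing miRanda-style target
scans, and anyone studying feature relevance in miRNA target recognition.

## Worked example

```python
from mirforest import ConfusionMatrix, metrics_from_confusion
from mirforest.evaluation import truncate

# fold-averaged confusion matrix of a 10x5 cross-validated forest
cm = ConfusionMatrix(tp=425, tn=293.6, fp=48.4, fn=57)
m = metrics_from_confusion(cm)
print(f"ACC {truncate(m.acc,2)}  SEN {truncate(m.sen,2)}  "
      f"SPE {truncate(m.spe,2)}  MCC {truncate(m.mcc,3)}")
```

prints `ACC 87.2  SEN 88.17  SPE 85.84  MCC 0.737` — 87.2% of sites
classified correctly, 88.17% of true targets recovered, 85.84% of
pseudo-targets rejected, with a balanced-quality MCC of 0.737 (printed
precision truncates toward zero; see `docs/methods.md`).

End to end on simulated data:

```python
import mirforest as mf

table = mf.generate_feature_table(mf.SyntheticConfig(n_pos=60, n_neg=60, rng_seed=7))
forest = mf.train_forest(table, mf.RFConfig(rng_seed=7))
print("rows:", len(table))
print(f"OOB error: {forest.oob_error:.3f}")
for name, imp in mf.rank_features_by_gini(forest)[:5]:
    print(f"  {name:18s} {imp:.3f}")
cv = mf.repeated_cv(table, mf.RFConfig(rng_seed=7), k=10, repeats=5, seed=7)
print(f"CV AUC: {cv.summary['auc'][0]:.3f} +/- {cv.summary['auc'][1]:.3f}")
```

prints

```
rows: 70
OOB error: 0.129
  position_5         0.126
  alignment_score    0.110
  mfe_seed           0.056
  position_16        0.044
  mfe_total          0.043
CV AUC: 0.920 +/- 0.031
```

Of 120 simulated pairs, 70 planted sites pass the aligner's filters; the
forest ranks seed-region and alignment-strength features on top and ranks
held-out sites with AUC 0.92.

The same workflow is scriptable from the shell:

```sh
mirforest simulate --n-pos 200 --n-neg 200 --seed 1 --out-prefix sim
mirforest align --mirna sim_mirna.fasta --targets sim_targets.fasta --out report.txt
mirforest extract --alignments report.txt --labels sim_labels.tsv --out features.tsv
mirforest train --features features.tsv --ntree 500 --seed 1 --model rf.joblib
mirforest refine --report report.txt --model rf.joblib --out refined.tsv
```

`mirforest run --out-dir run1` executes the whole chain with provenance
stamps; `refine` re-scores any miRanda-style report with a trained model.

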