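"""Run the complete pipeline on a small synthetic cohort.

Equivalent to ``pituradiomics run-all --out runs/demo --seed 1``: generate
phantoms, segment, extract features for the original and eroded ROI
variants, select features per variant, compute out-of-fold SVM scores, the
ROC cutoff, the per-variant confusion table, and the survival analysis.
Writes a run directory and prints the headline numbers.
"""

import json

from pituradiomics import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="runs/demo", seed=1, n_cases=24,
                     grid_shape=(48, 48, 18), selection_repeats=2,
                     max_features=2, cv_folds=6)
out = run_pipeline(cfg)
summary = json.loads((out / "reports" / "summary.json").read_text())

print(f"run directory: {out}")
print(f"median segmentation Dice: {summary['median_dice']:.3f}")
print("\nper-variant confusion (TP/TN/FP/FN, accuracy, AUC):")
for row in summary["confusion_by_variant"]:
    print(f"  {row['variant']:12s} {row['tp']:2d}/{row['tn']:2d}/"
          f"{row['fp']:2d}/{row['fn']:2d}  acc {row['accuracy']:.2f}  "
          f"AUC {row['auc']:.2f}  selected: {row['selected']}")
lr = summary["logrank"]
print(f"\nKaplan-Meier split at SVM-score cutoff {lr['cutoff']:.3f}: "
      f"log-rank p = {lr['p']:.2e}")
print("high-score cases progress sooner, mirroring the clinical finding.")
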