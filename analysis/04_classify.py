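#!/usr/bin/env python
"""MVPA classification of the GBC maps.

Runs the study's five contrasts under leave-one-subject-out CV: the
four-class Gaussian-process classification plus the binary SVM contrasts
(depressed ET vs each other group, primary depression vs controls), all on
a linear kernel with train-fold mean-centering.  Writes one metrics JSON
per contrast under results/classification/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from gbcmvpa.mvpa import FeatureMatrix, ModelSpec, compute_metrics, run_losocv
from gbcmvpa.pipeline import DEFAULT_CONTRASTS

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_features() -> FeatureMatrix:
    z = np.load(ROOT / "features.npz", allow_pickle=False)
    return FeatureMatrix(X=z["X"], subject_ids=list(z["subject_ids"]), labels=z["labels"])


def main() -> None:
    features = load_features()
    outdir = ROOT / "classification"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, groups in DEFAULT_CONTRASTS:
        sel = np.isin(features.labels, groups)
        sub = FeatureMatrix(X=features.X[sel],
                            subject_ids=[s for s, k in zip(features.subject_ids, sel) if k],
                            labels=features.labels[sel])
        model = ModelSpec(algorithm="svm" if len(groups) == 2 else "gpc-multiclass")
        report = compute_metrics(run_losocv(sub, model))
        report.save(outdir / f"{name}.json")
        line = f"{name:12s} ({model.algorithm}): balanced {100 * report.balanced_accuracy:6.2f}%, " \
               f"total {100 * report.total_accuracy:6.2f}%"
        if report.roc_auc is not None:
            line += f", AUC {report.roc_auc:.3f}"
        if len(groups) > 2:
            det_sens = 100 * report.per_class.loc["DET", "sensitivity"]
            line += f", DET sensitivity {det_sens:.2f}%"
        print(line)
    print(f"wrote metrics under {outdir}")


if __name__ == "__main__":
    main()
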