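#!/usr/bin/env python
"""Train the six-class behaviour classifier on the aviary session.

Subsamples the 100 Hz aviary trace to 25 Hz (every fourth sample),
windows it into 16-sample windows, extracts features, trains the
boosted-tree model on a stratified 80% split and evaluates on the
held-out 20%.  Writes the model to scratch/sim/model.json and the
held-out confusion matrix to results/confusion_matrix.csv.
"""

import argparse
from pathlib import Path

import accelflight as af
from accelflight import classify as cl
from accelflight.synthetic import read_trace_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    trace, truth = read_trace_csv(ROOT / "scratch" / "sim" / "aviary_100hz.csv")
    tr25 = af.subsample(trace, 4)
    lab25 = truth.labels[::4]
    windows = cl.make_windows(tr25, 16)
    features = cl.extract_features(tr25, windows)
    labels = cl.window_true_labels(lab25, windows, tr25.sample_rate)
    print(f"{len(windows)} windows of 16 samples ({16 / tr25.sample_rate:.2f} s) at 25 Hz")

    train_idx, test_idx = cl.stratified_split(len(features), labels.labels, 0.2,
                                              seed=args.seed)
    model = cl.train_classifier(features.iloc[train_idx], labels.labels[train_idx],
                                seed=args.seed)
    model.save(ROOT / "scratch" / "sim" / "model.json")

    pred = cl.predict(model, features.iloc[test_idx], 16, tr25.sample_rate)
    cm = cl.confusion(labels.labels[test_idx], pred)
    cm.counts.to_csv(ROOT / "results" / "confusion_matrix.csv")
    print("held-out confusion matrix -> results/confusion_matrix.csv")
    print(f"held-out accuracy {100 * cm.accuracy():.1f}%")
    for cls in cm.classes:
        print(f"  {cls:14s} recall {cm.recall_pct()[cls]:5.1f}%  "
              f"precision {cm.precision_pct()[cls]:5.1f}%")


if __name__ == "__main__":
    main()
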