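#!/usr/bin/env python
"""Classify the session condition from the physiological feature table.

Fits the model battery on the per-window features: a multinomial
logistic regression over baseline / visual / code with baseline as the
reference category, plus the three binary contrasts — each with
backward-elimination feature selection, a likelihood-ratio chi-square
against the null model (df = (classes-1) x retained predictors), and
accuracy / macro precision / macro recall.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cogload import pipeline as pl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/feature_table.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/model_report.json"))
    ap.add_argument("--scheme", choices=["in-sample", "k-fold"], default="in-sample")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    report = pl.classification_report(
        table, schemes=(args.scheme,), random_state=args.seed
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=1))

    print(f"model report -> {args.out}")
    for name, entry in report.items():
        m = entry["metrics"][args.scheme]
        print(
            f"{name:6s} {entry['kind']:11s} chi2={entry['chi_square']:8.2f} "
            f"df={entry['df']:3d} acc={m['accuracy']:6.2f} "
            f"prec={m['precision']:6.2f} rec={m['recall']:6.2f} "
            f"({len(entry['selected_features'])} features retained)"
        )


if __name__ == "__main__":
    main()
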