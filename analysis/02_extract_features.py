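#!/usr/bin/env python
"""Preprocess signals and extract the per-window feature table.

Cleans each PPG recording (DC removal, Savitzky-Golay detrending),
detects pulse peaks, decomposes skin conductance into tonic and phasic
components, cuts everything into 60-s windows and emits the labelled
feature table (19 HRV + 9 GSR features per window, 24 accelerometer
features with ``--accel``).
"""

import argparse
from pathlib import Path

from cogload import features as ft
from cogload import pipeline as pl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results/feature_table.csv"))
    ap.add_argument("--accel", action="store_true", help="include accelerometer features")
    ap.add_argument("--cda-fs-work", type=float, default=10.0,
                    help="working rate of the EDA deconvolution (Hz)")
    args = ap.parse_args()

    study = pl.read_study(args.study)
    table = ft.build_feature_table(
        study, include_accel=args.accel, cda_fs_work=args.cda_fs_work
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    n_feat = len(table.columns) - 3
    print(f"{len(table)} windows x {n_feat} features -> {args.out}")
    print(table.groupby("label").size().rename("windows").to_string())


if __name__ == "__main__":
    main()
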