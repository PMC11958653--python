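#!/usr/bin/env python
"""Score the questionnaires and run the subjective statistics battery.

NASA-TLX cognitive load and its six subscales are compared between the
visual- and code-based sessions with Shapiro-gated paired tests; the
three short-DSSQ states (engagement, distress, worry) go through a
repeated-measures ANOVA over the pre / post-visual / post-code
administrations with Mauchly's sphericity check, Huynh-Feldt correction
on violation, and Holm-adjusted pairwise post-hocs.
"""

import argparse
from pathlib import Path

from cogload import pipeline as pl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = pl.read_study(args.study)
    tlx = pl.tlx_comparison_table(study)
    dssq = pl.dssq_anova_table(study)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    tlx.to_csv(args.out_dir / "tlx_comparison.csv", index=False)
    dssq.to_csv(args.out_dir / "dssq_anova.csv", index=False)

    print("NASA-TLX visual vs code (negative effect = code higher):")
    print(tlx.round(4).to_string(index=False))
    print("\nDSSQ repeated-measures ANOVA with post-hocs:")
    print(dssq.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
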