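# cogload

Psychophysiological analysis of how work-instruction format affects
cognitive load and operational efficiency, built as a tested, reusable
pipeline and exercised end-to-end on a synthetic study generator with
known ground truth.

The study design it implements: participants complete a seated baseline
recording and two counterbalanced assembly sessions — one guided by
*visual* step-by-step instructions (low cognitive load) and one by a
symbolic *code* notation (high load) — while wearing a PPG + skin
conductance sensor on the non-dominant hand and a wrist accelerometer
on the dominant hand. Each session lasts at least five minutes and
until every assigned block pattern has been built three times. After
each session participants fill in the NASA-TLX and the short DSSQ;
assembly precision is scored from fiducial-marker centers of the placed
blocks.

## What the pipeline computes

* **Preprocessing** — DC removal, Savitzky–Golay detrending, pulse-peak
  detection with sub-sample refinement, RR-interval extraction, and
  non-overlapping 60-s segmentation.
* **EDA decomposition** — continuous decomposition analysis:
  `SC = SC_tonic + SC_phasic`, with the phasic part modelled as a
  non-negative sudomotor driver convolved with a Bateman kernel
  `k(t) = exp(-t/τ₂) − exp(-t/τ₁)` and recovered by ridge-regularized
  non-negative deconvolution; SCR events (onset, peak, amplitude,
  rise/decay times) are detected on the phasic component.
* **Features per 60-s window** — 19 HRV features (RMSSD, MEAN, MEDIAN,
  SDRR, SDSD, SDRR_RMSSD, HR, pNN25, pNN50, SD1, SD2, kurtosis,
  skewness, VLF/LF/HF/TP band powers, LF/HF and HF/LF), 9 skin
  conductance features (areas, peak count, mean rise/decay time,
  entropy, SDs, band power), and 24 accelerometer features (six
  statistics × X/Y/Z/resultant).
* **Questionnaires** — NASA-TLX overall cognitive load (raw RTLX mean
  or pairwise-weighted) with the performance-direction convention, and
  short-DSSQ engagement / distress / worry on 0–32.
* **Assembly precision** — sample SD of observed-minus-reference
  pairwise Euclidean distances between marker centers; invariant to
  rigid motion of the whole assembly, averaged over trials per session.
* **Statistics** — Shapiro–Wilk-gated paired comparisons (Student's
  paired t with Cohen's d, or Wilcoxon signed-rank with Pratt zeros,
  exact small-sample p-values and matched rank-biserial effect size);
  one-way repeated-measures ANOVA with Mauchly's sphericity test,
  Huynh–Feldt correction on violation, and Holm-adjusted post-hocs.
* **Classification** — binary and multinomial logistic regression of
  session condition from the feature table, with backward-elimination
  feature selection, likelihood-ratio chi-square vs the null model
  (`df = (classes − 1) × retained predictors`), and accuracy / macro
  precision / macro recall, in-sample or stratified k-fold.
* **Synthetic studies** — `cogload.synthetic` generates the whole
  protocol (signals, questionnaires, repetition schedules, block
  placements) with condition-dependent parameters and retains the
  generating ground truth, so every stage can be tested by recovery.

## Worked example

The numbered drivers under `analysis/` run the study end to end (here a
desk-scale study: 6 participants at 50 Hz):

```
python analysis/01_simulate_study.py --seed 1 --out results/study
python analysis/02_extract_features.py --study results/study --out results/feature_table.csv
python analysis/03_subjective_stats.py --study results/study --out-dir results
python analysis/04_performance_analysis.py --study results/study
python analysis/05_classification.py --features results/feature_table.csv
```

With seed 1 the simulation driver prints the session means

```
session  ntr  tct_min
code     6.00    7.92
visual  10.17    5.29
```

— more repetitions and shorter completion time under visual
instructions, because code-based repetitions are slower and sessions
extend past the five-minute floor until each pattern is built three
times. The performance driver adds mean precision SD 5.41 (visual) vs
3.37 (code): the slower code condition places blocks more precisely.
The subjective battery reports cognitive load visual vs code with a
paired-t effect size of −3.91 (code far higher on this small sample;
at the full study scale the generator injects the calibrated means
39.8 vs 57.2). The classification driver ends with

```
B-V-C  multinomial chi2=   70.99 df=  6 acc= 70.97 ...
B-C    binary      chi2=   54.48 df=  2 acc= 95.24 ...
```

— the baseline-vs-code contrast is the easiest boundary, and every
model's likelihood-ratio df equals (classes − 1) × retained features.

The same machinery is available programmatically through
`cogload.pipeline.RunConfig` / `run_pipeline`, which execute all stages
from a single config + seed and write every table, the model report and
a manifest with a config hash (identical config + seed ⇒ identical
outputs).

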