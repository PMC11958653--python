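"""End-to-end orchestration and artifact plumbing.

Runs the full analysis — synthetic-study generation (or ingestion of a
study directory), preprocessing, EDA decomposition, feature extraction,
questionnaire scoring, assembly precision, the paired/repeated-measures
statistics battery and condition classification — and writes every
result as a delimited table or JSON report plus a manifest with the
configuration hash and seed.  Identical (config, seed) produces
identical outputs.

Study directory layout (written by :func:`write_study`, read back by
:func:`read_study`):

    manifest.json                    study design, labels, scalar truth
    reference_patterns.json          pattern_id -> piece centers
    questionnaires.csv               participant_id, session, instrument, item, value
    trials.csv                       participant_id, session, trial_id,
                                     pattern_id, piece_id, cx, cy
    <participant>/<label>_ppg.csv    time_s, value
    <participant>/<label>_gsr.csv    time_s, value
    <participant>/<label>_accel.csv  time_s, x, y, z
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import models as mdl
from . import precision as prec
from . import questionnaires as qn
from . import stats as st
from . import synthetic as syn
from .preprocess import RawSignal, TriaxialSignal

log = logging.getLogger("cogload")

TASK_CONDITIONS = ("visual", "code")
DSSQ_SESSIONS = ("pre", "post_visual", "post_code")


@dataclass
class RunConfig:
    """One auditable document holding every pipeline parameter."""

    study: syn.StudyConfig | None = None
    input_dir: str | None = None
    output_dir: str = "results/run"
    include_accel: bool = False
    tlx_mode: str = "raw"
    printed_rmssd: bool = False
    window_s: float = 60.0
    cda_fs_work: float = 25.0
    min_scr_amplitude: float = 0.01
    alpha: float = 0.05
    posthoc_adjust: str = "holm"
    selection_criterion: str = "wald"
    removal_alpha: float = 0.10
    evaluation_scheme: str = "in-sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.study is None) == (self.input_dir is None):
            raise ValueError("exactly one of study / input_dir must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        study = doc.pop("study", None)
        if study is not None:
            effects = study.pop("effects", None)
            if effects is not None:
                study["effects"] = syn.ConditionEffects(**effects)
            study = syn.StudyConfig(**study)
        return cls(study=study, **doc)

    def content_hash(self) -> str:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# questionnaire scoring across a study


def tlx_scores(study: syn.SyntheticStudy, mode: str = "raw") -> pd.DataFrame:
    """Cognitive load + subscales per participant and task session."""
    rows = []
    for p, s in study.sessions():
        if s.tlx is None:
            continue
        scored = qn.score_tlx(s.tlx, mode=mode)
        rows.append({"participant_id": p.participant_id, "session": s.label, **scored})
    return pd.DataFrame(rows)


def dssq_scores(study: syn.SyntheticStudy) -> pd.DataFrame:
    """DSSQ state scores per participant and administration."""
    rows = []
    for p, s in study.sessions():
        scored = qn.score_dssq(s.dssq)
        rows.append(
            {"participant_id": p.participant_id, "session": s.dssq_session, **scored}
        )
    return pd.DataFrame(rows)


def _paired_frame(
    scores: pd.DataFrame, measures: list[str], first: str, second: str
) -> pd.DataFrame:
    wide = scores.set_index(["participant_id", "session"])
    rows = []
    for m in measures:
        pivot = wide[m].unstack("session")[[first, second]].dropna()
        res = st.paired_compare(pivot[first].to_numpy(), pivot[second].to_numpy())
        rows.append(
            {
                "measure": m,
                "shapiro_p": res.shapiro_p,
                "test": res.test_name,
                "statistic": res.statistic,
                "Z": res.z if res.z is not None else np.nan,
                "effect_size": res.effect_size,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def tlx_comparison_table(
    study: syn.SyntheticStudy, mode: str = "raw"
) -> pd.DataFrame:
    """Visual-vs-code paired comparison of cognitive load and subscales."""
    scores = tlx_scores(study, mode=mode)
    measures = ["cognitive_load", *qn.TLX_SUBSCALES]
    return _paired_frame(scores, measures, "visual", "code")


def dssq_anova_table(
    study: syn.SyntheticStudy,
    alpha_sphericity: float = 0.05,
    posthoc_adjust: str = "holm",
) -> pd.DataFrame:
    """Repeated-measures ANOVA of each DSSQ state over the three sessions."""
    scores = dssq_scores(study)
    wide = scores.set_index(["participant_id", "session"])
    rows = []
    for state in qn.DSSQ_STATES:
        pivot = wide[state].unstack("session")[list(DSSQ_SESSIONS)].dropna()
        res = st.rm_anova(
            pivot.to_numpy(),
            condition_names=list(DSSQ_SESSIONS),
            alpha_sphericity=alpha_sphericity,
            posthoc_adjust=posthoc_adjust,
        )
        for ph in res.posthoc:
            rows.append(
                {
                    "state": state,
                    "mauchly_p": res.mauchly_p,
                    "correction": res.correction,
                    "epsilon_hf": res.epsilon_hf,
                    "anova_p": res.corrected_p,
                    "pair": " vs ".join(ph.pair),
                    "posthoc_p": ph.p_adjusted,
                    "posthoc_effect_size": ph.effect_size,
                }
            )
    return pd.DataFrame(rows)


def performance_scores(study: syn.SyntheticStudy) -> pd.DataFrame:
    """NTR, TCT (min) and mean assembly-precision SD per task session."""
    perf = syn.performance_frame(study)
    rows = []
    for p, s in study.sessions():
        if s.label == "baseline" or not s.trials:
            continue
        results = [
            prec.precision_sd(
                tr.observed, study.reference_patterns[tr.pattern_id], tr.trial_id
            )
            for tr in s.trials
        ]
        rows.append(
            {
                "participant_id": p.participant_id,
                "session": s.label,
                "precision_sd": prec.session_precision(results),
            }
        )
    return perf.merge(pd.DataFrame(rows), on=["participant_id", "session"])


def performance_table(study: syn.SyntheticStudy) -> pd.DataFrame:
    """Visual-vs-code paired comparison of NTR, TCT and precision SD."""
    scores = performance_scores(study)
    return _paired_frame(scores, ["ntr", "tct_min", "precision_sd"], "visual", "code")


def accel_comparison_table(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Visual-vs-code paired comparison of per-axis mean acceleration.

    Segment-level axis means are first averaged within participant and
    session, then compared pairwise across the two task conditions.
    """
    cols = ["meanX", "meanY", "meanZ"]
    agg = (
        feature_table[feature_table["label"].isin(TASK_CONDITIONS)]
        .groupby(["participant_id", "label"])[cols]
        .mean()
        .reset_index()
        .rename(columns={"label": "session"})
    )
    return _paired_frame(agg, cols, "visual", "code")


# ---------------------------------------------------------------------------
# classification reports


def classification_report(
    feature_table: pd.DataFrame,
    feature_names: list[str] | None = None,
    criterion: str = "wald",
    removal_alpha: float = 0.10,
    schemes: tuple[str, ...] = ("in-sample",),
    random_state: int = 0,
) -> dict:
    """Multinomial + three binary logistic models with backward elimination.

    Mirrors the study's model battery: all three conditions against the
    baseline reference, then each pairwise binary contrast.  Returns a
    JSON-serializable report with the selection trace, coefficient and
    p-value tables, likelihood-ratio fit statistics and classification
    metrics for each requested evaluation scheme.
    """
    if feature_names is None:
        feature_names = [
            c
            for c in feature_table.columns
            if c not in ("participant_id", "label", "window_index")
        ]
    contrasts = {
        "B-V-C": (("baseline", "visual", "code"), "baseline"),
        "B-V": (("baseline", "visual"), "baseline"),
        "B-C": (("baseline", "code"), "baseline"),
        "V-C": (("visual", "code"), "visual"),
    }
    report: dict = {}
    for name, (labels, reference) in contrasts.items():
        sub = feature_table[feature_table["label"].isin(labels)].reset_index(drop=True)
        x, y = sub[feature_names], sub["label"]
        selected, trace, fit = mdl.backward_eliminate(
            x, y, reference, criterion=criterion, removal_alpha=removal_alpha
        )
        entry = {
            "kind": fit.kind,
            "reference_class": reference,
            "selected_features": selected,
            "n_candidates": len(feature_names),
            "trace": trace,
            "coefficients": fit.params.round(6).to_dict(),
            "wald_p_values": fit.pvalues.round(6).to_dict(),
            "chi_square": round(fit.chi_square, 3),
            "df": fit.df,
            "model_p": fit.model_p,
            "regularized": fit.regularized,
            "metrics": {},
        }
        for scheme in schemes:
            m = mdl.evaluate(
                fit, x, y, scheme=scheme, random_state=random_state,
                selection_kwargs={"criterion": criterion, "removal_alpha": removal_alpha},
            )
            entry["metrics"][scheme] = {
                "accuracy": round(m.accuracy, 2),
                "precision": round(m.precision, 2),
                "recall": round(m.recall, 2),
            }
        report[name] = entry
    return report


# ---------------------------------------------------------------------------
# study directory I/O


def write_study(study: syn.SyntheticStudy, out_dir: str | Path) -> Path:
    """Serialize a study to the documented directory layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(study.config),
        "participants": [],
    }
    for p in study.participants:
        pdir = out / p.participant_id
        pdir.mkdir(exist_ok=True)
        entry = {"participant_id": p.participant_id, "subgroup": p.subgroup,
                 "sessions": []}
        for s in p.sessions:
            sess = {
                "label": s.label, "order_index": s.order_index,
                "patterns": list(s.patterns), "tct_s": s.tct_s, "ntr": s.ntr,
                "dssq_session": s.dssq_session,
                "rep_times": list(map(float, s.rep_times)),
            }
            if s.ppg is not None:
                pd.DataFrame(
                    {"time_s": s.ppg.times, "value": s.ppg.samples}
                ).to_csv(pdir / f"{s.label}_ppg.csv", index=False)
            if s.gsr is not None:
                pd.DataFrame(
                    {"time_s": s.gsr.times, "value": s.gsr.samples}
                ).to_csv(pdir / f"{s.label}_gsr.csv", index=False)
            if s.accel is not None:
                t = s.accel.start_time + np.arange(s.accel.x.size) / s.accel.fs
                pd.DataFrame(
                    {"time_s": t, "x": s.accel.x, "y": s.accel.y, "z": s.accel.z}
                ).to_csv(pdir / f"{s.label}_accel.csv", index=False)
            entry["sessions"].append(sess)
        manifest["participants"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "reference_patterns.json").write_text(
        json.dumps(
            {
                str(pid): {str(k): list(v) for k, v in pat.centers.items()}
                for pid, pat in study.reference_patterns.items()
            }
        )
    )
    q = pd.concat([syn.tlx_frame(study), syn.dssq_frame(study)], ignore_index=True)
    q.to_csv(out / "questionnaires.csv", index=False)
    syn.trials_frame(study).to_csv(out / "trials.csv", index=False)
    return out


def _infer_fs(time_s: np.ndarray) -> float:
    """Sampling rate from timestamps, snapped to integer Hz when close.

    Rounding in the written timestamps otherwise yields rates like
    50.000000000001 Hz, which silently shortens an exact 60-s recording
    below the segmentation window.
    """
    fs = 1.0 / np.median(np.diff(time_s))
    return round(fs) if abs(fs - round(fs)) < 1e-6 * fs else fs


def _read_signal(path: Path, channel: str) -> RawSignal | None:
    if not path.exists():
        return None
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    fs = _infer_fs(df["time_s"].to_numpy())
    return RawSignal(
        samples=df["value"].to_numpy(), fs=fs, channel=channel,
        start_time=float(df["time_s"].iloc[0]),
    )


def read_study(in_dir: str | Path) -> syn.SyntheticStudy:
    """Load a study directory back into the in-memory containers.

    Columns are addressed by name, so header-order permutations parse
    identically.  Ground truth is not reconstructed from disk.
    """
    root = Path(in_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no participants found: missing {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("participants"):
        raise ValueError(f"no participants found in {manifest_path}")
    cfg_doc = manifest["config"]
    cfg_doc["effects"] = syn.ConditionEffects(**cfg_doc["effects"])
    config = syn.StudyConfig(**cfg_doc)
    refs = {
        int(pid): prec.MarkerPattern(
            centers={k: tuple(v) for k, v in pat.items()}, pattern_id=int(pid)
        )
        for pid, pat in json.loads(
            (root / "reference_patterns.json").read_text()
        ).items()
    }
    q = pd.read_csv(root / "questionnaires.csv")
    trials = pd.read_csv(root / "trials.csv")

    participants = []
    for pentry in manifest["participants"]:
        pid = pentry["participant_id"]
        pdir = root / pid
        sessions = []
        for sess in pentry["sessions"]:
            label = sess["label"]
            ppg = _read_signal(pdir / f"{label}_ppg.csv", "ppg")
            gsr = _read_signal(pdir / f"{label}_gsr.csv", "gsr")
            accel = None
            accel_path = pdir / f"{label}_accel.csv"
            if accel_path.exists():
                adf = pd.read_csv(accel_path)
                accel = TriaxialSignal(
                    x=adf["x"].to_numpy(), y=adf["y"].to_numpy(),
                    z=adf["z"].to_numpy(),
                    fs=_infer_fs(adf["time_s"].to_numpy()),
                )
            tlx = None
            tq = q[(q["participant_id"] == pid) & (q["session"] == label)
                   & (q["instrument"] == "tlx")]
            if not tq.empty:
                vals = dict(zip(tq["item"], tq["value"]))
                tlx = qn.TLXResponse(**{k: float(vals[k]) for k in qn.TLX_SUBSCALES})
            dsession = sess["dssq_session"]
            items = {}
            for state in qn.DSSQ_STATES:
                dq = q[(q["participant_id"] == pid) & (q["session"] == dsession)
                       & (q["instrument"] == f"dssq_{state}")].sort_values("item")
                items[state] = tuple(int(v) for v in dq["value"])
            dssq = qn.DSSQResponse(**items)
            trecs = []
            tsub = trials[(trials["participant_id"] == pid)
                          & (trials["session"] == label)]
            for trial_id, group in tsub.groupby("trial_id", sort=True):
                pattern_id = int(group["pattern_id"].iloc[0])
                centers = {
                    row["piece_id"]: (float(row["cx"]), float(row["cy"]))
                    for _, row in group.iterrows()
                }
                trecs.append(
                    syn.TrialRecord(
                        trial_id=trial_id, pattern_id=pattern_id,
                        observed=prec.MarkerPattern(centers, pattern_id),
                        t_start=0.0,
                    )
                )
            sessions.append(
                syn.SessionData(
                    label=label, order_index=sess["order_index"],
                    patterns=tuple(sess["patterns"]), ppg=ppg, gsr=gsr,
                    accel=accel, rep_times=list(sess["rep_times"]),
                    tct_s=sess["tct_s"], ntr=sess["ntr"], trials=trecs,
                    tlx=tlx, dssq=dssq, dssq_session=dsession, ground_truth={},
                )
            )
        participants.append(
            syn.ParticipantData(participant_id=pid, subgroup=pentry["subgroup"],
                                sessions=sessions)
        )
    return syn.SyntheticStudy(
        config=config, participants=participants, reference_patterns=refs
    )


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage and write all artifacts.

    Stage order: generate/ingest → preprocess + decompose + features →
    questionnaires → precision/performance → statistics → models.
    Returns the report dictionary that was also written to disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.study is not None:
        study_cfg = dataclasses.replace(config.study, seed=config.seed)
        log.info("generating synthetic study (n=%d)", study_cfg.n_participants)
        study = syn.generate_study(study_cfg)
    else:
        log.info("reading study from %s", config.input_dir)
        study = read_study(config.input_dir)

    log.info("extracting features")
    table = feat.build_feature_table(
        study,
        include_accel=config.include_accel,
        window_s=config.window_s,
        cda_fs_work=config.cda_fs_work,
        min_scr_amplitude=config.min_scr_amplitude,
    )
    table.to_csv(out / "feature_table.csv", index=False)

    log.info("questionnaires and performance")
    tlx_table = tlx_comparison_table(study, mode=config.tlx_mode)
    dssq_table = dssq_anova_table(
        study, alpha_sphericity=config.alpha, posthoc_adjust=config.posthoc_adjust
    )
    perf_table = performance_table(study)
    tlx_table.to_csv(out / "tlx_comparison.csv", index=False)
    dssq_table.to_csv(out / "dssq_anova.csv", index=False)
    perf_table.to_csv(out / "performance_comparison.csv", index=False)
    accel_table = None
    if config.include_accel and not table.empty:
        accel_table = accel_comparison_table(table)
        accel_table.to_csv(out / "accel_comparison.csv", index=False)

    log.info("classification models")
    model_report = classification_report(
        table,
        criterion=config.selection_criterion,
        removal_alpha=config.removal_alpha,
        schemes=(config.evaluation_scheme,),
        random_state=config.seed,
    )
    (out / "model_report.json").write_text(json.dumps(model_report, indent=1))

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_participants": len(study.participants),
        "n_feature_rows": int(len(table)),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    report = {
        "manifest": manifest,
        "tlx": tlx_table.to_dict("records"),
        "dssq": dssq_table.to_dict("records"),
        "performance": perf_table.to_dict("records"),
        "models": model_report,
    }
    if accel_table is not None:
        report["accel"] = accel_table.to_dict("records")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
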