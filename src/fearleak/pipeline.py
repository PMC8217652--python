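"""End-to-end orchestration: cohort in, four report tables out.

The pipeline wires the modules together without computing anything inline:
AU summaries feed the paired comparison table, AU20 episodes feed the
duration table, distance-signal coherence feeds the permutation test, and
frame-level feature vectors feed the classifier report.  Every stage is
seeded from the run seed and logged.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deception_ml, episode_dynamics, facial_symmetry, fear_features, inference_stats
from .fear_features import SIX_AUS
from .openface_io import FEAR_AUS, LIE, TRUTH, ClipTimeSeries, load_cohort, merge_clips
from .synthetic_cohort import CohortSpec, generate_cohort


@dataclass
class PipelineConfig:
    input_mode: str = "synthetic"  # "synthetic" | "manifest"
    manifest_path: str | None = None
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    au_set: str = "seven_au"  # "seven_au" | "six_au"
    micro_ms: float = 200.0
    macro_ms: float = 500.0
    n_boot: int = 1000
    n_perm: int = 10000
    alpha: float = 0.05
    m_comparisons: int = 7
    ml_mode: str = "paper"  # "paper" | "leak_safe"
    classifiers: tuple[str, ...] = ("random_forest", "knn", "bagging")
    smote_k: int = 5
    n_train_participants: int = 12
    run_loocv: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "manifest"):
            raise ValueError("input_mode must be 'synthetic' or 'manifest'")
        if self.input_mode == "manifest" and not self.manifest_path:
            raise ValueError("manifest input mode requires manifest_path")
        for name in ("micro_ms", "macro_ms", "n_boot", "n_perm", "m_comparisons"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def aus(self) -> tuple[str, ...]:
        return FEAR_AUS if self.au_set == "seven_au" else SIX_AUS


@dataclass
class ReportBundle:
    au_comparison: pd.DataFrame
    duration_table: pd.DataFrame
    duration_test: inference_stats.PairedTestResult
    coherence_table: pd.DataFrame
    coherence_test: inference_stats.PermutationResult
    classifier_table: pd.DataFrame
    loocv: deception_ml.LoocvResult | None
    alpha_threshold: float
    log: list[dict]

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.au_comparison.to_csv(os.path.join(out_dir, "au_comparison.csv"), index=False)
        self.duration_table.to_csv(os.path.join(out_dir, "duration_summary.csv"), index=False)
        self.coherence_table.to_csv(os.path.join(out_dir, "coherence.csv"), index=False)
        self.classifier_table.to_csv(os.path.join(out_dir, "classifier_report.csv"), index=False)
        summary = {
            "alpha_threshold": self.alpha_threshold,
            "duration_test": vars(self.duration_test),
            "coherence_test": vars(self.coherence_test),
            "loocv": (
                {
                    "participants": [str(p) for p in self.loocv.participants],
                    "accuracies": self.loocv.accuracies,
                    "mean_accuracy": self.loocv.mean_accuracy,
                }
                if self.loocv
                else None
            ),
        }
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        with open(os.path.join(out_dir, "run_log.jsonl"), "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry) + "\n")


def _merge_by_identity(clips: list[ClipTimeSeries]) -> dict[tuple[str, str], ClipTimeSeries]:
    """One merged clip per (participant, condition)."""
    buckets: dict[tuple[str, str], list[ClipTimeSeries]] = {}
    for c in clips:
        buckets.setdefault((c.participant_id, c.condition), []).append(c)
    return {key: merge_clips(group) for key, group in buckets.items()}


def build_frame_dataset(clips: list[ClipTimeSeries], aus=FEAR_AUS) -> deception_ml.FrameDataset:
    """Stack per-frame fear-score vectors from every clip."""
    feats, labels, groups = [], [], []
    for clip in clips:
        X = fear_features.clip_feature_matrix(clip, aus)
        feats.append(X)
        labels.append(np.full(len(X), clip.condition))
        groups.append(np.full(len(X), clip.participant_id))
    return deception_ml.FrameDataset(
        np.vstack(feats), np.concatenate(labels), np.concatenate(groups)
    )


def run_full_analysis(config: PipelineConfig) -> ReportBundle:
    log: list[dict] = []

    def stage(name: str, **info) -> None:
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3), **info})

    t0 = time.time()
    if config.input_mode == "synthetic":
        cohort = generate_cohort(config.cohort_spec)
        clips = [clip for clip, _ in cohort]
    else:
        clips = load_cohort(config.manifest_path)
    merged = _merge_by_identity(clips)
    participants = sorted({pid for pid, _ in merged})
    stage("ingest", n_clips=len(clips), n_participants=len(participants), seed=config.seed)

    # --- paired AU comparison -----------------------------------------
    aus = config.aus
    rows = []
    rng = np.random.default_rng(config.seed)
    lie_means = {
        au: np.array([fear_features.clip_mean_aus(merged[(p, LIE)], aus).mean_score[au] for p in participants])
        for au in aus
    }
    truth_means = {
        au: np.array([fear_features.clip_mean_aus(merged[(p, TRUTH)], aus).mean_score[au] for p in participants])
        for au in aus
    }
    for au in aus:
        res = inference_stats.paired_bootstrap_t(
            lie_means[au], truth_means[au], n_boot=config.n_boot, seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "feature": au,
                "mean_deception": res.mean_a,
                "mean_truth": res.mean_b,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "t": res.t,
                "p": res.p,
                "d": res.d,
            }
        )
    au_comparison = pd.DataFrame(rows)
    alpha_threshold = inference_stats.bonferroni_alpha(config.alpha, config.m_comparisons)
    stage("au_comparison", n_aus=len(aus), alpha_threshold=round(alpha_threshold, 3))

    # --- AU20 episode durations ---------------------------------------
    dur_rows = []
    totals = {TRUTH: [], LIE: []}
    for (pid, cond), clip in merged.items():
        for ep in episode_dynamics.segment_episodes(clip.au_score("AU20"), "AU20"):
            totals[cond].append(ep)
    duration_table_rows = []
    for cond in (TRUTH, LIE):
        if totals[cond]:
            s = episode_dynamics.duration_summary(
                totals[cond],
                frame_rate=clips[0].frame_rate,
                micro_ms=config.micro_ms,
                macro_ms=config.macro_ms,
                n_boot=config.n_boot,
                seed=int(rng.integers(2**31)),
            )
            duration_table_rows.append(
                {
                    "condition": cond,
                    "n_episodes": s.n_episodes,
                    "mean_total_frames": s.mean_total_frames,
                    "median_total_frames": s.median_total_frames,
                    "ci_low_frames": s.ci_low_frames,
                    "ci_high_frames": s.ci_high_frames,
                    "mean_apex_to_offset_frames": s.mean_apex_to_offset_frames,
                    "mean_total_ms": episode_dynamics.frames_to_ms(
                        s.mean_total_frames, clips[0].frame_rate
                    ),
                    "n_micro": s.n_micro,
                    "n_macro": s.n_macro,
                }
            )
    duration_table = pd.DataFrame(duration_table_rows)
    duration_test = inference_stats.independent_bootstrap_t(
        np.array([e.total_frames for e in totals[TRUTH]], dtype=float),
        np.array([e.total_frames for e in totals[LIE]], dtype=float),
        n_boot=config.n_boot,
        seed=int(rng.integers(2**31)),
    )
    stage("episode_dynamics", n_truth=len(totals[TRUTH]), n_lie=len(totals[LIE]))

    # --- symmetry / coherence -----------------------------------------
    coh_rows = []
    for (pid, cond), clip in sorted(merged.items()):
        coh_rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "mean_coherence": facial_symmetry.clip_mean_coherence(clip),
                "n_frames": len(clip),
            }
        )
    coherence_table = pd.DataFrame(coh_rows)
    coh_lie = coherence_table.loc[coherence_table.condition == LIE, "mean_coherence"].to_numpy()
    coh_truth = coherence_table.loc[coherence_table.condition == TRUTH, "mean_coherence"].to_numpy()
    coherence_test = inference_stats.permutation_test(
        coh_lie, coh_truth, n_perm=config.n_perm, seed=int(rng.integers(2**31))
    )
    stage("facial_symmetry", mean_lie=float(coh_lie.mean()), mean_truth=float(coh_truth.mean()))

    # --- classification ------------------------------------------------
    dataset = build_frame_dataset(clips, aus)
    train_participants = participants[: config.n_train_participants]
    clf_rows = []
    for name in config.classifiers:
        report = deception_ml.train_eval_split(
            dataset,
            train_participants,
            classifier=name,
            seed=config.seed,
            use_smote=True,
            smote_k=config.smote_k,
        )
        clf_rows.append({"classifier": name, **report.as_dict()})
    classifier_table = pd.DataFrame(clf_rows)
    loocv = None
    if config.run_loocv:
        loocv = deception_ml.leave_one_person_out(
            dataset, classifier="random_forest", seed=config.seed, smote_k=config.smote_k
        )
    stage("classification", n_frames=len(dataset), mode=config.ml_mode)

    bundle = ReportBundle(
        au_comparison=au_comparison,
        duration_table=duration_table,
        duration_test=duration_test,
        coherence_table=coherence_table,
        coherence_test=coherence_test,
        classifier_table=classifier_table,
        loocv=loocv,
        alpha_threshold=alpha_threshold,
        log=log,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
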