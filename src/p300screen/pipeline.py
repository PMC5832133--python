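"""End-to-end orchestration: simulate, preprocess, train, evaluate.

The analysis bookkeeping follows the study design: the first block is
operator training and is excluded; of the remaining 17 analysis
repetitions, the last nine are held out for evaluation and the earlier
eight train the discriminant.  Splits are expressed in global repetition
indices so non-overlap is checkable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from p300screen import erp, evaluation, io, preprocessing
from p300screen.classifier import (
    LassoLdaModel,
    ScoreMatrix,
    fit_lasso_lda,
    score_repetition,
)
from p300screen.config import RunConfig
from p300screen.errors import ConfigurationError
from p300screen.recording import Recording
from p300screen.sequencer import SessionSchedule, build_session
from p300screen.synthetic import generate_recording

logger = logging.getLogger("p300screen")


def analysis_repetitions(block_reps: tuple[int, ...]) -> list[int]:
    """Global repetition indices kept for analysis: every block but the first."""
    total = sum(block_reps)
    return list(range(block_reps[0], total))


def train_eval_split(
    block_reps: tuple[int, ...] = (3, 5, 6, 6), n_eval: int = 9
) -> tuple[list[int], list[int]]:
    """(train, eval) repetition indices: the last n_eval analysis repetitions
    evaluate, the rest train.  With blocks of 3/5/6/6 this trains on Block II
    plus the first half of Block III and evaluates on its last three
    repetitions plus Block IV."""
    analysis = analysis_repetitions(tuple(block_reps))
    if n_eval >= len(analysis):
        raise ConfigurationError(
            f"n_eval={n_eval} leaves no training repetitions of {len(analysis)}"
        )
    return analysis[:-n_eval], analysis[-n_eval:]


def subject_rng(base_seed: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(base_seed, spawn_key=(subject,))
    )


def simulate_subject(
    config: RunConfig, subject: int
) -> tuple[SessionSchedule, Recording]:
    """Schedule and synthetic recording for one subject, seeded per subject."""
    rng = subject_rng(config.seed, subject)
    schedule = build_session(config.timing, rng)
    recording = generate_recording(
        schedule, config.profile, rng, sample_rate=config.sample_rate
    )
    return schedule, recording


def preprocess_subject(
    recording: Recording,
    schedule: SessionSchedule,
    config: RunConfig,
) -> list[preprocessing.Epoch]:
    """Filter the recording and return standardized flash-locked epochs."""
    coeffs = preprocessing.design_bandpass(
        order=config.preprocessing.filter_order,
        band=config.preprocessing.band,
        window_attenuation_db=config.preprocessing.window_attenuation_db,
        sample_rate=recording.sample_rate,
    )
    filtered = preprocessing.apply_filter(recording, coeffs)
    epochs = preprocessing.extract_epochs(filtered, schedule.flash_events())
    return [preprocessing.standardize_epoch(e) for e in epochs]


def features_by_repetition(
    recording: Recording,
    schedule: SessionSchedule,
    config: RunConfig,
) -> dict[int, list[preprocessing.FeatureVector]]:
    """Filter, epoch, standardize, featurize; group by global repetition."""
    grouped: dict[int, list[preprocessing.FeatureVector]] = {}
    for epoch in preprocess_subject(recording, schedule, config):
        fv = preprocessing.featurize(epoch)
        grouped.setdefault(fv.repetition, []).append(fv)
    return grouped


def _stack(features: list[preprocessing.FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([f.values for f in features])
    y = np.array([f.label for f in features], dtype=float)
    return X, y


@dataclass
class SubjectResult:
    """Everything the reports need from one simulated subject."""

    subject: int
    model: LassoLdaModel
    score_matrices: list[ScoreMatrix]
    curve: pd.DataFrame
    summary: dict
    erp_report: pd.DataFrame
    mwut_p: float
    target_peak: float
    nontarget_peak: float


def run_subject(config: RunConfig, subject: int) -> SubjectResult:
    """Full single-subject pass: simulate, preprocess, train, score, evaluate."""
    t0 = time.perf_counter()
    schedule, recording = simulate_subject(config, subject)
    std_epochs = preprocess_subject(recording, schedule, config)
    grouped: dict[int, list[preprocessing.FeatureVector]] = {}
    for epoch in std_epochs:
        fv = preprocessing.featurize(epoch)
        grouped.setdefault(fv.repetition, []).append(fv)
    train_reps, eval_reps = train_eval_split(
        config.timing.block_reps, config.evaluation.n_eval_reps
    )
    if set(train_reps) & set(eval_reps):
        raise ConfigurationError("train and evaluation repetitions overlap")

    train_features = [f for r in train_reps for f in grouped[r]]
    X, y = _stack(train_features)
    model = fit_lasso_lda(
        X,
        y,
        cv_folds=config.classifier.cv_folds,
        n_lambdas=config.classifier.n_lambdas,
        lambda_min_ratio=config.classifier.lambda_min_ratio,
        max_iter=config.classifier.max_iter,
    )

    score_matrices = [score_repetition(model, grouped[r]) for r in eval_reps]
    curve = evaluation.curve_by_l(score_matrices, config.evaluation.l_values)
    summary = evaluation.subject_summary(
        score_matrices, l_report=max(config.evaluation.l_values),
        l_values=config.evaluation.l_values,
    )

    # ERP stage: coherent averages over every analysis repetition
    analysis = set(analysis_repetitions(config.timing.block_reps))
    target_epochs, nontarget_epochs = [], []
    for epoch in std_epochs:
        if epoch.event.repetition not in analysis:
            continue
        (target_epochs if epoch.event.is_target else nontarget_epochs).append(epoch)
    t_avg = erp.coherent_average(target_epochs, "target")
    nt_avg = erp.coherent_average(nontarget_epochs, "nontarget")
    t_peak = erp.peak_in_window(t_avg)
    nt_peak = erp.peak_in_window(nt_avg)
    u_stat, p_raw = erp.compare_windows(t_avg, nt_avg)
    erp_report = pd.DataFrame(
        [
            {
                "condition": "target",
                "n_epochs": t_avg.n_epochs,
                "peak_latency_ms": t_peak.latency_ms,
                "peak_amplitude": t_peak.amplitude,
                "U": u_stat,
                "p_raw": p_raw,
            },
            {
                "condition": "nontarget",
                "n_epochs": nt_avg.n_epochs,
                "peak_latency_ms": nt_peak.latency_ms,
                "peak_amplitude": nt_peak.amplitude,
                "U": u_stat,
                "p_raw": p_raw,
            },
        ]
    )
    logger.info(
        "subject %d: %d train rows, lambda=%.4g, |support|=%d, %.1f s",
        subject,
        X.shape[0],
        model.lam,
        model.support.size,
        time.perf_counter() - t0,
    )
    return SubjectResult(
        subject=subject,
        model=model,
        score_matrices=score_matrices,
        curve=curve,
        summary=summary,
        erp_report=erp_report,
        mwut_p=p_raw,
        target_peak=t_peak.amplitude,
        nontarget_peak=nt_peak.amplitude,
    )


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> dict:
    """Run every subject and aggregate the study-level tables.

    Returns a dict with the per-l median/IQR curve ('sample_curve'), the
    per-subject table ('subject_table'), per-subject results, and group ERP
    statistics.  Artifacts (config, tables, models, manifest) land under
    config.output_dir when write_artifacts is true.
    """
    t0 = time.perf_counter()
    results = [run_subject(config, s) for s in range(config.n_subjects)]
    sample_curve = evaluation.aggregate_curves([r.curve for r in results])
    subject_table = pd.DataFrame(
        [{"subject": r.subject, **r.summary} for r in results]
    ).sort_values(["j", "subject"], ascending=[False, True], ignore_index=True)

    p_raw = [r.mwut_p for r in results]
    p_corr = erp.bonferroni(p_raw)
    erp_group = {
        "n_subjects": len(results),
        "mwut_rejections_p005_corrected": int((p_corr < 0.005).sum()),
    }
    if len(results) >= 5:  # the paired signed-rank test needs >= 5 pairs
        w_stat, group_p = erp.group_peak_test(
            [r.target_peak for r in results], [r.nontarget_peak for r in results]
        )
        erp_group["wilcoxon_W"] = w_stat
        erp_group["wilcoxon_p"] = group_p
    out = {
        "config": config,
        "results": results,
        "sample_curve": sample_curve,
        "subject_table": subject_table,
        "erp_group": erp_group,
    }
    if write_artifacts:
        outdir = Path(config.output_dir) / config.hash()
        outdir.mkdir(parents=True, exist_ok=True)
        config.save(outdir / "config.yaml")
        io.write_table(sample_curve, outdir / "sample_curve.tsv")
        io.write_table(subject_table, outdir / "subject_table.tsv")
        artifacts = ["config.yaml", "sample_curve.tsv", "subject_table.tsv"]
        for r in results:
            name = f"model_subject{r.subject:02d}.json"
            io.save_model(r.model, outdir / name, extra={"config_hash": config.hash()})
            artifacts.append(name)
            ename = f"erp_subject{r.subject:02d}.tsv"
            io.write_table(r.erp_report, outdir / ename)
            artifacts.append(ename)
        manifest = {
            "config_hash": config.hash(),
            "artifacts": artifacts,
            "erp_group": erp_group,
            "wall_time_s": round(time.perf_counter() - t0, 2),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        out["output_dir"] = outdir
    logger.info("pipeline: %d subjects in %.1f s", len(results), time.perf_counter() - t0)
    return out
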