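"""End-to-end pipeline: simulate (or load) -> preprocess -> PCA -> LOO SVM
-> permutation null -> significance -> severity prediction.

Every stage is a pure function of its inputs and the seed, so a rerun with
the same configuration produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classify import loo_svm, tuning_curve
from .features import fit_pca
from .inference import (
    CVSpec,
    permutation_null,
    p_value,
    predict_severity,
    significance_thresholds,
)
from .io import load_cohort, save_beta_matrix, save_cohort, save_report
from .preprocess import PreprocessOptions, preprocess_cohort
from .simulate import SimulationConfig, make_design, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("nirscv")


@dataclass
class PipelineConfig:
    """All pipeline parameters with defaults reproducing the reference
    acquisition and analysis settings: 54 channels at 30 samples/s, 180-s
    runs of 18-s task / 12-s rest blocks, 32 principal components, the 10
    best PCs as SVM input, nested selection, C = 1, 1000 permutations, and
    significance levels 0.05 / 0.005."""

    # acquisition / design
    n_channels: int = 54
    sample_rate: float = 30.0
    total_duration: float = 180.0
    task_epoch: float = 18.0
    rest_epoch: float = 12.0
    # simulation (used when no cohort_path is given)
    effect_scale: float = 1.0
    noise_sd: float = 1.0
    global_sd: float = 1.0
    drift_sd: float = 0.5
    oxy_deoxy_ratio: float = -0.5
    # preprocessing
    detrend_cutoff: float = 128.0
    # decomposition / classification
    n_pc: int = 32
    k: int = 10
    k_range: tuple[int, ...] | None = None
    mode: str = "nested"
    C: float = 1.0
    # inference
    n_perm: int = 1000
    alphas: tuple[float, ...] = (0.05, 0.005)
    severity_n_perm: int = 10_000
    seed: int = 0
    # I/O
    cohort_path: str | None = None

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_channels=self.n_channels,
            effect_scale=self.effect_scale,
            noise_sd=self.noise_sd,
            global_sd=self.global_sd,
            drift_sd=self.drift_sd,
            oxy_deoxy_ratio=self.oxy_deoxy_ratio,
            seed=self.seed,
        )


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            if exc[0] is None:
                log.info("stage=%s wall_s=%.2f", name, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Execute the full analysis chain and return the JSON-able report.

    When ``config.cohort_path`` is set the cohort is loaded from disk,
    otherwise one is simulated from the config.  Artifacts (cohort, beta
    matrix, per-subject CV table, null distribution, severity table,
    report.json) are written under ``out_dir`` when given.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log.info("seed=%d", config.seed)

    with _stage("cohort"):
        if config.cohort_path is not None:
            cohort = load_cohort(config.cohort_path)
        else:
            design = make_design(
                config.sample_rate,
                config.total_duration,
                config.task_epoch,
                config.rest_epoch,
            )
            cohort = simulate_cohort(config.simulation_config(), design, rng)
            if out is not None:
                save_cohort(cohort, out / "cohort")

    with _stage("preprocess"):
        beta = preprocess_cohort(
            cohort, PreprocessOptions(cutoff_period=config.detrend_cutoff)
        )
        if out is not None:
            save_beta_matrix(beta, out / "betas.tsv")

    with _stage("decompose"):
        n_pc = min(config.n_pc, len(cohort) - 1, beta.values.shape[1])
        pca = fit_pca(beta, n_pc=n_pc)

    labels = cohort.labels
    with _stage("classify"):
        if config.k_range is not None:
            curve = tuning_curve(
                pca, labels, k_range=config.k_range, mode=config.mode, C=config.C
            )
            best_k = curve.best_k
        else:
            curve = None
            best_k = config.k
        cv = loo_svm(
            pca, labels, k=min(best_k, n_pc), mode=config.mode, C=config.C,
            subject_ids=cohort.subject_ids,
        )
        if out is not None:
            cv.to_frame().to_csv(out / "cv_result.tsv", sep="\t", index=False)

    with _stage("permute"):
        spec = (
            CVSpec(mode=config.mode, k=None, k_range=tuple(config.k_range), C=config.C)
            if config.k_range is not None
            else CVSpec(mode=config.mode, k=min(best_k, n_pc), C=config.C)
        )
        null = permutation_null(pca, labels, spec, n_perm=config.n_perm, rng=rng)
        observed = curve.max_accuracy if curve is not None else cv.accuracy
        p = p_value(observed, null)
        thresholds = significance_thresholds(null, config.alphas)
        if out is not None:
            np.savetxt(
                out / "null_accuracies.tsv",
                null.accuracies,
                fmt="%.6f",
                header="accuracy",
                comments="",
            )

    with _stage("severity"):
        severity = cohort.severity
        sev = None
        if np.isfinite(severity).sum() >= 3 and np.ptp(cv.scores) > 0:
            sev = predict_severity(
                cv, severity, n_perm=config.severity_n_perm, rng=rng
            )
            if out is not None:
                sev.to_frame().to_csv(out / "severity.tsv", sep="\t", index=False)

    report = {
        "accuracy": cv.accuracy,
        "observed_statistic": observed,
        "p_value": p,
        "thresholds": {str(a): t for a, t in thresholds.items()},
        "mode": config.mode,
        "k": int(cv.k),
        "best_k": int(best_k),
        "n_pc": int(n_pc),
        "n_perm": int(config.n_perm),
        "n_subjects": len(cohort),
        "seed": int(config.seed),
        "severity_r": None if sev is None else sev.r,
        "severity_r_predicted_observed": None
        if sev is None
        else float(np.sign(sev.slope) * sev.r),
        "severity_p": None if sev is None else sev.p,
        "severity_transform": None
        if sev is None
        else {"slope": sev.slope, "intercept": sev.intercept},
        "versions": {"nirscv": __version__, "numpy": np.__version__},
    }
    if curve is not None:
        report["tuning_curve"] = {
            "k_values": [int(k) for k in curve.k_values],
            "accuracy_per_k": [float(a) for a in curve.accuracy_per_k],
        }
    if out is not None:
        save_report(report, out / "report.json")
    return report
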