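"""Synthetic fNIRS cohorts with the statistical structure the analysis assumes.

The generator emulates a block-design two-chromophore (HbO/HbR) channel
recording: a task-locked hemodynamic response that is anticorrelated between
the two chromophores, one shared systemic ("global") time series per
chromophore, slow per-channel drift, and white measurement noise.  Group
structure is injected as a spatial amplitude pattern expressed more weakly in
the affected group, with a per-subject expression factor that also drives a
clinical severity score — so classification accuracy and score–severity
correlation are both recoverable quantities with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskDesign",
    "SimulationConfig",
    "SubjectTimeSeries",
    "SubjectRecord",
    "Cohort",
    "make_design",
    "simulate_subject",
    "simulate_cohort",
    "simulate_feature_table",
    "default_effect_pattern",
]

#: diagnostic labels; sorted order puts the control group second, which makes
#: it the positive class throughout the package (decision score > 0 -> TD)
AFFECTED_LABEL = "ASD"
CONTROL_LABEL = "TD"


@dataclass
class TaskDesign:
    """Block-design run timing plus its boxcar and HRF-convolved regressor."""

    sample_rate: float
    total_duration: float
    task_epoch: float
    rest_epoch: float
    boxcar: np.ndarray
    regressor: np.ndarray
    truncated: bool = False
    sub_epoch: float | None = None

    @property
    def n_samples(self) -> int:
        return self.boxcar.shape[0]


def make_design(
    sample_rate: float = 30.0,
    total_duration: float = 180.0,
    task_epoch: float = 18.0,
    rest_epoch: float = 12.0,
    hrf_params=None,
    sub_epoch: float | None = None,
) -> TaskDesign:
    """Build an alternating task/rest boxcar (task first) and its regressor.

    The regressor is the boxcar convolved with the canonical double-gamma HRF
    and rescaled to unit maximum.  ``sub_epoch`` optionally splits each task
    block into alternating gaze-on/diverted sub-epochs of that length; by
    default the task block is one continuous on-period, since the hemodynamic
    regressor cannot resolve few-second sub-epochs at a block design.  A run
    length that is not a whole number of task+rest cycles is permitted and
    flagged via ``truncated``.
    """
    from .preprocess import canonical_hrf

    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if total_duration <= 0 or task_epoch <= 0 or rest_epoch < 0:
        raise ValueError("durations must be positive (rest_epoch may be zero)")
    n = int(round(sample_rate * total_duration))
    t = np.arange(n) / sample_rate
    cycle = task_epoch + rest_epoch
    phase = np.mod(t, cycle)
    boxcar = (phase < task_epoch).astype(float)
    if sub_epoch is not None:
        if sub_epoch <= 0:
            raise ValueError("sub_epoch must be positive")
        sub_phase = np.mod(phase, 2.0 * sub_epoch)
        boxcar *= (sub_phase < sub_epoch).astype(float)
    truncated = abs(total_duration / cycle - round(total_duration / cycle)) > 1e-9

    kernel = canonical_hrf(sample_rate, hrf_params)
    regressor = np.convolve(boxcar, kernel)[:n]
    peak = regressor.max()
    if peak > 0:
        regressor = regressor / peak
    return TaskDesign(
        sample_rate=sample_rate,
        total_duration=total_duration,
        task_epoch=task_epoch,
        rest_epoch=rest_epoch,
        boxcar=boxcar,
        regressor=regressor,
        truncated=truncated,
        sub_epoch=sub_epoch,
    )


def default_effect_pattern(n_channels: int = 54) -> np.ndarray:
    """Group mean-difference map: a contiguous patch of ~1/4 of the channels
    (a stand-in for a dorsal-parietal cluster), unit amplitude elsewhere zero."""
    pattern = np.zeros(n_channels)
    width = max(1, n_channels // 4)
    start = n_channels // 2 - width // 2
    pattern[start : start + width] = 1.0
    return pattern


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    Counts and acquisition geometry default to the study conditions this
    package emulates: 54 channels at 30 samples/s, 19 control (TD) and 17
    affected (ASD) participants.  Amplitudes are in arbitrary beta units;
    noise SDs are in the same signal units as the task response.
    """

    n_channels: int = 54
    n_group_td: int = 19
    n_group_affected: int = 17
    baseline_map: np.ndarray | None = None
    effect_pattern: np.ndarray | None = None
    effect_scale: float = 1.0
    noise_sd: float = 1.0
    global_sd: float = 1.0
    drift_sd: float = 0.5
    oxy_deoxy_ratio: float = -0.5
    severity_intercept: float = 6.0
    severity_slope: float = 6.0
    severity_noise_sd: float = 1.5
    #: per-subject expression-factor distribution: Gamma(shape, 1/shape),
    #: mean 1, SD 1/sqrt(shape)
    expression_shape: float = 4.0
    #: AR(1) coefficient of the shared systemic component
    global_ar: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_group_td < 1 or self.n_group_affected < 1:
            raise ValueError("group counts must be >= 1")
        for name in ("noise_sd", "global_sd", "drift_sd", "severity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.oxy_deoxy_ratio >= 0:
            raise ValueError("oxy_deoxy_ratio must be negative (HbR task response opposes HbO)")
        if self.baseline_map is None:
            self.baseline_map = np.ones(self.n_channels)
        else:
            self.baseline_map = np.asarray(self.baseline_map, float)
        if self.effect_pattern is None:
            self.effect_pattern = default_effect_pattern(self.n_channels)
        else:
            self.effect_pattern = np.asarray(self.effect_pattern, float)
        if self.baseline_map.shape != (self.n_channels,) or self.effect_pattern.shape != (
            self.n_channels,
        ):
            raise ValueError("baseline_map/effect_pattern length must equal n_channels")


@dataclass
class SubjectTimeSeries:
    """Two-chromophore channel recording for one subject (channels x samples)."""

    oxy: np.ndarray
    deoxy: np.ndarray
    subject_id: str
    group: str

    def __post_init__(self):
        if self.oxy.shape != self.deoxy.shape:
            raise ValueError("oxy and deoxy must have the same shape")
        if not (np.isfinite(self.oxy).all() and np.isfinite(self.deoxy).all()):
            raise ValueError("time series must be finite")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    severity: float | None
    timeseries: SubjectTimeSeries | None = None


@dataclass
class Cohort:
    records: list[SubjectRecord]
    design: TaskDesign
    #: generator ground truth kept for recovery tests: injected amplitude
    #: maps, per-subject expression factors, severity parameters
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        groups = {r.group for r in self.records}
        if self.records and len(groups) > 2:
            raise ValueError("labels must come from exactly two classes")

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def severity(self) -> np.ndarray:
        return np.array(
            [np.nan if r.severity is None else r.severity for r in self.records]
        )

    def __len__(self) -> int:
        return len(self.records)


def _ar1(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series rescaled to the exact sample SD ``sd``."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0] / math.sqrt(1.0 - coef**2)
    for i in range(1, n):
        x[i] = coef * x[i - 1] + e[i]
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _drift(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Integrated white noise (random walk), centered and rescaled to SD ``sd``."""
    w = np.cumsum(rng.standard_normal(n))
    w -= w.mean()
    s = w.std()
    return w * (sd / s) if s > 0 else np.zeros(n)


def _chromophore(
    amplitude: np.ndarray,
    regressor: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n_ch = amplitude.shape[0]
    n = regressor.shape[0]
    out = amplitude[:, None] * regressor[None, :]
    if config.global_sd > 0:
        out += _ar1(n, config.global_ar, config.global_sd, rng)[None, :]
    if config.drift_sd > 0:
        for c in range(n_ch):
            out[c] += _drift(n, config.drift_sd, rng)
    if config.noise_sd > 0:
        out += config.noise_sd * rng.standard_normal((n_ch, n))
    return out


def simulate_subject(
    config: SimulationConfig,
    design: TaskDesign,
    group: str,
    amplitude_map: np.ndarray,
    rng: np.random.Generator,
    subject_id: str = "sub",
) -> SubjectTimeSeries:
    """One subject's two-chromophore recording.

    Per channel c: oxy = amplitude[c]*regressor + shared global + drift +
    noise; deoxy = oxy_deoxy_ratio*amplitude[c]*regressor + independent
    global/drift/noise terms of the same SDs.
    """
    amplitude_map = np.asarray(amplitude_map, float)
    if amplitude_map.shape != (config.n_channels,):
        raise ValueError("amplitude_map length must equal n_channels")
    oxy = _chromophore(amplitude_map, design.regressor, config, rng)
    deoxy = _chromophore(
        config.oxy_deoxy_ratio * amplitude_map, design.regressor, config, rng
    )
    return SubjectTimeSeries(oxy=oxy, deoxy=deoxy, subject_id=subject_id, group=group)


def simulate_cohort(
    config: SimulationConfig | None = None,
    design: TaskDesign | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Generate a two-group cohort with injected group structure.

    Control (TD) subjects receive the baseline amplitude map.  Affected (ASD)
    subjects receive ``baseline - effect_scale * effect_pattern * u_i`` where
    ``u_i >= 0`` is a per-subject expression factor (Gamma, mean 1), and a
    severity score ``intercept + slope*u_i + N(0, severity_noise_sd)``.
    Controls carry no severity.  Ground truth (maps and u_i) is retained on
    ``Cohort.truth`` for recovery tests.
    """
    config = config or SimulationConfig()
    design = design or make_design()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    records: list[SubjectRecord] = []
    maps = []
    u_factors = {}
    for i in range(config.n_group_td):
        sid = f"td{i + 1:02d}"
        amp = config.baseline_map.copy()
        ts = simulate_subject(config, design, CONTROL_LABEL, amp, rng, sid)
        records.append(SubjectRecord(sid, CONTROL_LABEL, None, ts))
        maps.append(amp)
    for i in range(config.n_group_affected):
        sid = f"asd{i + 1:02d}"
        u = rng.gamma(config.expression_shape, 1.0 / config.expression_shape)
        amp = config.baseline_map - config.effect_scale * config.effect_pattern * u
        severity = config.severity_intercept + config.severity_slope * u
        if config.severity_noise_sd > 0:
            severity += rng.normal(0.0, config.severity_noise_sd)
        ts = simulate_subject(config, design, AFFECTED_LABEL, amp, rng, sid)
        records.append(SubjectRecord(sid, AFFECTED_LABEL, float(severity), ts))
        maps.append(amp)
        u_factors[sid] = float(u)

    truth = {
        "amplitude_maps": np.array(maps),
        "u": u_factors,
        "effect_scale": config.effect_scale,
        "effect_pattern": config.effect_pattern.copy(),
        "severity_intercept": config.severity_intercept,
        "severity_slope": config.severity_slope,
        "severity_noise_sd": config.severity_noise_sd,
    }
    return Cohort(records=records, design=design, truth=truth)


def simulate_feature_table(
    n1: int,
    n2: int,
    n_features: int,
    effect_vector: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Fast-path feature table: iid standard-normal rows, ``effect_vector``
    added to the second group's rows.  Returns (features, labels) with labels
    TD (group 1) / ASD (group 2); with the zero effect vector the labels are
    independent of the features, the null configuration of the permutation
    experiments.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two subjects per group")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    X = rng.standard_normal((n1 + n2, n_features))
    if effect_vector is not None:
        effect_vector = np.asarray(effect_vector, float)
        if effect_vector.shape != (n_features,):
            raise ValueError("effect_vector length must equal n_features")
        X[n1:] += effect_vector
    labels = np.array([CONTROL_LABEL] * n1 + [AFFECTED_LABEL] * n2)
    return X, labels
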