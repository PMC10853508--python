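"""Channel-space preprocessing: from two-chromophore time series to one
GLM beta per channel per subject.

The chain is detrend -> global-component removal -> Hbdiff -> GLM.  Betas are
the amplitude of the task-locked hemodynamic response, estimated by ordinary
least squares of the processed signal on the HRF-convolved task regressor
plus an intercept.  The task regressor is passed through the same detrending
filter as the data, so the noiseless signal chain is exactly invertible:
a noiseless subject with amplitude map ``a`` and HbR/HbO task ratio ``r``
yields ``beta = (1 - r) * a`` to numerical precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .simulate import Cohort, SubjectTimeSeries, TaskDesign

__all__ = [
    "HRFParams",
    "BetaMap",
    "BetaMatrix",
    "PreprocessOptions",
    "canonical_hrf",
    "detrend",
    "remove_global",
    "hbdiff",
    "glm_betas",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds; SPM defaults)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


def canonical_hrf(sample_rate: float, params: HRFParams | None = None) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, peak normalized to 1.

    Difference of two gamma densities with shape delay/dispersion and scale
    dispersion; the undershoot is divided by ``peak_undershoot_ratio``; the
    kernel is truncated at ``kernel_length`` seconds.
    """
    from scipy.stats import gamma as gamma_dist

    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    params = params or HRFParams()
    t = np.arange(0.0, params.kernel_length, 1.0 / sample_rate)
    peak = gamma_dist.pdf(
        t, a=params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        a=params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - under / params.peak_undershoot_ratio
    m = kernel.max()
    if m <= 0:
        raise ValueError("degenerate HRF kernel")
    return kernel / m


def _dwt_level(sample_rate: float, cutoff_period: float, n: int) -> int:
    """Decomposition depth whose approximation band lies below 1/cutoff Hz."""
    level = max(1, math.ceil(math.log2(sample_rate * cutoff_period)) - 1)
    return min(level, max(1, int(math.floor(math.log2(n)))))


def detrend(
    timeseries: np.ndarray,
    cutoff_period: float = 128.0,
    sample_rate: float = 30.0,
    wavelet: str = "db4",
) -> np.ndarray:
    """Remove slow drift while keeping the task band intact.

    A least-squares line is removed first (this also eliminates the
    start/end discontinuity that a periodized wavelet transform would
    otherwise smear into the detail bands), then the approximation
    coefficients of a periodized discrete wavelet transform at the depth
    whose band lies below 1/``cutoff_period`` Hz are zeroed.  Components with
    period longer than ``cutoff_period`` (seconds) are removed and the output
    is (numerically) zero-mean.  Accepts a 1-D series or a channels-x-samples
    matrix (filtered per row).  The series must cover at least one cutoff
    period.
    """
    x = np.asarray(timeseries, float)
    if cutoff_period <= 0 or sample_rate <= 0:
        raise ValueError("cutoff_period and sample_rate must be positive")
    n = x.shape[-1]
    if n < cutoff_period * sample_rate:
        raise ValueError(
            "series shorter than the detrending cutoff period "
            f"({n} samples < {cutoff_period} s at {sample_rate}/s)"
        )
    x2 = np.atleast_2d(x)
    t = np.arange(n) / sample_rate
    D = np.column_stack([t - t.mean(), np.ones(n)])
    coef, *_ = np.linalg.lstsq(D, x2.T, rcond=None)
    resid = x2 - (D @ coef).T
    level = _dwt_level(sample_rate, cutoff_period, n)
    with warnings.catch_warnings():
        # pywt warns when the depth exceeds its conservative maximum; the
        # periodized transform is still exact, and deep levels are exactly
        # what a >100-s cutoff requires at 30 samples/s
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(resid, wavelet, mode="periodization", level=level, axis=-1)
    coeffs[0] = np.zeros_like(coeffs[0])
    out = pywt.waverec(coeffs, wavelet, mode="periodization", axis=-1)[..., :n]
    return out[0] if x.ndim == 1 else out


def remove_global(
    matrix: np.ndarray,
    protect: np.ndarray | None = None,
    uniform_sign_frac: float = 0.8,
) -> np.ndarray:
    """Remove the systemic component shared across channels.

    The first spatial principal component of the channels-x-samples matrix is
    taken as the global time series when its spatial loadings are near-uniform
    in sign (> ``uniform_sign_frac`` same-signed); otherwise the across-channel
    mean series is used.  The estimated global series is regressed out of
    every channel.  When ``protect`` is given (e.g. the task regressor), the
    global series is first orthogonalized against it so that task-locked
    variance is never removed.  Output channels are mean-centered.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    Xc = X - X.mean(axis=1, keepdims=True)
    scale = np.abs(Xc).max()
    if scale == 0:
        if np.any(X):
            raise ValueError("constant input has no global component to estimate")
        return Xc  # zero matrix passes through
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = U[:, 0]
    frac = max(np.mean(loadings >= 0), np.mean(loadings <= 0))
    g = Vt[0] if frac > uniform_sign_frac else Xc.mean(axis=0)

    if protect is not None:
        protect = np.atleast_2d(np.asarray(protect, float))
        if protect.shape[1] != X.shape[1]:
            raise ValueError("protect regressor length must equal sample count")
        P = protect - protect.mean(axis=1, keepdims=True)
        for row in P:
            nrm = row @ row
            if nrm > 0:
                g = g - (g @ row) / nrm * row
    gnorm = g @ g
    if gnorm / max((Vt[0] @ Vt[0]), 1e-300) < 1e-12 or gnorm == 0:
        return Xc  # nothing left to remove after protection
    beta = Xc @ g / gnorm
    return Xc - np.outer(beta, g)


def hbdiff(oxy: np.ndarray, deoxy: np.ndarray) -> np.ndarray:
    """Combined hemodynamic signal HbO - HbR (element-wise)."""
    oxy = np.asarray(oxy, float)
    deoxy = np.asarray(deoxy, float)
    if oxy.shape != deoxy.shape:
        raise ValueError("oxy and deoxy must have the same shape")
    return oxy - deoxy


@dataclass
class BetaMap:
    """Per-channel task amplitudes (GLM betas) for one subject."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise ValueError("beta values must be finite")


@dataclass
class BetaMatrix:
    """Stacked subjects-by-channels beta matrix, row order = cohort order."""

    values: np.ndarray
    subject_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.subject_ids):
            raise ValueError("values must be subjects x channels with one row per id")


def glm_betas(
    timeseries: SubjectTimeSeries | np.ndarray,
    design: TaskDesign,
    regressor: np.ndarray | None = None,
    use_hbdiff: bool = True,
) -> BetaMap:
    """Per-channel OLS of the (Hbdiff-combined) signal on [regressor, 1].

    ``regressor`` overrides the design regressor (used by the cohort pipeline
    to pass the detrended version).  Returns the task-regressor coefficient
    per channel.
    """
    if isinstance(timeseries, SubjectTimeSeries):
        signal = hbdiff(timeseries.oxy, timeseries.deoxy) if use_hbdiff else timeseries.oxy
        sid = timeseries.subject_id
    else:
        signal = np.atleast_2d(np.asarray(timeseries, float))
        sid = "anonymous"
    reg = design.regressor if regressor is None else np.asarray(regressor, float)
    if reg.shape[0] != signal.shape[1]:
        raise ValueError("regressor length must equal sample count")
    if np.ptp(reg) == 0:
        raise ValueError("constant regressor cannot be fit")
    if not np.isfinite(signal).all():
        raise ValueError("NaN or infinite values in input signal")
    D = np.column_stack([reg, np.ones_like(reg)])
    coef, *_ = np.linalg.lstsq(D, signal.T, rcond=None)
    return BetaMap(subject_id=sid, values=coef[0])


@dataclass
class PreprocessOptions:
    """Stage toggles and parameters for the cohort pipeline.

    Any stage can be skipped; the GLM stage always runs.  ``protect_task``
    shields the task regressor's subspace from the global filter.
    """

    detrend: bool = True
    cutoff_period: float = 128.0
    wavelet: str = "db4"
    remove_global: bool = True
    protect_task: bool = True
    use_hbdiff: bool = True


def preprocess_cohort(
    cohort: Cohort, options: PreprocessOptions | None = None
) -> BetaMatrix:
    """Run the full channel-space chain on every subject of a cohort.

    Each chromophore is detrended and global-filtered independently, the two
    are combined into Hbdiff, and a GLM against the (identically detrended)
    task regressor yields one beta per channel.
    """
    options = options or PreprocessOptions()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    design = cohort.design
    sr = design.sample_rate

    reg = design.regressor
    if options.detrend:
        reg = detrend(reg, options.cutoff_period, sr, options.wavelet)

    shapes = {r.timeseries.oxy.shape for r in cohort.records if r.timeseries is not None}
    if len(shapes) != 1:
        raise ValueError("all subjects must share channel count and sample count")

    rows = []
    for rec in cohort.records:
        ts = rec.timeseries
        if ts is None:
            raise ValueError(f"subject {rec.subject_id} has no time series")
        oxy, deoxy = ts.oxy, ts.deoxy
        if options.detrend:
            oxy = detrend(oxy, options.cutoff_period, sr, options.wavelet)
            deoxy = detrend(deoxy, options.cutoff_period, sr, options.wavelet)
        if options.remove_global:
            protect = reg if options.protect_task else None
            oxy = remove_global(oxy, protect=protect)
            deoxy = remove_global(deoxy, protect=protect)
        signal = hbdiff(oxy, deoxy) if options.use_hbdiff else oxy
        beta = glm_betas(signal, design, regressor=reg)
        rows.append(beta.values)
    return BetaMatrix(
        values=np.array(rows), subject_ids=cohort.subject_ids, labels=cohort.labels
    )
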