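"""Motion quantification, frame censoring, nuisance regression, band-pass.

The per-subject cleaning pipeline is fixed: displacement -> censor (drop
frames whose frame-to-frame displacement exceeds 2 mm) -> confound
regression (6 rigid-motion parameters + first 5 principal components of the
noise channels, plus an intercept, in a single design) -> band-pass
(0.01-0.1 Hz). All downstream correlation uses retained frames only.

Displacement is the first-difference rigid-body metric
``||dt||_2 + radius * ||dr||_2`` with a 50-mm rotation lever arm. Because the
frequency-domain band-pass is an orthogonal projection that does not commute
with the confound projection, the confounds are projected out once more
after filtering so that residual-confound orthogonality holds exactly on
the returned series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._utils import check_finite_2d
from .cohort import SubjectRecord

__all__ = [
    "DisplacementTrace",
    "CleanedSeries",
    "PreprocessConfig",
    "BandpassFilter",
    "ConfoundRegressor",
    "displacement",
    "censor",
    "noise_pcs",
    "select_highvar_voxel_channels",
    "regress_confounds",
    "bandpass",
    "preprocess_subject",
]


@dataclass
class DisplacementTrace:
    """Per-frame scalar head displacement (mm) with censoring bookkeeping."""

    values: np.ndarray
    radius_mm: float

    def summary(self) -> dict:
        v = self.values
        return {
            "median_mm": float(np.median(v)),
            "q25_mm": float(np.percentile(v, 25)),
            "q75_mm": float(np.percentile(v, 75)),
            "max_mm": float(v.max()),
            "mean_mm": float(v.mean()),
        }


@dataclass
class CleanedSeries:
    """Residual ROI series on retained frames, with the design record."""

    data: np.ndarray  # retained frames x regions
    frame_indices: np.ndarray  # original indices of retained frames
    confounds: np.ndarray  # retained frames x P design (no intercept column)
    confound_names: list
    dropped_confounds: list = field(default_factory=list)
    band_hz: tuple | None = None
    tr_s: float = 1.0
    usable: bool = True
    low_confidence: bool = False
    qc: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return 0 if self.data is None else self.data.shape[0]

    @property
    def censored_fraction(self) -> float:
        return float(self.qc.get("censored_fraction", 0.0))


@dataclass(frozen=True)
class PreprocessConfig:
    censor_mm: float = 2.0
    radius_mm: float = 50.0
    n_noise_pcs: int = 5
    band_hz: tuple = (0.01, 0.1)
    min_frames: int = 10
    low_confidence_frames: int = 30


def displacement(motion: np.ndarray, radius_mm: float = 50.0) -> DisplacementTrace:
    """Frame-to-frame rigid-body displacement in mm.

    ``motion`` is frames x 6 (3 rotations in radians, then 3 translations in
    mm); displacement at frame t is ``||dt||_2 + radius_mm * ||dr||_2`` of
    the first differences, and 0 at frame 0.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    m = check_finite_2d(motion, "motion", n_cols=6)
    diff = np.diff(m, axis=0)
    disp = np.zeros(m.shape[0])
    disp[1:] = np.linalg.norm(diff[:, 3:], axis=1) + radius_mm * np.linalg.norm(
        diff[:, :3], axis=1
    )
    return DisplacementTrace(values=disp, radius_mm=radius_mm)


def censor(trace, threshold_mm: float = 2.0) -> np.ndarray:
    """Retention mask: True exactly where displacement <= threshold."""
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    values = trace.values if isinstance(trace, DisplacementTrace) else np.asarray(trace, float)
    return values <= threshold_mm


def noise_pcs(noise_channels: np.ndarray, n_components: int = 5) -> np.ndarray:
    """Principal-component scores of the column-centred noise-channel matrix.

    Columns are ordered by decreasing explained variance and are mutually
    orthogonal. Asking for more components than the matrix rank returns the
    available ones with a warning.
    """
    x = check_finite_2d(noise_channels, "noise_channels")
    limit = min(x.shape)
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds min(frames, channels)={limit}")
    rank = np.linalg.matrix_rank(x - x.mean(0))
    k = n_components
    if k > rank:
        warnings.warn(
            f"noise channels have rank {rank} < n_components={n_components}; "
            "returning the available components",
            stacklevel=2,
        )
        k = rank
    return PCA(n_components=k, svd_solver="full").fit_transform(x)


def select_highvar_voxel_channels(candidate_signals: np.ndarray, fraction: float = 0.05):
    """Keep the ceil(fraction*M) columns of highest temporal SD.

    Ties break toward the lower column index. Returns (subset, indices) with
    indices in ascending original order.
    """
    x = check_finite_2d(candidate_signals, "candidate_signals")
    if x.shape[1] == 0:
        raise ValueError("candidate_signals has no columns")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.ceil(fraction * x.shape[1]))
    order = np.argsort(-x.std(0, ddof=1), kind="stable")
    idx = np.sort(order[:k])
    return x[:, idx], idx


def _regression_design(confounds: np.ndarray, names):
    """Intercept-first design; collinear columns dropped via pivoted QR."""
    n = confounds.shape[0]
    design = np.column_stack([np.ones(n), confounds])
    all_names = ["intercept"] + list(names)
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    keep_piv = piv[: int((diag > tol).sum())]
    keep = np.sort(keep_piv)
    dropped = [all_names[i] for i in range(design.shape[1]) if i not in set(keep.tolist())]
    return design[:, keep], [all_names[i] for i in keep], dropped


def regress_confounds(timeseries: np.ndarray, confounds: np.ndarray, names=None) -> CleanedSeries:
    """OLS residuals of each region on the confound design (intercept included)."""
    y = check_finite_2d(timeseries, "timeseries")
    c = check_finite_2d(confounds, "confounds")
    if y.shape[0] != c.shape[0]:
        raise ValueError("timeseries and confounds must have the same number of frames")
    if c.shape[1] >= y.shape[0]:
        raise ValueError("need fewer confounds than frames")
    names = list(names) if names is not None else [f"confound_{i}" for i in range(c.shape[1])]
    design, kept_names, dropped = _regression_design(c, names)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return CleanedSeries(
        data=resid,
        frame_indices=np.arange(y.shape[0]),
        confounds=c,
        confound_names=kept_names,
        dropped_confounds=dropped,
    )


def bandpass(
    timeseries: np.ndarray, low_hz: float = 0.01, high_hz: float = 0.1, tr_s: float = 1.0
) -> np.ndarray:
    """Linear detrend then real-FFT frequency mask; mean (DC) always removed."""
    y = check_finite_2d(timeseries, "timeseries")
    nyquist = 0.5 / tr_s
    if not 0 <= low_hz < high_hz <= nyquist + 1e-12:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 <= low < high <= {nyquist}"
        )
    y = scipy.signal.detrend(y, axis=0, type="linear")
    spec = np.fft.rfft(y, axis=0)
    freqs = np.fft.rfftfreq(y.shape[0], tr_s)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    mask[0] = False
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=y.shape[0], axis=0)


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer wrapping :func:`bandpass`."""

    def __init__(self, low_hz: float = 0.01, high_hz: float = 0.1, tr_s: float = 1.0):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.tr_s = tr_s

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return bandpass(X, self.low_hz, self.high_hz, self.tr_s)


class ConfoundRegressor(TransformerMixin, BaseEstimator):
    """Projects a confound design out of frames x regions data (fit_transform only).

    The projection is sample-specific (frames are the samples), so the
    transformer is used in fit_transform style on each subject.
    """

    def __init__(self, confounds=None, names=None):
        self.confounds = confounds
        self.names = names

    def fit(self, X, y=None):
        cleaned = regress_confounds(X, self.confounds, names=self.names)
        self.design_names_ = cleaned.confound_names
        self.dropped_ = cleaned.dropped_confounds
        self._residuals = cleaned.data
        return self

    def transform(self, X):
        return self._residuals

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def preprocess_subject(record: SubjectRecord, config: PreprocessConfig | None = None) -> CleanedSeries:
    """Full per-subject pipeline: displacement -> censor -> regression -> band-pass."""
    cfg = config or PreprocessConfig()
    trace = displacement(record.motion, cfg.radius_mm)
    mask = censor(trace, cfg.censor_mm)
    retained = np.flatnonzero(mask)
    qc = {
        "displacement": trace.summary(),
        "n_frames": int(mask.size),
        "n_retained": int(retained.size),
        "censored_fraction": float(1.0 - retained.size / mask.size),
        "mean_displacement_retained_mm": float(trace.values[mask].mean())
        if retained.size
        else float("nan"),
    }
    if retained.size < cfg.min_frames:
        return CleanedSeries(
            data=np.empty((0, record.timeseries.shape[1])),
            frame_indices=retained,
            confounds=np.empty((0, 0)),
            confound_names=[],
            tr_s=record.tr_s,
            usable=False,
            qc=qc,
        )

    pcs = noise_pcs(record.noise_channels[retained], cfg.n_noise_pcs)
    confounds = np.column_stack([record.motion[retained], pcs])
    names = [f"rot_{ax}" for ax in "xyz"] + [f"trans_{ax}" for ax in "xyz"] + [
        f"noise_pc{i + 1}" for i in range(pcs.shape[1])
    ]
    cleaned = regress_confounds(record.timeseries[retained], confounds, names=names)
    filtered = bandpass(cleaned.data, *cfg.band_hz, tr_s=record.tr_s)
    # The band-pass projection does not commute with the confound projection;
    # re-project so the orthogonality contract holds on the output exactly.
    design = np.column_stack([np.ones(filtered.shape[0]), confounds])
    beta, *_ = np.linalg.lstsq(design, filtered, rcond=None)
    filtered = filtered - design @ beta

    cleaned.data = filtered
    cleaned.frame_indices = retained
    cleaned.band_hz = tuple(cfg.band_hz)
    cleaned.tr_s = record.tr_s
    cleaned.low_confidence = retained.size < cfg.low_confidence_frames
    cleaned.qc = qc
    return cleaned
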