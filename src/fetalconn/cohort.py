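"""Seeded synthetic fetal BOLD cohorts.

Each simulated subject is a short resting-state scan (default 50 frames at
TR = 1 s) over the atlas regions. The signal model is additive:

* a band-limited (0.01-0.08 Hz, spectrally peaked near 0.04 Hz) latent
  neural component whose inter-regional correlation follows an edge-class
  growth truth evaluated at the subject's gestational age (sigmoid in age
  for within-lobe edges, linear for long-range edges, flat for the
  remainder);
* a sinusoid shared across regions at a per-subject cardiac frequency
  (~144 bpm), which the 1-Hz sampling aliases into the low-frequency band;
* a per-region linear drift;
* frame-localised artifact spikes co-occurring with large jumps in the
  six-parameter rigid-motion trace;
* white noise.

"Noise channels" for component-based nuisance correction carry the drift,
cardiac and white-noise parts but no neural component. Everything is
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._utils import as_rng, upper_vec
from .atlas import GA_MAX, GA_MIN, RoiAtlas, brain_volume_cm3

__all__ = [
    "GrowthTruth",
    "NoiseConfig",
    "SubjectRecord",
    "DEFAULT_LOBE_INFLECTIONS_GW",
    "edge_truth",
    "simulate_subject",
    "simulate_cohort",
    "uniform_ga_sampler",
    "stratified_ga_sampler",
]

KIND_FLAT, KIND_SIGMOID, KIND_LINEAR = 0, 1, 2

#: Default per-lobe sigmoid inflection ages (gestational weeks). The cortical
#: four follow the occipital < temporal < frontal < parietal maturation
#: sequence; subcortical tracks the overall network, limbic the frontal value.
DEFAULT_LOBE_INFLECTIONS_GW = {
    "occipital": 24.8,
    "temporal": 26.0,
    "frontal": 26.4,
    "parietal": 27.5,
    "subcortical": 26.3,
    "limbic": 26.4,
}


def _sigmoid(x, a, b, c, d):
    return d + c / (1.0 + np.exp(-(np.asarray(x, dtype=float) - a) / b))


@dataclass(frozen=True)
class GrowthTruth:
    """Per-edge growth model used to generate cohorts.

    ``kind`` selects the functional form per edge (0 flat, 1 sigmoid,
    2 linear); ``a, b, c, d`` are the four-parameter-logistic coefficients in
    Fisher-Z units (inflection week, slope scale in weeks, amplitude,
    baseline), ``slope``/``intercept`` the linear coefficients (Z per week).
    """

    kind: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray

    def __post_init__(self):
        n = self.kind.shape[0]
        for name in ("kind", "a", "b", "c", "d", "slope", "intercept"):
            arr = getattr(self, name)
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be ({n}, {n})")
            if not np.allclose(arr, arr.T):
                raise ValueError(f"{name} must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.kind.shape[0]

    @property
    def effect_mask(self) -> np.ndarray:
        """Symmetric boolean mask of edges with a genuine age effect."""
        sig = (self.kind == KIND_SIGMOID) & (self.c != 0)
        lin = (self.kind == KIND_LINEAR) & (self.slope != 0)
        out = sig | lin
        np.fill_diagonal(out, False)
        return out

    @property
    def mean_inflection_gw(self) -> float:
        """Amplitude-weighted mean inflection age over sigmoid-class edges."""
        kv, av, cv = (upper_vec(x) for x in (self.kind, self.a, self.c))
        sel = (kv == KIND_SIGMOID) & (cv > 0)
        if not sel.any():
            raise ValueError("truth has no sigmoid-class edge with positive amplitude")
        return float(np.average(av[sel], weights=cv[sel]))

    def evaluate_z(self, ga_weeks: float) -> np.ndarray:
        """Target Fisher-Z matrix at ``ga_weeks`` (diagonal set to 0)."""
        ga = float(ga_weeks)
        z = np.where(
            self.kind == KIND_SIGMOID,
            _sigmoid(ga, self.a, self.b, np.where(self.kind == KIND_SIGMOID, self.c, 0.0), self.d),
            np.where(self.kind == KIND_LINEAR, self.intercept + self.slope * ga, self.d),
        )
        np.fill_diagonal(z, 0.0)
        return z

    @classmethod
    def default(
        cls,
        atlas: RoiAtlas,
        lobe_inflections: dict | None = None,
        slope_scale_gw: float = 1.0,
        amplitude_z: float = 0.45,
        baseline_z: float = -0.01,
        long_slope_z_per_gw: float = 0.0075,
        long_value_at_21_z: float = -0.01,
    ) -> "GrowthTruth":
        """Edge-class defaults mirroring the study conditions.

        Long-range edges (top distance quartile at the 37-week reference)
        grow linearly; within-lobe edges follow a sigmoid at their lobe's
        inflection age; the remaining cross-lobe edges stay flat at the
        baseline. The default amplitudes keep the implied correlation
        targets jointly near positive semidefinite across gestation (the
        nearest-PSD projection then moves no entry by more than ~0.04), so
        the generator imposes essentially exactly what ``edge_truth``
        states.
        """
        infl = dict(DEFAULT_LOBE_INFLECTIONS_GW, **(lobe_inflections or {}))
        n = atlas.n_regions
        coords = atlas.coord_ref
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        dvec = upper_vec(dist)
        q75 = np.percentile(dvec, 75)

        lobes = np.asarray(atlas.lobe)
        a_lobe = np.array([infl[lb] for lb in lobes])
        a_edge = 0.5 * (a_lobe[:, None] + a_lobe[None, :])
        same_lobe = lobes[:, None] == lobes[None, :]

        long_mask = dist >= q75
        sigmoid_mask = ~long_mask & same_lobe
        kind = np.full((n, n), KIND_FLAT, dtype=int)
        kind[sigmoid_mask] = KIND_SIGMOID
        kind[long_mask] = KIND_LINEAR
        np.fill_diagonal(kind, KIND_FLAT)

        return cls(
            kind=kind,
            a=a_edge,
            b=np.full((n, n), float(slope_scale_gw)),
            c=np.where(kind == KIND_SIGMOID, float(amplitude_z), 0.0),
            d=np.full((n, n), float(baseline_z)),
            slope=np.where(kind == KIND_LINEAR, float(long_slope_z_per_gw), 0.0),
            intercept=np.full((n, n), long_value_at_21_z - long_slope_z_per_gw * 21.0),
        )

    @classmethod
    def null(cls, atlas: RoiAtlas, baseline_z: float = -0.05) -> "GrowthTruth":
        """No age effect anywhere: every edge flat at ``baseline_z``."""
        n = atlas.n_regions
        zeros = np.zeros((n, n))
        return cls(
            kind=np.full((n, n), KIND_FLAT, dtype=int),
            a=np.full((n, n), 26.0),
            b=np.ones((n, n)),
            c=zeros.copy(),
            d=np.full((n, n), float(baseline_z)),
            slope=zeros.copy(),
            intercept=zeros.copy(),
        )


def edge_truth(truth: GrowthTruth, atlas: RoiAtlas, ga_weeks: float) -> np.ndarray:
    """Target correlation matrix at ``ga_weeks`` (inverse Fisher transform).

    Symmetric with unit diagonal; raises if the truth implies a non-finite
    Fisher-Z value (which would mean a correlation magnitude of 1 or more).
    """
    if truth.n_regions != atlas.n_regions:
        raise ValueError("truth and atlas disagree on the number of regions")
    if not GA_MIN <= float(ga_weeks) <= GA_MAX:
        raise ValueError(f"ga_weeks must lie in [{GA_MIN}, {GA_MAX}]")
    z = truth.evaluate_z(ga_weeks)
    if not np.all(np.isfinite(z)):
        raise ValueError("growth truth implies non-finite Fisher-Z targets (|r| >= 1)")
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass(frozen=True)
class NoiseConfig:
    """Generator nuisance settings; defaults are the study-like conditions."""

    n_frames: int = 50
    tr_s: float = 1.0
    neural_sd: float = 1.0
    neural_band_hz: tuple = (0.01, 0.08)
    neural_peak_hz: float = 0.04
    neural_bw_hz: float = 0.05
    white_sd: float = 0.5
    cardiac_amp: float = 0.4
    cardiac_freq_mean_hz: float = 2.4
    cardiac_freq_sd_hz: float = 0.47
    cardiac_freq_range_hz: tuple = (2.0, 3.6)
    drift_amp: float = 0.5
    spike_prob: float = 0.05
    spike_amp: float = 3.0
    spike_jump_mm: tuple = (3.0, 6.0)
    motion_step_trans_mm: float = 0.15
    motion_step_rot_rad: float = 0.004
    motion_subject_sigma: float = 0.4
    n_noise_channels: int = 10
    # Noise voxels are selected for high physiological variance, so their
    # white-noise floor sits below the drift/cardiac content they carry.
    channel_white_sd: float = 0.5

    @classmethod
    def quiet(cls, **overrides) -> "NoiseConfig":
        """All nuisance amplitudes zero (pure neural signal); for validation."""
        base = dict(
            white_sd=0.0, cardiac_amp=0.0, drift_amp=0.0, spike_prob=0.0, spike_amp=0.0
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SubjectRecord:
    """One simulated fetus: scan, motion trace, noise channels, metadata."""

    subject_id: str
    ga_weeks: float
    ga_days: int
    timeseries: np.ndarray  # frames x regions, arbitrary BOLD units
    motion: np.ndarray  # frames x 6: 3 rotations (rad) then 3 translations (mm)
    noise_channels: np.ndarray  # frames x K
    brain_volume_cm3: float
    tr_s: float = 1.0


def _band_limited_latent(frames, n, cfg: NoiseConfig, rng) -> np.ndarray:
    """Unit-variance independent latent signals with a bump spectrum near 0.04 Hz."""
    freqs = np.fft.rfftfreq(frames, cfg.tr_s)
    w = np.exp(-0.5 * ((freqs - cfg.neural_peak_hz) / cfg.neural_bw_hz) ** 2)
    lo, hi = cfg.neural_band_hz
    w[(freqs < lo) | (freqs > hi)] = 0.0
    w[0] = 0.0
    spec = (rng.standard_normal((freqs.size, n)) + 1j * rng.standard_normal((freqs.size, n))) * w[
        :, None
    ]
    x = np.fft.irfft(spec, n=frames, axis=0)
    x -= x.mean(0)
    sd = x.std(0)
    sd[sd == 0] = 1.0
    x /= sd
    if frames > n + 1:
        # Band-limiting leaves few effective degrees of freedom, so standardized
        # columns are only approximately uncorrelated; when the scan is long
        # enough, whiten symmetrically so the imposed structure is exact.
        cov = (x.T @ x) / frames
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 1e-10, None)
        x = x @ ((v / np.sqrt(w)) @ v.T)
    return x


def _correlation_sqrt(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetric square root of the nearest positive-semidefinite matrix.

    Edge-wise growth targets need not be jointly positive semidefinite, so
    eigenvalues are clipped at ``floor`` before the root is formed.
    """
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    w = np.clip(w, floor, None)
    return (v * np.sqrt(w)) @ v.T


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _simulate_motion(frames, cfg: NoiseConfig, rng):
    """Random-walk rigid motion with occasional permanent jumps (spikes).

    Returns the frames x 6 trace (rotations rad, translations mm) and the
    boolean per-frame spike indicator.
    """
    scale = float(np.exp(rng.normal(0.0, cfg.motion_subject_sigma)))
    rot = np.vstack(
        [np.zeros(3), np.cumsum(rng.normal(0, cfg.motion_step_rot_rad * scale, (frames - 1, 3)), 0)]
    )
    trans = np.vstack(
        [
            np.zeros(3),
            np.cumsum(rng.normal(0, cfg.motion_step_trans_mm * scale, (frames - 1, 3)), 0),
        ]
    )
    spikes = np.zeros(frames, dtype=bool)
    spikes[1:] = rng.random(frames - 1) < cfg.spike_prob
    for f in np.flatnonzero(spikes):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        trans[f:] += rng.uniform(*cfg.spike_jump_mm) * direction
    return np.hstack([rot, trans]), spikes


def simulate_subject(
    atlas: RoiAtlas,
    truth: GrowthTruth,
    ga_weeks: float,
    noise: NoiseConfig | None = None,
    seed=0,
    subject_id: str = "sub000",
) -> SubjectRecord:
    """Simulate one subject's scan at gestational age ``ga_weeks``."""
    cfg = noise or NoiseConfig()
    rng = as_rng(seed)
    n = atlas.n_regions
    frames = cfg.n_frames
    t = np.arange(frames) * cfg.tr_s

    r_target = edge_truth(truth, atlas, ga_weeks)
    latent = _band_limited_latent(frames, n, cfg, rng)
    ts = cfg.neural_sd * (latent @ _correlation_sqrt(r_target))

    # Shared cardiac sinusoid, aliased by the 1-Hz frame rate.
    f_card = _truncated_normal(
        rng, cfg.cardiac_freq_mean_hz, cfg.cardiac_freq_sd_hz, *cfg.cardiac_freq_range_hz
    )
    card = np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi))
    ts += cfg.cardiac_amp * np.outer(card, rng.uniform(0.5, 1.5, n))

    ramp = np.linspace(-1.0, 1.0, frames)
    ts += np.outer(ramp, rng.normal(0, cfg.drift_amp, n))

    motion, spikes = _simulate_motion(frames, cfg, rng)
    ts[spikes] += cfg.spike_amp * rng.standard_normal((int(spikes.sum()), n))

    ts += rng.normal(0, cfg.white_sd, (frames, n))

    k = cfg.n_noise_channels
    channels = np.outer(ramp, rng.normal(0, cfg.drift_amp, k))
    channels += cfg.cardiac_amp * np.outer(card, rng.uniform(0.5, 1.5, k))
    channels += rng.normal(0, cfg.channel_white_sd, (frames, k))

    volume = float(np.clip(brain_volume_cm3(ga_weeks) + rng.normal(0, 15.0), 60.0, 500.0))
    return SubjectRecord(
        subject_id=subject_id,
        ga_weeks=float(ga_weeks),
        ga_days=int(round(float(ga_weeks) * 7)),
        timeseries=ts,
        motion=motion,
        noise_channels=channels,
        brain_volume_cm3=volume,
        tr_s=cfg.tr_s,
    )


def uniform_ga_sampler(lo: float = 21.0, hi: float = 37.0):
    """Gestational ages drawn uniformly on [lo, hi] weeks."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(lo, hi, n)

    return sample


def stratified_ga_sampler(strata=((21.0, 26.0, 8), (26.0, 29.0, 8), (29.0, 37.0, 16))):
    """Fixed per-stage counts (default 8/8/16 across the three study stages)."""
    total = sum(c for _, _, c in strata)

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        if n != total:
            raise ValueError(f"stratified sampler is defined for n={total}, got {n}")
        ga = np.concatenate([rng.uniform(lo, hi, c) for lo, hi, c in strata])
        return rng.permuted(ga)

    return sample


def simulate_cohort(
    atlas: RoiAtlas,
    truth: GrowthTruth,
    n_subjects: int = 32,
    noise: NoiseConfig | None = None,
    seed=0,
    ga_sampler=None,
) -> list:
    """Simulate a cohort; per-subject seeds derive from the master seed."""
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be at least 2, got {n_subjects}")
    rng = as_rng(seed)
    sampler = ga_sampler or uniform_ga_sampler()
    ga = np.asarray(sampler(rng, n_subjects), dtype=float)
    sub_seeds = rng.integers(0, 2**31 - 1, n_subjects)
    return [
        simulate_subject(
            atlas, truth, ga[i], noise=noise, seed=int(sub_seeds[i]), subject_id=f"sub{i:03d}"
        )
        for i in range(n_subjects)
    ]


def noise_config_to_dict(cfg: NoiseConfig) -> dict:
    return dataclasses.asdict(cfg)
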