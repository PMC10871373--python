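"""Synthetic voltammetry sessions and bisection behaviour with known ground truth.

The generator emulates the data structure of an awake intracranial
fast-scan cyclic voltammetry (FSCV) experiment paired with a visual
temporal-bisection task:

* calibration sets: voltammetric sweep features that are a linear mixture of
  a dopamine template and a serotonin template plus i.i.d. Gaussian noise,
  with known concentration labels;
* session recordings: a 10 Hz sweep-feature timeseries driven by a slowly
  drifting tonic concentration (reflected Gaussian random walk) plus
  stimulus-locked exponential-decay transients, a linear feature drift and
  measurement noise;
* behaviour: a cumulative-Gaussian bisection observer whose per-trial
  bisection point shifts with the (z-scored) phasic transient amplitude
  (high transients -> more 'short' judgements) and whose spread shrinks
  with the (z-scored) tonic level at stimulus onset.

Everything is deterministic given the master seed: independent substreams
are spawned per component (trial order, tonic walk, transient amplitudes,
sweep noise, behaviour) so that e.g. skipping sweep synthesis does not
perturb the behavioural stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TaskConfig",
    "ObserverParams",
    "NeurochemParams",
    "CalibrationSet",
    "SessionRecording",
    "default_templates",
    "generate_calibration_set",
    "generate_session",
]


@dataclass
class TaskConfig:
    """Temporal-bisection task layout.

    Anchors default to the 500 ms / 1100 ms pair; probe durations are a
    linear grid of ``n_levels`` values spanning the anchors (inclusive),
    each presented equally often.
    """

    anchor_short: float = 0.5
    anchor_long: float = 1.1
    n_levels: int = 7
    n_trials: int = 300
    iti_mean: float = 5.0
    iti_jitter: float = 1.0
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        if not self.anchor_short < self.anchor_long:
            raise ValueError("anchor_short must be < anchor_long")
        if self.n_trials < self.n_levels:
            raise ValueError("n_trials must be at least n_levels")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.iti_jitter < 0 or self.iti_jitter >= self.iti_mean:
            raise ValueError("iti_jitter must be in [0, iti_mean)")

    @property
    def duration_levels(self) -> np.ndarray:
        return np.linspace(self.anchor_short, self.anchor_long, self.n_levels)

    def level_counts(self) -> np.ndarray:
        """Per-level trial counts: as balanced as possible, remainder placed
        symmetrically about the midpoint (outermost level pairs first, the
        middle level taking an odd leftover when the grid has one)."""
        q, r = divmod(self.n_trials, self.n_levels)
        counts = np.full(self.n_levels, q, dtype=int)
        order: list[int] = []
        if r % 2 == 1 and self.n_levels % 2 == 1:
            order.append(self.n_levels // 2)
        lo, hi = 0, self.n_levels - 1
        while lo < hi:
            order.extend([lo, hi])
            lo += 1
            hi -= 1
        for i in order[:r]:
            counts[i] += 1
        return counts

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.anchor_short + self.anchor_long)


@dataclass
class ObserverParams:
    """Cumulative-Gaussian bisection observer.

    ``bp_true`` is the generative bisection point (s); ``weber_true`` the
    generative Weber fraction (JND/BP, JND = 0.6745*sigma).
    ``phasic_coupling`` is the per-trial BP shift (s) per unit z-scored
    phasic transient amplitude, signed so that positive coupling makes
    high-dopamine trials more likely to be judged 'short' (temporal
    underestimation). ``tonic_coupling`` scales the trial sigma as
    ``sigma * exp(-tonic_coupling * z(tonic))`` so positive coupling means
    higher tonic level -> better precision.
    """

    bp_true: float = 0.8
    weber_true: float = 0.1
    lapse: float = 0.0
    phasic_coupling: float = 0.0
    tonic_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.weber_true <= 0:
            raise ValueError("weber_true must be positive")

    @property
    def sigma_true(self) -> float:
        # JND = 0.6745*sigma for the Gaussian model; weber = JND/BP
        return self.weber_true * self.bp_true / norm.ppf(0.75)


def default_templates(n_features: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm Gaussian-bump pseudo-voltammogram templates.

    The two analytes peak at different positions along the sweep axis so the
    templates are linearly independent but partially overlapping, as real
    dopamine/serotonin voltammograms are.
    """
    x = np.linspace(0.0, 1.0, n_features)
    t_da = np.exp(-0.5 * ((x - 0.35) / 0.10) ** 2)
    t_5ht = np.exp(-0.5 * ((x - 0.65) / 0.12) ** 2)
    return t_da / np.linalg.norm(t_da), t_5ht / np.linalg.norm(t_5ht)


@dataclass
class NeurochemParams:
    """Generative neurochemical signal parameters (concentrations in uM)."""

    template_da: np.ndarray = None  # type: ignore[assignment]
    template_5ht: np.ndarray = None  # type: ignore[assignment]
    tonic_mean: float = 1.0
    tonic_walk_sd: float = 0.008
    transient_amp_mean: float = 0.2
    transient_amp_sd: float = 0.05
    transient_amp_mean_5ht: float = 0.0
    transient_amp_sd_5ht: float = 0.0
    transient_latency: float = 0.6
    transient_tau: float = 0.2
    noise_sd: float = 0.1
    drift_slope: float = 1e-4

    def __post_init__(self) -> None:
        if self.template_da is None or self.template_5ht is None:
            t_da, t_5ht = default_templates()
            if self.template_da is None:
                self.template_da = t_da
            if self.template_5ht is None:
                self.template_5ht = t_5ht
        self.template_da = np.asarray(self.template_da, dtype=float)
        self.template_5ht = np.asarray(self.template_5ht, dtype=float)
        if self.template_da.shape != self.template_5ht.shape:
            raise ValueError("templates must have identical shape")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.transient_tau <= 0:
            raise ValueError("transient_tau must be positive")
        _check_independent(self.template_da, self.template_5ht)

    @property
    def n_features(self) -> int:
        return self.template_da.size


def _check_independent(a: np.ndarray, b: np.ndarray, tol: float = 1e-6) -> None:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("analyte templates must be non-zero")
    cosine = abs(float(a @ b) / (na * nb))
    if cosine > 1.0 - tol:
        raise ValueError("analyte templates are collinear; decoding is degenerate")


@dataclass
class CalibrationSet:
    """Sweep features with known analyte concentration labels."""

    sweeps: np.ndarray
    labels_da: np.ndarray
    labels_5ht: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.sweeps) == len(self.labels_da) == len(self.labels_5ht)):
            raise ValueError("sweeps and label vectors must have matching length")
        if np.any(self.labels_da < 0) or np.any(self.labels_5ht < 0):
            raise ValueError("concentration labels must be non-negative")


@dataclass
class SessionRecording:
    """One participant-session: sweeps, ground truth and the trial table.

    ``trials`` columns: onset_s, duration_s, response ('short'/'long'),
    truth_phasic_amp (uM), truth_tonic_at_onset (uM).
    """

    timestamps: np.ndarray
    sweeps: np.ndarray | None
    truth_da: np.ndarray
    truth_5ht: np.ndarray
    truth_tonic_da: np.ndarray
    trials: pd.DataFrame
    sample_rate: float
    seed: int

    def __post_init__(self) -> None:
        dt = np.diff(self.timestamps)
        if len(dt) and not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ValueError("timestamps must be uniformly spaced")
        last_needed = self.trials["onset_s"].max() + 1.1
        if last_needed > self.timestamps[-1] + 1e-9:
            raise ValueError("recording too short: a trial epoch extends past the end")


def generate_calibration_set(
    neuro: NeurochemParams,
    n_samples: int = 500,
    conc_grid: np.ndarray | list[float] = (0.0, 0.5, 1.0, 2.0),
    seed: int = 0,
) -> CalibrationSet:
    """In-vitro-style calibration sweeps over a factorial concentration grid.

    Labels cycle through the full factorial of ``conc_grid`` for both
    analytes; each sweep is ``da*template_da + 5ht*template_5ht`` plus
    Gaussian feature noise of ``neuro.noise_sd``.
    """
    grid = np.asarray(conc_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("conc_grid must be non-empty and non-negative")
    da_f, s_f = np.meshgrid(grid, grid, indexing="ij")
    factorial = np.column_stack([da_f.ravel(), s_f.ravel()])
    reps = int(np.ceil(n_samples / len(factorial)))
    labels = np.tile(factorial, (reps, 1))[:n_samples]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = rng.permutation(labels, axis=0)
    clean = np.outer(labels[:, 0], neuro.template_da) + np.outer(labels[:, 1], neuro.template_5ht)
    sweeps = clean + rng.normal(0.0, neuro.noise_sd, size=clean.shape)
    return CalibrationSet(sweeps=sweeps, labels_da=labels[:, 0], labels_5ht=labels[:, 1])


def _transient_train(
    timestamps: np.ndarray,
    onsets: np.ndarray,
    amps: np.ndarray,
    latency: float,
    tau: float,
) -> np.ndarray:
    """Sum of per-trial causal exponential-decay kernels."""
    out = np.zeros_like(timestamps)
    dt = timestamps[1] - timestamps[0]
    span = int(np.ceil(8.0 * tau / dt))  # kernel support truncated at 8 tau
    for onset, amp in zip(onsets, amps):
        i0 = int(np.searchsorted(timestamps, onset + latency - 1e-9))
        i1 = min(i0 + span, len(timestamps))
        if i0 >= i1:
            continue
        t_rel = timestamps[i0:i1] - onset - latency
        out[i0:i1] += amp * np.exp(-t_rel / tau)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_session(
    task: TaskConfig | None = None,
    observer: ObserverParams | None = None,
    neuro: NeurochemParams | None = None,
    seed: int = 0,
    include_sweeps: bool = True,
) -> SessionRecording:
    """Simulate one FSCV + bisection session with full ground truth.

    Trial onsets are snapped to the sample grid; durations are a balanced,
    shuffled assignment over the task's duration grid. The response is
    'long' with probability ``lapse/2 + (1-lapse)*Phi((d - bp_trial)/sigma_trial)``
    where ``bp_trial = bp_true + phasic_coupling*z(amp)`` (high transient
    amplitude -> more 'short' judgements for positive coupling) and
    ``sigma_trial = sigma_true*exp(-tonic_coupling*z(tonic at onset))``.

    Set ``include_sweeps=False`` to skip sweep-feature synthesis (behavioural
    simulations); all other streams are unchanged.
    """
    task = task or TaskConfig()
    observer = observer or ObserverParams()
    neuro = neuro or NeurochemParams()

    ss = np.random.SeedSequence(seed)
    rng_order, rng_tonic, rng_amp, rng_noise, rng_beh, rng_iti = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    dt = 1.0 / task.sample_rate
    # balanced duration assignment, shuffled
    durations = np.repeat(task.duration_levels, task.level_counts())
    durations = rng_order.permutation(durations)

    # onsets: jittered ITIs, snapped to the sample grid; leading margin for baselines
    itis = task.iti_mean + rng_iti.uniform(-task.iti_jitter, task.iti_jitter, task.n_trials - 1)
    onsets = np.concatenate([[2.0], 2.0 + np.cumsum(itis)])
    onsets = np.round(onsets * task.sample_rate) / task.sample_rate
    total = onsets[-1] + 4.0
    n_samp = int(np.round(total * task.sample_rate)) + 1
    timestamps = np.arange(n_samp) * dt
    if onsets[-1] + 1.1 > timestamps[-1]:
        raise ValueError("session too short for the configured number of trials")

    # tonic: reflected Gaussian random walk (|Brownian| is Brownian reflected at 0)
    walk = neuro.tonic_mean + np.cumsum(rng_tonic.normal(0.0, neuro.tonic_walk_sd, n_samp))
    tonic_da = np.abs(walk)
    walk5 = neuro.tonic_mean + np.cumsum(rng_tonic.normal(0.0, neuro.tonic_walk_sd, n_samp))
    tonic_5ht = np.abs(walk5)

    amps = np.clip(
        rng_amp.normal(neuro.transient_amp_mean, neuro.transient_amp_sd, task.n_trials), 0.0, None
    )
    truth_da = tonic_da + _transient_train(
        timestamps, onsets, amps, neuro.transient_latency, neuro.transient_tau
    )
    truth_5ht = tonic_5ht.copy()
    if neuro.transient_amp_mean_5ht > 0 or neuro.transient_amp_sd_5ht > 0:
        amps5 = np.clip(
            rng_amp.normal(
                neuro.transient_amp_mean_5ht, neuro.transient_amp_sd_5ht, task.n_trials
            ),
            0.0,
            None,
        )
        truth_5ht = truth_5ht + _transient_train(
            timestamps, onsets, amps5, neuro.transient_latency, neuro.transient_tau
        )

    sweeps = None
    if include_sweeps:
        sweeps = (
            np.outer(truth_da, neuro.template_da)
            + np.outer(truth_5ht, neuro.template_5ht)
            + neuro.drift_slope * timestamps[:, None]
            + rng_noise.normal(0.0, neuro.noise_sd, (n_samp, neuro.n_features))
        )

    onset_idx = np.round(onsets * task.sample_rate).astype(int)
    tonic_at_onset = tonic_da[onset_idx]
    bp_trial = observer.bp_true + observer.phasic_coupling * _zscore(amps)
    sigma_trial = observer.sigma_true * np.exp(-observer.tonic_coupling * _zscore(tonic_at_onset))
    p_long = observer.lapse / 2.0 + (1.0 - observer.lapse) * norm.cdf(
        (durations - bp_trial) / sigma_trial
    )
    responses = np.where(rng_beh.uniform(size=task.n_trials) < p_long, "long", "short")

    trials = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": durations,
            "response": responses,
            "truth_phasic_amp": amps,
            "truth_tonic_at_onset": tonic_at_onset,
        }
    )
    return SessionRecording(
        timestamps=timestamps,
        sweeps=sweeps,
        truth_da=truth_da,
        truth_5ht=truth_5ht,
        truth_tonic_da=tonic_da,
        trials=trials,
        sample_rate=task.sample_rate,
        seed=seed,
    )
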