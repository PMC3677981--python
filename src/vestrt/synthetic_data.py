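"""Synthetic stand-ins for the unpublished measurements.

The original per-trial button presses and 1 kHz inertial-measurement-unit
(IMU) recordings were never deposited.  This module generates both:

* RT datasets with ex-Gaussian trial noise centered so that the
  distribution's ``mu`` (or optionally its mode) equals the model RT
  ``T_threshold + T_additional`` — matching the experimental design of 30
  correct trials per condition per participant, 20 participants, and a 96%
  correct rate;
* "recorded" motion traces: the commanded profile delayed by an onset lag,
  plus a deterministic vibration waveform (translations only by default —
  the physical platform vibrated measurably for translations, barely for
  rotations) plus seeded white noise, at 1 kHz.  The vibration spectrum of
  the real platform was never published; the default here is a SYNTHETIC
  stand-in (a few fixed-phase 10–40 Hz sinusoids scaled to the peak of the
  commanded signal).

It also provides the onset estimator used to time-lock trials
(cross-correlation of the recording against the commanded signal) and
repeated-measurement averaging, which removes random but not deterministic
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .exgauss import ExGaussianParams, exgauss_mode, exgauss_sample
from .profiles import ConditionSpec, MotionProfile, ROTATION, make_profile
from .sensor_model import SensorParams, time_to_threshold

__all__ = [
    "VibrationSpec",
    "DEFAULT_TRANSLATION_VIBRATION",
    "RTDataset",
    "RecordedTrace",
    "simulate_rt_dataset",
    "make_recording",
    "average_recordings",
    "estimate_onset",
]


@dataclass(frozen=True)
class VibrationSpec:
    """Deterministic vibration: fixed-phase sinusoids with amplitudes given
    relative to the peak of the commanded signal."""

    frequencies_hz: tuple[float, ...]
    relative_amplitudes: tuple[float, ...]
    phases_rad: tuple[float, ...]

    def waveform(self, time: np.ndarray, peak: float) -> np.ndarray:
        out = np.zeros_like(time)
        for f, a, ph in zip(self.frequencies_hz, self.relative_amplitudes, self.phases_rad):
            out += a * peak * np.sin(2.0 * np.pi * f * time + ph)
        return out


#: Synthetic stand-in for the platform's translation vibration (the real
#: spectrum was only ever shown graphically).
DEFAULT_TRANSLATION_VIBRATION = VibrationSpec(
    frequencies_hz=(13.0, 24.0, 37.0),
    relative_amplitudes=(0.12, 0.08, 0.05),
    phases_rad=(0.4, 1.7, 2.9),
)


@dataclass(frozen=True)
class RTDataset:
    """Per-trial RT table plus the generating configuration.

    ``trials`` columns: condition_id, trial, direction, rt_ms, correct.
    """

    trials: pd.DataFrame
    params: SensorParams
    t_additional: float
    noise: dict[str, tuple[float, float]]
    seed: int

    def correct_trials(self, condition_id: str) -> np.ndarray:
        df = self.trials
        mask = (df["condition_id"] == condition_id) & df["correct"]
        return df.loc[mask, "rt_ms"].to_numpy()

    def to_csv(self, path_or_buf) -> None:
        self.trials.to_csv(path_or_buf, index=False, float_format="%.6f")


@dataclass(frozen=True)
class RecordedTrace:
    """One simulated IMU recording: acceleration for translations, angular
    velocity for rotations (what the real gyroscopes reported)."""

    time: np.ndarray
    signal: np.ndarray
    sample_rate: float
    motion_type: str
    direction: str  # {"leftward", "rightward"}
    true_lag_ms: float
    label: str = ""


def _commanded_quantity(profile: MotionProfile) -> np.ndarray:
    """The quantity the IMU reports: acceleration (translation) or
    integrated angular velocity (rotation)."""
    if profile.motion_type == ROTATION:
        return integrate.cumulative_trapezoid(
            profile.acceleration, profile.time, initial=0.0
        )
    return profile.acceleration


def simulate_rt_dataset(
    specs: list[ConditionSpec],
    params: SensorParams,
    t_additional: float,
    noise: dict[str, tuple[float, float]],
    n_trials: int = 600,
    error_rate: float = 0.04,
    seed: int = 0,
    sample_rate: float = 1000.0,
    measure_kind: str = "mu",
) -> RTDataset:
    """Simulate per-trial RTs around the model's predicted latencies.

    For each condition the ex-Gaussian location is chosen so that the
    distribution's mu (default) or mode equals ``T_threshold +
    t_additional``; trials are drawn as Gaussian + Exponential with the
    condition's (sigma, tau).  Directions are randomized and wrong answers
    are injected at ``error_rate`` and flagged (they are excluded before
    any fitting, as in the experimental protocol).
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    if measure_kind not in ("mu", "mode"):
        raise ValueError("measure_kind must be 'mu' or 'mode'")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        t_thr = time_to_threshold(make_profile(spec, sample_rate), params)
        if t_thr is None:
            raise ValueError(
                f"condition {spec.id}: stimulus never crosses sensory threshold"
            )
        target = t_thr + t_additional
        sigma, tau = noise[spec.id]
        mu_gen = target
        if measure_kind == "mode":
            # shift so the distribution's mode lands on the model RT
            mode0 = exgauss_mode(ExGaussianParams(mu=0.0, sigma=sigma, tau=tau))
            mu_gen = target - mode0
        gen = ExGaussianParams(mu=mu_gen, sigma=sigma, tau=tau)
        rts = exgauss_sample(gen, n_trials, rng)
        directions = rng.choice(["leftward", "rightward"], size=n_trials)
        correct = rng.random(n_trials) >= error_rate
        for k in range(n_trials):
            rows.append(
                {
                    "condition_id": spec.id,
                    "trial": k,
                    "direction": directions[k],
                    "rt_ms": rts[k],
                    "correct": bool(correct[k]),
                }
            )
    return RTDataset(
        trials=pd.DataFrame(rows),
        params=params,
        t_additional=t_additional,
        noise=dict(noise),
        seed=seed,
    )


def make_recording(
    profile: MotionProfile,
    vibration: VibrationSpec | None = None,
    noise_sd: float = 0.0,
    lag_ms: float = 0.0,
    seed: int | np.random.Generator | None = None,
    direction: str = "rightward",
) -> RecordedTrace:
    """Simulate one IMU recording of a commanded profile.

    The commanded signal is delayed by ``lag_ms``, the deterministic
    vibration waveform (identical on every call for a given spec) is added,
    and seeded white noise on top.  Leftward trials are sign-flipped.
    """
    if abs(lag_ms) > 500.0:
        raise ValueError("onset lag must lie within +/-500 ms")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    commanded = _commanded_quantity(profile)
    t = profile.time
    delayed = np.interp(t - lag_ms / 1000.0, t, commanded, left=0.0, right=commanded[-1])
    sig = delayed.copy()
    if vibration is not None:
        sig = sig + vibration.waveform(t, float(np.max(np.abs(commanded))))
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    if direction == "leftward":
        sig = -sig
    elif direction != "rightward":
        raise ValueError("direction must be 'leftward' or 'rightward'")
    return RecordedTrace(
        time=t,
        signal=sig,
        sample_rate=profile.sample_rate,
        motion_type=profile.motion_type,
        direction=direction,
        true_lag_ms=lag_ms,
        label=profile.label,
    )


def average_recordings(traces: list[RecordedTrace]) -> RecordedTrace:
    """Pointwise mean after sign-normalizing leftward trials.

    Averaging many repetitions suppresses the random noise by 1/sqrt(n)
    while the deterministic vibration component survives unchanged.
    """
    if not traces:
        raise ValueError("no recordings to average")
    rates = {tr.sample_rate for tr in traces}
    if len(rates) != 1:
        raise ValueError("mixed sample rates")
    lengths = {len(tr.signal) for tr in traces}
    if len(lengths) != 1:
        raise ValueError("recordings must have equal length")
    stack = np.stack(
        [tr.signal if tr.direction == "rightward" else -tr.signal for tr in traces]
    )
    return RecordedTrace(
        time=traces[0].time,
        signal=stack.mean(axis=0),
        sample_rate=traces[0].sample_rate,
        motion_type=traces[0].motion_type,
        direction="rightward",
        true_lag_ms=float(np.mean([tr.true_lag_ms for tr in traces])),
        label=traces[0].label,
    )


def estimate_onset(recorded: RecordedTrace, commanded: MotionProfile) -> float:
    """Onset lag (ms) maximizing the cross-correlation of the recording with
    the commanded signal, at the 1-sample (1 ms at 1 kHz) resolution.

    The sign of the correlation is ignored, so leftward recordings align
    against a rightward command without explicit flipping.
    """
    ref = _commanded_quantity(commanded)
    if not np.any(ref):
        raise ValueError("all-zero commanded signal")
    if recorded.sample_rate != commanded.sample_rate:
        raise ValueError("sample-rate mismatch between recording and command")
    corr = np.correlate(recorded.signal, ref, mode="full")
    lags = np.arange(-(len(ref) - 1), len(recorded.signal))
    best = lags[int(np.argmax(np.abs(corr)))]
    return 1000.0 * best / recorded.sample_rate
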