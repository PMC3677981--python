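"""Commanded motion stimuli and their kinematics.

A stimulus is parameterized by three quantities: the shape of its
acceleration profile (trapezoidal or triangular), the total duration ``T``
(acceleration phase on ``[0, T/2]`` followed by a mirrored deceleration
phase on ``[T/2, T]``), and an amplitude.  For translations the amplitude
is the peak acceleration (m/s²); for yaw rotations it is the peak angular
velocity (°/s), the conventional unit for rotational stimuli because
semicircular-canal afferents encode angular velocity at mid frequencies.

The triangular profile rises linearly to its peak at ``T/4`` and falls back
to zero at ``T/2``.  The trapezoidal profile reaches peak acceleration at
``T/10``, holds a plateau until ``2T/5`` and falls to zero at ``T/2``.  Both
geometries displace the platform by ``v_peak * T / 2`` in total, which is
how the built-in condition table's distances are obtained.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, replace, field

import numpy as np
from scipy import integrate

__all__ = [
    "MotionProfile",
    "ConditionSpec",
    "CONDITIONS",
    "make_profile",
    "kinematics",
    "scale_amplitude",
    "peak_acceleration",
    "profile_to_csv",
    "profile_from_csv",
]

TRANSLATION = "translation"
ROTATION = "rotation"
TRAPEZOIDAL = "trapezoidal"
TRIANGULAR = "triangular"

_SHAPES = (TRAPEZOIDAL, TRIANGULAR)
_MOTION_TYPES = (TRANSLATION, ROTATION)


@dataclass(frozen=True)
class MotionProfile:
    """A sampled acceleration trace with kinematic metadata.

    ``acceleration`` is in m/s² for translations and °/s² for rotations.
    ``amplitude`` follows the stimulus convention: peak acceleration for
    translations, peak angular velocity for rotations.
    """

    time: np.ndarray
    acceleration: np.ndarray
    sample_rate: float
    motion_type: str
    shape: str
    duration: float
    amplitude: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(
            self, "acceleration", np.asarray(self.acceleration, dtype=float)
        )
        if self.time.shape != self.acceleration.shape or self.time.ndim != 1:
            raise ValueError("time and acceleration must be 1-D arrays of equal length")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform at sample_rate")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: stimulus definition plus the previously
    reported discrimination threshold and total travel distance for it."""

    id: str
    motion_type: str
    shape: str
    duration: float  # s
    amplitude: float  # m/s² (translation) or °/s (rotation)
    printed_threshold: float  # same units as amplitude
    printed_distance: float  # m (translation) or ° (rotation)
    label: str = ""


def _spec(cid, motion, shape, T, amp, thr, dist, label):
    return ConditionSpec(cid, motion, shape, T, amp, thr, dist, label)


#: The eight built-in conditions (4 translations, 4 yaw rotations).
CONDITIONS: dict[str, ConditionSpec] = {
    s.id: s
    for s in (
        _spec("I", TRANSLATION, TRAPEZOIDAL, 5.0, 0.16, 0.06, 0.80, "Tra 5 s"),
        _spec("II", TRANSLATION, TRIANGULAR, 5.0, 0.16, 0.07, 0.50, "Tri 5 s"),
        _spec("III", TRANSLATION, TRIANGULAR, 2.5, 0.16, 0.06, 0.125, "Tri 2.5 s"),
        _spec("IV", TRANSLATION, TRIANGULAR, 2.5, 0.09, 0.05, 0.07, "Low Amp"),
        _spec("V", ROTATION, TRIANGULAR, 5.0, 17.0, 1.6, 42.5, "Tri 5 s"),
        _spec("VI", ROTATION, TRAPEZOIDAL, 5.0, 17.0, 1.7, 42.5, "Tra 5 s"),
        _spec("VII", ROTATION, TRAPEZOIDAL, 2.5, 17.0, 1.4, 21.3, "Tra 2.5 s"),
        _spec("VIII", ROTATION, TRAPEZOIDAL, 2.5, 10.0, 1.4, 12.5, "Low Amp"),
    )
}


def peak_acceleration(spec: ConditionSpec) -> float:
    """Peak acceleration of a condition's commanded profile.

    For translations this is the amplitude itself.  For rotations the
    amplitude is the peak angular velocity ``v`` and the peak acceleration
    follows from the profile geometry: ``4 v / T`` for a triangle (area of
    the acceleration triangle over the half-duration equals ``v``) and
    ``v / (0.4 T)`` for a trapezoid (plateau plus two ramps cover an
    effective ``0.4 T``).
    """
    if spec.motion_type == TRANSLATION:
        return spec.amplitude
    if spec.shape == TRIANGULAR:
        return 4.0 * spec.amplitude / spec.duration
    return spec.amplitude / (0.4 * spec.duration)


def _half_phase(t: np.ndarray, T: float, shape: str) -> np.ndarray:
    """Normalized acceleration on the acceleration phase [0, T/2], zero after."""
    half = T / 2.0
    if shape == TRIANGULAR:
        rise = T / 4.0
        up = t / rise
        down = 2.0 - t / rise
        a = np.where(t <= rise, up, down)
    else:
        rise = T / 10.0
        plateau_end = 2.0 * T / 5.0
        a = np.where(
            t <= rise,
            t / rise,
            np.where(t <= plateau_end, 1.0, (half - t) / rise),
        )
    return np.where((t >= 0) & (t <= half), np.clip(a, 0.0, 1.0), 0.0)


def make_profile(spec: ConditionSpec, sample_rate: float = 1000.0) -> MotionProfile:
    """Construct the commanded stimulus for a condition.

    The acceleration phase occupies ``[0, T/2]``; the deceleration phase is
    its negated mirror image on ``[T/2, T]``, so the motion ends at rest and
    the acceleration trace is antisymmetric about ``T/2``.
    """
    if spec.shape not in _SHAPES:
        raise ValueError(f"unknown profile shape {spec.shape!r}; expected one of {_SHAPES}")
    if spec.motion_type not in _MOTION_TYPES:
        raise ValueError(
            f"unknown motion type {spec.motion_type!r}; expected one of {_MOTION_TYPES}"
        )
    if spec.duration <= 0:
        raise ValueError("duration must be positive")
    if spec.amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if sample_rate < 100.0:
        raise ValueError("sample_rate must be at least 100 Hz")

    T = spec.duration
    n = int(round(T * sample_rate))
    t = np.arange(n + 1) / sample_rate
    a_pk = peak_acceleration(spec)
    a = a_pk * (_half_phase(t, T, spec.shape) - _half_phase(T - t, T, spec.shape))
    return MotionProfile(
        time=t,
        acceleration=a,
        sample_rate=sample_rate,
        motion_type=spec.motion_type,
        shape=spec.shape,
        duration=T,
        amplitude=spec.amplitude,
        label=spec.id or spec.label,
    )


def kinematics(profile: MotionProfile) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and displacement traces (cumulative trapezoid-rule integrals)."""
    v = integrate.cumulative_trapezoid(profile.acceleration, profile.time, initial=0.0)
    d = integrate.cumulative_trapezoid(v, profile.time, initial=0.0)
    return v, d


def scale_amplitude(profile: MotionProfile, factor: float) -> MotionProfile:
    """Scale the acceleration trace (and the amplitude metadata) pointwise."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(
        profile,
        acceleration=profile.acceleration * factor,
        amplitude=profile.amplitude * factor,
    )


# ---------------------------------------------------------------------------
# serialization: two-column CSV with a JSON header comment for metadata

_META_FIELDS = ("sample_rate", "motion_type", "shape", "duration", "amplitude", "label")


def profile_to_csv(profile: MotionProfile, path_or_buf) -> None:
    meta = {k: getattr(profile, k) for k in _META_FIELDS}
    header = "# " + json.dumps(meta) + "\ntime_s,acceleration\n"
    body = "\n".join(
        f"{t:.6f},{a:.10g}" for t, a in zip(profile.time, profile.acceleration)
    )
    text = header + body + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def profile_from_csv(path_or_buf) -> MotionProfile:
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing JSON metadata header comment")
    meta = json.loads(lines[0][1:].strip())
    data = np.loadtxt(io.StringIO("\n".join(lines[2:])), delimiter=",")
    return MotionProfile(time=data[:, 0], acceleration=data[:, 1], **meta)
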