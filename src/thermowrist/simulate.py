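"""Synthetic wrist-sensor cohort generator.

Emulates the structure of a head-target recording study: each participant
performs ~15 s behaviors with a hand held at each of six head locations
(plus an off-body recording) while rotating the elbow, and a wrist device
samples four thermopiles, two orientation-derived IMU channels and a
proximity channel at an irregular 5-7 Hz.

Generative model per sample::

    value = location mean + participant offset
            + participant-location jitter (optional)
            + elbow-rotation sinusoid (IMU channels only)
            + i.i.d. Gaussian noise

The participant offset is one 7-vector per participant shared by all their
segments; the optional participant-location jitter perturbs each location's
signature independently per participant (off by default), modeling people
who hold the hand differently at each spot rather than merely reading
shifted sensors.

Location means encode the physics: skin is warmer than ambient so head
targets raise the thermopile readings (each thermopile has a different
field of view, so the 4-vector differs by location); the hand is near a
surface so proximity drops from its out-of-range ceiling; wrist orientation
differs by location. Nose, cheek and eyebrow are deliberately given nearly
identical proximity/orientation signatures — they are distinguishable
mainly through the thermal channels, which is the confusability structure
the analysis is designed to detect. The ``thermal_contrast`` dial scales
every thermal deviation from ambient: 0 removes all thermal information
while leaving the other channels untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import HEAD_TARGETS, OFF_BODY, TARGET_LABELS, Dataset, Segment

logger = logging.getLogger(__name__)

#: Ambient thermopile reading (device units ~ degrees C) used as the
#: baseline that thermal contrasts are measured from.
AMBIENT_THERMAL = 26.0

#: Proximity reading when no surface is in range (sensor ceiling).
PROXIMITY_CEILING = 255.0


@dataclass(frozen=True)
class LocationSignature:
    """Expected sensor readings while the hand is at one location."""

    target: str
    thermal_mean: tuple[float, float, float, float]
    proximity_mean: float
    imu_mean: tuple[float, float]
    within_segment_sd: tuple[float, ...]  # 7 values, channel order

    def __post_init__(self) -> None:
        if self.target not in TARGET_LABELS:
            raise ValueError(f"unknown target {self.target!r}")
        if len(self.within_segment_sd) != 7:
            raise ValueError("within_segment_sd needs 7 values")
        if any(sd < 0 for sd in self.within_segment_sd):
            raise ValueError("within_segment_sd must be non-negative")
        if self.target in HEAD_TARGETS:
            if min(self.thermal_mean) <= AMBIENT_THERMAL:
                raise ValueError(
                    f"{self.target}: head-target thermopile means must exceed "
                    f"ambient ({AMBIENT_THERMAL})"
                )
            if self.proximity_mean >= PROXIMITY_CEILING:
                raise ValueError(
                    f"{self.target}: head-target proximity must be below the "
                    "out-of-range ceiling"
                )

    def mean_vector(self, thermal_contrast: float) -> np.ndarray:
        """Channel-ordered mean with thermal deviations scaled by the dial."""
        thermal = AMBIENT_THERMAL + thermal_contrast * (
            np.asarray(self.thermal_mean) - AMBIENT_THERMAL
        )
        return np.concatenate(
            [thermal, np.asarray(self.imu_mean), [self.proximity_mean]]
        )


_NOISE_SD = (0.3, 0.3, 0.3, 0.3, 0.15, 0.15, 5.0)


def _sig(target, thermal, prox, imu):
    return LocationSignature(target, thermal, prox, imu, _NOISE_SD)


def default_signatures() -> dict[str, LocationSignature]:
    """Per-location signatures.

    Thermopile 4-vectors differ per head location (different fields of
    view); nose/cheek/eyebrow share nearly identical proximity and
    orientation values, and top-head/back-head share a raised-arm
    orientation, so every location has at least one neighbor the
    no-thermal subspace confuses it with while the thermal subspace
    separates them all.
    """
    return {
        s.target: s
        for s in [
            _sig("mouth", (33.5, 32.0, 31.0, 30.0), 35.0, (0.30, -0.20)),
            _sig("nose", (32.5, 33.5, 31.5, 30.5), 22.0, (0.35, -0.10)),
            _sig("cheek", (31.5, 32.5, 33.5, 30.5), 24.0, (0.25, 0.00)),
            _sig("eyebrow", (31.0, 31.5, 33.0, 32.5), 26.0, (0.30, 0.10)),
            _sig("top-head", (30.0, 31.0, 32.0, 33.5), 60.0, (-0.45, 0.35)),
            _sig("back-head", (29.5, 30.0, 31.0, 33.0), 68.0, (-0.38, 0.45)),
            LocationSignature(
                OFF_BODY,
                (AMBIENT_THERMAL,) * 4,
                PROXIMITY_CEILING,
                (0.0, 0.0),
                _NOISE_SD,
            ),
        ]
    }


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reflect the emulated study: 39 participants, ~15 s per
    behavior, 5-7 Hz sampling, circular elbow rotation during each behavior
    and a ~1 s rater lag at segment edges before both raters agree the hand
    is on target.
    """

    n_participants: int = 39
    segment_duration_s: float = 15.0
    rate_hz_range: tuple[float, float] = (5.0, 7.0)
    signatures: dict[str, LocationSignature] = field(default_factory=default_signatures)
    participant_sd: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8, 0.2, 0.2, 8.0)
    participant_location_sd: tuple[float, ...] = (0.0,) * 7
    elbow_rotation_amplitude: tuple[float, float] = (0.25, 0.25)
    elbow_rotation_hz: float = 0.5
    rater_lag_s: float = 1.0
    thermal_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants (paired analyses)")
        if self.segment_duration_s <= 0:
            raise ValueError("segment duration must be positive")
        low, high = self.rate_hz_range
        if not (0 < low <= high):
            raise ValueError("rate range must satisfy 0 < low <= high")
        for name in ("participant_sd", "participant_location_sd"):
            sd = getattr(self, name)
            if len(sd) != 7 or any(s < 0 for s in sd):
                raise ValueError(f"{name} needs 7 non-negative values")
        if self.rater_lag_s < 0:
            raise ValueError("rater lag must be non-negative")
        missing = [t for t in TARGET_LABELS if t not in self.signatures]
        if missing:
            raise ValueError(f"signatures missing for {missing}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signatures"] = {k: asdict(v) for k, v in self.signatures.items()}
        return d


def default_config(**overrides) -> CohortConfig:
    """The default study conditions, optionally with field overrides."""
    return CohortConfig(**overrides)


def _draw_timestamps(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    low, high = cfg.rate_hz_range
    # inter-sample gaps uniform in [1/high, 1/low] s; keep every sample
    # whose timestamp fits inside the nominal duration
    max_n = int(np.ceil(cfg.segment_duration_s * high)) + 2
    gaps = rng.uniform(1.0 / high, 1.0 / low, size=max_n)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    return t[t <= cfg.segment_duration_s]


def _participant_offset(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, cfg.participant_sd, size=7)


def generate_session(
    cfg: CohortConfig, participant_id: str, rng_seed: int
) -> list[Segment]:
    """Generate one participant's session: six head segments plus off-body.

    Fully determined by ``(cfg, participant_id, rng_seed)``. The
    participant's random channel offset is drawn first from ``rng_seed``,
    then each segment's timestamps, rotation phase and noise.
    """
    if not isinstance(rng_seed, (int, np.integer)):
        raise TypeError("rng_seed must be an integer")
    rng = np.random.default_rng(rng_seed)
    offset = _participant_offset(cfg, rng)
    segments = []
    for k, label in enumerate(TARGET_LABELS):
        sig = cfg.signatures[label]
        t = _draw_timestamps(cfg, rng)
        n = t.shape[0]
        mean = sig.mean_vector(cfg.thermal_contrast)
        # participant-specific deviation of this location's signature
        # (how *this* person holds the hand here); its thermal part scales
        # with the contrast dial like every other thermal deviation
        loc_jitter = rng.normal(0.0, cfg.participant_location_sd, size=7)
        loc_jitter[:4] *= cfg.thermal_contrast
        values = mean[None, :] + offset[None, :] + loc_jitter[None, :]
        values = values + rng.normal(0.0, sig.within_segment_sd, size=(n, 7))
        # circular elbow rotation shows up as quadrature sinusoids on the
        # two orientation channels (head targets only; the arm rests off-body)
        if label != OFF_BODY:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            omega = 2.0 * np.pi * cfg.elbow_rotation_hz * t + phase
            amp = cfg.elbow_rotation_amplitude
            values[:, 4] += amp[0] * np.sin(omega)
            values[:, 5] += amp[1] * np.cos(omega)
            on_target = (t >= cfg.rater_lag_s) & (t <= t[-1] - cfg.rater_lag_s)
        else:
            on_target = np.zeros(n, dtype=bool)
        segments.append(
            Segment(
                participant_id=participant_id,
                segment_id=f"seg{k:02d}-{label}",
                label=label,
                t=t,
                values=values,
                on_target=on_target,
            )
        )
    return segments


def generate_cohort(cfg: CohortConfig) -> Dataset:
    """Generate the full cohort; deterministic in ``cfg.seed``."""
    segments = []
    for i in range(cfg.n_participants):
        pid = f"P{i:03d}"
        # stable per-participant seed derived from the master seed
        seed = int(
            np.random.SeedSequence([cfg.seed, i]).generate_state(1, np.uint32)[0]
        )
        logger.info("generating participant %s (seed %d)", pid, seed)
        segments.extend(generate_session(cfg, pid, seed))
    return Dataset(segments=segments)
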