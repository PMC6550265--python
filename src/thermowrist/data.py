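"""Core domain types and dataset serialization.

A recording session is a set of :class:`Segment` objects, one per behavior:
the participant held a hand at one of six head locations (or off the body)
while seven sensor channels were sampled at an irregular 5-7 Hz. Channel
order is a single global constant, ``CHANNELS``; downstream code selects
channels only through :class:`ChannelSubset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Fixed global channel order: four thermopiles, two orientation-derived
#: IMU channels, one time-of-flight proximity channel.
CHANNELS: tuple[str, ...] = (
    "thermal1",
    "thermal2",
    "thermal3",
    "thermal4",
    "imu1",
    "imu2",
    "proximity",
)

HEAD_TARGETS: tuple[str, ...] = (
    "mouth",
    "nose",
    "cheek",
    "eyebrow",
    "top-head",
    "back-head",
)
OFF_BODY = "off-body"
TARGET_LABELS: tuple[str, ...] = HEAD_TARGETS + (OFF_BODY,)

CSV_COLUMNS = [
    "participant_id",
    "segment_id",
    "label",
    "t",
    *CHANNELS[:4],
    "imu1",
    "imu2",
    "proximity",
    "on_target",
]


@dataclass(frozen=True)
class ChannelSubset:
    """A named selection of channel positions within ``CHANNELS``."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError("channel subset must be non-empty")
        if any(i < 0 or i >= len(CHANNELS) for i in self.indices):
            raise ValueError("channel index out of range")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(CHANNELS[i] for i in self.indices)

    def __len__(self) -> int:
        return len(self.indices)


#: Proximity + IMU only (the baseline sensor complement).
NO_THERMAL = ChannelSubset("no-thermal", (4, 5, 6))
#: All seven channels.
WITH_THERMAL = ChannelSubset("with-thermal", (0, 1, 2, 3, 4, 5, 6))
#: The four thermopiles alone.
THERMAL_ONLY = ChannelSubset("thermal-only", (0, 1, 2, 3))

SUBSETS = {s.name: s for s in (NO_THERMAL, WITH_THERMAL, THERMAL_ONLY)}


class ValidationError(ValueError):
    """A domain invariant was violated."""


class ParseError(ValueError):
    """A serialized dataset could not be parsed."""


@dataclass
class Segment:
    """One contiguous labeled recording.

    Parameters
    ----------
    participant_id, segment_id : str
        Opaque identifiers; (participant_id, segment_id) is unique in a
        dataset.
    label : str
        One of ``TARGET_LABELS``.
    t : ndarray, shape (n,)
        Seconds since session start; strictly increasing, non-negative.
    values : ndarray, shape (n, 7)
        Sensor readings in ``CHANNELS`` order.
    on_target : ndarray of bool, shape (n,)
        True where both raters marked the hand as on the target. All False
        for off-body segments.
    """

    participant_id: str
    segment_id: str
    label: str
    t: np.ndarray
    values: np.ndarray
    on_target: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.on_target = np.asarray(self.on_target, dtype=bool)
        if self.label not in TARGET_LABELS:
            raise ValidationError(f"unknown target label {self.label!r}")
        n = self.t.shape[0]
        if n < 1:
            raise ValidationError("segment must contain at least one sample")
        if self.values.shape != (n, len(CHANNELS)):
            raise ValidationError(
                f"expected values of shape ({n}, {len(CHANNELS)}), "
                f"got {self.values.shape}"
            )
        if self.on_target.shape != (n,):
            raise ValidationError("on_target mask length must equal sample count")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite sample in segment")
        if np.any(self.t < 0):
            raise ValidationError("timestamps must be non-negative")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"timestamps not strictly increasing in segment "
                f"({self.participant_id}, {self.segment_id})"
            )
        if self.label == OFF_BODY and self.on_target.any():
            raise ValidationError("off-body segments cannot be on-target")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    def equals(self, other: "Segment", atol: float = 1e-9) -> bool:
        return (
            self.participant_id == other.participant_id
            and self.segment_id == other.segment_id
            and self.label == other.label
            and np.array_equal(self.on_target, other.on_target)
            and np.allclose(self.t, other.t, atol=atol, rtol=0)
            and np.allclose(self.values, other.values, atol=atol, rtol=0)
        )


@dataclass
class Dataset:
    """A cohort of segments with a fixed channel order."""

    segments: list[Segment]
    channel_names: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        if tuple(self.channel_names) != CHANNELS:
            raise ValidationError("channel order must be the global CHANNELS constant")

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.participant_id, None)
        return list(seen)

    def segments_for(self, participant_id: str) -> list[Segment]:
        return [s for s in self.segments if s.participant_id == participant_id]

    def equals(self, other: "Dataset", atol: float = 1e-9) -> bool:
        if len(self.segments) != len(other.segments):
            return False
        return all(a.equals(b, atol=atol) for a, b in zip(self.segments, other.segments))

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per sample, sorted by participant, segment, t."""
        parts = []
        for s in self.segments:
            df = pd.DataFrame(s.values, columns=list(CHANNELS))
            df.insert(0, "participant_id", s.participant_id)
            df.insert(1, "segment_id", s.segment_id)
            df.insert(2, "label", s.label)
            df.insert(3, "t", s.t)
            df["on_target"] = s.on_target.astype(int)
            parts.append(df[CSV_COLUMNS])
        if not parts:
            return pd.DataFrame(columns=CSV_COLUMNS)
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(
            ["participant_id", "segment_id", "t"], kind="stable"
        ).reset_index(drop=True)


def _segment_from_rows(pid: str, sid: str, rows: pd.DataFrame) -> Segment:
    labels = rows["label"].unique()
    if len(labels) != 1:
        raise ParseError(
            f"segment ({pid}, {sid}) has multiple labels: {sorted(labels)}"
        )
    # file order is authoritative: decreasing timestamps must surface as a
    # validation error, not be silently re-sorted
    try:
        return Segment(
            participant_id=str(pid),
            segment_id=str(sid),
            label=str(labels[0]),
            t=rows["t"].to_numpy(dtype=float),
            values=rows[list(CHANNELS)].to_numpy(dtype=float),
            on_target=rows["on_target"].to_numpy(dtype=float).astype(bool),
        )
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:  # non-numeric cell etc.
        first_line = int(rows.index.min()) + 2  # header + 1-based
        raise ParseError(
            f"malformed row near line {first_line} in segment ({pid}, {sid}): {exc}"
        ) from exc


def read_dataset(path) -> Dataset:
    """Read a cohort CSV (one row per sample) into a :class:`Dataset`.

    The file must contain exactly the documented columns. Segments are
    grouped by (participant_id, segment_id) with sample order preserved.
    """
    try:
        df = pd.read_csv(path, dtype={"participant_id": str, "segment_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        raise ParseError(f"unexpected columns: {extra}")
    segments = []
    for (pid, sid), rows in df.groupby(["participant_id", "segment_id"], sort=True):
        segments.append(_segment_from_rows(pid, sid, rows))
    return Dataset(segments=segments)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a cohort CSV; ``read_dataset`` recovers the dataset exactly.

    Rows are sorted by participant, segment, then timestamp, so output is a
    deterministic function of the dataset.
    """
    dataset.to_frame().to_csv(path, index=False)


def mask_samples(segment: Segment, on_target_only: bool) -> np.ndarray:
    """Return the (n_selected, 7) sample matrix used for statistics.

    Head-target statistics conventionally use only the samples both raters
    marked on-target; off-body segments (all-False mask) always contribute
    all samples.
    """
    if on_target_only and segment.label != OFF_BODY:
        sel = segment.values[segment.on_target]
        if sel.shape[0] == 0:
            raise ValidationError(
                f"segment ({segment.participant_id}, {segment.segment_id}) "
                "has no on-target samples"
            )
        return sel
    return segment.values


def subset_dataset(dataset: Dataset, transform) -> Dataset:
    """Return a new Dataset with ``values`` mapped through ``transform``."""
    return Dataset(
        segments=[replace(s, values=transform(s.values)) for s in dataset.segments]
    )
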