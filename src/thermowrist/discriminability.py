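"""Discriminability-distance analysis.

For one participant and one pair of head targets, the *discriminability
distance* is the Euclidean distance between the two segments' per-channel
median vectors (computed on z-scaled, on-target samples). A permutation
baseline re-partitions the pooled samples of the two segments into groups
of the original sizes many times and records the distance each time; the
median of that null distribution is the baseline discriminability expected
when the labels carry no information.

Cohort-level inference runs three paired signed-rank analyses per target
pair across participants:

1. observed distance vs. permutation-null median, proximity+IMU channels;
2. observed distance vs. permutation-null median, all seven channels;
3. observed distance without vs. with the thermal channels.

Because Euclidean distances over nested channel sets obey the partition
identity ``d_with**2 = d_no**2 + d_thermal**2``, the paired difference in
analysis 3 is strictly positive whenever the thermal medians differ at all
— extra channels can only add length. Analysis 3 therefore measures the
*size* of the thermal increment but cannot serve as a null-calibrated test
of whether the thermal channels carry information. For that question the
module additionally reports a *thermal-gain* test: per participant, the
thermal-only distance is referred to its own coupled permutation null,
giving a p-value that is uniform when the thermal channels are
uninformative; across participants these quantiles are tested against 1/2
with the signed-rank test. See ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data import (
    HEAD_TARGETS,
    NO_THERMAL,
    THERMAL_ONLY,
    WITH_THERMAL,
    ChannelSubset,
    Dataset,
    Segment,
    mask_samples,
)
from .stats import (
    bonferroni,
    effect_size,
    median_abs_deviation,
    wilcoxon_signed_rank,
)

logger = logging.getLogger(__name__)

N_PAIRS = len(HEAD_TARGETS) * (len(HEAD_TARGETS) - 1) // 2  # 15
PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(HEAD_TARGETS, 2))


@dataclass(frozen=True)
class MedianVector:
    """Per-channel medians of one segment over a channel subset."""

    subset: ChannelSubset
    values: np.ndarray


@dataclass
class NullDistribution:
    """Permutation null of the pair distance for one participant/pair."""

    participant_id: str
    pair: tuple[str, str]
    subset: ChannelSubset
    n_shuffles: int
    distances: np.ndarray
    observed: float

    @property
    def null_median(self) -> float:
        return float(np.median(self.distances))

    @property
    def p_value(self) -> float:
        """Empirical p with the add-one convention (never exactly zero)."""
        r = int(np.count_nonzero(self.distances >= self.observed))
        return (r + 1) / (self.n_shuffles + 1)


def median_vector(
    segment: Segment, subset: ChannelSubset, on_target_only: bool = True
) -> MedianVector:
    """Per-channel median over the segment's (optionally masked) samples.

    Even sample counts use the mean of the two middle order statistics.
    """
    samples = mask_samples(segment, on_target_only)
    return MedianVector(subset, np.median(samples[:, subset.indices], axis=0))


def pair_distance(a: MedianVector, b: MedianVector) -> float:
    """Euclidean distance between two median vectors on one subset."""
    if a.subset != b.subset:
        raise ValueError(
            f"subset mismatch: {a.subset.name!r} vs {b.subset.name!r}"
        )
    return float(np.linalg.norm(a.values - b.values))


def _canonical(seg_a: Segment, seg_b: Segment) -> tuple[Segment, Segment]:
    """Order the two segments by the global head-target order."""
    if HEAD_TARGETS.index(seg_a.label) > HEAD_TARGETS.index(seg_b.label):
        return seg_b, seg_a
    return seg_a, seg_b


def _null_median_matrix(
    pooled: np.ndarray, n_a: int, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_shuffles, 2, n_channels) group-median array under re-partition."""
    n = pooled.shape[0]
    # one random permutation of the pooled samples per shuffle
    keys = rng.random((n_shuffles, n))
    order = np.argsort(keys, axis=1)
    grp_a = pooled[order[:, :n_a]]  # (S, n_a, k)
    grp_b = pooled[order[:, n_a:]]
    med = np.stack(
        [np.median(grp_a, axis=1), np.median(grp_b, axis=1)], axis=1
    )
    return med


def permutation_null(
    seg_a: Segment,
    seg_b: Segment,
    subset: ChannelSubset,
    n_shuffles: int = 1000,
    seed: int = 0,
    on_target_only: bool = True,
) -> NullDistribution:
    """Permutation baseline for one participant's pair of head segments.

    Pools both segments' samples, re-partitions into the original group
    sizes ``n_shuffles`` times, and records the median-vector distance each
    time. Deterministic in ``seed`` and invariant to the order the two
    segments are given (they are put in a canonical label order first).
    """
    if seg_a.participant_id != seg_b.participant_id:
        raise ValueError("both segments must come from one participant")
    if seg_a.label == seg_b.label:
        raise ValueError("segments must have distinct head-target labels")
    seg_a, seg_b = _canonical(seg_a, seg_b)
    A = mask_samples(seg_a, on_target_only)[:, subset.indices]
    B = mask_samples(seg_b, on_target_only)[:, subset.indices]
    observed = float(np.linalg.norm(np.median(A, axis=0) - np.median(B, axis=0)))
    pooled = np.vstack([A, B])
    rng = np.random.default_rng(seed)
    med = _null_median_matrix(pooled, A.shape[0], n_shuffles, rng)
    distances = np.linalg.norm(med[:, 0, :] - med[:, 1, :], axis=1)
    return NullDistribution(
        participant_id=seg_a.participant_id,
        pair=(seg_a.label, seg_b.label),
        subset=subset,
        n_shuffles=n_shuffles,
        distances=distances,
        observed=observed,
    )


@dataclass
class DiscriminabilityResult:
    """Cohort-level rows plus the per-participant distance table."""

    rows: pd.DataFrame
    per_participant: pd.DataFrame
    n_shuffles: int
    seed: int


def _participant_segments(dataset: Dataset) -> dict[str, dict[str, Segment]]:
    by_pid: dict[str, dict[str, Segment]] = {}
    for seg in dataset.segments:
        if seg.label in HEAD_TARGETS:
            by_pid.setdefault(seg.participant_id, {})[seg.label] = seg
    return by_pid


def run_discriminability(
    dataset: Dataset,
    n_shuffles: int = 1000,
    seed: int = 0,
    on_target_only: bool = True,
) -> DiscriminabilityResult:
    """Full pairwise discriminability analysis of a z-scaled cohort.

    For each of the 15 head-target pairs: per-participant observed
    distances without and with the thermal channels, coupled permutation
    nulls (the same re-partitions are used for every channel subset), the
    three cohort signed-rank analyses with Bonferroni correction over the
    15-pair family, the robust paired effect size and the null-calibrated
    thermal-gain test.

    Participants missing a head target are excluded from the affected
    pairs with a warning.
    """
    by_pid = _participant_segments(dataset)
    pids = list(by_pid)
    if len(pids) < 2:
        raise ValueError("need at least 2 participants with head segments")

    recs = []
    for p_idx, pid in enumerate(pids):
        segs = by_pid[pid]
        for pair_idx, (la, lb) in enumerate(PAIRS):
            if la not in segs or lb not in segs:
                logger.warning(
                    "participant %s lacks %s; excluded from pair %s-%s",
                    pid,
                    la if la not in segs else lb,
                    la,
                    lb,
                )
                continue
            A = mask_samples(segs[la], on_target_only)
            B = mask_samples(segs[lb], on_target_only)
            med_a = np.median(A, axis=0)
            med_b = np.median(B, axis=0)
            diff = med_a - med_b
            pooled = np.vstack([A, B])
            sub_seed = int(
                np.random.SeedSequence([seed, p_idx, pair_idx]).generate_state(
                    1, np.uint32
                )[0]
            )
            rng = np.random.default_rng(sub_seed)
            med = _null_median_matrix(pooled, A.shape[0], n_shuffles, rng)
            null_diff = med[:, 0, :] - med[:, 1, :]

            rec = {"participant_id": pid, "pair_a": la, "pair_b": lb}
            for subset in (NO_THERMAL, WITH_THERMAL, THERMAL_ONLY):
                idx = list(subset.indices)
                obs = float(np.linalg.norm(diff[idx]))
                null_d = np.linalg.norm(null_diff[:, idx], axis=1)
                key = subset.name.replace("-", "_")
                rec[f"dist_{key}"] = obs
                rec[f"null_median_{key}"] = float(np.median(null_d))
                rec[f"p_perm_{key}"] = (
                    int(np.count_nonzero(null_d >= obs)) + 1
                ) / (n_shuffles + 1)
            recs.append(rec)

    per_participant = pd.DataFrame.from_records(recs)

    rows = []
    for la, lb in PAIRS:
        sub = per_participant[
            (per_participant["pair_a"] == la) & (per_participant["pair_b"] == lb)
        ]
        if len(sub) < 2:
            logger.warning("pair %s-%s has <2 participants; skipped", la, lb)
            continue
        obs_no = sub["dist_no_thermal"].to_numpy()
        obs_with = sub["dist_with_thermal"].to_numpy()
        null_no = sub["null_median_no_thermal"].to_numpy()
        null_with = sub["null_median_with_thermal"].to_numpy()
        p_gain_i = sub["p_perm_thermal_only"].to_numpy()

        _, p_obs_null_no = wilcoxon_signed_rank(null_no, obs_no)
        _, p_obs_null_with = wilcoxon_signed_rank(null_with, obs_with)
        _, p_no_with = wilcoxon_signed_rank(obs_no, obs_with)
        # thermal-gain: per-participant permutation quantiles vs 1/2
        _, p_gain = wilcoxon_signed_rank(np.full(len(p_gain_i), 0.5), p_gain_i)
        try:
            es = effect_size(obs_no, obs_with)
        except ValueError:
            logger.warning("pair %s-%s: degenerate paired differences", la, lb)
            es = float("nan")

        rows.append(
            {
                "pair_a": la,
                "pair_b": lb,
                "n_participants": len(sub),
                "dist_no_thermal_median": float(np.median(obs_no)),
                "dist_no_thermal_mad": median_abs_deviation(obs_no),
                "dist_with_thermal_median": float(np.median(obs_with)),
                "dist_with_thermal_mad": median_abs_deviation(obs_with),
                "null_no_thermal_median": float(np.median(null_no)),
                "null_with_thermal_median": float(np.median(null_with)),
                "p_obs_vs_null_no_thermal": p_obs_null_no,
                "p_obs_vs_null_with_thermal": p_obs_null_with,
                "p_no_vs_with": p_no_with,
                "p_thermal_gain": p_gain,
                "effect_size": es,
            }
        )

    rows_df = pd.DataFrame(rows)
    m = len(rows_df)
    for col in (
        "p_obs_vs_null_no_thermal",
        "p_obs_vs_null_with_thermal",
        "p_no_vs_with",
        "p_thermal_gain",
    ):
        rows_df[col + "_bonf"] = [bonferroni(p, m) for p in rows_df[col]]
    return DiscriminabilityResult(
        rows=rows_df, per_participant=per_participant, n_shuffles=n_shuffles, seed=seed
    )
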