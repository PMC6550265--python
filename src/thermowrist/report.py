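"""Pipeline orchestration: simulate -> discriminate -> classify.

One master seed drives the whole run; stage seeds are derived by fixed
offsets (simulate: +0, discriminate: +1000, classify: +2000) so a stage
can be rerun independently yet reproducibly. All result files are
deterministic functions of (config, master seed); the manifest records a
SHA-256 digest per output so reruns can be verified bit-for-bit (the
manifest's wall-clock timestamp is informational and excluded from that
comparison).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import evaluate_general, evaluate_per_participant, summarize
from .data import HEAD_TARGETS, NO_THERMAL, WITH_THERMAL, Dataset, write_dataset
from .discriminability import PAIRS, run_discriminability
from .scaling import z_scale
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

SIMULATE_SEED_OFFSET = 0
DISCRIMINATE_SEED_OFFSET = 1000
CLASSIFY_SEED_OFFSET = 2000

TABLE1_COLUMNS = [
    "pair_a",
    "pair_b",
    "n_participants",
    "dist_no_thermal_median",
    "dist_no_thermal_mad",
    "dist_with_thermal_median",
    "dist_with_thermal_mad",
    "p_no_vs_with",
    "p_no_vs_with_bonf",
    "effect_size",
]

SUPP_COLUMNS = [
    "pair_a",
    "pair_b",
    "null_no_thermal_median",
    "null_with_thermal_median",
    "p_obs_vs_null_no_thermal",
    "p_obs_vs_null_no_thermal_bonf",
    "p_obs_vs_null_with_thermal",
    "p_obs_vs_null_with_thermal_bonf",
    "p_thermal_gain",
    "p_thermal_gain_bonf",
]


@dataclass
class RunConfig:
    """Three-stage pipeline configuration (YAML section per stage)."""

    simulate: dict = field(default_factory=dict)
    discriminate: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {"simulate", "discriminate", "classify"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**{k: raw.get(k, {}) or {} for k in ("simulate", "discriminate", "classify")})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def classification_report(
    dataset: Dataset,
    seed: int,
    subsets=(NO_THERMAL, WITH_THERMAL),
    targets=HEAD_TARGETS,
    modes=("per-participant", "general"),
    **opts,
) -> dict:
    """Per-target, per-subset evaluation dictionary."""
    report: dict = {"seed": seed, "options": dict(opts), "targets": {}}
    for target in targets:
        report["targets"][target] = {}
        for subset in subsets:
            entry: dict = {}
            if "per-participant" in modes:
                res = evaluate_per_participant(
                    dataset, target, subset, seed=seed, **opts
                )
                entry["per_participant"] = {
                    "auroc": dict(
                        zip(res["participant_id"], res["auroc"].astype(float))
                    ),
                    **{
                        k: v
                        for k, v in summarize(res).items()
                    },
                }
            if "general" in modes:
                gen = evaluate_general(dataset, target, subset, seed=seed, **opts)
                entry["general"] = {
                    "auroc": dict(
                        zip(gen["participant_id"], gen["auroc"].astype(float))
                    ),
                    **{k: v for k, v in summarize(gen).items()},
                }
            report["targets"][target][subset.name] = entry
    return _jsonable(report)


def run_all(config: RunConfig, out_dir, master_seed: int = 0) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Outputs: cohort.csv, table1.csv, supp_tables.csv, report.json,
    manifest.json. Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": master_seed,
        "stage_seeds": {
            "simulate": master_seed + SIMULATE_SEED_OFFSET,
            "discriminate": master_seed + DISCRIMINATE_SEED_OFFSET,
            "classify": master_seed + CLASSIFY_SEED_OFFSET,
        },
        "config": {
            "simulate": dict(config.simulate),
            "discriminate": dict(config.discriminate),
            "classify": dict(config.classify),
        },
        "outputs": {},
        "complete": False,
    }

    cfg = CohortConfig(**config.simulate, seed=master_seed + SIMULATE_SEED_OFFSET)
    logger.info("simulate: %d participants", cfg.n_participants)
    cohort = generate_cohort(cfg)
    cohort_path = out / "cohort.csv"
    write_dataset(cohort, cohort_path)
    manifest["outputs"]["cohort.csv"] = _digest(cohort_path)

    scaled = z_scale(cohort)
    disc_opts = dict(config.discriminate)
    logger.info("discriminate: %s shuffles", disc_opts.get("n_shuffles", 1000))
    result = run_discriminability(
        scaled, seed=master_seed + DISCRIMINATE_SEED_OFFSET, **disc_opts
    )
    table1_path = out / "table1.csv"
    supp_path = out / "supp_tables.csv"
    result.rows[TABLE1_COLUMNS].to_csv(table1_path, index=False)
    result.rows[["pair_a", "pair_b"] + SUPP_COLUMNS[2:]].to_csv(supp_path, index=False)
    manifest["outputs"]["table1.csv"] = _digest(table1_path)
    manifest["outputs"]["supp_tables.csv"] = _digest(supp_path)

    cls_opts = dict(config.classify)
    modes = tuple(cls_opts.pop("modes", ("per-participant", "general")))
    targets = tuple(cls_opts.pop("targets", HEAD_TARGETS))
    logger.info("classify: targets=%s modes=%s", targets, modes)
    report = classification_report(
        scaled,
        seed=master_seed + CLASSIFY_SEED_OFFSET,
        targets=targets,
        modes=modes,
        **cls_opts,
    )
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest["outputs"]["report.json"] = _digest(report_path)

    manifest["complete"] = True
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_summary(table1: pd.DataFrame, report: dict) -> str:
    """Human-readable markdown summary of a finished run.

    A 15-row pairwise discriminability table and a 6-row per-target AUROC
    table (median +/- MAD for both channel subsets).
    """
    have = {(a, b) for a, b in zip(table1["pair_a"], table1["pair_b"])}
    missing = [p for p in PAIRS if p not in have]
    if missing:
        raise ValueError(f"missing pairs in table: {missing}")
    lines = [
        "# Discriminability (median +/- MAD across participants)",
        "",
        "| Target pair | No thermal | With thermal | p (Bonf.) | Effect size |",
        "|---|---|---|---|---|",
    ]
    for _, r in table1.iterrows():
        lines.append(
            f"| {r.pair_a}-{r.pair_b} "
            f"| {r.dist_no_thermal_median:.2f} ± {r.dist_no_thermal_mad:.2f} "
            f"| {r.dist_with_thermal_median:.2f} ± {r.dist_with_thermal_mad:.2f} "
            f"| {r.p_no_vs_with_bonf:.2e} | {r.effect_size:.2f} |"
        )
    targets = report.get("targets", {})
    if not targets:
        raise ValueError("empty classification report")
    lines += [
        "",
        "# Classification AUROC (median +/- MAD across participants)",
        "",
        "| Target | No thermal | With thermal |",
        "|---|---|---|",
    ]
    for target, entry in targets.items():
        cells = []
        for name in (NO_THERMAL.name, WITH_THERMAL.name):
            s = entry.get(name, {}).get("per_participant")
            cells.append(
                f"{s['auroc_median']:.2f} ± {s['auroc_mad']:.2f}" if s else "-"
            )
        lines.append(f"| {target} | {cells[0]} | {cells[1]} |")
    return "\n".join(lines) + "\n"
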