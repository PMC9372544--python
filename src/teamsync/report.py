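"""End-to-end analysis runs: validated input -> tidy CSV report bundle.

Every report cell is produced by a library operation; this layer only
composes them, writes CSV files and records run metadata (seed, config
hash, package versions) for provenance.  Plots are optional and
headless-safe; CSV is the canonical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, connectivity, event_model, scoring, stroop

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Analysis switches for a report run."""

    input_path: str
    out_dir: str
    seed: int = 0
    pooling: str = "team_match"
    stroop_pooling: str = "trials"
    min_bounds: tuple = (0, 1, 2, 3, 4, 5, 6, 7)
    max_bounds: tuple = (1, 2, 3, 4, 5, 6, 7)
    d_values: tuple = (1, 2, 3, 4)
    alphas: tuple = (0.05, 0.01)
    test: str = "rank"
    log_level: str = "INFO"

    def __post_init__(self):
        for a in self.alphas:
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("min_bounds", "max_bounds", "d_values", "alphas"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_metadata(config: RunConfig, out: Path, kind: str) -> None:
    import numpy
    import pandas
    import scipy

    meta = {
        "kind": kind,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "versions": {
            "teamsync": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")


def run_soccer_analysis(config: RunConfig) -> dict[str, Path]:
    """Full soccer pipeline: counts + rates, sequence-length sweeps, and
    the scoring sweep.  Returns the paths of the written files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    possessions = event_model.read_possession_table(config.input_path)
    frame = event_model.possessions_to_frame(possessions)
    summaries = event_model.summarize_thirds(frame)

    paths: dict[str, Path] = {}
    try:
        # Fig-1-style condition totals, normalized by total playing time
        n_team_matches = frame.groupby(["match_id", "team_id"]).ngroups
        total_minutes = (
            summaries["duration_min"].iloc[0] * n_team_matches
            if not summaries.empty
            else 1.0
        )
        totals = (
            summaries.groupby("condition", sort=False)[["n_p", "n_c", "goals", "N0"]]
            .sum()
            .reset_index()
        )
        totals = event_model.rate_normalize(
            totals.assign(match_id="all", team_id="all", duration_min=total_minutes),
            total_minutes,
        ).drop(columns=["match_id", "team_id", "duration_min"])
        paths["counts"] = out / "condition_counts.csv"
        totals.to_csv(paths["counts"], index=False, lineterminator="\n")

        sweeps = []
        if config.min_bounds:
            sweeps.append(
                connectivity.sweep_sequence_lengths(
                    frame, config.min_bounds, "min", pooling=config.pooling
                )
            )
        if config.max_bounds:
            sweeps.append(
                connectivity.sweep_sequence_lengths(
                    frame, config.max_bounds, "max", pooling=config.pooling
                )
            )
        paths["sweep"] = out / "connectivity_sweep.csv"
        pd.concat(sweeps, ignore_index=True).to_csv(
            paths["sweep"], index=False, lineterminator="\n"
        )

        paths["scoring"] = out / "scoring_sweep.csv"
        scoring.scoring_sweep(summaries, config.d_values).to_csv(
            paths["scoring"], index=False, lineterminator="\n"
        )
        _write_metadata(config, out, "soccer")
    except Exception:
        for path in paths.values():  # do not leave partial bundles behind
            path.unlink(missing_ok=True)
        raise
    return paths


def run_stroop_analysis(config: RunConfig) -> dict[str, Path]:
    """Full Stroop pipeline: per-group medians with 95% CIs, pairwise
    tempo p-value matrices, and ECDF evaluation points."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = event_model.read_stroop_table(config.input_path)
    frame = event_model.stroop_to_frame(trials)

    groupings: list[tuple[str, str | None]] = []
    if (frame["gender"] == "male").any():
        groupings.append(("male", None))
    for phase in stroop.FEMALE_PHASES:
        if ((frame["gender"] == "female") & (frame["phase"] == phase)).any():
            groupings.append(("female", phase))

    summary_rows, pairwise_rows, cdf_rows = [], [], []
    for gender, phase in groupings:
        label = gender if phase is None else f"{gender}/{phase}"
        try:
            pairwise, summaries = stroop.tempo_comparison(
                frame, gender, phase, pooling=config.stroop_pooling
            )
        except Exception as exc:  # insufficient group: report and continue
            logger.warning("group %s skipped: %s", label, exc)
            continue
        pairwise_rows.append(pairwise.assign(group=label))
        for tempo, summ in summaries.items():
            summary_rows.append(
                {
                    "group": label,
                    "tempo_bpm": tempo,
                    "n_trials": summ.n_trials,
                    "median_s": summ.median,
                    "ci_low_s": summ.ci_low,
                    "ci_high_s": summ.ci_high,
                }
            )
            cdf_rows.append(
                pd.DataFrame(
                    {
                        "group": label,
                        "tempo_bpm": tempo,
                        "rt_s": summ.ecdf.x[1:],
                        "cum_prob": summ.ecdf.y[1:],
                    }
                )
            )

    paths: dict[str, Path] = {}
    paths["summaries"] = out / "group_summaries.csv"
    pd.DataFrame(summary_rows).to_csv(paths["summaries"], index=False, lineterminator="\n")
    paths["pairwise"] = out / "pairwise_tempo_tests.csv"
    if pairwise_rows:
        pd.concat(pairwise_rows, ignore_index=True).to_csv(
            paths["pairwise"], index=False, lineterminator="\n"
        )
    else:
        logger.warning("no group admitted a pairwise comparison")
        pd.DataFrame(
            columns=["tempo_a", "tempo_b", "n_a", "n_b", "p_value", "method", "group"]
        ).to_csv(paths["pairwise"], index=False, lineterminator="\n")
    paths["cdf"] = out / "cdf_points.csv"
    pd.concat(cdf_rows, ignore_index=True).to_csv(
        paths["cdf"], index=False, lineterminator="\n"
    ) if cdf_rows else pd.DataFrame(
        columns=["group", "tempo_bpm", "rt_s", "cum_prob"]
    ).to_csv(paths["cdf"], index=False, lineterminator="\n")
    _write_metadata(config, out, "stroop")
    return paths
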