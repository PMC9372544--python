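"""Seeded generators emulating the statistical structure of both experiments.

Soccer.  A match consists of three 10-minute thirds played by two teams
of five.  One third is played without stimulation (wR); during the other
two, one team hears the synchronous rhythm (Sy) while the opponent hears
the non-synchronous one (nS), and vice versa.  The wR third's position
is balanced-randomized (6/6/4 over beginning/middle/end for the 16 male
matches, 5/5/4 for the 14 female matches).  Possessions alternate
between the teams at a configurable rate; within a possession each
contact turns into a completed pass with probability
``base_pass_success`` plus the active condition's effect, and the
possession ends at the first failed contact (a geometric chain whose
single parameter maps directly onto the connectivity index: with
pass-success q, the expected passes per possession are q/(1-q), each
possession has n_passes + 1 contacts, and the connectivity C = n_p/n_c
converges to q).  At the end of a possession a goal falls with a
probability that grows with the length of the completed pass sequence —
build-up play scores, reflecting an exercise in which long-distance
shots are not allowed.

The default condition effects are chosen such that the asymptotic
relative connectivity is +4% under Sy and -8% under nS — the magnitudes
reported for the male experiment — and the resulting goal-rate gap
between Sy and nS is on the order of 30%.  These are generator inputs
with known ground truth, not empirical claims.

Stroop.  Participants are grouped by (gender, menstrual phase) and tempo
with the study's group sizes as default; each participant completes 3
blocks x 2 runs x 48 trials (24 congruent + 24 incongruent, randomized).
Reaction times follow a shifted lognormal, slowed additively on
incongruent Stroop-run trials (interference), and scaled by the group's
tempo effect during the music block only.  The true median of the
analysis selection is therefore known in closed form:
``(1 + effect) * (shift + interference + exp(mu))``.

Everything is reproducible: configurations carry a seed, and each match
or participant draws from its own spawned substream, so subsets can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, PairingError
from .event_model import (
    NS_TEMPI,
    THIRD_MINUTES,
    ConditionSchedule,
)

# ---------------------------------------------------------------------------
# soccer experiment
# ---------------------------------------------------------------------------


def _default_goal_probs() -> dict[int, float]:
    # goal chance of a possession by completed-pass count; sequences of
    # >= 4 passes use the last level
    return {0: 0.0, 1: 0.02, 2: 0.06, 3: 0.10, 4: 0.15}


@dataclass(frozen=True)
class MatchSimConfig:
    """Parameters of the possession-level match simulator.

    ``possession_rate`` is per team per minute; effects are additive
    changes of the per-contact pass-success probability under the cRAS
    conditions.  ``wR_position_counts`` fixes how often the third
    without stimulation falls at the beginning/middle/end across the
    experiment and must sum to ``n_matches``.
    """

    n_matches: int = 16
    players_per_team: int = 5
    third_minutes: float = THIRD_MINUTES
    possession_rate: float = 4.0
    base_pass_success: float = 0.65
    effect_Sy: float = 0.0
    effect_nS: float = 0.0
    goal_prob_per_pass_level: dict[int, float] = field(default_factory=_default_goal_probs)
    wR_position_counts: tuple[int, int, int] = (6, 6, 4)
    seed: int = 0

    def __post_init__(self):
        if self.n_matches < 1:
            raise ConfigError("n_matches must be >= 1")
        if sum(self.wR_position_counts) != self.n_matches:
            raise ConfigError(
                f"wR_position_counts {self.wR_position_counts} must sum to "
                f"n_matches ({self.n_matches})"
            )
        if not 0 < self.base_pass_success < 1:
            raise ConfigError("base_pass_success must lie in (0, 1)")
        for cond in ("Sy", "nS"):
            raw = self.base_pass_success + (
                self.effect_Sy if cond == "Sy" else self.effect_nS
            )
            if not 0 <= raw <= 1:
                logging.getLogger(__name__).warning(
                    "pass success under %s (%.3f) falls outside [0, 1]; clipped",
                    cond,
                    raw,
                )
        if any(not 0 <= g <= 1 for g in self.goal_prob_per_pass_level.values()):
            raise ConfigError("goal probabilities must lie in [0, 1]")
        if self.possession_rate <= 0 or self.third_minutes <= 0:
            raise ConfigError("possession_rate and third_minutes must be positive")

    def pass_success(self, condition: str) -> float:
        q = self.base_pass_success
        if condition == "Sy":
            q += self.effect_Sy
        elif condition == "nS":
            q += self.effect_nS
        return min(max(q, 0.0), 1.0)


def male16(seed: int = 0, **overrides) -> MatchSimConfig:
    """Preset emulating the male experiment: 16 matches, wR thirds at
    6/6/4 positions, a synchronous boost and a non-synchronous penalty
    whose asymptotic relative connectivities are +0.04 and -0.08."""
    base = overrides.pop("base_pass_success", 0.65)
    return MatchSimConfig(
        n_matches=overrides.pop("n_matches", 16),
        wR_position_counts=overrides.pop("wR_position_counts", (6, 6, 4)),
        base_pass_success=base,
        effect_Sy=overrides.pop("effect_Sy", 0.04 * base),
        effect_nS=overrides.pop("effect_nS", -0.08 * base),
        seed=seed,
        **overrides,
    )


def female14(seed: int = 0, **overrides) -> MatchSimConfig:
    """Preset emulating the female experiment: 14 matches, wR thirds at
    5/5/4 positions, no condition effects (the null)."""
    return MatchSimConfig(
        n_matches=overrides.pop("n_matches", 14),
        wR_position_counts=overrides.pop("wR_position_counts", (5, 5, 4)),
        effect_Sy=overrides.pop("effect_Sy", 0.0),
        effect_nS=overrides.pop("effect_nS", 0.0),
        seed=seed,
        **overrides,
    )


def analytic_relative_connectivity(config: MatchSimConfig, condition: str) -> float:
    """Asymptotic relative connectivity injected for a cRAS condition.

    Under the geometric possession chain the connectivity of a long
    third converges to the pass-success probability q, so the generator's
    ground-truth relative connectivity is (q_cond - q_wR) / q_wR.
    """
    q0 = config.pass_success("wR")
    return (config.pass_success(condition) - q0) / q0


def _goal_prob_lookup(mapping: dict[int, float], n_passes: np.ndarray) -> np.ndarray:
    levels = sorted(mapping)
    top = levels[-1]
    probs = np.empty(n_passes.shape, dtype=float)
    clipped = np.minimum(n_passes, top)
    table = np.zeros(top + 1)
    last = 0.0
    for lvl in range(top + 1):
        last = mapping.get(lvl, last)
        table[lvl] = last
    probs = table[clipped]
    return probs


def simulate_match(config: MatchSimConfig, match_id: str, rng: np.random.Generator):
    """Simulate one match.

    Returns ``(frame, schedule, tallies)`` where ``frame`` is a valid
    possession table for both teams, ``schedule`` the
    :class:`ConditionSchedule` from the first team's perspective, and
    ``tallies`` the generator's own per-third bookkeeping (one row per
    team and third with pass/contact/goal/no-pass totals) kept
    independently of the event-model aggregation for cross-checks.
    """
    # chronological conditions for team A; caller fixed the wR slot
    team_a, team_b = f"{match_id}-A", f"{match_id}-B"
    wr_slot = rng.integers(0, 3)  # overridden by simulate_experiment
    return _simulate_match_at(config, match_id, team_a, team_b, int(wr_slot), rng)


def _simulate_match_at(
    config: MatchSimConfig,
    match_id: str,
    team_a: str,
    team_b: str,
    wr_slot: int,
    rng: np.random.Generator,
):
    cras = ["Sy", "nS"] if rng.random() < 0.5 else ["nS", "Sy"]
    thirds_a = []
    k = 0
    for slot in range(3):
        if slot == wr_slot:
            thirds_a.append("wR")
        else:
            thirds_a.append(cras[k])
            k += 1
    swap = {"Sy": "nS", "nS": "Sy", "wR": "wR"}
    tempi = {f"{team_a}-p{i + 1}": bpm for i, bpm in enumerate(NS_TEMPI)}
    schedule = ConditionSchedule(match_id, tuple(thirds_a), tempi)

    frames = []
    tallies = []
    mean_possessions = config.possession_rate * config.third_minutes
    for slot, cond_a in enumerate(schedule.thirds):
        cond = {team_a: cond_a, team_b: swap[cond_a]}
        n_total = int(rng.poisson(2 * mean_possessions))
        first = team_a if rng.random() < 0.5 else team_b
        second = team_b if first == team_a else team_a
        teams = np.where(np.arange(n_total) % 2 == 0, first, second)
        q = np.where(
            teams == team_a,
            config.pass_success(cond[team_a]),
            config.pass_success(cond[team_b]),
        )
        # geometric chain: passes completed before the first failed contact
        n_passes = rng.geometric(1.0 - q) - 1 if n_total else np.zeros(0, dtype=int)
        n_contacts = n_passes + 1
        goals = rng.random(n_total) < _goal_prob_lookup(
            config.goal_prob_per_pass_level, n_passes
        )
        frames.append(
            pd.DataFrame(
                {
                    "match_id": match_id,
                    "team_id": teams,
                    "condition": np.where(teams == team_a, cond[team_a], cond[team_b]),
                    "order_index": np.arange(n_total),
                    "n_passes": n_passes,
                    "n_contacts": n_contacts,
                    "goal": goals.astype(int),
                }
            )
        )
        for team in (team_a, team_b):
            sel = teams == team
            tallies.append(
                {
                    "match_id": match_id,
                    "team_id": team,
                    "condition": cond[team],
                    "slot": slot,
                    "n_p": int(n_passes[sel].sum()),
                    "n_c": int(n_contacts[sel].sum()),
                    "goals": int(goals[sel].sum()),
                    "N0": int((n_passes[sel] == 0).sum()),
                }
            )
    frame = pd.concat(frames, ignore_index=True)
    return frame, schedule, pd.DataFrame(tallies)


@dataclass(frozen=True)
class SimulatedExperiment:
    possessions: pd.DataFrame
    schedules: list[ConditionSchedule]
    tallies: pd.DataFrame
    ground_truth: dict


def simulate_experiment(config: MatchSimConfig) -> SimulatedExperiment:
    """Simulate a full experiment of ``config.n_matches`` matches.

    The wR-position counts are honored exactly (the assignment of
    positions to matches is randomized); every match draws from its own
    spawned substream, so the output is reproducible from the seed and
    independent of how many matches are generated.
    """
    root = np.random.SeedSequence(config.seed)
    scheduler_rng = np.random.default_rng(root.spawn(1)[0])
    slots = np.repeat([0, 1, 2], config.wR_position_counts)
    scheduler_rng.shuffle(slots)
    match_streams = root.spawn(config.n_matches + 1)[1:]

    frames, schedules, tallies = [], [], []
    for i in range(config.n_matches):
        match_id = f"M{i + 1:02d}"
        rng = np.random.default_rng(match_streams[i])
        frame, schedule, tally = _simulate_match_at(
            config, match_id, f"{match_id}-A", f"{match_id}-B", int(slots[i]), rng
        )
        frames.append(frame)
        schedules.append(schedule)
        tallies.append(tally)

    possessions = pd.concat(frames, ignore_index=True)
    ground_truth = {
        "run_id": f"soccer-seed{config.seed}",
        "config": dataclasses.asdict(config),
        "pass_success": {c: config.pass_success(c) for c in ("wR", "Sy", "nS")},
        "relative_connectivity": {
            c: analytic_relative_connectivity(config, c) for c in ("Sy", "nS")
        },
    }
    return SimulatedExperiment(
        possessions, schedules, pd.concat(tallies, ignore_index=True), ground_truth
    )


# ---------------------------------------------------------------------------
# Stroop experiment
# ---------------------------------------------------------------------------

#: Participants per (gender, phase) group and tempo in the emulated study.
TABLE1_GROUP_SIZES: dict[tuple[str, Optional[str]], dict[int, int]] = {
    ("male", None): {100: 20, 140: 20, 180: 20},
    ("female", "menstrual"): {100: 10, 140: 10, 180: 10},
    ("female", "folicular"): {100: 2, 140: 2, 180: 5},
    ("female", "ovulatory"): {100: 4, 140: 6, 180: 3},
    ("female", "luteal"): {100: 8, 140: 7, 180: 8},
}


@dataclass(frozen=True)
class StroopSimConfig:
    """Parameters of the Stroop trial simulator.

    Reaction times are ``factor * (rt_shift + interference +
    lognormal(rt_log_mean, rt_log_sd))`` where the additive
    ``stroop_interference`` applies to incongruent Stroop-run trials
    only and ``factor = 1 + tempo_effects[group][tempo]`` during the
    music block (1 elsewhere).  ``tempo_effects`` maps a group key
    (gender, phase-or-None) to ``{tempo: fractional median shift}``;
    e.g. ``{("male", None): {140: -0.065}}`` speeds male 140-bpm trials
    up by 6.5%.
    """

    group_sizes: dict[tuple[str, Optional[str]], dict[int, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_GROUP_SIZES.items()}
    )
    trials_per_run: int = 48
    rt_shift: float = 0.3
    rt_log_mean: float = float(np.log(1.2))
    rt_log_sd: float = 0.35
    stroop_interference: float = 0.15
    tempo_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_run % 2:
            raise ConfigError("trials_per_run must be even (half congruent)")
        if any(n < 0 for sizes in self.group_sizes.values() for n in sizes.values()):
            raise ConfigError("group sizes must be >= 0")
        if self.rt_shift < 0 or self.rt_log_sd <= 0:
            raise ConfigError("rt model must yield positive reaction times")
        for group, effects in self.tempo_effects.items():
            for tempo, eff in effects.items():
                if eff <= -1:
                    raise ConfigError(
                        f"tempo effect {eff} for {group}@{tempo} makes rt non-positive"
                    )

    def effect(self, gender: str, phase: Optional[str], tempo: int) -> float:
        return self.tempo_effects.get((gender, phase), {}).get(tempo, 0.0)

    def true_median(self, gender: str, phase: Optional[str], tempo: int) -> float:
        """Exact median reaction time of the default analysis selection
        (music block, Stroop run, incongruent trials)."""
        base = self.rt_shift + self.stroop_interference + float(np.exp(self.rt_log_mean))
        return (1.0 + self.effect(gender, phase, tempo)) * base


def male_stroop_preset(seed: int = 0, effect_140: float = -0.065) -> StroopSimConfig:
    """Male groups only (20 per tempo) with the reported 6.5% speed-up
    at 140 bpm injected."""
    return StroopSimConfig(
        group_sizes={("male", None): dict(TABLE1_GROUP_SIZES[("male", None)])},
        tempo_effects={("male", None): {140: effect_140}},
        seed=seed,
    )


@dataclass(frozen=True)
class SimulatedStroop:
    trials: pd.DataFrame
    ground_truth: dict


def simulate_stroop(config: StroopSimConfig) -> SimulatedStroop:
    """Simulate the full Stroop trial table.

    Per participant: 3 blocks x 2 runs (neutral, stroop) x
    ``trials_per_run`` trials, half congruent, order randomized; the
    assigned tempo appears only on block-2 rows.  Ground truth stores
    the injected effects and the exact group medians of the default
    analysis selection.
    """
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root)
    half = config.trials_per_run // 2
    m = config.trials_per_run
    cols: dict[str, list] = {name: [] for name in (
        "participant_id", "gender", "phase", "tempo_bpm", "block", "run",
        "congruent", "rt_s",
    )}
    pid = 0
    for (gender, phase), sizes in sorted(
        config.group_sizes.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        for tempo in sorted(sizes):
            for _ in range(sizes[tempo]):
                pid += 1
                participant = f"P{pid:03d}"
                for block in (1, 2, 3):
                    factor = (
                        1.0 + config.effect(gender, phase, tempo) if block == 2 else 1.0
                    )
                    for run in ("neutral", "stroop"):
                        congruent = np.zeros(m, dtype=bool)
                        congruent[:half] = True
                        rng.shuffle(congruent)
                        interference = np.where(
                            (~congruent) & (run == "stroop"),
                            config.stroop_interference,
                            0.0,
                        )
                        rt = factor * (
                            config.rt_shift
                            + interference
                            + rng.lognormal(config.rt_log_mean, config.rt_log_sd, m)
                        )
                        cols["participant_id"].append(np.full(m, participant, dtype=object))
                        cols["gender"].append(np.full(m, gender, dtype=object))
                        cols["phase"].append(np.full(
                            m, phase if phase is not None else "not_applicable", dtype=object
                        ))
                        cols["tempo_bpm"].append(
                            np.full(m, float(tempo) if block == 2 else np.nan)
                        )
                        cols["block"].append(np.full(m, block, dtype=np.int64))
                        cols["run"].append(np.full(m, run, dtype=object))
                        cols["congruent"].append(congruent.astype(np.int64))
                        cols["rt_s"].append(rt)
    trials = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    trials["tempo_bpm"] = trials["tempo_bpm"].astype("Int64")
    ground_truth = {
        "run_id": f"stroop-seed{config.seed}",
        "config": {
            "trials_per_run": config.trials_per_run,
            "rt_shift": config.rt_shift,
            "rt_log_mean": config.rt_log_mean,
            "rt_log_sd": config.rt_log_sd,
            "stroop_interference": config.stroop_interference,
            "seed": config.seed,
        },
        "true_medians": {
            (gender, phase, tempo): config.true_median(gender, phase, tempo)
            for (gender, phase), sizes in config.group_sizes.items()
            for tempo in sizes
        },
        "tempo_effects": {k: dict(v) for k, v in config.tempo_effects.items()},
    }
    return SimulatedStroop(trials, ground_truth)


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------


def ground_truth_report(ground_truth: dict, estimates: dict) -> pd.DataFrame:
    """Side-by-side table of injected vs recovered quantities.

    ``estimates`` must carry the same ``run_id`` as the ground truth
    (pairing check) plus a ``values`` mapping quantity-name -> estimate;
    an optional ``errors`` mapping adds Monte-Carlo error bars.
    """
    if estimates.get("run_id") != ground_truth.get("run_id"):
        raise PairingError(
            f"estimates for run {estimates.get('run_id')!r} cannot be paired "
            f"with ground truth of run {ground_truth.get('run_id')!r}"
        )
    injected = ground_truth.get("relative_connectivity") or {
        "/".join(str(p) for p in k if p is not None): v
        for k, v in ground_truth.get("true_medians", {}).items()
    }
    rows = []
    for name, value in estimates["values"].items():
        rows.append(
            {
                "quantity": name,
                "injected": injected.get(name, np.nan),
                "recovered": value,
                "mc_error": estimates.get("errors", {}).get(name, np.nan),
            }
        )
    frame = pd.DataFrame(rows)
    frame["difference"] = frame["recovered"] - frame["injected"]
    return frame
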