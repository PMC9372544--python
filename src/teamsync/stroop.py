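"""Reaction-time analysis of the color-word matching Stroop task.

The attention-modulation analysis compares reaction-time distributions of
groups that heard the rhythm at different tempi (100, 140, 180 bpm).
The default selection keeps the incongruent trials of the Stroop run in
the music block; distributions are characterized by their empirical CDF
and by the sample median with a distribution-free 95% confidence
interval from order statistics, and groups are compared pairwise with
the two-sided Mann-Whitney-Wilcoxon rank test.  Female participants can
be stratified by menstrual-cycle phase (taken from the input table; the
study assigned phases by forward-counting).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from . import inference
from .errors import InsufficientDataError, ValidationError
from .event_model import PHASES, STROOP_TEMPI, stroop_to_frame

#: Menstrual-cycle strata analysed for female participants.
FEMALE_PHASES = ("menstrual", "folicular", "ovulatory", "luteal")


@dataclass(frozen=True)
class GroupSpec:
    gender: str
    tempo_bpm: int
    phase: Optional[str] = None

    def label(self) -> str:
        base = self.gender if self.phase is None else f"{self.gender}/{self.phase}"
        return f"{base}@{self.tempo_bpm}bpm"


@dataclass(frozen=True)
class RtDistributionSummary:
    """Median, 95% CI of the median, and ECDF of one group's reaction times."""

    group: GroupSpec
    n_trials: int
    median: float
    ci_low: float
    ci_high: float
    ecdf: ECDF


def select_trials(
    trials,
    block: int = 2,
    run: str = "stroop",
    congruent: bool = False,
) -> pd.DataFrame:
    """Subset of trials used for an analysis.

    The default keeps the incongruent trials of the Stroop run in the
    music block — the selection underlying all tempo comparisons.
    Raises :class:`InsufficientDataError` when nothing is left.
    """
    frame = stroop_to_frame(trials)
    mask = (
        (frame["block"] == block)
        & (frame["run"] == run)
        & (frame["congruent"].astype(int) == int(congruent))
    )
    out = frame[mask].reset_index(drop=True)
    if out.empty:
        raise InsufficientDataError(
            f"selection (block={block}, run={run}, congruent={congruent}) "
            "retains no trials"
        )
    return out


def ecdf(rts) -> ECDF:
    """Right-continuous empirical CDF of a reaction-time sample."""
    arr = np.asarray(rts, dtype=float).ravel()
    if arr.size == 0:
        raise InsufficientDataError("cannot build an ECDF from an empty sample")
    return ECDF(arr)


def median_ci_ranks(n: int, level: float = 0.95):
    """Order-statistic ranks (1-based, inclusive) of the distribution-free
    CI for the median.

    The interval [X(l), X(n+1-l)] with the largest l such that
    P(l <= B <= n - l) >= level for B ~ Binomial(n, 1/2); raises when no
    such l exists (n = 5 is the largest sample without a proper 95% CI).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    dist = stats.binom(n, 0.5)
    best = None
    for l in range(1, n // 2 + 1):
        cover = dist.cdf(n - l) - dist.cdf(l - 1)
        if cover >= level:
            best = l
        else:
            break
    if best is None:
        raise InsufficientDataError(
            f"n={n} is too small for a distribution-free {level:.0%} CI of the median"
        )
    return best, n + 1 - best


def median_ci(rts, level: float = 0.95, method: str = "order", n_boot: int = 2000, random_state=None):
    """Sample median with a confidence interval.

    ``method="order"`` (default) uses the distribution-free
    order-statistic interval; ``method="bootstrap"`` the seeded
    percentile bootstrap.  Returns ``(median, ci_low, ci_high)``.
    """
    arr = np.sort(np.asarray(rts, dtype=float).ravel())
    n = arr.size
    med = float(np.median(arr))
    if method == "order":
        lo, hi = median_ci_ranks(n, level)
        return med, float(arr[lo - 1]), float(arr[hi - 1])
    if method == "bootstrap":
        if n < 2:
            raise InsufficientDataError("bootstrap CI needs n >= 2")
        rng = np.random.default_rng(random_state)
        meds = np.median(rng.choice(arr, size=(n_boot, n), replace=True), axis=1)
        alpha = (1 - level) / 2
        return med, float(np.quantile(meds, alpha)), float(np.quantile(meds, 1 - alpha))
    raise ValueError(f"unknown method {method!r}")


def stratify_by_phase(trials) -> dict[str, pd.DataFrame]:
    """Partition female trials by menstrual-cycle phase.

    Returns a dict with one (possibly empty) frame per phase in
    :data:`FEMALE_PHASES`; the partition of the female rows is exhaustive
    and disjoint.  Unknown phase labels raise a validation error.
    """
    frame = stroop_to_frame(trials)
    female = frame[frame["gender"] == "female"]
    unknown = set(female["phase"]) - set(PHASES)
    if unknown:
        raise ValidationError(f"unknown phase label(s) {sorted(unknown)}")
    return {
        phase: female[female["phase"] == phase].reset_index(drop=True)
        for phase in FEMALE_PHASES
    }


def _participant_medians(frame: pd.DataFrame) -> np.ndarray:
    return frame.groupby("participant_id")["rt_s"].median().to_numpy()


def group_summary(frame: pd.DataFrame, group: GroupSpec, level: float = 0.95) -> RtDistributionSummary:
    rts = frame["rt_s"].to_numpy(dtype=float)
    med, lo, hi = median_ci(rts, level)
    return RtDistributionSummary(group, rts.size, med, lo, hi, ecdf(rts))


def tempo_comparison(
    trials,
    gender: str,
    phase: Optional[str] = None,
    pooling: str = "trials",
    selection: Optional[dict] = None,
    tempi=STROOP_TEMPI,
):
    """Pairwise tempo contrasts within a gender (or phase stratum).

    Applies the default trial selection (music block, Stroop run,
    incongruent) unless ``selection`` overrides it, splits by tempo, and
    returns ``(pairwise, summaries)``: a DataFrame with one row per
    unordered tempo pair (two-sided rank-test p-value and sample sizes)
    and a dict ``tempo -> RtDistributionSummary``.

    ``pooling="trials"`` (default) compares pooled trial-level samples,
    matching cumulative-distribution plots of all trials;
    ``pooling="participants"`` compares per-participant median reaction
    times instead.
    """
    frame = select_trials(trials, **(selection or {}))
    frame = frame[frame["gender"] == gender]
    if phase is not None:
        frame = frame[frame["phase"] == phase]
    samples: dict[int, np.ndarray] = {}
    summaries: dict[int, RtDistributionSummary] = {}
    for tempo in tempi:
        sub = frame[frame["tempo_bpm"] == tempo]
        if sub.empty:
            raise InsufficientDataError(
                f"group {gender}{'' if phase is None else '/' + phase} at "
                f"{tempo} bpm has no trials under the selection"
            )
        samples[tempo] = (
            _participant_medians(sub) if pooling == "participants" else sub["rt_s"].to_numpy()
        )
        summaries[tempo] = group_summary(sub, GroupSpec(gender, tempo, phase))
    if pooling not in ("trials", "participants"):
        raise ValueError(f"unknown pooling {pooling!r}")
    rows = []
    for a, b in combinations(tempi, 2):
        res = inference.mann_whitney(samples[a], samples[b])
        rows.append(
            {
                "tempo_a": a,
                "tempo_b": b,
                "n_a": res.n_x,
                "n_b": res.n_y,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows), summaries
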