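"""Team connectivity: the pass/contact ratio and its condition contrasts.

The connectivity of a team during one third is C = n_p / n_c, the number
of completed passes divided by the number of ball contacts — a
dimensionless index in [0, 1] that operationalizes generalized
synchronization of team play: the more tightly the players' actions are
coupled, the fewer touches each pass needs.  To remove the absolute
strength of a (randomly constituted) team, each cRAS third is expressed
relative to the same team-match's third without stimulation,

    rel = (C_cond - C_wR) / C_wR,

so a value of 0.1 connotes a 10% connectivity increase over playing
without rhythm.  The Sy and nS samples of relative values are compared
with a two-sided rank test (t-test as parametric counterpart), and the
whole analysis can be restricted to pass sequences of bounded length,
reproducing the minimal/maximal sequence-length sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import inference
from .errors import InsufficientDataError, UndefinedStatisticError
from .event_model import possessions_to_frame, summaries_to_frame, summarize_thirds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityValue:
    match_id: str
    team_id: str
    condition: str
    value: float


@dataclass(frozen=True)
class RelativeConnectivity:
    match_id: str
    team_id: str
    condition: str
    value: float


@dataclass(frozen=True)
class SequenceLengthFilter:
    """Keep possessions by pass-sequence length.

    ``mode="min"`` keeps possessions with at least ``bound`` passes,
    ``mode="max"`` those with at most ``bound`` passes, ``mode="none"``
    keeps everything.  Bounds are inclusive; the length of a possession
    is its number of completed passes (length 0 = possession without a
    pass).
    """

    mode: str = "none"
    bound: int = 0

    def __post_init__(self):
        if self.mode not in ("min", "max", "none"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.bound < 0:
            raise ValueError("bound must be >= 0")

    def mask(self, n_passes: np.ndarray) -> np.ndarray:
        if self.mode == "min":
            return n_passes >= self.bound
        if self.mode == "max":
            return n_passes <= self.bound
        return np.ones_like(np.asarray(n_passes), dtype=bool)


def filter_possessions(possessions, seq_filter: SequenceLengthFilter) -> pd.DataFrame:
    """Subset of the possessions satisfying the sequence-length filter.

    An empty result is permitted; downstream statistics raise on thirds
    left without contacts.
    """
    frame = possessions_to_frame(possessions)
    return frame[seq_filter.mask(frame["n_passes"].to_numpy())].reset_index(drop=True)


def connectivity_index(summary) -> ConnectivityValue:
    """C = n_p / n_c for one third summary (record or frame row)."""
    n_p, n_c = int(summary.n_p), int(summary.n_c)
    if n_c == 0:
        raise UndefinedStatisticError(
            f"third ({summary.match_id}, {summary.team_id}, {summary.condition}) "
            "has no recorded ball contact; connectivity undefined"
        )
    return ConnectivityValue(
        summary.match_id, summary.team_id, summary.condition, n_p / n_c
    )


def relative_connectivity(c_cond, c_wr) -> RelativeConnectivity:
    """Relative connectivity (C_cond - C_wR) / C_wR of one team-match.

    Raises :class:`UndefinedStatisticError` when the reference value is
    zero; callers drop such team-matches from the sample (logged).
    """
    if c_wr.value == 0:
        raise UndefinedStatisticError(
            f"team-match ({c_cond.match_id}, {c_cond.team_id}) has zero wR "
            "connectivity; relative value undefined"
        )
    return RelativeConnectivity(
        c_cond.match_id,
        c_cond.team_id,
        c_cond.condition,
        (c_cond.value - c_wr.value) / c_wr.value,
    )


def relative_change(c_cond: float, c_wr: float) -> float:
    """Scalar form of :func:`relative_connectivity`."""
    if c_wr == 0:
        raise UndefinedStatisticError("reference connectivity is zero")
    return (c_cond - c_wr) / c_wr


def relative_connectivity_table(
    possessions,
    seq_filter: Optional[SequenceLengthFilter] = None,
    pooling: str = "team_match",
) -> pd.DataFrame:
    """Relative connectivity values for every team-match and cRAS condition.

    One row per (match, team, condition in {Sy, nS}) with the value
    normalized to the same team-match's wR third — the most granular unit
    consistent with the design (``pooling="team_match"``, default).  With
    ``pooling="match_mean"`` the two teams of a match are averaged first.
    Team-matches whose (filtered) wR third has no contacts or no passes
    are dropped with a logged warning rather than imputed.
    """
    frame = possessions_to_frame(possessions)
    if seq_filter is not None:
        frame = filter_possessions(frame, seq_filter)
    summaries = summarize_thirds(frame)
    if summaries.empty:
        return pd.DataFrame(columns=["match_id", "team_id", "condition", "value"])
    pivot_p = summaries.pivot_table(
        index=["match_id", "team_id"], columns="condition", values="n_p", aggfunc="sum"
    )
    pivot_c = summaries.pivot_table(
        index=["match_id", "team_id"], columns="condition", values="n_c", aggfunc="sum"
    )
    rows = []
    for key in pivot_p.index:
        match_id, team_id = key
        nc = pivot_c.loc[key]
        np_ = pivot_p.loc[key]
        if "wR" not in nc or pd.isna(nc["wR"]) or nc["wR"] == 0 or np_["wR"] == 0:
            logger.warning(
                "team-match (%s, %s): wR third missing, empty or pass-free "
                "after filtering; dropped from relative-connectivity sample",
                match_id,
                team_id,
            )
            continue
        c_wr = np_["wR"] / nc["wR"]
        for cond in ("Sy", "nS"):
            if cond not in nc or pd.isna(nc[cond]) or nc[cond] == 0:
                logger.warning(
                    "team-match (%s, %s): %s third empty after filtering; dropped",
                    match_id,
                    team_id,
                    cond,
                )
                continue
            c_cond = np_[cond] / nc[cond]
            rows.append(
                {
                    "match_id": match_id,
                    "team_id": team_id,
                    "condition": cond,
                    "value": (c_cond - c_wr) / c_wr,
                }
            )
    table = pd.DataFrame(rows, columns=["match_id", "team_id", "condition", "value"])
    if pooling == "match_mean":
        table = (
            table.groupby(["match_id", "condition"], sort=False)["value"]
            .mean()
            .reset_index()
            .assign(team_id="pooled")
        )[["match_id", "team_id", "condition", "value"]]
    elif pooling != "team_match":
        raise ValueError(f"unknown pooling {pooling!r}")
    return table


@dataclass(frozen=True)
class ContrastResult:
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str


def condition_contrast(values_sy, values_ns, test: str = "rank", **kwargs) -> ContrastResult:
    """Compare the Sy and nS samples of relative connectivity values.

    ``test="rank"`` uses the two-sided Mann-Whitney-Wilcoxon test (exact
    when the assignment count allows), ``test="t"`` the two-sample
    Student t-test.  Returns the p-value together with both sample
    medians.
    """
    a = np.asarray(values_sy, dtype=float).ravel()
    b = np.asarray(values_ns, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"condition contrast needs >= 2 values per sample (got {a.size}, {b.size})"
        )
    if test == "rank":
        res = inference.mann_whitney(a, b, **kwargs)
    elif test == "t":
        res = inference.two_sample_t(a, b, **kwargs)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ContrastResult(
        res.p_value, float(np.median(a)), float(np.median(b)), a.size, b.size, res.method
    )


def sweep_sequence_lengths(
    possessions,
    bounds,
    mode: str,
    pooling: str = "team_match",
    tests=("rank", "t"),
) -> pd.DataFrame:
    """Condition contrast as a function of the sequence-length bound.

    One row per bound with sample sizes, medians and one p-value column
    per requested test (``p_rank``, ``p_t``).  Bounds where a sample
    collapses (undefined statistics, too few values) yield missing cells
    with a logged reason instead of raising.
    """
    bounds = list(bounds)
    if not bounds:
        raise ValueError("bounds must be a nonempty list")
    frame = possessions_to_frame(possessions)
    rows = []
    for bound in bounds:
        seq_filter = SequenceLengthFilter(mode=mode, bound=bound) if mode != "none" else SequenceLengthFilter()
        table = relative_connectivity_table(frame, seq_filter, pooling=pooling)
        sy = table.loc[table["condition"] == "Sy", "value"].to_numpy()
        ns = table.loc[table["condition"] == "nS", "value"].to_numpy()
        row = {
            "bound": bound,
            "mode": mode,
            "n_Sy": sy.size,
            "n_nS": ns.size,
            "median_Sy": float(np.median(sy)) if sy.size else np.nan,
            "median_nS": float(np.median(ns)) if ns.size else np.nan,
        }
        for test in tests:
            col = f"p_{'rank' if test == 'rank' else 't'}"
            try:
                row[col] = condition_contrast(sy, ns, test=test).p_value
            except (InsufficientDataError, UndefinedStatisticError) as exc:
                logger.warning("bound %s (%s): %s", bound, mode, exc)
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
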