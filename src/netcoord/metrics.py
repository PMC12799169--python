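"""Group-level convergence measures and individual decision classification.

All metrics operate on tidy transcripts (one row per agent per trial, the
``TRANSCRIPT_COLUMNS`` schema) whether simulated or imported, and all
equality between responses goes through the shared canonicalization.

Conventions declared here so downstream analyses can rescale: entropy is
Shannon entropy in base 2 (bits); the normalized variant divides by
log2(N), the maximum for N participants, so it lies in [0, 1] and is 0
iff the whole group gives one response.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .agents import canonicalize
from .simulate import Transcript

STRATEGY_LABELS = ("new", "repeat_self", "repeat_partner", "earlier_context")

TranscriptLike = Union[Transcript, pd.DataFrame]


def _records(transcript: TranscriptLike) -> pd.DataFrame:
    df = transcript.records if isinstance(transcript, Transcript) else transcript
    return df


def _trial_responses(df: pd.DataFrame, trial: int) -> list[str]:
    rows = df[df["trial"] == trial]
    if rows.empty:
        raise KeyError(f"trial {trial} not present in transcript")
    return [canonicalize(r) for r in rows["response"]]


def dominant_proportion(transcript: TranscriptLike, trial: int) -> float:
    """Share of the group giving the trial's modal (dominant) response.

    Ties over the mode do not matter: tied modes share the same count. Lies
    in [1/N, 1]; 1 means full behavioral consensus on that trial.
    """
    responses = _trial_responses(_records(transcript), trial)
    counts = pd.Series(responses).value_counts()
    return float(counts.iloc[0]) / len(responses)


def modal_response(transcript: TranscriptLike, trial: int) -> str:
    """The dominant canonicalized response; ties break lexicographically."""
    responses = _trial_responses(_records(transcript), trial)
    counts = pd.Series(responses).value_counts()
    top = counts[counts == counts.iloc[0]].index
    return sorted(top)[0]


def response_entropy(
    transcript: TranscriptLike, trial: int, normalized: bool = False
) -> float:
    """Shannon entropy (bits) of the trial's response distribution.

    ``normalized=True`` divides by log2(N): 0 iff all N responses are
    identical, 1 iff all are distinct.
    """
    responses = _trial_responses(_records(transcript), trial)
    counts = pd.Series(responses).value_counts().to_numpy(dtype=float)
    h = float(stats.entropy(counts, base=2))
    if normalized:
        n = len(responses)
        h = h / np.log2(n) if n > 1 else 0.0
    return h


def _history(df: pd.DataFrame, agent: int, trial: int) -> pd.DataFrame:
    rows = df[(df["agent"] == agent) & (df["trial"] < trial)]
    if len(rows) != trial - 1:
        raise ValueError(
            f"transcript is missing history rows for agent {agent} before "
            f"trial {trial}"
        )
    return rows.sort_values("trial")


def classify_decision(transcript: TranscriptLike, agent: int, trial: int) -> str:
    """Label one agent-trial with its decision strategy.

    Trial 1 is always ``new``. Afterwards, with r the current canonicalized
    response: r equal to the agent's own trial t-1 response -> ``repeat_self``
    (agreement cases where it also equals the partner's t-1 response are
    coded repeat_self, since self-consistency was rewarded); else equal to
    the partner's t-1 response -> ``repeat_partner``; else seen in the
    agent's own productions or received responses at trials <= t-2 ->
    ``earlier_context``; otherwise ``new``.
    """
    if trial < 1:
        raise ValueError(f"trial must be >= 1; got {trial}")
    if trial == 1:
        return "new"
    df = _records(transcript)
    current_rows = df[(df["agent"] == agent) & (df["trial"] == trial)]
    if current_rows.empty:
        raise ValueError(f"no record for agent {agent} at trial {trial}")
    r = canonicalize(current_rows["response"].iloc[0])
    history = _history(df, agent, trial)
    last = history[history["trial"] == trial - 1]
    if r == canonicalize(last["response"].iloc[0]):
        return "repeat_self"
    if r == canonicalize(last["partner_response"].iloc[0]):
        return "repeat_partner"
    earlier = history[history["trial"] <= trial - 2]
    seen = {canonicalize(x) for x in earlier["response"]}
    seen |= {canonicalize(x) for x in earlier["partner_response"]}
    if r in seen:
        return "earlier_context"
    return "new"


def strategy_time_series(transcript: TranscriptLike) -> pd.DataFrame:
    """Per-trial proportions of the four decision strategies.

    Returns a frame indexed by trial with one column per label; rows sum
    to 1 (every agent-trial gets exactly one label). A single pass keeps
    running per-agent histories, so classification matches
    :func:`classify_decision` row for row.
    """
    df = _records(transcript).sort_values(["trial", "agent"])
    trials = sorted(df["trial"].unique())
    own_last: dict[int, str] = {}
    partner_last: dict[int, str] = {}
    earlier: dict[int, set[str]] = {}
    counts = {t: dict.fromkeys(STRATEGY_LABELS, 0) for t in trials}
    n_per_trial: dict[int, int] = {}

    for trial in trials:
        rows = df[df["trial"] == trial]
        n_per_trial[trial] = len(rows)
        labels: dict[int, str] = {}
        for row in rows.itertuples(index=False):
            agent = row.agent
            r = canonicalize(row.response)
            if trial == trials[0]:
                label = "new"
            elif r == own_last[agent]:
                label = "repeat_self"
            elif r == partner_last[agent]:
                label = "repeat_partner"
            elif r in earlier.get(agent, set()):
                label = "earlier_context"
            else:
                label = "new"
            labels[agent] = label
            counts[trial][label] += 1
        # roll histories forward after the whole trial is classified
        for row in rows.itertuples(index=False):
            agent = row.agent
            earlier.setdefault(agent, set())
            if agent in own_last:
                earlier[agent].add(own_last[agent])
                earlier[agent].add(partner_last[agent])
            own_last[agent] = canonicalize(row.response)
            partner_last[agent] = canonicalize(row.partner_response)

    out = pd.DataFrame(
        [
            {
                "trial": t,
                **{lab: counts[t][lab] / n_per_trial[t] for lab in STRATEGY_LABELS},
            }
            for t in trials
        ]
    ).set_index("trial")
    return out


def coordination_rate_by_response(transcript: TranscriptLike) -> pd.DataFrame:
    """Per-token coordination rate: matched records / records produced.

    Indexed by canonicalized token with columns ``rate`` and ``count``,
    sorted by descending rate then token.
    """
    df = _records(transcript).copy()
    df["token"] = [canonicalize(r) for r in df["response"]]
    grouped = df.groupby("token")["matched"].agg(["mean", "size"])
    grouped.columns = ["rate", "count"]
    return grouped.sort_values(["rate", "token"], ascending=[False, True])


def partner_context_entropy(transcript: TranscriptLike, agent: int) -> float:
    """Entropy (bits) of the multiset of responses the agent received.

    Measures how much variation an agent was exposed to in its social
    context across the whole run; invariant to trial order.
    """
    df = _records(transcript)
    received = df[df["agent"] == agent]["partner_response"]
    if received.empty:
        raise ValueError(f"agent {agent} has no records")
    counts = pd.Series([canonicalize(r) for r in received]).value_counts()
    return float(stats.entropy(counts.to_numpy(dtype=float), base=2))


def convergence_series(transcript: TranscriptLike) -> pd.DataFrame:
    """Dominant proportion and (normalized) entropy for every trial."""
    df = _records(transcript)
    trials = sorted(df["trial"].unique())
    return pd.DataFrame(
        [
            {
                "trial": t,
                "dominant_proportion": dominant_proportion(df, t),
                "entropy": response_entropy(df, t, normalized=False),
                "normalized_entropy": response_entropy(df, t, normalized=True),
            }
            for t in trials
        ]
    ).set_index("trial")


def metrics_table(transcript: TranscriptLike) -> pd.DataFrame:
    """Long-format (run_id, trial, measure, value) export for GLM fitting."""
    df = _records(transcript)
    run_id = df["run_id"].iloc[0] if len(df) else ""
    conv = convergence_series(df).reset_index()
    strat = strategy_time_series(df).reset_index()
    long = pd.concat(
        [
            conv.melt(id_vars="trial", var_name="measure", value_name="value"),
            strat.melt(id_vars="trial", var_name="measure", value_name="value"),
        ],
        ignore_index=True,
    )
    long.insert(0, "run_id", run_id)
    return long.sort_values(["measure", "trial"]).reset_index(drop=True)
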