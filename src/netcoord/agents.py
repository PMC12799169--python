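"""Generative agent models for networked coordination games.

Two models are implemented:

* the minimal **naming game** (speaker/hearer vocabulary dynamics): on a
  successful match both players' vocabularies collapse to the matched token,
  otherwise the hearer adds the speaker's token;
* the **context-aware agent (CAA)**, which on each trial samples its response
  either from a background *prior* distribution over tokens (with a
  probability that starts at alpha and decays over trials) or from a *memory
  trace* of tokens seen in its own interaction history, weighted by recency
  and past coordination success.

Prior libraries are synthetic stand-ins for empirical background-knowledge
distributions: Zipf-skewed token frequencies, with the hashtag condition
additionally concentrating probability mass on a small core of tokens tied
to narrative events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

_SIMPLEX_TOL = 1e-9

#: seed names for the face-naming condition token pool
_NAME_POOL = [
    "Emily", "Maddie", "Taylor", "Sarah", "Jessica", "Ashley", "Hannah",
    "Rachel", "Laura", "Megan", "Claire", "Anna", "Grace", "Sophie",
    "Olivia", "Chloe", "Mary", "Katie", "Lauren", "Julia",
]


def canonicalize(token: str) -> str:
    """Canonical form used for every equality test between responses.

    Strips a leading ``#``, trims surrounding whitespace and casefolds, so
    ``#Tsunami`` and ``tsunami`` coordinate.
    """
    token = token.strip()
    if token.startswith("#"):
        token = token[1:]
    return token.strip().casefold()


@dataclass(frozen=True)
class PriorLibrary:
    """Background-knowledge response distribution: tokens on a simplex.

    ``event_tags`` optionally maps tokens to narrative-event names (hashtag
    condition only); untagged tokens are interchangeable filler.
    """

    tokens: tuple[str, ...]
    probs: np.ndarray
    event_tags: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if len(self.tokens) != probs.size or probs.size == 0:
            raise ValueError("tokens and probs must be equal-length and nonempty")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("probs must be a probability simplex")
        canon = [canonicalize(t) for t in self.tokens]
        if len(set(canon)) != len(canon):
            raise ValueError("tokens must be unique after canonicalization")

    def sample(self, rng: np.random.Generator) -> str:
        return self.tokens[int(rng.choice(len(self.tokens), p=self.probs))]

    def to_dict(self) -> dict:
        return {
            "tokens": list(self.tokens),
            "probs": self.probs.tolist(),
            "event_tags": dict(self.event_tags) if self.event_tags else None,
        }


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def make_prior_library(
    content: str,
    n_tokens: int = 50,
    zipf_exponent: float = 1.5,
    n_core_events: int = 8,
    core_mass: float = 0.6,
    rng: Optional[np.random.Generator] = None,
    event_names: Optional[Sequence[str]] = None,
) -> PriorLibrary:
    """Build a synthetic prior library for one content condition.

    hashtag
        ``core_mass`` of the probability is concentrated (Zipf-weighted) on
        ``n_core_events`` event-tagged tokens named after the narrative's
        causal events; the remaining mass is Zipf-distributed over a long
        tail of filler hashtags.
    name
        A flatter Zipf distribution over interchangeable, untagged names
        (``zipf_exponent`` defaults to 1.0 via :func:`default_prior_spec`;
        pass it explicitly here).

    The shuffle of tail-token order is the only use of ``rng``; omit it for
    a deterministic library.
    """
    if content not in ("hashtag", "name"):
        raise ValueError(f"content must be 'hashtag' or 'name'; got {content!r}")
    if content == "name":
        n_core_events = 0
        core_mass = 0.0
    if not (0 <= n_core_events <= n_tokens):
        raise ValueError("need 0 <= n_core_events <= n_tokens")
    if not (0.0 <= core_mass < 1.0):
        raise ValueError(f"core_mass must lie in [0, 1); got {core_mass}")
    if n_core_events > 0 and core_mass == 0.0:
        raise ValueError("core events declared but carry no probability mass")

    if content == "hashtag":
        if event_names is None:
            from .alignment import fukushima_event_set

            event_names = [e.name for e in fukushima_event_set().events]
        if n_core_events > len(event_names):
            raise ValueError(
                f"n_core_events={n_core_events} exceeds the "
                f"{len(event_names)} available event names"
            )
        core_tokens = [f"#{name}" for name in event_names[:n_core_events]]
        tail_tokens = [f"#tag{i:03d}" for i in range(n_tokens - n_core_events)]
        tags = {tok: name for tok, name in zip(core_tokens, event_names)}
    else:
        pool = list(_NAME_POOL) + [f"Name{i:03d}" for i in range(len(_NAME_POOL), n_tokens)]
        core_tokens, tags = [], None
        tail_tokens = pool[:n_tokens]

    if rng is not None and tail_tokens:
        tail_tokens = [tail_tokens[i] for i in rng.permutation(len(tail_tokens))]

    n_tail = len(tail_tokens)
    probs = np.empty(n_tokens)
    if n_core_events:
        probs[:n_core_events] = core_mass * _zipf_weights(n_core_events, zipf_exponent)
        probs[n_core_events:] = (1 - core_mass) * _zipf_weights(n_tail, zipf_exponent)
    else:
        probs[:] = _zipf_weights(n_tail, zipf_exponent)
    return PriorLibrary(
        tokens=tuple(core_tokens + tail_tokens), probs=probs, event_tags=tags
    )


def default_prior_spec(content: str) -> dict:
    """Default :func:`make_prior_library` parameters per content condition."""
    if content == "hashtag":
        return {"content": "hashtag", "n_tokens": 50, "zipf_exponent": 1.5,
                "n_core_events": 8, "core_mass": 0.6}
    return {"content": "name", "n_tokens": 30, "zipf_exponent": 1.0,
            "n_core_events": 0, "core_mass": 0.0}


# ---------------------------------------------------------------------------
# Naming-game baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NameGameState:
    """A naming-game player's vocabulary (ordered, duplicate-free)."""

    agent_id: int
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        canon = [canonicalize(t) for t in self.vocabulary]
        if len(set(canon)) != len(canon):
            raise ValueError("vocabulary contains duplicate tokens")


def name_game_respond(
    state: NameGameState, prior: PriorLibrary, rng: np.random.Generator
) -> str:
    """Uniform draw from the vocabulary; fall back to the prior when empty."""
    if state.vocabulary:
        return state.vocabulary[int(rng.integers(len(state.vocabulary)))]
    if prior is None:
        raise ValueError("empty vocabulary and no prior to draw from")
    return prior.sample(rng)


def name_game_update(
    speaker: NameGameState, hearer: NameGameState, spoken: str
) -> tuple[NameGameState, NameGameState]:
    """Apply the naming-game vocabulary rule after the speaker says ``spoken``.

    Success (the hearer already knows the token): both vocabularies collapse
    to just that token. Failure: the hearer learns the token; the speaker is
    unchanged.
    """
    spoken_c = canonicalize(spoken)
    hearer_canon = [canonicalize(t) for t in hearer.vocabulary]
    if spoken_c in hearer_canon:
        collapsed = (spoken,)
        return (
            replace(speaker, vocabulary=collapsed),
            replace(hearer, vocabulary=collapsed),
        )
    return speaker, replace(hearer, vocabulary=hearer.vocabulary + (spoken,))


# ---------------------------------------------------------------------------
# Context-aware agent
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CAAParams:
    """Knobs of the context-aware agent.

    alpha
        Weight of background knowledge in [0, 1]: the probability of
        sampling from the prior on trial 1. May also be drawn per agent
        from a Beta distribution (see :func:`sample_alphas`).
    schedule
        How the prior-sampling probability decays across trials:
        ``linear`` (reference; reaches alpha/T by the last trial),
        ``exponential`` (alpha * schedule_rate**(t-1)) or ``constant``.
    match_bonus
        Multiplier >= 1 on the memory weight of tokens from a successful
        (coordinated) trial.
    recency_decay
        Per-trial multiplicative decay in (0, 1] applied to all existing
        memory weights before new tokens are added.
    """

    alpha: float = 0.5
    schedule: str = "linear"
    schedule_rate: float = 0.9
    match_bonus: float = 2.0
    recency_decay: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1]; got {self.alpha}")
        if self.schedule not in ("linear", "exponential", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if not (0.0 < self.schedule_rate <= 1.0):
            raise ValueError("schedule_rate must lie in (0, 1]")
        if self.match_bonus < 1.0:
            raise ValueError("match_bonus must be >= 1")
        if not (0.0 < self.recency_decay <= 1.0):
            raise ValueError("recency_decay must lie in (0, 1]")


@dataclass(frozen=True)
class CAAState:
    """A context-aware agent: alpha plus a weighted memory trace.

    ``memory_trace`` maps canonicalized tokens to strictly positive weights
    accumulated from the agent's interaction history; it is empty before
    trial 1.
    """

    agent_id: int
    alpha: float
    memory_trace: Mapping[str, float] = field(default_factory=dict)
    last_response: Optional[str] = None

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.memory_trace.values()):
            raise ValueError("memory-trace weights must be strictly positive")


def caa_sample_probability(
    alpha: float, trial: int, T: int, params: CAAParams
) -> float:
    """Probability p_t of sampling from the prior on trial ``trial`` of ``T``.

    Monotone nonincreasing in t for the linear and exponential schedules,
    so background knowledge matters progressively less as interaction
    history accumulates. Linear reference: ``alpha * (1 - (t-1)/T)``.
    """
    if not (1 <= trial <= T):
        raise ValueError(f"trial must lie in 1..{T}; got {trial}")
    if params.schedule == "linear":
        p = alpha * (1.0 - (trial - 1) / T)
    elif params.schedule == "exponential":
        p = alpha * params.schedule_rate ** (trial - 1)
    else:
        p = alpha
    assert 0.0 <= p <= 1.0
    return p


def caa_respond(
    state: CAAState,
    prior: PriorLibrary,
    trial: int,
    T: int,
    params: CAAParams,
    rng: np.random.Generator,
) -> str:
    """Sample a response: prior with probability p_t, else the memory trace.

    Memory sampling is proportional to accumulated weights; an empty trace
    (trial 1) always falls back to the prior.
    """
    if prior is None or len(prior.tokens) == 0:
        raise ValueError("CAA requires a nonempty prior library")
    p_t = caa_sample_probability(state.alpha, trial, T, params)
    if not state.memory_trace or rng.random() < p_t:
        return prior.sample(rng)
    tokens = list(state.memory_trace)
    weights = np.fromiter(
        (state.memory_trace[t] for t in tokens), dtype=float, count=len(tokens)
    )
    return tokens[int(rng.choice(len(tokens), p=weights / weights.sum()))]


def caa_update(
    state: CAAState,
    own: str,
    partner: str,
    matched: bool,
    params: CAAParams,
) -> CAAState:
    """Fold one trial's outcome into the memory trace.

    Existing weights decay by ``recency_decay``; the agent's own token and
    the partner's token are then each added with weight 1, scaled by
    ``match_bonus`` when the pair coordinated.
    """
    if matched != (canonicalize(own) == canonicalize(partner)):
        raise ValueError("matched flag inconsistent with the two responses")
    memory = {t: w * params.recency_decay for t, w in state.memory_trace.items()}
    increment = params.match_bonus if matched else 1.0
    for token in (own, partner):
        key = canonicalize(token)
        memory[key] = memory.get(key, 0.0) + increment
    return replace(state, memory_trace=memory, last_response=own)


def sample_alphas(
    n: int,
    alpha: float | tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-agent alpha values: a shared scalar, or Beta(a, b) draws."""
    if isinstance(alpha, tuple):
        a, b = alpha
        return rng.beta(a, b, size=n)
    return np.full(n, float(alpha))
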