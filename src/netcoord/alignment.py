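"""Embedding-based narrative alignment of hashtag responses.

A long-form narrative is segmented into labelled causal events (topic
sentence, causes, plant damage, first- and second-order effects). Each
hashtag is embedded, cosine similarity is computed against every event's
text embedding, and the similarity vector is normalized with a
temperature-scaled softmax into a *credence* simplex over events: how much
the hashtag aligns with each component of the narrative's causal structure.

The embedder is pluggable: any callable ``text -> 1-D vector`` that is
deterministic and returns nonzero vectors for nonempty text satisfies the
contract. The packaged :class:`HashedNGramEmbedder` is a deterministic
character-n-gram bag using a stable hash, so the whole pipeline runs with
no model downloads; a pretrained sentence encoder can be dropped in for
real analyses.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

_SIMPLEX_TOL = 1e-9

EVENT_LABELS = (
    "topic",
    "cause",
    "plant_damage",
    "first_order_effect",
    "second_order_effect",
)

Embedder = Callable[[str], np.ndarray]


@dataclass(frozen=True)
class NarrativeEvent:
    label: str
    name: str
    text: str

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if not self.name or not self.text.strip():
            raise ValueError("events need a name and nonempty text")


@dataclass(frozen=True)
class NarrativeEventSet:
    """Ordered set of labelled causal events segmented from a narrative."""

    events: tuple[NarrativeEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("event set must be nonempty")
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            raise ValueError("event names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.events)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.events)

    def to_json(self) -> list[dict]:
        return [
            {"label": e.label, "name": e.name, "text": e.text} for e in self.events
        ]

    @classmethod
    def from_json(cls, records: Iterable[Mapping[str, str]]) -> "NarrativeEventSet":
        return cls(
            events=tuple(
                NarrativeEvent(r["label"], r["name"], r["text"]) for r in records
            )
        )


def fukushima_event_set() -> NarrativeEventSet:
    """Synthetic reconstruction of the disaster narrative's 8 causal events.

    The event texts are written from a one-sentence summary of the 2011
    Fukushima narrative (earthquake -> tsunami -> reactor damage ->
    radiation leak, displacement, contamination, and the Setsuden
    energy-saving movement); they are a stand-in for the original
    experiment's narrative segmentation, not its verbatim text.
    """
    return NarrativeEventSet(
        events=(
            NarrativeEvent(
                "topic",
                "NuclearDisaster",
                "The Fukushima nuclear disaster struck Japan in 2011, a "
                "catastrophe that unfolded from a natural hazard into a "
                "lasting crisis for local communities and the environment.",
            ),
            NarrativeEvent(
                "cause",
                "Earthquake",
                "A massive magnitude nine earthquake shook the seabed off "
                "the northeastern coast of Japan.",
            ),
            NarrativeEvent(
                "cause",
                "Tsunami",
                "The earthquake triggered an enormous tsunami wave that "
                "flooded the coastline and overwhelmed the sea walls.",
            ),
            NarrativeEvent(
                "plant_damage",
                "ReactorDamage",
                "Flood water damaged the nuclear power plant, knocking out "
                "the reactor cooling systems and causing meltdowns.",
            ),
            NarrativeEvent(
                "first_order_effect",
                "RadiationLeak",
                "Radioactive material leaked from the damaged reactors into "
                "the surrounding air, soil, and ocean water.",
            ),
            NarrativeEvent(
                "first_order_effect",
                "Displacement",
                "Tens of thousands of residents were evacuated and displaced "
                "from their homes in the exclusion zone.",
            ),
            NarrativeEvent(
                "second_order_effect",
                "Contamination",
                "Long-term contamination raised fears of radiation poisoning "
                "and health effects in food, water, and fisheries.",
            ),
            NarrativeEvent(
                "second_order_effect",
                "Setsuden",
                "Electricity shortages inspired Setsuden, a nationwide "
                "energy-saving movement to conserve power.",
            ),
        )
    )


_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")


def normalize_hashtag(tag: str) -> str:
    """Prepare a hashtag for embedding: drop '#', split camelCase/underscores."""
    tag = tag.strip().lstrip("#")
    tag = tag.replace("_", " ").replace("-", " ")
    tag = _CAMEL_RE.sub(" ", tag)
    return " ".join(tag.split()).casefold()


class HashedNGramEmbedder:
    """Deterministic fixture embedder: hashed character n-gram bag.

    Words are padded with boundary markers and decomposed into character
    n-grams; each n-gram increments one of ``dim`` buckets chosen by a
    stable CRC32 hash. Vectors are L2-normalized. Deterministic across
    processes (no hash randomization), so tests and analyses reproduce
    exactly; it captures lexical overlap only, not meaning.
    """

    def __init__(self, dim: int = 256, ngram_range: tuple[int, int] = (3, 4)):
        if dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.dim = dim
        self.ngram_range = ngram_range

    def __call__(self, text: str) -> np.ndarray:
        text = normalize_hashtag(text) if text.startswith("#") else text.casefold()
        vec = np.zeros(self.dim)
        lo, hi = self.ngram_range
        for word in re.findall(r"[a-z0-9]+", text):
            padded = f"<{word}>"
            for n in range(lo, hi + 1):
                for i in range(max(len(padded) - n + 1, 0)):
                    gram = padded[i : i + n]
                    vec[zlib.crc32(gram.encode()) % self.dim] += 1.0
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError(f"cannot embed text with no word characters: {text!r}")
        return vec / norm


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|), clipped to [-1, 1] against round-off."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def softmax(scores: np.ndarray, tau: float) -> np.ndarray:
    """Temperature-scaled softmax with max-subtraction for stability."""
    if tau <= 0:
        raise ValueError(f"temperature tau must be > 0; got {tau}")
    z = np.asarray(scores, dtype=float) / tau
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass(frozen=True)
class AlignmentVector:
    """Per-event cosine similarities and their softmax credences."""

    similarities: np.ndarray
    credences: np.ndarray
    tau: float
    event_names: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.similarities, dtype=float)
        a = np.asarray(self.credences, dtype=float)
        object.__setattr__(self, "similarities", s)
        object.__setattr__(self, "credences", a)
        if s.shape != a.shape or s.ndim != 1:
            raise ValueError("similarities and credences must be matching 1-D arrays")
        if (a < 0).any() or abs(a.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("credences must form a probability simplex")
        if int(np.argmax(a)) != int(np.argmax(s)):
            raise ValueError("softmax must preserve the argmax of the similarities")


def alignment_vector(
    hashtag: str,
    events: NarrativeEventSet,
    embedder: Embedder,
    tau: float = 0.1,
) -> AlignmentVector:
    """Map one hashtag to a credence simplex over narrative events.

    ``a_i = softmax(s / tau)_i`` where ``s_i`` is the cosine similarity
    between the hashtag embedding and event i's text embedding. Low tau
    sharpens toward the best-matching event; high tau flattens toward
    uniform.
    """
    if not normalize_hashtag(hashtag):
        raise ValueError("hashtag is empty after canonicalization")
    h = embedder(hashtag)
    s = np.array([cosine_similarity(h, embedder(e.text)) for e in events.events])
    return AlignmentVector(
        similarities=s, credences=softmax(s, tau), tau=tau, event_names=events.names
    )


def mean_alignment(
    hashtags: Sequence[str],
    events: NarrativeEventSet,
    embedder: Embedder,
    tau: float = 0.1,
) -> np.ndarray:
    """Per-participant score: arithmetic mean of alignment credences.

    A mean of simplices is itself a simplex (convexity).
    """
    if len(hashtags) == 0:
        raise ValueError("participant must have produced at least one hashtag")
    vectors = [alignment_vector(h, events, embedder, tau).credences for h in hashtags]
    return np.mean(vectors, axis=0)


def aggregate_by_label(
    credences: np.ndarray, events: NarrativeEventSet
) -> dict[str, float]:
    """Sum credences within each event-label class (still a simplex)."""
    credences = np.asarray(credences, dtype=float)
    if credences.shape != (len(events.events),):
        raise ValueError("credence vector length must match the event set")
    out = {label: 0.0 for label in EVENT_LABELS if label in events.labels}
    for event, a in zip(events.events, credences):
        out[event.label] += float(a)
    return out


def compare_groups(
    scores_group1: Sequence[float], scores_group2: Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample t test between per-participant alignment scores.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p value.
    """
    g1 = np.asarray(scores_group1, dtype=float)
    g2 = np.asarray(scores_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two observations")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        raise ValueError("both groups are constant; the test is degenerate")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
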