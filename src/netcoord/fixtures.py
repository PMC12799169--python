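"""Hand-authored fixtures: small transcripts with known ground truth.

The toy transcript is a 4-agent, 6-trial run written by hand so that every
decision-strategy label (new, repeat self, repeat partner, earlier context)
occurs at least once, including the agreement tie rule (own and partner's
previous responses identical) that must be coded as repeat self. The
expected labels in ``TOY_STRATEGY_LABELS`` were assigned manually by
walking the history rules and serve as the ground truth that the
classifier is tested against.
"""

from __future__ import annotations

import pandas as pd

from .networks import NetworkSpec
from .simulate import RunConfig, TRANSCRIPT_COLUMNS, Transcript

#: (trial, pairs, {agent: response})
_TOY_TRIALS = [
    (1, [(0, 1), (2, 3)], {0: "A", 1: "B", 2: "C", 3: "C"}),
    (2, [(0, 1), (2, 3)], {0: "B", 1: "B", 2: "C", 3: "D"}),
    (3, [(0, 2), (1, 3)], {0: "A", 1: "E", 2: "D", 3: "C"}),
    (4, [(0, 1), (2, 3)], {0: "B", 1: "A", 2: "D", 3: "D"}),
    (5, [(0, 1), (2, 3)], {0: "F", 1: "B", 2: "D", 3: "D"}),
    (6, [(0, 1), (2, 3)], {0: "F", 1: "F", 2: "D", 3: "D"}),
]

#: manually derived ground-truth labels, keyed by (agent, trial)
TOY_STRATEGY_LABELS: dict[tuple[int, int], str] = {
    (0, 1): "new", (1, 1): "new", (2, 1): "new", (3, 1): "new",
    (0, 2): "repeat_partner",      # B was partner 1's trial-1 response
    (1, 2): "repeat_self",
    (2, 2): "repeat_self",         # tie rule: own and partner both said C
    (3, 2): "new",
    (0, 3): "earlier_context",     # A is agent 0's own trial-1 response
    (1, 3): "new",
    (2, 3): "repeat_partner",
    (3, 3): "repeat_partner",
    (0, 4): "earlier_context",     # B produced/received at trials <= 2
    (1, 4): "earlier_context",     # A received from agent 0 at trial 1
    (2, 4): "repeat_self",
    (3, 4): "earlier_context",     # D was agent 3's own trial-2 response
    (0, 5): "new",
    (1, 5): "repeat_partner",
    (2, 5): "repeat_self",
    (3, 5): "repeat_self",         # tie rule again (both said D at trial 4)
    (0, 6): "repeat_self",
    (1, 6): "repeat_partner",
    (2, 6): "repeat_self",
    (3, 6): "repeat_self",
}


def make_toy_transcript() -> Transcript:
    """Build the 4-agent, 6-trial ground-truth transcript."""
    rows: list[dict] = []
    points = {a: 0 for a in range(4)}
    for trial, pairs, responses in _TOY_TRIALS:
        partner = {}
        for i, j in pairs:
            partner[i], partner[j] = j, i
        for agent in range(4):
            j = partner[agent]
            matched = responses[agent] == responses[j]
            if matched:
                points[agent] += 1
            rows.append(
                {
                    "run_id": "toy",
                    "trial": trial,
                    "agent": agent,
                    "partner": j,
                    "response": responses[agent],
                    "partner_response": responses[j],
                    "matched": matched,
                    "points": points[agent],
                }
            )
    config = RunConfig(
        network=NetworkSpec(size=4, structure="homogeneous"),
        T=6,
        content="name",
        model="name_game",
        seed=0,
        run_id="toy",
    )
    return Transcript(
        config=config, records=pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)
    )
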