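"""Orchestration of full experimental runs.

A run builds the fixed interaction network, then iterates T trials. Each
trial draws a perfect matching of the group within the network's edges,
every agent produces one response from its pre-trial state (all pairs
interact simultaneously), matched pairs earn one point each, and agent
states are updated by the model rules before the next trial. The output is
a tidy transcript: one row per agent per trial.

Randomness is structured so results are a pure function of the run config:
one root seed spawns independent streams for pairing, speaker/hearer role
assignment, and each agent's own draws, so adding agents never perturbs
another agent's stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import (
    CAAParams,
    CAAState,
    NameGameState,
    PriorLibrary,
    caa_respond,
    caa_update,
    canonicalize,
    default_prior_spec,
    make_prior_library,
    name_game_respond,
    name_game_update,
    sample_alphas,
)
from .networks import (
    ConfigurationError,
    Network,
    NetworkSpec,
    build_network,
    sample_pairing,
)

TRANSCRIPT_COLUMNS = [
    "run_id",
    "trial",
    "agent",
    "partner",
    "response",
    "partner_response",
    "matched",
    "points",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experimental run."""

    network: NetworkSpec
    T: int = 40
    content: str = "hashtag"
    model: str = "name_game"
    caa_params: Optional[CAAParams] = None
    prior_spec: Optional[dict] = None
    seed: int = 0
    run_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ConfigurationError(f"T must be >= 1; got {self.T}")
        if self.content not in ("hashtag", "name"):
            raise ConfigurationError(f"unknown content {self.content!r}")
        if self.model not in ("name_game", "caa"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.model == "caa" and self.caa_params is None:
            object.__setattr__(self, "caa_params", CAAParams())
        if self.run_id is None:
            rid = (
                f"{self.model}-{self.content}-{self.network.structure}"
                f"-n{self.network.size}-s{self.seed}"
            )
            object.__setattr__(self, "run_id", rid)

    def to_dict(self) -> dict:
        d = {
            "network": {"size": self.network.size, "structure": self.network.structure},
            "T": self.T,
            "content": self.content,
            "model": self.model,
            "caa_params": asdict(self.caa_params) if self.caa_params else None,
            "prior_spec": self.prior_spec,
            "seed": self.seed,
            "run_id": self.run_id,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        net = d.pop("network")
        spec = NetworkSpec(size=int(net["size"]), structure=net["structure"])
        caa = d.pop("caa_params", None)
        params = CAAParams(**caa) if isinstance(caa, dict) else caa
        known = {"T", "content", "model", "prior_spec", "seed", "run_id"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(network=spec, caa_params=params, **d)


@dataclass
class Transcript:
    """Run metadata plus the tidy per-agent-per-trial interaction table."""

    config: RunConfig
    records: pd.DataFrame

    @property
    def run_id(self) -> str:
        return self.config.run_id

    def responses_at(self, trial: int) -> pd.Series:
        rows = self.records[self.records["trial"] == trial]
        if rows.empty:
            raise KeyError(f"trial {trial} not in transcript")
        return rows.set_index("agent")["response"]

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_csv(cls, path, config: Optional[RunConfig] = None) -> "Transcript":
        df = pd.read_csv(path, dtype={"response": str, "partner_response": str})
        df["matched"] = df["matched"].astype(bool)
        if config is None:
            n = df["agent"].nunique()
            t = int(df["trial"].max())
            spec = NetworkSpec(size=n if n % 2 == 0 else n + 1, structure="homogeneous")
            config = RunConfig(
                network=spec, T=t, run_id=str(df["run_id"].iloc[0])
            )
        return cls(config=config, records=df[TRANSCRIPT_COLUMNS].copy())


def _resolve_prior(config: RunConfig, rng: np.random.Generator) -> PriorLibrary:
    spec = dict(config.prior_spec or default_prior_spec(config.content))
    spec.setdefault("content", config.content)
    return make_prior_library(rng=rng, **spec)


def run_simulation(config: RunConfig) -> Transcript:
    """Execute one run and return its transcript (N x T records).

    Deterministic given the config seed. Background knowledge (the prior
    library) is shared by all agents in a run; each agent keeps its own
    model state.
    """
    net: Network = build_network(config.network)
    n, T = config.network.size, config.T

    root = np.random.SeedSequence(config.seed)
    prior_ss, pairing_ss, role_ss, alpha_ss, agents_ss = root.spawn(5)
    pairing_rng = np.random.default_rng(pairing_ss)
    role_rng = np.random.default_rng(role_ss)
    agent_rngs = [np.random.default_rng(s) for s in agents_ss.spawn(n)]
    prior = _resolve_prior(config, np.random.default_rng(prior_ss))

    if config.model == "name_game":
        states: list = [NameGameState(agent_id=i) for i in range(n)]
    else:
        params = config.caa_params
        alpha = params.alpha
        alphas = sample_alphas(n, alpha, np.random.default_rng(alpha_ss))
        states = [CAAState(agent_id=i, alpha=float(alphas[i])) for i in range(n)]

    points = np.zeros(n, dtype=int)
    rows: list[dict] = []
    for trial in range(1, T + 1):
        pairing = sample_pairing(net, trial, pairing_rng)
        partner = pairing.partner_of()

        # responses from pre-trial states: all pairs interact simultaneously
        responses = [
            name_game_respond(states[i], prior, agent_rngs[i])
            if config.model == "name_game"
            else caa_respond(states[i], prior, trial, T, config.caa_params, agent_rngs[i])
            for i in range(n)
        ]

        matched = {
            i: canonicalize(responses[i]) == canonicalize(responses[partner[i]])
            for i in range(n)
        }
        for i in range(n):
            if matched[i]:
                points[i] += 1

        if config.model == "name_game":
            for i, j in pairing:
                speaker, hearer = (i, j) if role_rng.random() < 0.5 else (j, i)
                states[speaker], states[hearer] = name_game_update(
                    states[speaker], states[hearer], responses[speaker]
                )
        else:
            states = [
                caa_update(
                    states[i], responses[i], responses[partner[i]],
                    matched[i], config.caa_params,
                )
                for i in range(n)
            ]

        for i in range(n):
            rows.append(
                {
                    "run_id": config.run_id,
                    "trial": trial,
                    "agent": i,
                    "partner": partner[i],
                    "response": responses[i],
                    "partner_response": responses[partner[i]],
                    "matched": matched[i],
                    "points": int(points[i]),
                }
            )

    records = pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)
    return Transcript(config=config, records=records)


def run_batch(configs: Sequence[RunConfig]) -> pd.DataFrame:
    """Run every config and concatenate the transcripts into one tidy table."""
    run_ids = [c.run_id for c in configs]
    dupes = {r for r in run_ids if run_ids.count(r) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate run_id(s): {sorted(dupes)}")
    if not configs:
        return pd.DataFrame(columns=TRANSCRIPT_COLUMNS)
    frames = [run_simulation(c).records for c in configs]
    return pd.concat(frames, ignore_index=True)


def design_grid(seed: int = 0, T: int = 40) -> list[RunConfig]:
    """The packaged 26-run experimental design grid.

    Face-name content: three runs per structure at N in {20, 50} (12 runs,
    naming-game model). Hashtag content: three runs per structure at
    N in {20, 50} plus one run per structure at N=100 (14 runs, CAA model).
    Totals: 26 runs, 1,040 agents, 1,040 x 40 = 41,600 interaction records.
    """
    rng = np.random.default_rng(seed)
    configs: list[RunConfig] = []

    def add(content: str, model: str, structure: str, size: int, rep: int) -> None:
        run_seed = int(rng.integers(2**31))
        configs.append(
            RunConfig(
                network=NetworkSpec(size=size, structure=structure),
                T=T,
                content=content,
                model=model,
                caa_params=CAAParams() if model == "caa" else None,
                seed=run_seed,
                run_id=f"{content}-{structure}-n{size}-r{rep}",
            )
        )

    for structure in ("homogeneous", "spatial"):
        for size in (20, 50):
            for rep in range(3):
                add("name", "name_game", structure, size, rep)
    for structure in ("homogeneous", "spatial"):
        for size in (20, 50):
            for rep in range(3):
                add("hashtag", "caa", structure, size, rep)
        add("hashtag", "caa", structure, 100, 0)
    assert len(configs) == 26
    assert sum(c.network.size for c in configs) == 1040
    return configs
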