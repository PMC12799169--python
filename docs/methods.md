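# Methods

This note documents the modeling choices behind `netcoord`: what each
component assumes, which parameters matter, what the synthetic generators
do and do not emulate, and where the design was genuinely open.

## Networks and pairing

Both experimental structures are fixed simple graphs over an even number N
of agents. The homogeneous structure is the complete graph; the spatial
structure is the circulant ring lattice C_N(1, 2), the standard reading of
"4 nearest neighbors, two per side". N must be even because every trial
pairs the entire group (a perfect matching); odd N is rejected rather than
leaving an agent unpartnered. Spatial N < 6 is rejected so the lattice is
simple.

**Matching sampler.** The per-trial pairing is drawn in two stages:
randomized greedy (random node order, each unmatched node picks a uniform
unmatched neighbor, restart on dead end), falling back after 20 failed
restarts to a maximum-cardinality matching under i.i.d. Uniform(0,1) edge
weights (networkx blossom). Greedy almost never dead-ends on the complete
graph and is cheap there; on the sparse ring lattice it strands isolated
nodes with probability approaching 1 as N grows (measured: 0/200 single
attempts succeed at N = 50), which is why the fallback exists. Under either
route every perfect matching has strictly positive probability —
sufficient for the qualitative claims — but the draw is *not* uniform over
matchings, and no distributional equivalence with any human-subject
platform's matcher is claimed.

## Agent models

**Naming game.** The baseline agent is purely social: a vocabulary updated
by the collapse-on-success / add-on-failure rule, with uniform selection
from the vocabulary when responding (the tie-break among vocabulary items
is not otherwise constrained). Trial-1 responses come from the prior
library, standing in for participants' free invention. Speaker and hearer
are assigned by fair coin within each pair on each trial.

**Context-aware agent.** The CAA reference rules here are a deliberately
simple stand-in: the original model's exact memory and update equations are
described in supplementary material not available to this implementation,
so the mechanism is built to reproduce the *documented qualitative claims*
(prior knowledge prolongs exploration; its influence decays over trials;
larger α attenuates the effect of network structure) while keeping every
knob explicit and swappable:

- `alpha` ∈ [0, 1] (default 0.5): probability of sampling from the prior on
  trial 1. May be a scalar shared by all agents or drawn per agent from a
  Beta distribution (`sample_alphas`).
- schedule (default `linear`): p_t = α(1 − (t−1)/T), reaching α/T on the
  final trial; `exponential` (α·r^(t−1), r = 0.9 default) and `constant`
  are provided for sensitivity analysis. Linear is the default because the
  modeled claim is a steady shift from background knowledge toward social
  context as trials accumulate.
- `recency_decay` (default 0.9): geometric decay of all memory weights per
  trial, so recent context dominates. 1.0 disables forgetting.
- `match_bonus` (default 2.0): reinforcement multiplier for tokens from a
  successful (coordinated) trial, implementing reward sensitivity.

After each trial the agent's own token and the partner's token are each
added to memory with weight 1 × (bonus if matched); memory sampling is
weight-proportional. CAA agents do not use naming-game vocabulary collapse
— whether the original model does is unknown, and the two models are
intentionally kept mechanistically distinct (tested as a behavioral
contrast, not equivalence).

**Canonicalization.** All response equality (matching, metrics) strips a
leading `#`, trims whitespace, and casefolds, so `#Tsunami` and `tsunami`
coordinate. Nothing suggests case should distinguish hashtags.

## Prior libraries (synthetic)

Empirical background-knowledge distributions are not redistributable here,
so `make_prior_library` builds synthetic ones:

- **hashtag**: `core_mass` = 0.6 of probability concentrated
  (Zipf-weighted, exponent 1.5) on 8 event-tagged tokens named after the
  narrative's causal events, the remainder Zipf over a 42-token filler
  tail. The 8/0.6 split encodes "most prior mass sits on the narrative's
  discrete causal events" with a heavy tail of idiosyncratic responses.
- **name**: flat-ish Zipf (exponent 1.0) over 30 interchangeable names,
  seeded with the high-coordination names observed in this literature.

One library is shared by all agents in a run (background knowledge is
assumed constant across participants). These libraries emulate skew and
event-concentration only; they do not emulate real lexical diversity,
typing variation, or response latency, so a green simulation test
establishes qualitative mechanism behavior, not quantitative fit to any
human dataset.

## Simulation semantics

All pairs interact simultaneously within a trial: every response is
computed from pre-trial states, then all updates are applied. Matched
agents gain one point each; cumulative points equal matched-trial counts
by construction (tested). One root seed spawns independent RNG streams for
the prior build, pairing, role assignment, and each agent, so transcripts
are a pure function of the run config and adding agents does not perturb
existing agents' draws.

The packaged 26-run design grid (three runs per structure at N ∈ {20, 50}
per content condition, plus one run per structure at N = 100 for hashtag)
totals 1,040 agents and 41,600 interaction records at T = 40. Grid replays
use the naming-game model for face-name content and the CAA for hashtag
content.

## Metrics

Entropy is Shannon entropy in base 2; the normalized variant divides by
log₂(N) (the N-response maximum). These constants are a declared
convention — analyses importing transcripts from elsewhere can rescale.
No count smoothing is applied.

Decision strategies: trial 1 is `new`; then `repeat_self` if the response
equals the agent's own trial-(t−1) response (including agreement ties,
where it also equals the partner's — self-consistency was the rewarded
behavior), else `repeat_partner` against the partner's trial-(t−1)
response, else `earlier_context` if the token appears among the agent's own
productions or received responses at trials ≤ t−2 (unbounded memory; no
forgetting window is applied because none is documented), else `new`.
The hand-labelled 4-agent fixture in `netcoord.fixtures` pins every branch
of this rule, including the tie.

Dominant proportion needs no mode tie-break (tied modes share a count);
when a modal token is exported, ties break lexicographically for
determinism.

## Narrative alignment

Credences are softmax(s/τ) of per-event cosine similarities, computed with
max-subtraction. τ defaults to 0.1 — small enough that credences visibly
concentrate on the best event while remaining smooth; the measure's tested
properties (simplex preservation, argmax preservation, monotonicity, τ→0
one-hot and τ→∞ uniform limits) hold for every τ > 0, so no conclusion in
this package depends on the default.

The packaged event set is a **synthetic reconstruction**: 8 events (topic;
earthquake and tsunami as causes; reactor damage; radiation leak and
displacement as first-order effects; contamination and Setsuden as
second-order effects) written from a one-sentence summary of the 2011
Fukushima narrative, with plant damage kept as its own label class since it
is analyzed separately. It is not the original experiment's narrative text.

The packaged embedder is a hashed character n-gram bag (CRC32 buckets,
n = 3–4, dim 256, L2-normalized): fully deterministic, dependency-free, and
sensitive to lexical overlap only. It makes the pipeline testable offline;
it is *not* a semantic encoder, and real analyses should plug in a sentence
embedder via the embedder contract (any deterministic `text -> vector`
callable). Group comparisons use Welch's two-sample t test
(scipy, Welch–Satterthwaite df).

## Numerical conventions

Simplex checks use 1e−9 absolute tolerance. Probability draws use numpy
Generators exclusively. Degenerate inputs fail loudly: zero vectors in
cosine similarity, τ ≤ 0, empty priors, odd N, missing transcript history
rows, both-constant groups in the Welch test.

## Known limitations

- CAA rules are a stand-in, not the original equations; only qualitative
  claims are reproduced, and no α is fitted to human data.
- The matching distribution is positive-support, not uniform.
- The fixture embedder measures lexical overlap, so alignment scores from
  it are meaningful only for token-overlap constructions (as in tests).
- Human-subject headline statistics (GLM coefficients, reported t values)
  require the experimental dataset and are out of scope; the package
  exports tidy tables a stats environment could fit instead.
- No dropout/attrition modeling: simulated groups are always complete.
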