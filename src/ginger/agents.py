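"""The four ablation agents behind one interface.

* ``IBL``    — instance-based learning over hand-crafted attributes only.
* ``GER``    — adds a generative-model representation of each option as an
               extra attribute whose similarity is the generative model's own
               metric (exponentiated symmetric KL for Gaussian posteriors,
               cosine for embeddings).
* ``GIN``    — chooses by a utility-prediction network over representations,
               trained not on environment rewards but to match the blended
               values of an internal teacher IBL model.
* ``GINGER`` — runs GIN and GER side by side and averages their per-option
               values evenly.

All four run with identical default IBL parameters and no fitting; the
ablation has zero free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np

from . import ibl
from .ibl import AgentParams, Memory, Option, SimilaritySpec, exact_match
from .nn import MLPRegressor
from .representations import (Embedding, GaussianRepresentation,
                              cosine_similarity, kl_similarity)

__all__ = [
    "UtilityNetSpec",
    "AGENT_KINDS",
    "Agent",
    "IBLAgent",
    "GERAgent",
    "GINAgent",
    "GINGERAgent",
    "make_agent",
    "train_to_match",
    "ginger_values",
    "pretrain",
    "gm_similarity",
    "representation_vector",
    "REPRESENTATION_ATTR",
]

AGENT_KINDS = ("IBL", "GER", "GIN", "GINGER")

#: Attribute name under which the generative-model representation is stored.
REPRESENTATION_ATTR = "_gm"

#: Shared instance-pool key: all decision instances live in one pool and are
#: differentiated by partial matching against the queried option.
_POOL = "decision"


@dataclass
class UtilityNetSpec:
    """Architecture and training cadence of the utility-prediction network.

    Presets used by the experiments: visual tasks use two fully connected
    layers of 64 units on the latent posterior mean; the phishing task uses
    two layers of 128 units on the email embedding (plus a 2-dim one-hot
    action code appended to the input).
    """

    input_dim: int
    hidden: tuple = (64, 64)
    epochs_per_update: int = 20
    learning_rate: float = 1e-3
    seed: int = 0
    update_every: int = 1  # trials between refits
    zero_init_output: bool = True
    batch_size: int = 32

    def __post_init__(self):
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("network widths must be positive")
        if self.update_every < 1:
            raise ValueError("update_every must be >= 1")

    def build(self) -> MLPRegressor:
        return MLPRegressor(
            [self.input_dim, *self.hidden, 1],
            seed=self.seed,
            lr=self.learning_rate,
            zero_init_output=self.zero_init_output,
            batch_size=self.batch_size,
        )


def gm_similarity(a: Any, b: Any, kl_scale: float = 1.0,
                  rescale_cosine: bool = False) -> float:
    """Dispatch Sim_GM on the representation type."""
    if isinstance(a, GaussianRepresentation) and isinstance(b, GaussianRepresentation):
        return kl_similarity(a, b, scale=kl_scale)
    if isinstance(a, Embedding) and isinstance(b, Embedding):
        c = cosine_similarity(a, b)
        return (1.0 + c) / 2.0 if rescale_cosine else c
    raise TypeError(f"cannot compare representations {type(a)} and {type(b)}")


def representation_vector(rep: Any) -> np.ndarray:
    """Flatten a representation into the utility network's input vector
    (posterior mean for Gaussians, raw values for embeddings)."""
    if isinstance(rep, GaussianRepresentation):
        return rep.mean
    if isinstance(rep, Embedding):
        return rep.values
    return np.asarray(rep, dtype=float)


def train_to_match(net: MLPRegressor, inputs: Sequence[np.ndarray],
                   targets: Sequence[float], epochs: int) -> MLPRegressor:
    """Fit the utility network to reproduce the teacher IBL's blended values.

    With ``epochs == 0`` the network is returned unchanged.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if X.shape[1] != net.input_dim:
        raise ValueError(f"input dim {X.shape[1]} != net input dim {net.input_dim}")
    if epochs > 0:
        net.fit(X, y, epochs=epochs)
    return net


def ginger_values(gin: Mapping[Any, float], ger: Mapping[Any, float]) -> dict:
    """Even average of the two sub-models' option values."""
    if set(gin) != set(ger):
        raise ValueError("option sets differ between GIN and GER values")
    return {k: 0.5 * gin[k] + 0.5 * ger[k] for k in gin}


class Agent:
    """Shared plumbing: step/observe protocol, memory, seeding."""

    kind: str = "?"

    def __init__(self, params: AgentParams | None = None,
                 prepopulation: float | None = ibl.DEFAULT_PREPOPULATION_UTILITY,
                 seed: int = 0):
        self.params = params if params is not None else AgentParams()
        self.prepopulation = prepopulation
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self._pending: Option | None = None
        self.trial_index = 0

    # -- subclass surface ---------------------------------------------------
    def values(self, options: Sequence[Option]) -> dict[Option, float]:
        raise NotImplementedError

    def _record(self, option: Option, reward: float) -> None:
        raise NotImplementedError

    # -- protocol -----------------------------------------------------------
    def step(self, options: Sequence[Option]) -> tuple[Option, dict[Option, float]]:
        vals = self.values(options)
        choice = ibl.choose(vals, self.rng)
        self._pending = choice
        return choice, vals

    def observe(self, option: Option, reward: float) -> None:
        if self._pending is None:
            raise RuntimeError("observe() called before step() on this trial")
        self._pending = None
        self.trial_index += 1
        self._record(option, reward)

    def _prepopulate(self, memory: Memory) -> None:
        if self.prepopulation is not None:
            ibl.prepopulate(memory, Option({}, id="_prior"),
                            self.prepopulation, option_key=_POOL)


def _handcrafted(option: Option) -> dict:
    return {k: v for k, v in option.attributes.items() if k != REPRESENTATION_ATTR}


class IBLAgent(Agent):
    """Baseline: exact-match similarity over hand-crafted attributes."""

    kind = "IBL"

    def __init__(self, params=None, prepopulation=ibl.DEFAULT_PREPOPULATION_UTILITY,
                 seed: int = 0):
        super().__init__(params, prepopulation, seed)
        self.memory = Memory()
        self.sims = SimilaritySpec(default=exact_match)
        self._prepopulate(self.memory)

    def values(self, options):
        return {
            opt: ibl.blended_value(_POOL, self.memory,
                                   Option(_handcrafted(opt), id=opt.id),
                                   self.params, self.sims, self.rng)
            for opt in options
        }

    def _record(self, option, reward):
        ibl.record_outcome(self.memory, Option(_handcrafted(option), id=option.id),
                           reward, option_key=_POOL)


class GERAgent(Agent):
    """IBL plus the generative representation as an additional attribute.

    The representation attribute is scored by the generative model's own
    similarity metric; all other attributes keep exact-match similarity and
    unit weight.
    """

    kind = "GER"

    def __init__(self, params=None, prepopulation=ibl.DEFAULT_PREPOPULATION_UTILITY,
                 seed: int = 0, kl_scale: float = 1.0, rescale_cosine: bool = False):
        super().__init__(params, prepopulation, seed)
        self.memory = Memory()
        self.sims = SimilaritySpec(
            functions={REPRESENTATION_ATTR: lambda a, b: gm_similarity(
                a, b, kl_scale=kl_scale, rescale_cosine=rescale_cosine)},
            default=exact_match,
        )
        self._prepopulate(self.memory)

    @staticmethod
    def _query(option: Option) -> Option:
        if REPRESENTATION_ATTR not in option.attributes:
            raise ValueError(f"option {option.id!r} carries no representation")
        return option

    def values(self, options):
        return {
            opt: ibl.blended_value(_POOL, self.memory, self._query(opt),
                                   self.params, self.sims, self.rng)
            for opt in options
        }

    def _record(self, option, reward):
        ibl.record_outcome(self.memory, self._query(option), reward,
                           option_key=_POOL)


class GINAgent(Agent):
    """Utility network over representations, trained to match an internal
    teacher IBL model's blended values.

    The teacher uses hand-crafted attributes (the baseline IBL feature set)
    and is updated with every observed outcome; the network is refit on the
    accumulated (representation, teacher value) pairs every
    ``net_spec.update_every`` trials for ``epochs_per_update`` epochs.
    """

    kind = "GIN"

    def __init__(self, net_spec: UtilityNetSpec, params=None,
                 prepopulation=ibl.DEFAULT_PREPOPULATION_UTILITY, seed: int = 0,
                 teacher_uses_representation: bool = False, kl_scale: float = 1.0,
                 rescale_cosine: bool = False,
                 featurizer: Callable[[Option], np.ndarray] | None = None):
        super().__init__(params, prepopulation, seed)
        self.net_spec = net_spec
        self.net = net_spec.build()
        self.featurizer = featurizer
        if teacher_uses_representation:
            self.teacher: Agent = GERAgent(self.params, prepopulation, seed,
                                           kl_scale=kl_scale,
                                           rescale_cosine=rescale_cosine)
        else:
            self.teacher = IBLAgent(self.params, prepopulation, seed)
        self._train_options: list[Option] = []
        self._since_refit = 0

    def _vector(self, option: Option) -> np.ndarray:
        if self.featurizer is not None:
            return np.asarray(self.featurizer(option), dtype=float)
        if REPRESENTATION_ATTR not in option.attributes:
            raise ValueError(f"option {option.id!r} carries no representation")
        return representation_vector(option.attributes[REPRESENTATION_ATTR])

    def values(self, options):
        X = np.stack([self._vector(opt) for opt in options])
        preds = np.atleast_1d(self.net.predict(X))
        return {opt: float(v) for opt, v in zip(options, preds)}

    def refit(self) -> None:
        """Refit the network against the teacher's *current* blended values."""
        if not self._train_options:
            return
        X = [self._vector(o) for o in self._train_options]
        targets = [self.teacher.values([o])[o] for o in self._train_options]
        train_to_match(self.net, X, targets, self.net_spec.epochs_per_update)

    def _record(self, option, reward):
        self.teacher._record(option, reward)
        self._train_options.append(option)
        self._since_refit += 1
        if self._since_refit >= self.net_spec.update_every:
            self._since_refit = 0
            self.refit()


class GINGERAgent(Agent):
    """Full model: even average of the GIN and GER option values."""

    kind = "GINGER"

    def __init__(self, net_spec: UtilityNetSpec, params=None,
                 prepopulation=ibl.DEFAULT_PREPOPULATION_UTILITY, seed: int = 0,
                 kl_scale: float = 1.0, rescale_cosine: bool = False,
                 featurizer: Callable[[Option], np.ndarray] | None = None):
        super().__init__(params, prepopulation, seed)
        self.gin = GINAgent(net_spec, self.params, prepopulation, seed,
                            kl_scale=kl_scale, rescale_cosine=rescale_cosine,
                            featurizer=featurizer)
        self.ger = GERAgent(self.params, prepopulation, seed,
                            kl_scale=kl_scale, rescale_cosine=rescale_cosine)

    def values(self, options):
        return ginger_values(self.gin.values(options), self.ger.values(options))

    def _record(self, option, reward):
        self.gin._record(option, reward)
        self.ger._record(option, reward)


def make_agent(kind: str, net_spec: UtilityNetSpec | None = None,
               params: AgentParams | None = None,
               prepopulation: float | None = ibl.DEFAULT_PREPOPULATION_UTILITY,
               seed: int = 0, **kw) -> Agent:
    """Construct one of the four ablation agents by name."""
    kind = kind.upper()
    if kind not in AGENT_KINDS:
        raise ValueError(f"unknown agent kind {kind!r} (choose from {AGENT_KINDS})")
    if kind == "IBL":
        return IBLAgent(params, prepopulation, seed)
    if kind == "GER":
        return GERAgent(params, prepopulation, seed, **kw)
    if net_spec is None:
        raise ValueError(f"{kind} requires a UtilityNetSpec")
    if kind == "GIN":
        return GINAgent(net_spec, params, prepopulation, seed, **kw)
    return GINGERAgent(net_spec, params, prepopulation, seed, **kw)


def pretrain(agent: Agent, experiences: Iterable[tuple[Option, float]]) -> Agent:
    """Record a batch of (option, reward) experiences before trial 1, then
    give any utility network one initial fit."""
    for option, reward in experiences:
        agent._record(option, float(reward))
    for sub in _gin_parts(agent):
        sub.refit()
    return agent


def _gin_parts(agent: Agent) -> list[GINAgent]:
    if isinstance(agent, GINAgent):
        return [agent]
    if isinstance(agent, GINGERAgent):
        return [agent.gin]
    return []
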