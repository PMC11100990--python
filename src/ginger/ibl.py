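"""Instance-based learning engine: memory, activation, retrieval, blending.

Instance-based learning (IBL) models decide by retrieving remembered decision
events ("instances") and blending their observed utilities.  Each instance i
holds the attribute values of the option that was chosen, the utility u_i
that followed, and the set of time steps T_i at which the same event
occurred.  Availability in memory is scored by the activation

    A_i(t) = ln( sum_{t' in T_i} (t - t')^(-d) )
             + mu * sum_j omega_j * (S_ij - 1)
             + sigma * xi

combining power-law recency/frequency decay (d), partial matching of the
instance's attributes to the queried option (mismatch penalty mu, attribute
weights omega_j, per-attribute similarities S_ij in [0, 1]), and transient
noise sigma*xi.  Retrieval probabilities are a soft-max over activations with
temperature tau, and the blended value of an option is the
retrieval-probability-weighted mean of the stored utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

__all__ = [
    "AgentParams",
    "Instance",
    "Memory",
    "Option",
    "SimilaritySpec",
    "exact_match",
    "activation",
    "retrieval_probabilities",
    "blended_value",
    "choose",
    "record_outcome",
    "prepopulate",
]

#: Default optimistic prepopulation utility (the tasks' maximum reward).
DEFAULT_PREPOPULATION_UTILITY = 1.0


@dataclass
class AgentParams:
    """IBL free parameters, at their conventional default values.

    ``tau`` defaults to ``sigma * sqrt(2)``.  ``noise_dist`` selects the
    distribution of the activation noise term xi: ``"logistic"`` draws
    ln((1-u)/u) with u ~ Uniform(0,1), ``"normal"`` draws a standard normal.
    """

    d: float = 0.5
    mu: float = 1.0
    omega: Mapping[str, float] | float = 1.0
    sigma: float = 0.25
    tau: float | None = None
    noise_on: bool = True
    noise_dist: str = "logistic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("decay d must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau is None:
            self.tau = self.sigma * math.sqrt(2.0)
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if isinstance(self.omega, Mapping):
            if any(w < 0 for w in self.omega.values()):
                raise ValueError("omega weights must be >= 0")
        elif self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.noise_dist not in ("logistic", "normal"):
            raise ValueError(f"unknown noise_dist {self.noise_dist!r}")

    def weight(self, attr: str) -> float:
        if isinstance(self.omega, Mapping):
            return float(self.omega.get(attr, 1.0))
        return float(self.omega)


def _noise(params: AgentParams, rng: np.random.Generator) -> float:
    if params.noise_dist == "normal":
        return float(rng.standard_normal())
    u = float(rng.uniform())
    # guard against u == 0 exactly (measure zero, but cheap)
    u = min(max(u, 1e-12), 1.0 - 1e-12)
    return math.log((1.0 - u) / u)


def _freeze(value: Any) -> Any:
    """Hashable canonical form of an attribute value (for instance identity)."""
    if isinstance(value, np.ndarray):
        return ("ndarray", value.shape, value.tobytes())
    return value


@dataclass
class Instance:
    """One remembered decision event."""

    attributes: dict[str, Any]
    utility: float
    occurrences: list[int] = field(default_factory=list)
    id: int = 0

    def key(self) -> tuple:
        attrs = tuple(sorted((k, _freeze(v)) for k, v in self.attributes.items()))
        return (attrs, self.utility)


@dataclass
class Option:
    """A choosable alternative: attribute values, optionally a representation."""

    attributes: dict[str, Any]
    id: Any = None

    def __hash__(self) -> int:  # options are used as dict keys for values
        return hash(self.id) if self.id is not None else id(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Option):
            return NotImplemented
        if self.id is not None and other.id is not None:
            return self.id == other.id
        return self is other


class SimilaritySpec:
    """Per-attribute similarity functions, each mapping two values into [0, 1].

    Self-similarity must be 1 (the range maximum) for every attribute; the
    mismatch term of the activation equation is mu * omega_j * (S_ij - 1),
    which vanishes for a perfect match.
    """

    def __init__(
        self,
        functions: Mapping[str, Callable[[Any, Any], float]] | None = None,
        default: Callable[[Any, Any], float] | None = None,
    ) -> None:
        self.functions = dict(functions or {})
        self.default = default

    def similarity(self, attr: str, a: Any, b: Any) -> float:
        fn = self.functions.get(attr, self.default)
        if fn is None:
            raise KeyError(f"missing similarity for attribute {attr!r}")
        return float(fn(a, b))


def exact_match(a: Any, b: Any) -> float:
    """Binary similarity: 1 for identical values, 0 otherwise."""
    return 1.0 if a == b else 0.0


class Memory:
    """Instance store partitioned by option key, with a decision clock.

    The clock counts decisions: it starts at 0 and advances by one each time
    an outcome is recorded.  Activations for the trial currently being
    decided are evaluated at time ``clock + 1``, so every stored occurrence
    (including prepopulated ones at time 0) lies strictly in the past.
    Re-observing an identical (attributes, utility) event appends a new
    occurrence to the existing instance instead of duplicating it.
    """

    def __init__(self) -> None:
        self.clock: int = 0
        self._by_option: dict[Any, dict[tuple, Instance]] = {}
        self._next_id = 0

    @property
    def now(self) -> int:
        """Time step of the trial currently being decided."""
        return self.clock + 1

    def option_keys(self) -> list[Any]:
        return list(self._by_option)

    def instances(self, option_key: Any) -> list[Instance]:
        return list(self._by_option.get(option_key, {}).values())

    def all_instances(self) -> list[Instance]:
        return [inst for d in self._by_option.values() for inst in d.values()]

    def _insert(self, option_key: Any, attributes: dict, utility: float, t: int) -> Instance:
        bucket = self._by_option.setdefault(option_key, {})
        probe = Instance(dict(attributes), float(utility))
        existing = bucket.get(probe.key())
        if existing is not None:
            existing.occurrences.append(t)
            return existing
        probe.occurrences = [t]
        probe.id = self._next_id
        self._next_id += 1
        bucket[probe.key()] = probe
        return probe

    def to_dict(self) -> dict:
        """JSON-serializable dump (arrays become lists)."""

        def conv(v: Any) -> Any:
            if isinstance(v, np.ndarray):
                return v.tolist()
            if hasattr(v, "to_dict"):
                return v.to_dict()
            return v

        return {
            "clock": self.clock,
            "options": {
                str(k): [
                    {
                        "attributes": {a: conv(v) for a, v in inst.attributes.items()},
                        "utility": inst.utility,
                        "occurrences": list(inst.occurrences),
                    }
                    for inst in bucket.values()
                ]
                for k, bucket in self._by_option.items()
            },
        }


def activation(
    instance: Instance,
    query: Option,
    params: AgentParams,
    clock: int,
    sims: SimilaritySpec,
    rng: np.random.Generator | None = None,
) -> float:
    """Activation of one instance against the queried option at time ``clock``.

    The mismatch sum runs over the attributes present in *both* the query and
    the instance, so instances recorded under a sparser attribute schema
    (e.g. earlier task phases) partially match later, richer queries without
    penalty for attributes they never carried.
    """
    if not instance.occurrences:
        raise ValueError("no occurrences")
    if any(t >= clock for t in instance.occurrences):
        raise ValueError("future occurrence")

    base = math.log(sum((clock - t) ** (-params.d) for t in instance.occurrences))

    mismatch = 0.0
    for attr, qval in query.attributes.items():
        if attr not in instance.attributes:
            continue
        s = sims.similarity(attr, instance.attributes[attr], qval)
        mismatch += params.weight(attr) * (s - 1.0)

    a = base + params.mu * mismatch
    if params.noise_on and params.sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise is on")
        a += params.sigma * _noise(params, rng)
    return a


def retrieval_probabilities(activations, tau: float) -> np.ndarray:
    """Soft-max over activations with temperature tau (max-shifted)."""
    a = np.asarray(activations, dtype=float)
    if a.size == 0:
        raise ValueError("empty activations")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite activation")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    z = (a - a.max()) / tau
    e = np.exp(z)
    return e / e.sum()


def blended_value(
    option_key: Any,
    memory: Memory,
    query: Option,
    params: AgentParams,
    sims: SimilaritySpec,
    rng: np.random.Generator | None = None,
) -> float:
    """Blended value of an option: retrieval-probability-weighted utility."""
    insts = memory.instances(option_key)
    if not insts:
        raise ValueError(f"cold option {option_key!r}")
    acts = [activation(i, query, params, memory.now, sims, rng) for i in insts]
    p = retrieval_probabilities(acts, params.tau)
    u = np.array([i.utility for i in insts])
    return float(p @ u)


def choose(values: Mapping[Any, float], rng: np.random.Generator) -> Any:
    """Argmax choice with uniform random tie-breaking among exact ties."""
    if not values:
        raise ValueError("empty value mapping")
    items = list(values.items())
    vals = np.array([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite option value")
    best = vals.max()
    tied = [k for (k, v) in items if v == best]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def record_outcome(memory: Memory, option: Option, utility: float, option_key: Any = None) -> Memory:
    """Advance the clock and store the experienced (option, utility) event."""
    if not math.isfinite(utility):
        raise ValueError("utility must be finite")
    memory.clock += 1
    key = option_key if option_key is not None else option.id
    memory._insert(key, option.attributes, utility, memory.clock)
    return memory


def prepopulate(memory: Memory, option: Option, utility: float = DEFAULT_PREPOPULATION_UTILITY,
                option_key: Any = None) -> Memory:
    """Insert a default instance at time 0 so an unvisited option has a value.

    Optimistic prepopulation (utility = the task's maximum reward) induces
    exploration: every option looks good until it is actually tried.
    """
    key = option_key if option_key is not None else option.id
    memory._insert(key, option.attributes, float(utility), 0)
    return memory
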