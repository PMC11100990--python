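"""Seeded simulators for the three decision-making paradigms.

* Contextual bandit: three options, each a unique shape/color/texture
  combination so that all 9 feature values appear exactly once per trial.
  One feature is the "feature of interest"; choosing the option that carries
  it pays 1 with probability 0.75, any other option pays 1 with probability
  0.25.  Episodes last 20-25 trials, then the feature of interest changes.
* Transfer of learning: three 15-trial phases of increasing stimulus
  complexity (shape only, then shape+color, then shape+color+texture; 45
  trials total).  Each phase's rewarded feature lives in the newest
  dimension, so earlier dimensions become distractors and knowledge must
  transfer.
* Phishing identification: a synthetic email corpus with six binary
  expert-coded features and embeddings; each trial offers the binary
  ham/phishing categorization of one email, rewarded 1 for a correct call
  and 0 otherwise, after a seeded 10% of the corpus is set aside for
  pretraining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .agents import REPRESENTATION_ATTR
from .ibl import Option
from .representations import (COLORS, SHAPES, TEXTURES, Email,
                              generate_synthetic_emails)

__all__ = [
    "Feature",
    "TrialRecord",
    "BanditTaskSpec",
    "BanditTask",
    "TransferTaskSpec",
    "TransferTask",
    "PhishingTaskSpec",
    "PhishingTask",
    "bandit_trial",
    "bandit_feedback",
    "bandit_episodes",
    "transfer_trial",
    "phishing_stream",
]

DIMENSIONS = {"shape": SHAPES, "color": COLORS, "texture": TEXTURES}
DIM_ORDER = ("shape", "color", "texture")


@dataclass(frozen=True)
class Feature:
    """One of the 9 feature values: a (dimension, value) pair."""

    dimension: str
    value: str

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.value not in DIMENSIONS[self.dimension]:
            raise ValueError(f"unknown value {self.value!r} for {self.dimension}")

    def contained_in(self, option: Option) -> bool:
        return option.attributes.get(self.dimension) == self.value


ALL_FEATURES = tuple(Feature(d, v) for d in DIM_ORDER for v in DIMENSIONS[d])


@dataclass
class TrialRecord:
    """One step of an episode — the unit of all evaluation."""

    run_id: int
    agent: str
    task: str
    episode: int
    trial: int              # global trial index within the run, 1-based
    trial_in_episode: int   # 1-based
    phase: int
    options: list
    chosen: Any
    correct: bool
    reward: float
    values: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        opts = ";".join(
            "|".join(f"{k}={v}" for k, v in sorted(o.attributes.items())
                     if not k.startswith("_"))
            for o in self.options)
        return {
            "run_id": self.run_id,
            "agent": self.agent,
            "task": self.task,
            "episode": self.episode,
            "trial": self.trial,
            "trial_in_episode": self.trial_in_episode,
            "phase": self.phase,
            "options": opts,
            "chosen": str(self.chosen),
            "correct": int(self.correct),
            "reward": self.reward,
            "values": ";".join(f"{k}:{v:.10g}" for k, v in
                               sorted(self.values.items(), key=lambda kv: str(kv[0]))),
        }


# --------------------------------------------------------------------------
# Contextual bandit

@dataclass
class BanditTaskSpec:
    n_options: int = 3
    p_reward_target: float = 0.75
    p_reward_other: float = 0.25
    episode_length_range: tuple = (20, 25)
    n_episodes: int = 20
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_reward_target, self.p_reward_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("reward probabilities must lie in [0, 1]")
        lo, hi = self.episode_length_range
        if not (isinstance(lo, int) and isinstance(hi, int) and lo <= hi):
            raise ValueError("episode_length_range must be ordered integers")


def bandit_trial(rng: np.random.Generator, dims: Sequence[str] = DIM_ORDER,
                 trial_tag: Any = None) -> list[Option]:
    """Generate one trial's options: within each dimension the three values
    are a random permutation over the three screen positions, so all 9
    features appear exactly once across the options."""
    perms = {d: rng.permutation(len(DIMENSIONS[d])) for d in dims}
    options = []
    for pos in range(3):
        attrs = {d: DIMENSIONS[d][perms[d][pos]] for d in dims}
        options.append(Option(attrs, id=(trial_tag, pos)))
    return options


def bandit_feedback(spec: BanditTaskSpec, option: Option, feature: Feature,
                    rng: np.random.Generator, trial_options: Sequence[Option] | None = None) -> float:
    """Bernoulli reward: p_target if the chosen option carries the feature
    of interest, else p_other."""
    if trial_options is not None and option not in trial_options:
        raise ValueError("chosen option is not part of the current trial")
    p = spec.p_reward_target if feature.contained_in(option) else spec.p_reward_other
    return float(rng.uniform() < p)


def bandit_episodes(spec: BanditTaskSpec, rng: np.random.Generator) -> list[tuple[Feature, int]]:
    """Episode schedule: (feature of interest, length) pairs with lengths
    uniform on the configured range and no immediately repeated feature."""
    lo, hi = spec.episode_length_range
    schedule = []
    prev = None
    for _ in range(spec.n_episodes):
        candidates = [f for f in ALL_FEATURES if f != prev]
        feature = candidates[int(rng.integers(len(candidates)))]
        length = int(rng.integers(lo, hi + 1))
        schedule.append((feature, length))
        prev = feature
    return schedule


class BanditTask:
    """Stateful bandit simulator walking through a seeded episode schedule."""

    name = "bandit"

    def __init__(self, spec: BanditTaskSpec | None = None, seed: int | None = None):
        self.spec = spec or BanditTaskSpec()
        self.rng = np.random.default_rng(self.spec.seed if seed is None else seed)
        self.schedule = bandit_episodes(self.spec, self.rng)
        self._trial_counter = 0

    def trial(self, dims: Sequence[str] = DIM_ORDER) -> list[Option]:
        self._trial_counter += 1
        return bandit_trial(self.rng, dims, trial_tag=self._trial_counter)

    def feedback(self, option: Option, feature: Feature,
                 trial_options: Sequence[Option] | None = None) -> float:
        return bandit_feedback(self.spec, option, feature, self.rng, trial_options)


# --------------------------------------------------------------------------
# Transfer of learning

@dataclass
class TransferTaskSpec:
    trials_per_phase: int = 15
    n_phases: int = 3
    p_reward_target: float = 0.75
    p_reward_other: float = 0.25
    seed: int = 0

    @property
    def total_trials(self) -> int:
        return self.trials_per_phase * self.n_phases


def transfer_trial(rng: np.random.Generator, phase: int,
                   trial_tag: Any = None) -> list[Option]:
    """Options restricted to the phase's active dimensions (phase 1: shape
    only; 2: +color; 3: +texture), with per-dimension feature coverage."""
    if phase not in (1, 2, 3):
        raise ValueError(f"invalid phase {phase}")
    dims = DIM_ORDER[:phase]
    return bandit_trial(rng, dims, trial_tag=trial_tag)


class TransferTask:
    """Three-phase transfer simulator: the rewarded feature of each phase is
    drawn from the newest active dimension."""

    name = "transfer"

    def __init__(self, spec: TransferTaskSpec | None = None, seed: int | None = None):
        self.spec = spec or TransferTaskSpec()
        self.rng = np.random.default_rng(self.spec.seed if seed is None else seed)
        self.phase_targets = [
            Feature(DIM_ORDER[p], DIMENSIONS[DIM_ORDER[p]][int(self.rng.integers(3))])
            for p in range(self.spec.n_phases)
        ]
        self._trial_counter = 0

    def phase_of(self, trial: int) -> int:
        """1-based phase for a 1-based global trial index."""
        return (trial - 1) // self.spec.trials_per_phase + 1

    def trial(self, phase: int) -> list[Option]:
        self._trial_counter += 1
        return transfer_trial(self.rng, phase, trial_tag=self._trial_counter)

    def feedback(self, option: Option, phase: int) -> float:
        target = self.phase_targets[phase - 1]
        p = (self.spec.p_reward_target if target.contained_in(option)
             else self.spec.p_reward_other)
        return float(self.rng.uniform() < p)


# --------------------------------------------------------------------------
# Phishing identification

ACTIONS = ("ham", "phishing")


@dataclass
class PhishingTaskSpec:
    n_emails: int = 239
    embedding_dim: int = 1536
    phishing_fraction: float = 0.5
    effect_strength: float = 0.4
    noise_sd: float = 0.1
    pretrain_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.pretrain_fraction < 1):
            raise ValueError("pretrain_fraction must lie in (0, 1)")


def phishing_stream(corpus: Sequence[Email], pretrain_fraction: float,
                    rng: np.random.Generator) -> tuple[list[Email], list[Email]]:
    """Partition the corpus into a seeded pretraining sample (fraction of the
    corpus, rounded half up) and the remaining trial stream in seeded order."""
    if not corpus:
        raise ValueError("empty corpus")
    if not (0 < pretrain_fraction < 1):
        raise ValueError("pretrain_fraction must lie in (0, 1)")
    n = len(corpus)
    n_pre = int(math.floor(n * pretrain_fraction + 0.5))
    order = rng.permutation(n)
    pre = [corpus[i] for i in order[:n_pre]]
    stream = [corpus[i] for i in order[n_pre:]]
    return pre, stream


class PhishingTask:
    """Sequential email categorization over a synthetic corpus."""

    name = "phishing"

    def __init__(self, spec: PhishingTaskSpec | None = None, seed: int | None = None,
                 corpus: Sequence[Email] | None = None):
        self.spec = spec or PhishingTaskSpec()
        s = self.spec.seed if seed is None else seed
        self.rng = np.random.default_rng(s)
        if corpus is None:
            corpus = generate_synthetic_emails(
                n=self.spec.n_emails,
                embedding_dim=self.spec.embedding_dim,
                phishing_fraction=self.spec.phishing_fraction,
                effect_strength=self.spec.effect_strength,
                noise_sd=self.spec.noise_sd,
                seed=s,
            )
        self.corpus = list(corpus)
        self.pretrain_emails, self.stream = phishing_stream(
            self.corpus, self.spec.pretrain_fraction, self.rng)

    @staticmethod
    def options_for(email: Email) -> list[Option]:
        """The two categorization options for one email.  Both carry the
        email's expert features and embedding; they differ in the ``action``
        attribute."""
        opts = []
        for action in ACTIONS:
            attrs = dict(email.features)
            attrs["action"] = action
            attrs[REPRESENTATION_ATTR] = email.embedding
            opts.append(Option(attrs, id=(email.id, action)))
        return opts

    @staticmethod
    def reward(email: Email, action: str) -> float:
        return 1.0 if action == email.label else 0.0

    def pretraining_experiences(self) -> list[tuple[Option, float]]:
        """(option, reward) pairs for the pretraining subset: the correct
        categorization with reward 1 and the incorrect one with reward 0."""
        out = []
        for email in self.pretrain_emails:
            for opt in self.options_for(email):
                out.append((opt, self.reward(email, opt.attributes["action"])))
        return out
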