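"""Experiment execution: wire agents to task simulators, log every trial,
and aggregate curves and ablation reports reproducibly.

A master seed plus run index deterministically derives every stream of
randomness (via numpy ``SeedSequence`` spawning), so re-running an identical
configuration reproduces the numeric content of every output byte for byte.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np

from .agents import (Agent, GERAgent, GINAgent, GINGERAgent, IBLAgent,
                     REPRESENTATION_ATTR, UtilityNetSpec, make_agent, pretrain)
from .ibl import AgentParams, Option
from .representations import (COLORS, SHAPES, TEXTURES, BVAESpec, BetaVAE,
                              GaussianRepresentation, StimulusSpec,
                              render_stimulus, train_bvae)
from .tasks import (BanditTask, BanditTaskSpec, PhishingTask, PhishingTaskSpec,
                    TransferTask, TransferTaskSpec, TrialRecord)

__all__ = [
    "derive_seed",
    "StimulusRepresenter",
    "all_stimulus_specs",
    "phishing_featurizer",
    "build_agent_for_task",
    "run_bandit",
    "run_transfer",
    "run_phishing",
    "run_task",
]


def derive_seed(master: int, *path: int) -> int:
    """Derive an independent child seed (< 2**31) from a master seed and an
    index path, using numpy's splittable SeedSequence scheme."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def all_stimulus_specs(size: int = 32) -> list[StimulusSpec]:
    """Every renderable stimulus across all task phases: 3 shape-only,
    9 shape+color, and 27 full-factor specs (39 total)."""
    specs = [StimulusSpec(s, size=size) for s in SHAPES]
    specs += [StimulusSpec(s, c, size=size) for s in SHAPES for c in COLORS]
    specs += [StimulusSpec(s, c, t, size=size)
              for s in SHAPES for c in COLORS for t in TEXTURES]
    return specs


class StimulusRepresenter:
    """Trains one beta-VAE over the full stimulus set and attaches cached
    latent posteriors to visual options."""

    def __init__(self, spec: BVAESpec | None = None, size: int = 32,
                 model: BetaVAE | None = None):
        self.size = size
        if model is None:
            self.spec = spec or BVAESpec()
            stimuli = all_stimulus_specs(size)
            model = train_bvae([render_stimulus(s) for s in stimuli], self.spec)
        else:
            self.spec = model.spec
        self.model = model
        self._cache: dict[StimulusSpec, GaussianRepresentation] = {}

    def representation(self, stim: StimulusSpec) -> GaussianRepresentation:
        if stim not in self._cache:
            self._cache[stim] = self.model.encode(render_stimulus(stim))
        return self._cache[stim]

    def attach(self, options: Sequence[Option]) -> list[Option]:
        """Return options with the generative representation attribute set,
        rendered from their shape/color/texture attributes."""
        out = []
        for opt in options:
            stim = StimulusSpec(
                shape=opt.attributes["shape"],
                color=opt.attributes.get("color"),
                texture=opt.attributes.get("texture"),
                size=self.size,
            )
            attrs = dict(opt.attributes)
            attrs[REPRESENTATION_ATTR] = self.representation(stim)
            out.append(Option(attrs, id=opt.id))
        return out


def phishing_featurizer(option: Option) -> np.ndarray:
    """Utility-net input for a phishing option: the email embedding with a
    2-dim one-hot code of the candidate action appended."""
    emb = option.attributes[REPRESENTATION_ATTR].values
    action = option.attributes["action"]
    onehot = np.array([1.0, 0.0]) if action == "ham" else np.array([0.0, 1.0])
    return np.concatenate([emb, onehot])


def _needs_representations(agent: Agent) -> bool:
    return not isinstance(agent, IBLAgent)


def run_bandit(agent: Agent, spec: BanditTaskSpec, run_id: int = 0,
               representer: StimulusRepresenter | None = None,
               task_seed: int | None = None) -> list[TrialRecord]:
    """Run one agent through a full bandit episode schedule."""
    task = BanditTask(spec, seed=task_seed)
    if _needs_representations(agent) and representer is None:
        raise ValueError(f"{agent.kind} agent needs a stimulus representer")
    records = []
    trial_global = 0
    for ep_idx, (feature, length) in enumerate(task.schedule, start=1):
        for t in range(1, length + 1):
            trial_global += 1
            options = task.trial()
            if representer is not None:
                options = representer.attach(options)
            choice, vals = agent.step(options)
            reward = task.feedback(choice, feature, options)
            agent.observe(choice, reward)
            records.append(TrialRecord(
                run_id=run_id, agent=agent.kind, task=task.name,
                episode=ep_idx, trial=trial_global, trial_in_episode=t,
                phase=1, options=options, chosen=choice.id,
                correct=feature.contained_in(choice), reward=reward,
                values={str(o.id): v for o, v in vals.items()},
            ))
    return records


def run_transfer(agent: Agent, spec: TransferTaskSpec, run_id: int = 0,
                 representer: StimulusRepresenter | None = None,
                 task_seed: int | None = None) -> list[TrialRecord]:
    """Run one agent through the three-phase transfer schedule (45 trials)."""
    task = TransferTask(spec, seed=task_seed)
    if _needs_representations(agent) and representer is None:
        raise ValueError(f"{agent.kind} agent needs a stimulus representer")
    records = []
    for trial in range(1, spec.total_trials + 1):
        phase = task.phase_of(trial)
        options = task.trial(phase)
        if representer is not None:
            options = representer.attach(options)
        choice, vals = agent.step(options)
        reward = task.feedback(choice, phase)
        agent.observe(choice, reward)
        target = task.phase_targets[phase - 1]
        records.append(TrialRecord(
            run_id=run_id, agent=agent.kind, task=task.name,
            episode=phase, trial=trial,
            trial_in_episode=(trial - 1) % spec.trials_per_phase + 1,
            phase=phase, options=options, chosen=choice.id,
            correct=target.contained_in(choice), reward=reward,
            values={str(o.id): v for o, v in vals.items()},
        ))
    return records


def run_phishing(agent: Agent, task: PhishingTask, run_id: int = 0,
                 do_pretrain: bool = True) -> list[TrialRecord]:
    """Run one agent through the phishing stream after seeded pretraining."""
    if do_pretrain:
        pretrain(agent, task.pretraining_experiences())
    records = []
    for i, email in enumerate(task.stream, start=1):
        options = task.options_for(email)
        choice, vals = agent.step(options)
        action = choice.attributes["action"]
        reward = task.reward(email, action)
        agent.observe(choice, reward)
        records.append(TrialRecord(
            run_id=run_id, agent=agent.kind, task=task.name,
            episode=1, trial=i, trial_in_episode=i, phase=1,
            options=options, chosen=choice.id, correct=bool(reward == 1.0),
            reward=reward,
            values={str(o.id): v for o, v in vals.items()},
        ))
    return records


def build_agent_for_task(kind: str, task_name: str, seed: int,
                         params: AgentParams | None = None,
                         net_spec: UtilityNetSpec | None = None,
                         prepopulation: float | None = 1.0,
                         embedding_dim: int = 1536,
                         latent_dim: int = 9, **kw) -> Agent:
    """Construct an agent with the task-appropriate utility-net preset:
    two 64-unit layers over the latent posterior mean for visual tasks, two
    128-unit layers over the embedding (+ action code) for phishing."""
    kind = kind.upper()
    if kind in ("GIN", "GINGER") and net_spec is None:
        if task_name == "phishing":
            net_spec = UtilityNetSpec(input_dim=embedding_dim + 2, hidden=(128, 128), seed=seed)
        else:
            net_spec = UtilityNetSpec(input_dim=latent_dim, hidden=(64, 64), seed=seed)
    if task_name == "phishing" and kind in ("GIN", "GINGER"):
        kw.setdefault("featurizer", phishing_featurizer)
    return make_agent(kind, net_spec=net_spec, params=params,
                      prepopulation=prepopulation, seed=seed, **kw)


def run_task(task_name: str, agent: Agent, run_id: int, task_seed: int,
             task_spec=None, representer: StimulusRepresenter | None = None,
             phishing_task: PhishingTask | None = None) -> list[TrialRecord]:
    """Dispatch a single run of any of the three tasks."""
    if task_name == "bandit":
        return run_bandit(agent, task_spec or BanditTaskSpec(), run_id,
                          representer, task_seed)
    if task_name == "transfer":
        return run_transfer(agent, task_spec or TransferTaskSpec(), run_id,
                            representer, task_seed)
    if task_name == "phishing":
        task = phishing_task or PhishingTask(task_spec or PhishingTaskSpec(),
                                             seed=task_seed)
        return run_phishing(agent, task, run_id)
    raise ValueError(f"unknown task {task_name!r}")
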