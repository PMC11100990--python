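"""Model-vs-behavior statistics: learning curves, mean residual sum of
squares, BIC, and transfer-of-learning metrics.

Model fit to a reference (e.g. human) learning curve is scored by the mean
residual sum of squares RSS/n with RSS = sum_i (y_i - p(x_i))^2, and by the
Bayesian information criterion BIC = n*ln(RSS/n) + k*ln(n).  All agents in
the ablation run with default parameters, so k = 0 and BIC is a monotone
transform of the mean RSS — the two rank models identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tasks import TrialRecord

__all__ = [
    "Curve",
    "mean_rss",
    "bic",
    "transfer_metrics",
    "learning_curve",
    "ablation_report",
]


@dataclass
class Curve:
    """Per-trial-index curve (probability of a correct choice, or reward),
    indexed contiguously from 1, with optional confidence band."""

    values: np.ndarray
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    n: np.ndarray | None = None
    run_id: int | str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("curve must be a non-empty 1-D sequence")

    def __len__(self):
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        m = len(self)
        return pd.DataFrame({
            "trial_index": np.arange(1, m + 1),
            "mean": self.values,
            "ci_lo": self.ci_lo if self.ci_lo is not None else self.values,
            "ci_hi": self.ci_hi if self.ci_hi is not None else self.values,
            "n": self.n if self.n is not None else np.ones(m, dtype=int),
        })


def _as_values(curve) -> np.ndarray:
    if isinstance(curve, Curve):
        return curve.values
    return np.asarray(curve, dtype=float)


def mean_rss(model, reference) -> float:
    """Mean residual sum of squares between two aligned curves."""
    y, p = _as_values(reference), _as_values(model)
    if y.shape != p.shape:
        raise ValueError(f"curve length mismatch: {p.shape} vs {y.shape}")
    return float(np.mean((y - p) ** 2))


def bic(rss: float, n: int, k_params: int = 0) -> float:
    """Bayesian information criterion n*ln(RSS/n) + k*ln(n).

    A perfect fit (RSS = 0) returns -inf with a warning.
    """
    if rss < 0 or n < 1 or k_params < 0:
        raise ValueError("rss must be >= 0, n >= 1, k_params >= 0")
    if rss == 0:
        warnings.warn("RSS is exactly 0; BIC is -infinity", RuntimeWarning)
        return -math.inf
    return n * math.log(rss / n) + k_params * math.log(n)


def transfer_metrics(rewards: Sequence[float], phase_boundaries: Sequence[int],
                     jumpstart_n: int = 3) -> list[dict]:
    """Jumpstart / episodic / asymptotic performance for each phase.

    ``phase_boundaries`` are the 0-based start indices of each phase (the
    first is usually 0).  Jumpstart is the mean of the first ``jumpstart_n``
    rewards after each boundary, asymptotic the mean of the final three,
    episodic the mean over the whole phase.
    """
    r = np.asarray(rewards, dtype=float)
    bounds = list(phase_boundaries) + [len(r)]
    out = []
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        phase = r[lo:hi]
        if len(phase) < max(jumpstart_n, 3):
            raise ValueError(f"phase {i} shorter than {max(jumpstart_n, 3)} trials")
        out.append({
            "phase": i,
            "jumpstart": float(phase[:jumpstart_n].mean()),
            "episodic": float(phase.mean()),
            "asymptotic": float(phase[-3:].mean()),
        })
    return out


def learning_curve(records: Iterable[TrialRecord], align: str = "trial_in_episode",
                   field: str = "correct", max_index: int | None = None) -> Curve:
    """Aggregate trial records into a mean curve with a 95% CI band.

    Per aligned trial index: the mean of the chosen field across all
    episodes/runs, with a normal-approximation CI (mean +/- 1.96*SE) clipped
    to [0, 1] when the field is a probability.
    """
    buckets: dict[int, list[float]] = {}
    for rec in records:
        idx = getattr(rec, align)
        if max_index is not None and idx > max_index:
            continue
        buckets.setdefault(idx, []).append(float(getattr(rec, field)))
    if not buckets:
        raise ValueError("empty record stream")
    m = max(buckets)
    means, lo, hi, ns = [], [], [], []
    for i in range(1, m + 1):
        vals = np.asarray(buckets.get(i, [np.nan]))
        mu = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        means.append(mu)
        lo.append(max(mu - 1.96 * se, 0.0) if field == "correct" else mu - 1.96 * se)
        hi.append(min(mu + 1.96 * se, 1.0) if field == "correct" else mu + 1.96 * se)
        ns.append(len(vals))
    return Curve(np.array(means), np.array(lo), np.array(hi), np.array(ns))


def ablation_report(agent_curves: Mapping[str, object], reference,
                    task: str = "", k_params: int = 0) -> pd.DataFrame:
    """One row per agent: mean RSS (and its 95% CI across runs when per-run
    curves are supplied) and BIC against the reference curve.

    ``agent_curves`` maps agent kind to either a single aligned curve or a
    list of per-run curves.  Rows are sorted by agent kind so the output is
    stable under input permutation.
    """
    y = _as_values(reference)
    rows = []
    for agent in sorted(agent_curves):
        entry = agent_curves[agent]
        if isinstance(entry, (list, tuple)):
            per_run = [mean_rss(c, y) for c in entry]
        else:
            per_run = [mean_rss(entry, y)]
        per_run = np.asarray(per_run)
        m = float(per_run.mean())
        se = float(per_run.std(ddof=1) / math.sqrt(len(per_run))) if len(per_run) > 1 else 0.0
        n = len(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            b = bic(m * n, n, k_params)
        rows.append({
            "agent": agent,
            "task": task,
            "n_runs": len(per_run),
            "mean_rss": m,
            "bic": b,
            "ci_lo": m - 1.96 * se,
            "ci_hi": m + 1.96 * se,
        })
    return pd.DataFrame(rows)
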