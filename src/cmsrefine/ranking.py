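"""Ranking-error machinery for snapshot selection.

For a set of snapshots per target, the *reference* ranking is the ascending
order of LRMSD to the reference crystal structure (rank 1 = best). A scoring
function proposes a *predicted* order (descending score). Selecting the top
``n`` predicted snapshots, the ranking error sums their capped reference
ranks over all targets:

    rank(i)  = min(i, max)
    epsilon  = sum_targets sum_{i in top-n predicted} rank(ref_rank_i)

and is normalized by the best and worst attainable values,

    epsilon_eta = (epsilon - rank_min) / (rank_max - rank_min),
    rank_min    = |TR| * n (n + 1) / 2
    rank_max    = |TR| * (max + 1) * n

so a perfect selection (reference ranks 1..n per target) gives
epsilon_eta = 0. Note rank_max uses (max + 1) while the worst capped rank is
max, so epsilon_eta can approach but never reach exactly 1; the formula is
implemented as printed.

:func:`alpha_n_sweep` maps epsilon_eta over a grid of CS_alpha weights and
selection depths ``n``, reporting the best alpha per n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import SnapshotRecord, cs_alpha

__all__ = [
    "RankingConfig",
    "RankingOutcome",
    "TargetScores",
    "SweepResult",
    "reference_ranks",
    "capped_rank",
    "ranking_error",
    "predicted_order",
    "alpha_n_sweep",
]


@dataclass
class RankingConfig:
    n_snapshots: int
    max_rank: int = 100
    targets: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.max_rank < self.n_snapshots:
            raise ValueError("max_rank must be >= n_snapshots")


@dataclass
class RankingOutcome:
    epsilon: int
    epsilon_eta: float
    per_target_errors: dict[str, int] = field(default_factory=dict)


def reference_ranks(records: Sequence[SnapshotRecord]) -> np.ndarray:
    """1-based ranks by ascending LRMSD; ties broken by (replica, time)."""
    missing = [i for i, r in enumerate(records) if r.lrmsd is None]
    if missing:
        raise ValueError(f"records without LRMSD at indices {missing}")
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].lrmsd, records[i].replica, records[i].time_ps))
    ranks = np.empty(len(records), dtype=int)
    for rank0, idx in enumerate(order):
        ranks[idx] = rank0 + 1
    return ranks


def capped_rank(rank: int, max_rank: int) -> int:
    """``min(rank, max_rank)``."""
    if rank < 1:
        raise ValueError("ranks are 1-based")
    return min(rank, max_rank)


def predicted_order(scores: Sequence[float], records: Sequence[SnapshotRecord] | None = None) -> list[int]:
    """Indices in descending-score order; ties broken by time then replica."""
    scores = np.asarray(scores, dtype=float)
    if records is not None:
        key = lambda i: (-scores[i], records[i].time_ps, records[i].replica)
    else:
        key = lambda i: (-scores[i], i)
    return sorted(range(len(scores)), key=key)


def ranking_error(
    predicted_orders: Mapping[str, Sequence[int]],
    ref_ranks: Mapping[str, Sequence[int]],
    config: RankingConfig,
) -> RankingOutcome:
    """Capped ranking error of the top-n predicted snapshots per target."""
    targets = config.targets if config.targets is not None else sorted(predicted_orders)
    n = config.n_snapshots
    per_target: dict[str, int] = {}
    for target in targets:
        order = list(predicted_orders[target])
        ranks = np.asarray(ref_ranks[target], dtype=int)
        if len(order) < n:
            raise ValueError(f"target {target!r} has {len(order)} snapshots, needs >= {n}")
        per_target[target] = int(sum(capped_rank(int(ranks[i]), config.max_rank)
                                     for i in order[:n]))
    epsilon = int(sum(per_target.values()))
    n_targets = len(targets)
    rank_min = n_targets * n * (n + 1) // 2
    rank_max = n_targets * (config.max_rank + 1) * n
    eta = (epsilon - rank_min) / (rank_max - rank_min)
    return RankingOutcome(epsilon=epsilon, epsilon_eta=eta, per_target_errors=per_target)


@dataclass
class TargetScores:
    """Per-target inputs for the alpha x n sweep."""

    zrank_eta: np.ndarray
    fes_eta: np.ndarray
    lrmsd: np.ndarray
    replica: np.ndarray | None = None
    time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.zrank_eta = np.asarray(self.zrank_eta, dtype=float)
        self.fes_eta = np.asarray(self.fes_eta, dtype=float)
        self.lrmsd = np.asarray(self.lrmsd, dtype=float)
        k = len(self.zrank_eta)
        if not (len(self.fes_eta) == len(self.lrmsd) == k):
            raise ValueError("score/lrmsd arrays must have equal lengths")
        if self.replica is None:
            self.replica = np.zeros(k, dtype=int)
        if self.time_ps is None:
            self.time_ps = np.arange(k, dtype=float)

    def records(self) -> list[SnapshotRecord]:
        return [SnapshotRecord(replica=int(r), time_ps=float(t), lrmsd=float(l))
                for r, t, l in zip(self.replica, self.time_ps, self.lrmsd)]


@dataclass
class SweepResult:
    alphas: np.ndarray
    n_values: np.ndarray
    epsilon_eta: np.ndarray  # shape (len(alphas), len(n_values))
    best_alpha_per_n: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.epsilon_eta, index=self.alphas, columns=self.n_values)
        df.index.name = "alpha"
        df.columns.name = "n"
        return df

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t")
            fh.write("# best_alpha_per_n\t" +
                     "\t".join(f"{a:g}" for a in self.best_alpha_per_n) + "\n")


def alpha_n_sweep(
    targets: Mapping[str, TargetScores],
    alphas: Sequence[float],
    n_values: Sequence[int],
    max_rank: int = 100,
) -> SweepResult:
    """epsilon_eta over every (alpha, n) pair, plus the argmin alpha per n.

    For each alpha the predicted order per target is the descending order of
    ``CS_alpha``; reference ranks come from the targets' LRMSD values. Ties
    in the argmin go to the smallest alpha.
    """
    if not targets:
        raise ValueError("need at least one target")
    alphas = np.asarray(list(alphas), dtype=float)
    n_values = np.asarray(list(n_values), dtype=int)

    ref: dict[str, np.ndarray] = {}
    recs: dict[str, list[SnapshotRecord]] = {}
    for name, ts in targets.items():
        recs[name] = ts.records()
        ref[name] = reference_ranks(recs[name])

    matrix = np.empty((len(alphas), len(n_values)))
    for ai, alpha in enumerate(alphas):
        orders = {
            name: predicted_order(cs_alpha(ts.zrank_eta, ts.fes_eta, float(alpha)), recs[name])
            for name, ts in targets.items()
        }
        for ni, n in enumerate(n_values):
            config = RankingConfig(n_snapshots=int(n), max_rank=max_rank)
            matrix[ai, ni] = ranking_error(orders, ref, config).epsilon_eta
    best = alphas[np.argmin(matrix, axis=0)]
    return SweepResult(alphas=alphas, n_values=n_values, epsilon_eta=matrix, best_alpha_per_n=best)
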