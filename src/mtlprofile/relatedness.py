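"""Inter-task relatedness: training-dynamics affinity and Cramér's V.

Two M x M relatedness measures feed the group-selection step:

* the *task-affinity* measure z(i -> j): while an all-task MTL network
  trains, for each mini-batch and each task i the shared trunk is
  snapshotted, one plain gradient step of size eta is taken on task i's
  loss alone, and every other task's lookahead loss is compared with its
  current loss: z = 1 - L_j(lookahead) / L_j(current).  The trunk is
  restored before the ordinary combined update, so probing never alters
  training.  Raw values are divided by the epoch's learning rate (the
  halving schedule otherwise drives them toward zero), averaged over
  batches within an epoch, then over epochs.  The result is directed and
  generally asymmetric.

* the *Cramér's V* association v(i, j) between the ordinal target
  columns themselves: the classical chi-square-based coefficient,
  symmetric and in [0, 1], with no bias correction.  The chi-square
  p-value is reported alongside but does not gate anything.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .networks import ArchitectureConfig, MultiTaskMLP, TrainingConfig, build_mtl_all, train
from .profiles import ProfileSpec

__all__ = [
    "RelatednessMatrix",
    "AffinityTrace",
    "TagProbe",
    "probe_batch_affinity",
    "probe_affinity",
    "cramers_v",
    "association_matrix",
]

logger = logging.getLogger(__name__)

_LOSS_FLOOR = 1e-12


@dataclass
class RelatednessMatrix:
    """M x M relatedness values; entry (i, j) measures task i onto task j."""

    values: np.ndarray
    kind: str  # "tag" | "vtag"
    item_names: tuple[str, ...]
    fold_id: int | None = None

    @property
    def M(self) -> int:
        return len(self.item_names)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.item_names, columns=self.item_names).to_csv(path)

    def plot_heatmap(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.6 * self.M, 1 + 0.5 * self.M))
        im = ax.imshow(self.values, cmap="viridis")
        ax.set_xticks(range(self.M), self.item_names, rotation=90)
        ax.set_yticks(range(self.M), self.item_names)
        ax.set_xlabel("onto task j")
        ax.set_ylabel("task i")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


@dataclass
class AffinityTrace:
    """Per-epoch mean raw z matrices (before eta scaling) and the eta used."""

    epoch_z: list[np.ndarray] = field(default_factory=list)
    eta: list[float] = field(default_factory=list)


def probe_batch_affinity(model, X: np.ndarray, y: dict[str, np.ndarray], eta: float) -> np.ndarray:
    """Raw lookahead affinities z(i -> j) for one batch (diagonal nan).

    ``model`` only needs the probe protocol: ``task_names``,
    ``task_losses``, ``shared_gradient``, ``shared_params`` and
    ``set_shared_params``.  The shared parameters are snapshotted and
    restored, so the call is side-effect-free.
    """
    names = list(model.task_names)
    M = len(names)
    z = np.full((M, M), np.nan)
    current = model.task_losses(X, y)
    snapshot = [p.copy() for p in model.shared_params()]
    try:
        for i, name_i in enumerate(names):
            grad = model.shared_gradient(X, y, name_i)
            model.set_shared_params([s - eta * g for s, g in zip(snapshot, grad)])
            lookahead = model.task_losses(X, y)
            model.set_shared_params(snapshot)
            for j, name_j in enumerate(names):
                if j == i:
                    continue
                if current[name_j] <= _LOSS_FLOOR:
                    logger.debug("zero current loss for %s; pair (%s -> %s) skipped",
                                 name_j, name_i, name_j)
                    continue
                z[i, j] = 1.0 - lookahead[name_j] / current[name_j]
    finally:
        model.set_shared_params(snapshot)
    return z


class TagProbe:
    """Accumulates per-batch affinities into per-epoch and overall means."""

    def __init__(self, task_names: tuple[str, ...]):
        self.task_names = tuple(task_names)
        M = len(self.task_names)
        self._sum = np.zeros((M, M))
        self._count = np.zeros((M, M))
        self.trace = AffinityTrace()

    def observe(self, model, X, y, lr: float) -> None:
        z = probe_batch_affinity(model, X, y, lr)
        ok = np.isfinite(z)
        self._sum[ok] += z[ok]
        self._count[ok] += 1

    def end_epoch(self, lr: float) -> None:
        with np.errstate(invalid="ignore"):
            epoch_mean = np.where(self._count > 0, self._sum / self._count, np.nan)
        self.trace.epoch_z.append(epoch_mean)
        self.trace.eta.append(lr)
        self._sum[...] = 0.0
        self._count[...] = 0.0

    def result(self, fold_id: int | None = None) -> RelatednessMatrix:
        """Mean over epochs of the eta-scaled per-epoch affinities."""
        if not self.trace.epoch_z:
            raise ValueError("probe observed no completed epochs")
        scaled = [z / eta for z, eta in zip(self.trace.epoch_z, self.trace.eta)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values = np.nanmean(np.stack(scaled), axis=0)
        return RelatednessMatrix(values=values, kind="tag",
                                 item_names=self.task_names, fold_id=fold_id)


def probe_affinity(
    X_train: np.ndarray,
    y_train: dict[str, np.ndarray],
    X_val: np.ndarray,
    y_val: dict[str, np.ndarray],
    profile: ProfileSpec,
    arch: ArchitectureConfig = ArchitectureConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    fold_id: int | None = None,
) -> tuple[RelatednessMatrix, AffinityTrace, MultiTaskMLP]:
    """Train an all-task MTL while probing lookahead affinities.

    Returns the epoch-averaged affinity matrix, the raw per-epoch trace,
    and the trained probe network.
    """
    if profile.M < 2:
        raise ValueError("affinity needs at least 2 tasks")
    model = build_mtl_all(X_train.shape[1], profile, arch, seed=seed)
    probe = TagProbe(model.task_names)
    train(model, X_train, y_train, X_val, y_val, train_cfg, probe=probe)
    return probe.result(fold_id), probe.trace, model


# ---------------------------------------------------------------------------
# Cramér's V

def cramers_v(x, y) -> tuple[float, float, float]:
    """Classical (uncorrected) Cramér's V with its chi-square test.

    Returns ``(v, chi2, p_value)`` where
    v = sqrt(chi2 / (n * (min(rows, cols) - 1))) from the contingency
    table of x and y.  Symmetric in its arguments.  If either variable
    has fewer than 2 observed levels, v is defined as 0 with a warning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    r, c = table.shape
    if min(r, c) < 2:
        warnings.warn("a variable has < 2 observed levels; Cramér's V defined as 0")
        return 0.0, 0.0, 1.0
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    n = table.sum()
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return v, float(chi2), float(p)


def association_matrix(
    targets: pd.DataFrame, fold_id: int | None = None
) -> RelatednessMatrix:
    """Pairwise Cramér's V between all target items (symmetric, diag 1)."""
    names = tuple(targets.columns)
    M = len(names)
    if M < 2:
        raise ValueError("need at least 2 items")
    values = np.ones((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            v, _, _ = cramers_v(targets.iloc[:, i], targets.iloc[:, j])
            values[i, j] = values[j, i] = v
    return RelatednessMatrix(values=values, kind="vtag", item_names=names, fold_id=fold_id)
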