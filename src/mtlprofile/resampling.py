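"""Monte Carlo cross-validation plans.

Each seeded plan splits the cohort into an 80% full-training set and a
20% hold-out test set, splits full-training again into 75% training and
25% validation, and partitions full-training into k folds used only for
computing task-relatedness matrices.  A suite of such plans (seeds
0..n_seeds-1 by default) drives the repeated-split evaluation protocol.
Non-integral sizes are floored on the smaller partition, the remainder
going to the larger one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ResamplingPlan", "make_plan", "plan_suite"]


@dataclass
class ResamplingPlan:
    seed: int
    test_rows: np.ndarray
    full_train_rows: np.ndarray
    train_rows: np.ndarray
    val_rows: np.ndarray
    folds: list[np.ndarray]

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_train_rows(self, f: int) -> np.ndarray:
        """Full-training rows outside fold f (the fold's training subset)."""
        return np.concatenate([self.folds[i] for i in range(self.k) if i != f])

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "test_rows": self.test_rows.tolist(),
            "train_rows": self.train_rows.tolist(),
            "val_rows": self.val_rows.tolist(),
            "folds": [f.tolist() for f in self.folds],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResamplingPlan":
        doc = json.loads(Path(path).read_text())
        folds = [np.array(f, dtype=np.int64) for f in doc["folds"]]
        train = np.array(doc["train_rows"], dtype=np.int64)
        val = np.array(doc["val_rows"], dtype=np.int64)
        return cls(
            seed=doc["seed"],
            test_rows=np.array(doc["test_rows"], dtype=np.int64),
            full_train_rows=np.sort(np.concatenate([train, val])),
            train_rows=train,
            val_rows=val,
            folds=folds,
        )


def make_plan(
    n_rows: int,
    seed: int,
    test_frac: float = 0.20,
    val_frac: float = 0.25,
    k: int = 3,
) -> ResamplingPlan:
    """One seeded Monte Carlo split with inner train/val and k folds."""
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if n_rows < 5 * k:
        raise ValueError(f"n_rows={n_rows} too small for k={k} folds")
    n_test = int(np.floor(n_rows * test_frac))
    if n_test < 1 or n_rows - n_test < k:
        raise ValueError("infeasible split sizes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    test = np.sort(perm[:n_test])
    full_train = np.sort(perm[n_test:])

    inner = rng.permutation(full_train)
    n_val = int(np.floor(len(full_train) * val_frac))
    if n_val < 1:
        raise ValueError("validation set would be empty")
    val = np.sort(inner[:n_val])
    train = np.sort(inner[n_val:])

    fold_perm = rng.permutation(full_train)
    folds = [np.sort(f) for f in np.array_split(fold_perm, k)]
    return ResamplingPlan(
        seed=seed,
        test_rows=test,
        full_train_rows=full_train,
        train_rows=train,
        val_rows=val,
        folds=folds,
    )


def plan_suite(
    n_rows: int,
    n_seeds: int = 50,
    test_frac: float = 0.20,
    val_frac: float = 0.25,
    k: int = 3,
    seeds: list[int] | None = None,
) -> list[ResamplingPlan]:
    """One plan per seed (default seeds 0..n_seeds-1)."""
    if seeds is None:
        if n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        seeds = list(range(n_seeds))
    return [make_plan(n_rows, s, test_frac, val_frac, k) for s in seeds]
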