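"""Exhaustive task-group enumeration, scoring and selection.

All subsets of the M tasks with at least 2 members are candidate groups
(catalog size L = 2^M - M - 1).  The score of a group for one of its
member tasks j is the mean relatedness of the other members onto j
(directed affinity entries for the training-dynamics measure, symmetric
entries for Cramér's V), averaged over the k relatedness matrices
computed on the k-fold training subsets.  For each task the argmax group
is selected; the union of selected groups defines the model ensemble,
with each task *primary* in its own argmax group and *secondary*
wherever else it appears.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

__all__ = [
    "GroupCatalog",
    "GroupScoreTable",
    "SelectedGroup",
    "GroupingResult",
    "enumerate_groups",
    "group_score",
    "score_catalog",
    "fold_average",
    "select_max_groups",
]

Group = tuple[int, ...]


@dataclass(frozen=True)
class GroupCatalog:
    """All unordered task subsets of size >= 2 over tasks 0..M-1."""

    M: int
    groups: tuple[Group, ...]

    @property
    def L(self) -> int:
        return len(self.groups)


@dataclass
class GroupScoreTable:
    """Per-(group, member task) relatedness-onto-task scores."""

    M: int
    scores: dict[Group, dict[int, float]]


@dataclass(frozen=True)
class SelectedGroup:
    members: Group
    primary: Group  # tasks whose argmax group this is (used at inference)
    secondary: Group  # trained-only members

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "primary": list(self.primary),
            "secondary": list(self.secondary),
        }


@dataclass
class GroupingResult:
    M: int
    groups: list[SelectedGroup]

    def primary_group_of(self, task: int) -> Group:
        for g in self.groups:
            if task in g.primary:
                return g.members
        raise KeyError(f"task {task} has no primary group")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"M": self.M, "groups": [g.to_dict() for g in self.groups]}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupingResult":
        doc = json.loads(Path(path).read_text())
        groups = [
            SelectedGroup(tuple(g["members"]), tuple(g["primary"]), tuple(g["secondary"]))
            for g in doc["groups"]
        ]
        return cls(M=doc["M"], groups=groups)


def enumerate_groups(M: int, max_tasks: int = 20) -> GroupCatalog:
    """All subsets of size 2..M; L = 2^M - M - 1 grows fast, hence the guard."""
    if not 2 <= M <= max_tasks:
        raise ValueError(
            f"M={M} outside the supported range [2, {max_tasks}]; raise max_tasks "
            "explicitly if the exponential catalog is intended"
        )
    groups = tuple(g for m in range(2, M + 1) for g in combinations(range(M), m))
    return GroupCatalog(M=M, groups=groups)


def group_score(matrix: np.ndarray, group: Group, j: int) -> float:
    """Mean relatedness of the other group members onto task j
    (entry (i, j) is the measure of task i onto task j)."""
    if j not in group:
        raise ValueError(f"task {j} is not a member of group {group}")
    if len(group) < 2:
        raise ValueError("group must have at least 2 members")
    others = [i for i in group if i != j]
    return float(np.mean([matrix[i, j] for i in others]))


def score_catalog(matrix: np.ndarray, catalog: GroupCatalog) -> GroupScoreTable:
    """Score every (group, member) pair of the catalog against one matrix."""
    matrix = np.asarray(matrix, dtype=float)
    scores = {
        g: {j: group_score(matrix, g, j) for j in g} for g in catalog.groups
    }
    return GroupScoreTable(M=catalog.M, scores=scores)


def fold_average(tables: list[GroupScoreTable]) -> GroupScoreTable:
    """Arithmetic mean of per-fold scores, per (group, member task)."""
    if not tables:
        raise ValueError("need at least one fold table")
    first = tables[0]
    for t in tables[1:]:
        if t.M != first.M or t.scores.keys() != first.scores.keys():
            raise ValueError("fold score tables cover different catalogs")
    out: dict[Group, dict[int, float]] = {}
    for g in first.scores:
        out[g] = {
            j: float(np.mean([t.scores[g][j] for t in tables])) for j in first.scores[g]
        }
    return GroupScoreTable(M=first.M, scores=out)


def select_max_groups(table: GroupScoreTable) -> GroupingResult:
    """Per task, pick the argmax-scoring group containing it (ties go to
    the smallest group, then lexicographically smallest members); the
    deduplicated union of picks is the ensemble.  Every task is primary
    in exactly one selected group."""
    M = table.M
    argmax_of: dict[int, Group] = {}
    for j in range(M):
        candidates = [(g, s[j]) for g, s in table.scores.items() if j in s]
        if not candidates:
            raise ValueError(f"no scored group contains task {j}")
        best_score = max(s for _, s in candidates)
        tied = [g for g, s in candidates if s == best_score]
        argmax_of[j] = min(tied, key=lambda g: (len(g), g))

    selected: list[Group] = []
    for j in range(M):
        if argmax_of[j] not in selected:
            selected.append(argmax_of[j])
    groups = []
    for g in selected:
        primary = tuple(j for j in g if argmax_of[j] == g)
        secondary = tuple(j for j in g if argmax_of[j] != g)
        groups.append(SelectedGroup(members=g, primary=primary, secondary=secondary))
    return GroupingResult(M=M, groups=groups)
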