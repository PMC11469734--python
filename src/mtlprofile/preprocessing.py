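"""Deterministic feature/target encoding.

Continuous features are min-max scaled into [0, 1] on the fitting rows
only (held-out values outside the fitted range are clipped); categorical
features are one-hot encoded with category maps covering every level
seen anywhere in the table, so held-out rows always encode.  Target
level codes map to contiguous class indices in declared level order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import CohortTable
from .profiles import ProfileSpec

__all__ = ["bin_eqvas", "Encoders", "EncodedMatrix", "fit_encoders", "encode"]


def bin_eqvas(score: int) -> int:
    """Bin an EQ-VAS overall health score (1..100) into 4 equal classes.

    Closed intervals: [1, 25] -> 1, [26, 50] -> 2, [51, 75] -> 3,
    [76, 100] -> 4.
    """
    if not 1 <= score <= 100:
        raise ValueError(f"EQ-VAS score must be in 1..100, got {score}")
    return 1 + (int(score) - 1) // 25


@dataclass
class Encoders:
    """Fitted min-max ranges, category maps, and the target level order."""

    cont_ranges: dict[str, tuple[float, float]]
    cat_levels: dict[str, list]
    profile: ProfileSpec

    @property
    def n_encoded_features(self) -> int:
        return len(self.cont_ranges) + sum(len(v) for v in self.cat_levels.values())

    def to_json(self, path: str | Path) -> None:
        doc = {
            "cont_ranges": {k: list(v) for k, v in self.cont_ranges.items()},
            "cat_levels": {k: [str(x) for x in v] for k, v in self.cat_levels.items()},
            "items": [
                {"name": it.name, "levels": list(map(int, it.levels))}
                for it in self.profile.items
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Encoders":
        from .profiles import ItemSpec

        doc = json.loads(Path(path).read_text())
        return cls(
            cont_ranges={k: (v[0], v[1]) for k, v in doc["cont_ranges"].items()},
            cat_levels={k: list(v) for k, v in doc["cat_levels"].items()},
            profile=ProfileSpec(
                tuple(ItemSpec(d["name"], tuple(d["levels"])) for d in doc["items"])
            ),
        )


@dataclass
class EncodedMatrix:
    """Design matrix in [0, 1] plus per-item class-index target vectors."""

    X: np.ndarray
    y: dict[str, np.ndarray]
    feature_names: list[str]
    encoders: Encoders


def fit_encoders(table: CohortTable, fit_rows: np.ndarray | None = None) -> Encoders:
    """Fit min-max ranges on ``fit_rows`` only; category maps on the whole table."""
    if fit_rows is None:
        fit_rows = np.arange(table.n_rows)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    sub = table.data.iloc[fit_rows]
    cont_ranges: dict[str, tuple[float, float]] = {}
    cat_levels: dict[str, list] = {}
    for col, role in table.feature_roles.items():
        if role == "continuous":
            lo, hi = float(sub[col].min()), float(sub[col].max())
            if lo == hi:
                warnings.warn(f"constant continuous column {col!r}; encoding as 0")
            cont_ranges[col] = (lo, hi)
        else:
            cat_levels[col] = sorted(table.data[col].unique().tolist())
    return Encoders(cont_ranges, cat_levels, table.profile)


def encode(table: CohortTable, encoders: Encoders, rows: np.ndarray | None = None) -> EncodedMatrix:
    """Encode the given rows (default: all) with previously fitted encoders."""
    if rows is None:
        rows = np.arange(table.n_rows)
    sub = table.data.iloc[np.asarray(rows)]
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col, role in table.feature_roles.items():
        if role == "continuous":
            lo, hi = encoders.cont_ranges[col]
            v = sub[col].to_numpy(dtype=float)
            scaled = np.zeros_like(v) if hi == lo else np.clip((v - lo) / (hi - lo), 0.0, 1.0)
            blocks.append(scaled[:, None])
            names.append(col)
        else:
            levels = encoders.cat_levels[col]
            v = sub[col].to_numpy()
            onehot = np.zeros((len(sub), len(levels)))
            for j, lev in enumerate(levels):
                onehot[:, j] = v == lev
            blocks.append(onehot)
            names.extend(f"{col}={lev}" for lev in levels)
    X = np.hstack(blocks) if blocks else np.zeros((len(sub), 0))
    y = {
        item.name: np.array([item.class_index(v) for v in sub[item.name]], dtype=np.int64)
        for item in encoders.profile.items
    }
    return EncodedMatrix(X=X, y=y, feature_names=names, encoders=encoders)


def decode_targets(y: dict[str, np.ndarray], profile: ProfileSpec) -> dict[str, np.ndarray]:
    """Map class indices back to the declared ordinal level codes."""
    return {
        item.name: np.asarray(item.levels)[np.asarray(y[item.name])]
        for item in profile.items
    }
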