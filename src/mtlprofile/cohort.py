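"""Synthetic cohorts with correlated ordinal multi-task targets.

The generator emulates the statistical structure that task-grouping
methods are meant to detect: M ordinal target items whose pairwise
dependence is planted explicitly.  Each item i has a continuous latent
score

    s_i = w_feature * t_i  +  w_latent * f_i  +  noise_sd * eps_i

where (t_1..t_M) are feature-driven signals and (f_1..f_M) are shared
standard-normal factors, both mixed so that their cross-item correlation
matrix equals the requested ``dependence`` matrix, and eps_i is
independent noise.  The latent score is cut at per-item thresholds
(equal-probability Gaussian quantiles, shifted by ``class_skew``) to
yield the item's declared ordinal levels.  Dependence = identity gives
independent targets; a loading of 1 with equal thresholds and vanishing
noise makes two targets identical columns.

Because the feature-driven part is mixed with the same loadings as the
latent part, tasks with high planted dependence genuinely share
predictable structure -- joint (multi-task) learning can exploit it,
which is the regime the grouping methods are designed for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .profiles import ItemSpec, ProfileSpec

__all__ = [
    "CohortSpec",
    "CohortTable",
    "generate_cohort",
    "uniform_dependence",
    "write_cohort",
    "read_cohort",
]


def uniform_dependence(M: int, loading: float) -> np.ndarray:
    """M x M dependence matrix with a common off-diagonal loading."""
    D = np.full((M, M), float(loading))
    np.fill_diagonal(D, 1.0)
    return D


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_rows: int
    profile: ProfileSpec
    n_continuous: int = 10
    categorical_cardinalities: tuple[int, ...] = (2, 3)
    dependence: np.ndarray | None = None  # default: identity (independent targets)
    class_skew: tuple[float, ...] | None = None  # per-item threshold offsets
    noise_sd: float = 0.5
    w_feature: float = 1.0
    w_latent: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        M = self.profile.M
        if self.dependence is None:
            self.dependence = np.eye(M)
        self.dependence = np.asarray(self.dependence, dtype=float)
        if self.dependence.shape != (M, M):
            raise ValueError(f"dependence must be {M}x{M}")
        if not np.allclose(self.dependence, self.dependence.T):
            raise ValueError("dependence matrix must be symmetric")
        if not np.allclose(np.diag(self.dependence), 1.0):
            raise ValueError("dependence diagonal must be 1")
        if self.dependence.min() < 0 or self.dependence.max() > 1 + 1e-12:
            raise ValueError("dependence entries must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.class_skew is None:
            self.class_skew = tuple(0.0 for _ in range(M))
        if len(self.class_skew) != M:
            raise ValueError("class_skew needs one offset per item")


@dataclass
class CohortTable:
    """One row per patient: features plus one ordinal target column per item."""

    data: pd.DataFrame
    profile: ProfileSpec
    feature_roles: dict[str, str]  # column -> "continuous" | "categorical"

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def feature_columns(self) -> list[str]:
        return list(self.feature_roles)

    @property
    def target_columns(self) -> list[str]:
        return list(self.profile.names)

    def targets(self, rows: np.ndarray | None = None) -> pd.DataFrame:
        sub = self.data if rows is None else self.data.iloc[rows]
        return sub[list(self.profile.names)]


def _mixing_root(D: np.ndarray) -> np.ndarray:
    """Symmetric square root of the dependence matrix (PSD-clipped)."""
    w, V = np.linalg.eigh(D)
    w = np.clip(w, 0.0, None)
    C = V @ np.diag(np.sqrt(w)) @ V.T
    # renormalise rows so each latent keeps unit systematic variance
    norms = np.linalg.norm(C, axis=1)
    norms[norms == 0] = 1.0
    return C / norms[:, None]


def _orthonormal_directions(rng: np.random.Generator, p: int, M: int) -> np.ndarray:
    """M near-orthonormal weight vectors in R^p (exactly orthonormal if p >= M)."""
    A = rng.standard_normal((p, max(M, 1)))
    Q, _ = np.linalg.qr(A)
    if Q.shape[1] >= M:
        return Q[:, :M].T
    # fewer features than items: fall back to random unit directions
    B = rng.standard_normal((M, p))
    return B / np.linalg.norm(B, axis=1, keepdims=True)


def _item_thresholds(item: ItemSpec, sigma: float, offset: float) -> np.ndarray:
    """Equal-probability Gaussian cut points, shifted by the skew offset."""
    K = item.n_classes
    qs = np.arange(1, K) / K
    return norm.ppf(qs) * sigma + offset


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort; identical specs (incl. seed) give identical tables."""
    M = spec.profile.M
    if spec.n_rows < 10 * M:
        raise ValueError(
            f"n_rows={spec.n_rows} too small for M={M} targets; need >= {10 * M} "
            "rows to stratify splits and folds"
        )
    rng = np.random.default_rng(spec.seed)

    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    X_cont = rng.uniform(0.0, 1.0, size=(spec.n_rows, spec.n_continuous))
    for j in range(spec.n_continuous):
        name = f"x{j}"
        cols[name] = X_cont[:, j]
        roles[name] = "continuous"
    for j, card in enumerate(spec.categorical_cardinalities):
        name = f"c{j}"
        cols[name] = rng.integers(0, card, size=spec.n_rows)
        roles[name] = "categorical"

    # standardised continuous features drive the predictable signal
    Xs = (X_cont - 0.5) / np.sqrt(1.0 / 12.0)
    Q = _orthonormal_directions(rng, spec.n_continuous, M)  # M x p
    base_signals = Xs @ Q.T  # n x M, ~unit variance, cross-item corr ~ 0
    factors = rng.standard_normal((spec.n_rows, M))
    eps = rng.standard_normal((spec.n_rows, M))

    C = _mixing_root(spec.dependence)  # M x M, rows unit norm
    systematic = spec.w_feature * base_signals @ C.T + spec.w_latent * factors @ C.T
    latent = systematic + spec.noise_sd * eps

    sigma = np.sqrt(spec.w_feature**2 + spec.w_latent**2 + spec.noise_sd**2)
    for i, item in enumerate(spec.profile.items):
        cuts = _item_thresholds(item, sigma, spec.class_skew[i])
        idx = np.searchsorted(cuts, latent[:, i])
        cols[item.name] = np.asarray(item.levels)[idx]

    data = pd.DataFrame(cols)
    data.insert(0, "row_id", np.arange(spec.n_rows))
    return CohortTable(data=data, profile=spec.profile, feature_roles=roles)


# ---------------------------------------------------------------------------
# CSV + sidecar schema I/O

def write_cohort(table: CohortTable, csv_path: str | Path, schema_path: str | Path) -> None:
    """Write the cohort as CSV plus a JSON schema naming each column's role."""
    table.data.to_csv(csv_path, index=False)
    schema = {"columns": {}}
    for col, role in table.feature_roles.items():
        schema["columns"][col] = {"role": role}
    for item in table.profile.items:
        schema["columns"][item.name] = {"role": "target", "levels": list(map(int, item.levels))}
    Path(schema_path).write_text(json.dumps(schema, indent=2))


def read_cohort(csv_path: str | Path, schema_path: str | Path) -> CohortTable:
    schema = json.loads(Path(schema_path).read_text())
    data = pd.read_csv(csv_path)
    roles: dict[str, str] = {}
    items: list[ItemSpec] = []
    for col, info in schema["columns"].items():
        if info["role"] == "target":
            items.append(ItemSpec(col, tuple(info["levels"])))
        else:
            roles[col] = info["role"]
    table = CohortTable(data=data, profile=ProfileSpec(tuple(items)), feature_roles=roles)
    for item in table.profile.items:
        bad = ~data[item.name].isin(item.levels)
        if bad.any():
            raise ValueError(f"target {item.name!r} has values outside its level set")
    return table
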