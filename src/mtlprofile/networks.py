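"""Multi-task MLP architectures and their training loop.

All networks are rectifier MLPs built from the same blocks: an optional
shared trunk of h/2 hidden layers, one branch of h/2 hidden layers per
task, and one output head per task (sigmoid + binary cross-entropy for
binary items, softmax + categorical cross-entropy for multinomial
items).  The total training loss is the unweighted sum of per-task
losses.  Variants:

- ``stl``        -- single task, all h hidden layers in the trunk;
- ``mtl_all``    -- shared trunk + M branches (classic hard sharing);
- ``mtl_group``  -- same shape restricted to one task group; only the
                    group's *primary* tasks are used at inference, the
                    remaining (secondary) heads exist to aid training;
- ``mtl_concat`` -- all-task MTL whose head for task j reads the
                    concatenated last branch layers of every member of
                    j's primary group instead of j's branch alone.

Training is plain SGD with momentum, a halving learning-rate schedule,
and early stopping on the summed validation loss; everything is seeded
and the best-validation weights are restored at the end.  The forward,
backward and update passes are implemented directly in numpy so that
per-task gradients on the shared trunk can be taken and the trunk
snapshot/restored exactly -- the contract the task-affinity probe needs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .grouping import GroupingResult
from .profiles import ItemSpec, ProfileSpec

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "MultiTaskMLP",
    "TaskEnsemble",
    "build_stl",
    "build_mtl_all",
    "build_mtl_group",
    "build_mtl_concat",
    "build_group_ensemble",
    "build_stl_ensemble",
    "transfer_pretrained",
    "train",
    "count_parameters",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """h hidden rectifier layers of r nodes (trunk h/2 + branch h/2)."""

    h: int = 4
    r: int = 100

    def __post_init__(self) -> None:
        if self.h % 2 != 0 or self.h < 2:
            raise ValueError("h must be even and >= 2 (trunk h/2, branch h/2)")
        if self.r < 1:
            raise ValueError("r must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    lr: float = 0.0005
    momentum: float = 0.9
    lr_halving_period: int = 15
    patience: int = 15
    min_epochs: int = 10
    max_epochs: int = 200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.momentum + 1, self.lr_halving_period, self.patience,
               self.min_epochs, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("training configuration values must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch (halved every halving period)."""
        return self.lr * 0.5 ** ((epoch - 1) // self.lr_halving_period)


class Dense:
    """A fully connected layer with Glorot-uniform seeded initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


_EPS = 1e-12


class MultiTaskMLP:
    """Shared trunk, per-task branches, per-task heads, optional concat links."""

    def __init__(
        self,
        variant: str,
        input_dim: int,
        items: tuple[ItemSpec, ...],
        arch: ArchitectureConfig,
        trunk_depth: int,
        seed: int,
        head_sources: dict[str, list[str]] | None = None,
        inference_tasks: tuple[str, ...] | None = None,
    ):
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.arch = arch
        self.items = {it.name: it for it in items}
        self.task_names = tuple(it.name for it in items)
        branch_depth = arch.h - trunk_depth

        self.trunk: list[Dense] = []
        dim = input_dim
        for _ in range(trunk_depth):
            self.trunk.append(Dense(dim, arch.r, rng))
            dim = arch.r
        trunk_out_dim = dim

        self.branches: dict[str, list[Dense]] = {}
        for name in self.task_names:
            layers, d = [], trunk_out_dim
            for _ in range(branch_depth):
                layers.append(Dense(d, arch.r, rng))
                d = arch.r
            self.branches[name] = layers

        self.head_sources = head_sources or {n: [n] for n in self.task_names}
        branch_out_dim = arch.r if branch_depth > 0 else trunk_out_dim
        self.heads: dict[str, Dense] = {}
        for name, item in self.items.items():
            n_out = 1 if item.kind == "binary" else item.n_classes
            n_in = branch_out_dim * len(self.head_sources[name])
            self.heads[name] = Dense(n_in, n_out, rng)

        self.inference_tasks = inference_tasks or self.task_names
        self.history: dict[str, list] = {}

    # -- parameter bookkeeping ---------------------------------------------
    def _all_layers(self) -> list[Dense]:
        out = list(self.trunk)
        for name in self.task_names:
            out.extend(self.branches[name])
        out.extend(self.heads[name] for name in self.task_names)
        return out

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for lyr in self._all_layers():
            out.extend((lyr.W, lyr.b))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w

    def shared_params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for lyr in self.trunk:
            out.extend((lyr.W, lyr.b))
        return out

    def set_shared_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.shared_params(), values, strict=True):
            p[...] = v

    # -- forward / losses ---------------------------------------------------
    def _forward(self, X: np.ndarray) -> dict:
        acts = [X]
        a = X
        for lyr in self.trunk:
            a = _relu(a @ lyr.W + lyr.b)
            acts.append(a)
        branch_acts: dict[str, list[np.ndarray]] = {}
        branch_out: dict[str, np.ndarray] = {}
        for name in self.task_names:
            ba, cur = [], a
            for lyr in self.branches[name]:
                cur = _relu(cur @ lyr.W + lyr.b)
                ba.append(cur)
            branch_acts[name] = ba
            branch_out[name] = cur
        head_inputs: dict[str, np.ndarray] = {}
        logits: dict[str, np.ndarray] = {}
        for name in self.task_names:
            inp = np.hstack([branch_out[s] for s in self.head_sources[name]])
            head_inputs[name] = inp
            h = self.heads[name]
            logits[name] = inp @ h.W + h.b
        return {
            "trunk_acts": acts,
            "branch_acts": branch_acts,
            "branch_out": branch_out,
            "head_inputs": head_inputs,
            "logits": logits,
        }

    def _loss_and_dlogits(
        self, name: str, logits: np.ndarray, y: np.ndarray
    ) -> tuple[float, np.ndarray]:
        item = self.items[name]
        B = len(y)
        if item.kind == "binary":
            p = _sigmoid(logits[:, 0])
            loss = -np.mean(y * np.log(p + _EPS) + (1 - y) * np.log(1 - p + _EPS))
            dz = ((p - y) / B)[:, None]
        else:
            p = _softmax(logits)
            loss = -np.mean(np.log(p[np.arange(B), y] + _EPS))
            grad = p.copy()
            grad[np.arange(B), y] -= 1.0
            dz = grad / B
        return float(loss), dz

    def task_losses(self, X: np.ndarray, y: dict[str, np.ndarray]) -> dict[str, float]:
        cache = self._forward(X)
        return {
            name: self._loss_and_dlogits(name, cache["logits"][name], y[name])[0]
            for name in self.task_names
        }

    # -- backward -----------------------------------------------------------
    def _backward(
        self, cache: dict, dlogits: dict[str, np.ndarray]
    ) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict, dict]:
        """Gradients for (trunk layers, branches, heads) given head-logit grads."""
        r_out = {n: cache["branch_out"][n].shape[1] for n in self.task_names}
        d_branch_out = {n: None for n in self.task_names}
        head_grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, dz in dlogits.items():
            h = self.heads[name]
            inp = cache["head_inputs"][name]
            head_grads[name] = (inp.T @ dz, dz.sum(axis=0))
            dinp = dz @ h.W.T
            off = 0
            for src in self.head_sources[name]:
                w = r_out[src]
                piece = dinp[:, off : off + w]
                d_branch_out[src] = piece if d_branch_out[src] is None else d_branch_out[src] + piece
                off += w

        trunk_out = cache["trunk_acts"][-1]
        d_trunk_out = np.zeros_like(trunk_out)
        branch_grads: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for name in self.task_names:
            da = d_branch_out[name]
            layers = self.branches[name]
            grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(layers)
            if da is None:
                branch_grads[name] = [
                    (np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers
                ]
                continue
            for li in range(len(layers) - 1, -1, -1):
                act = cache["branch_acts"][name][li]
                da = da * (act > 0)
                prev = cache["branch_acts"][name][li - 1] if li > 0 else trunk_out
                grads[li] = (prev.T @ da, da.sum(axis=0))
                da = da @ layers[li].W.T
            branch_grads[name] = grads
            d_trunk_out = d_trunk_out + da

        trunk_grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.trunk)
        da = d_trunk_out
        for li in range(len(self.trunk) - 1, -1, -1):
            act = cache["trunk_acts"][li + 1]
            da = da * (act > 0)
            prev = cache["trunk_acts"][li]
            trunk_grads[li] = (prev.T @ da, da.sum(axis=0))
            da = da @ self.trunk[li].W.T
        return trunk_grads, branch_grads, head_grads

    def _flatten_grads(self, trunk_grads, branch_grads, head_grads) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for gW, gb in trunk_grads:
            out.extend((gW, gb))
        for name in self.task_names:
            for gW, gb in branch_grads[name]:
                out.extend((gW, gb))
        for name in self.task_names:
            gW, gb = head_grads.get(name, (np.zeros_like(self.heads[name].W),
                                           np.zeros_like(self.heads[name].b)))
            out.extend((gW, gb))
        return out

    def loss_and_gradients(
        self, X: np.ndarray, y: dict[str, np.ndarray]
    ) -> tuple[float, dict[str, float], list[np.ndarray]]:
        """Summed loss, per-task losses, and gradients for all parameters."""
        cache = self._forward(X)
        dlogits, losses = {}, {}
        for name in self.task_names:
            losses[name], dlogits[name] = self._loss_and_dlogits(
                name, cache["logits"][name], y[name]
            )
        grads = self._flatten_grads(*self._backward(cache, dlogits))
        return float(sum(losses.values())), losses, grads

    def shared_gradient(self, X: np.ndarray, y: dict[str, np.ndarray], task: str) -> list[np.ndarray]:
        """Gradient of the single task's loss w.r.t. the shared trunk only."""
        cache = self._forward(X)
        _, dz = self._loss_and_dlogits(task, cache["logits"][task], y[task])
        trunk_grads, _, _ = self._backward(cache, {task: dz})
        out: list[np.ndarray] = []
        for gW, gb in trunk_grads:
            out.extend((gW, gb))
        return out

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> dict[str, np.ndarray]:
        cache = self._forward(X)
        out = {}
        for name in self.task_names:
            z = cache["logits"][name]
            out[name] = _sigmoid(z[:, 0]) if self.items[name].kind == "binary" else _softmax(z)
        return out

    def predict(self, X: np.ndarray, tasks: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        """Predicted class index per row per task (binary threshold 0.5)."""
        tasks = tasks or self.inference_tasks
        proba = self.predict_proba(X)
        out = {}
        for name in tasks:
            p = proba[name]
            out[name] = (p >= 0.5).astype(np.int64) if p.ndim == 1 else p.argmax(axis=1)
        return out


class TaskEnsemble:
    """Routes each task to the member model for which it is primary."""

    def __init__(self, members: list[MultiTaskMLP]):
        self.members = members
        self.owner: dict[str, MultiTaskMLP] = {}
        for m in members:
            for t in m.inference_tasks:
                if t in self.owner:
                    raise ValueError(f"task {t!r} owned by more than one member")
                self.owner[t] = m

    @property
    def task_names(self) -> tuple[str, ...]:
        return tuple(self.owner)

    def predict(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {t: m.predict(X, tasks=(t,))[t] for t, m in self.owner.items()}


# ---------------------------------------------------------------------------
# builders

def build_stl(
    input_dim: int, item: ItemSpec, arch: ArchitectureConfig = ArchitectureConfig(), seed: int = 0
) -> MultiTaskMLP:
    """Single-task MLP: h hidden layers then one output head."""
    return MultiTaskMLP("stl", input_dim, (item,), arch, trunk_depth=arch.h, seed=seed)


def build_mtl_all(
    input_dim: int, profile: ProfileSpec, arch: ArchitectureConfig = ArchitectureConfig(), seed: int = 0
) -> MultiTaskMLP:
    """Classic all-task MTL: h/2 shared trunk layers + M branches of h/2."""
    return MultiTaskMLP("mtl_all", input_dim, profile.items, arch, trunk_depth=arch.h // 2, seed=seed)


def build_mtl_group(
    input_dim: int,
    profile: ProfileSpec,
    group: tuple[int, ...],
    primary: tuple[int, ...] | None = None,
    arch: ArchitectureConfig = ArchitectureConfig(),
    seed: int = 0,
) -> MultiTaskMLP:
    """MTL restricted to one task group; non-primary heads are secondary."""
    if len(group) < 2:
        raise ValueError("a task group must contain at least 2 tasks")
    items = tuple(profile.items[i] for i in group)
    inference = tuple(profile.items[i].name for i in (primary if primary is not None else group))
    return MultiTaskMLP(
        "mtl_group", input_dim, items, arch, trunk_depth=arch.h // 2, seed=seed,
        inference_tasks=inference,
    )


def build_mtl_concat(
    input_dim: int,
    profile: ProfileSpec,
    grouping: GroupingResult,
    arch: ArchitectureConfig = ArchitectureConfig(),
    seed: int = 0,
) -> MultiTaskMLP:
    """All-task MTL whose head j reads the concatenated last branch layers
    of every member of j's primary group (j's own branch included)."""
    if grouping.M != profile.M:
        raise ValueError("grouping does not match the profile's task count")
    head_sources = {}
    for j, item in enumerate(profile.items):
        members = grouping.primary_group_of(j)
        head_sources[item.name] = [profile.items[i].name for i in members]
    return MultiTaskMLP(
        "mtl_concat", input_dim, profile.items, arch, trunk_depth=arch.h // 2,
        seed=seed, head_sources=head_sources,
    )


def build_stl_ensemble(
    input_dim: int, profile: ProfileSpec, arch: ArchitectureConfig = ArchitectureConfig(), seed: int = 0
) -> list[MultiTaskMLP]:
    """One independently initialised STL model per item (the eSTL members)."""
    return [build_stl(input_dim, it, arch, seed=seed + i) for i, it in enumerate(profile.items)]


def build_group_ensemble(
    input_dim: int,
    profile: ProfileSpec,
    grouping: GroupingResult,
    arch: ArchitectureConfig = ArchitectureConfig(),
    seed: int = 0,
) -> list[MultiTaskMLP]:
    """One grouped-MTL member per selected group (primaries marked)."""
    return [
        build_mtl_group(input_dim, profile, g.members, g.primary, arch, seed=seed + gi)
        for gi, g in enumerate(grouping.groups)
    ]


def transfer_pretrained(source: MultiTaskMLP, target: MultiTaskMLP) -> MultiTaskMLP:
    """Copy trunk and branch weights from a trained all-task MTL into a
    concatenation model; the (re-shaped) heads keep their fresh weights."""
    if len(source.trunk) != len(target.trunk) or set(source.task_names) != set(target.task_names):
        raise ValueError("source and target trunk/branch structure must match")
    for ls, lt in zip(source.trunk, target.trunk):
        if ls.W.shape != lt.W.shape:
            raise ValueError("trunk layer shape mismatch")
        lt.W[...] = ls.W
        lt.b[...] = ls.b
    for name in target.task_names:
        if len(source.branches[name]) != len(target.branches[name]):
            raise ValueError("branch depth mismatch")
        for ls, lt in zip(source.branches[name], target.branches[name]):
            if ls.W.shape != lt.W.shape:
                raise ValueError("branch layer shape mismatch")
            lt.W[...] = ls.W
            lt.b[...] = ls.b
    return target


def count_parameters(model: MultiTaskMLP) -> int:
    """Total trainable scalar parameters."""
    return sum(l.n_params for l in model._all_layers())


# ---------------------------------------------------------------------------
# training

def _batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(
    model: MultiTaskMLP,
    X_train: np.ndarray,
    y_train: dict[str, np.ndarray],
    X_val: np.ndarray,
    y_val: dict[str, np.ndarray],
    cfg: TrainingConfig = TrainingConfig(),
    probe=None,
) -> MultiTaskMLP:
    """SGD with momentum on the summed loss; halving lr schedule; early
    stopping (patience on the summed validation loss, never before
    ``min_epochs``); restores the best-validation weights.

    ``probe``, if given, is called as ``probe.observe(model, Xb, yb, lr)``
    before each ordinary update and ``probe.end_epoch(lr)`` after each
    epoch; it must leave the model unchanged (the task-affinity probe's
    snapshot/restore contract).
    """
    if len(X_val) == 0:
        raise ValueError("validation set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p) for p in params]
    n = len(X_train)

    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0
    hist = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(1, cfg.max_epochs + 1):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for idx in _batches(n, cfg.batch_size, order):
            Xb = X_train[idx]
            yb = {t: v[idx] for t, v in y_train.items()}
            if probe is not None:
                probe.observe(model, Xb, yb, lr)
            total, _, grads = model.loss_and_gradients(Xb, yb)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (variant {model.variant})"
                )
            for p, v, g in zip(params, velocity, grads):
                v *= cfg.momentum
                v -= lr * g
                p += v
            epoch_losses.append(total)
        if probe is not None:
            probe.end_epoch(lr)

        val_loss = float(sum(model.task_losses(X_val, y_val).values()))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        hist["train_loss"].append(float(np.mean(epoch_losses)))
        hist["val_loss"].append(val_loss)
        hist["lr"].append(lr)

        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if epoch >= cfg.min_epochs and since_best >= cfg.patience:
            break

    model.set_weights(best_weights)
    hist["best_epoch"] = best_epoch
    hist["stop_epoch"] = epoch
    model.history = hist
    return model
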