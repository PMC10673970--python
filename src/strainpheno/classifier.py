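"""Cross-validated training, selection and ensembling of the classifier.

Training uses 5-fold cross-validation with *group-aware* fold assignment:
a propensity match group (one carrier plus its matched controls) never
straddles folds, so matched subjects cannot leak between training and
validation. The five fold-trained networks form the final ensemble; the
ensemble probability for a subject is the arithmetic mean of the five
members' predicted probabilities.

Model selection follows a parsimony rule: among candidate configurations
the one with the highest mean fold F1 wins, ties going to the fewest
trainable parameters, then to listed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import NormalizedCurveSet
from .tcn import DilatedCausalNet, NetworkConfig, TrainingHistory, _f1, _sigmoid, train_network


@dataclass
class TrainedEnsemble:
    members: list[DilatedCausalNet]
    config: NetworkConfig
    fold_assignments: dict[str, int]          # match-group id -> fold
    training_history: list[TrainingHistory] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("ensemble needs at least one member")
        # members share all hyperparameters; per-fold init seeds may differ
        base = {k: v for k, v in self.config.__dict__.items() if k != "seed"}
        for m in self.members:
            if {k: v for k, v in m.config.__dict__.items() if k != "seed"} != base:
                raise ValueError("all ensemble members must share one configuration")

    @property
    def input_shape(self) -> tuple[int, int]:
        return (self.members[0].n_channels, -1)


def build_network(config: NetworkConfig, input_shape: tuple[int, int] = (6, 101)) -> DilatedCausalNet:
    """Construct an untrained network for a (channels, T) input shape.

    Causal left-padding means T may be shorter than the receptive field; the
    receptive field is available as ``net.receptive_field``.
    """
    n_channels, T = input_shape
    if n_channels < 1 or T < 1:
        raise ValueError(f"input_shape must be positive, got {input_shape}")
    return DilatedCausalNet(config, n_channels=n_channels)


def assign_group_folds(
    group_ids: list[str], group_sizes: dict[str, int], k: int, seed: int
) -> dict[str, int]:
    """Deal match groups round-robin into k folds after a seeded shuffle.

    Raises if any single group holds more subjects than a fold can.
    """
    n_total = sum(group_sizes[g] for g in group_ids)
    capacity = int(np.ceil(n_total / k))
    for g in group_ids:
        if group_sizes[g] > capacity:
            raise ValueError(
                f"match group {g!r} has {group_sizes[g]} subjects, larger than a fold "
                f"(capacity {capacity})"
            )
    rng = np.random.default_rng(seed)
    order = sorted(group_ids)
    rng.shuffle(order)
    return {g: i % k for i, g in enumerate(order)}


def train_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[str],
    config: NetworkConfig,
    k: int = 5,
    seed: int = 0,
) -> tuple[TrainedEnsemble, list[float]]:
    """Group-aware k-fold CV; returns the ensemble and per-fold F1 scores.

    ``groups[i]`` is the match-group id of sample i (unmatched controls get
    singleton group ids). Each member trains on k-1 folds with binary
    cross-entropy and early stopping, and is scored by F1 (carrier =
    positive class, threshold 0.5) on its held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3 or len(y) != X.shape[0] or len(groups) != X.shape[0]:
        raise ValueError("X must be (N, 6, T) aligned with y and groups")
    sizes: dict[str, int] = {}
    for g in groups:
        sizes[g] = sizes.get(g, 0) + 1
    ss = np.random.SeedSequence(seed)
    fold_seed, *member_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(k + 1)]
    fold_of_group = assign_group_folds(list(sizes), sizes, k, fold_seed)
    fold = np.array([fold_of_group[g] for g in groups])

    members: list[DilatedCausalNet] = []
    histories: list[TrainingHistory] = []
    fold_f1: list[float] = []
    for f in range(k):
        tr, va = fold != f, fold == f
        if va.sum() == 0 or len(np.unique(y[va])) < 2:
            raise ValueError(f"fold {f} lacks both classes in validation")
        member_cfg = NetworkConfig(**{**config.__dict__, "seed": member_seeds[f]})
        net = build_network(member_cfg, input_shape=X.shape[1:])
        hist = train_network(net, X[tr], y[tr], X[va], y[va], seed=member_seeds[f])
        members.append(net)
        histories.append(hist)
        fold_f1.append(_f1(net.predict_proba(X[va]), y[va]))

    ensemble = TrainedEnsemble(
        members=members,
        config=config,
        fold_assignments=fold_of_group,
        training_history=histories,
        fold_f1=fold_f1,
    )
    return ensemble, fold_f1


#: Default axes of the cross-validated hyperparameter search.
DEFAULT_GRID: dict[str, tuple] = {
    "n_feature_maps": (16, 32),
    "n_levels": (3, 4, 5),
    "kernel_size": (3, 5),
    "dropout": (0.1, 0.3),
}


def expand_grid(axes: dict[str, tuple] | None = None) -> list[NetworkConfig]:
    """All configurations spanned by the grid axes (defaults elsewhere)."""
    import itertools

    axes = axes or DEFAULT_GRID
    keys = list(axes)
    configs = []
    for combo in itertools.product(*(axes[k] for k in keys)):
        configs.append(NetworkConfig(**dict(zip(keys, combo))))
    return configs


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[str],
    configs: list[NetworkConfig],
    k: int = 5,
    seed: int = 0,
) -> tuple[NetworkConfig, list[tuple[NetworkConfig, float, int]]]:
    """Cross-validate every candidate configuration and pick the winner.

    Returns (selected config, the (config, mean F1, parameter count) table
    fed to :func:`select_model`).
    """
    runs: list[tuple[NetworkConfig, float, int]] = []
    for cfg in configs:
        ensemble, fold_f1 = train_cv(X, y, groups, cfg, k=k, seed=seed)
        runs.append((cfg, float(np.mean(fold_f1)), ensemble.members[0].n_parameters))
    return select_model(runs), runs


def save_ensemble(ensemble: TrainedEnsemble, directory) -> None:
    """Write per-fold weight checkpoints (.npz) with a JSON config sidecar."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(ensemble.members):
        params = member.get_params()
        np.savez(directory / f"fold{i}.npz", *params)
    sidecar = {
        "config": ensemble.config.__dict__,
        "member_seeds": [m.config.seed for m in ensemble.members],
        "n_members": len(ensemble.members),
        "n_channels": ensemble.members[0].n_channels,
        "fold_assignments": ensemble.fold_assignments,
        "fold_f1": ensemble.fold_f1,
    }
    (directory / "config.json").write_text(json.dumps(sidecar, indent=2))


def load_ensemble(directory) -> TrainedEnsemble:
    """Load an ensemble written by :func:`save_ensemble`."""
    import json
    from pathlib import Path

    from .tcn import DilatedCausalNet

    directory = Path(directory)
    sidecar = json.loads((directory / "config.json").read_text())
    config = NetworkConfig(**sidecar["config"])
    members = []
    for i in range(sidecar["n_members"]):
        member_cfg = NetworkConfig(
            **{**sidecar["config"], "seed": sidecar["member_seeds"][i]}
        )
        net = DilatedCausalNet(member_cfg, n_channels=sidecar["n_channels"])
        with np.load(directory / f"fold{i}.npz") as data:
            net.set_params([data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))])
        members.append(net)
    return TrainedEnsemble(
        members=members,
        config=config,
        fold_assignments=sidecar["fold_assignments"],
        fold_f1=sidecar["fold_f1"],
    )


def select_model(cv_runs: list[tuple[NetworkConfig, float, int]]) -> NetworkConfig:
    """Pick the simplest configuration with the highest mean fold F1.

    ``cv_runs`` holds (config, mean F1, trainable parameter count) tuples.
    Within 1e-9 of the best F1, fewer parameters win; remaining ties keep
    listed order.
    """
    if not cv_runs:
        raise ValueError("cv_runs must be nonempty")
    best_f1 = max(f1 for _, f1, _ in cv_runs)
    candidates = [
        (i, cfg, n_par) for i, (cfg, f1, n_par) in enumerate(cv_runs)
        if f1 >= best_f1 - 1e-9
    ]
    candidates.sort(key=lambda t: (t[2], t[0]))
    return candidates[0][1]


def predict_ensemble(ensemble: TrainedEnsemble, x) -> np.ndarray | float:
    """Mean of the member probabilities for one or many normalized curve sets.

    Accepts a :class:`NormalizedCurveSet`, a (6, T) matrix, or an (N, 6, T)
    batch. Returns a scalar for single inputs, an array for batches.
    """
    single = False
    if isinstance(x, NormalizedCurveSet):
        X = x.matrix[None]
        single = True
    else:
        X = np.asarray(x, dtype=float)
        if X.ndim == 2:
            X = X[None]
            single = True
    n_channels = ensemble.members[0].n_channels
    if X.ndim != 3 or X.shape[1] != n_channels:
        raise ValueError(f"input must be (N, {n_channels}, T), got shape {X.shape}")
    probs = np.mean([m.predict_proba(X) for m in ensemble.members], axis=0)
    return float(probs[0]) if single else probs


def ensemble_probs_and_grads(
    ensemble: TrainedEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean probability and its input gradient (attribution target).

    F(x) = (1/5) sum_i sigmoid(logit_i(x)); the gradient follows by the
    chain rule through each member's sigmoid.
    """
    vals = None
    grads = None
    for m in ensemble.members:
        logits, g = m.input_gradients(X)
        p = _sigmoid(logits)
        g = (p * (1.0 - p))[:, None, None] * g
        vals = p if vals is None else vals + p
        grads = g if grads is None else grads + g
    n = len(ensemble.members)
    return vals / n, grads / n
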