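"""K-means phenotype clustering of normalized relevance maps.

Carriers with ensemble probability strictly above the detection threshold
(default 50%) are partitioned into k clusters (default 4) by Lloyd's
algorithm on the flattened 6 x T relevance maps, Euclidean distance,
k-means++ seeding and multiple restarts. Carriers at or below the
threshold form cluster "O" — variant carriers the classifier cannot
distinguish from controls.

Cluster letters A-D are assigned post hoc from morphology diagnostics of
each cluster's mean apical-septal strain curve (peak magnitude, peak
timing relative to AVC, presence of a second shortening peak), so the
lettering is stable across clustering seeds:

* D — smallest mean peak-strain magnitude (reduced peak strain);
* C — latest peak among the rest (post-systolic shortening);
* B — deeper late-diastolic shortening than the remaining cluster (the
  second peak depresses the mean curve at t ~ 0.6-0.78, the notch does not);
* A — the remainder (diastolic notch).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .attribution import RelevanceMap
from .records import NormalizedCurveSet, segment_index

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeAssignment:
    subject_id: str
    probability: float
    cluster: str                  # "O", "A".."D", or "K0".. for k != 4
    distance_to_center: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_to_center < 0:
            raise ValueError("distance must be >= 0")
        if (self.cluster == "O") != (self.probability <= 0.5):
            raise ValueError(
                f"{self.subject_id}: cluster O is exactly the carriers at or below "
                "the 50% threshold"
            )


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray                 # (k, 6, T)
    assignments: dict[str, int]         # subject_id -> cluster index
    inertia: float
    seed: int
    n_init: int
    inertia_history: list[float] = field(default_factory=list)
    letters: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")

    def sizes(self) -> dict[int, int]:
        out = {i: 0 for i in range(self.k)}
        for c in self.assignments.values():
            out[c] += 1
        return out


@dataclass
class MinSizeReport:
    passed: bool
    minimum: int
    sizes: dict[int, int]
    offending: list[int]


def select_detected(
    carriers: list[tuple[str, float]], threshold: float = 0.5
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Split carriers into detected (> threshold) and cluster-O (the rest)."""
    for sid, p in carriers:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{sid}: probability {p} outside [0, 1]")
    detected = [(s, p) for s, p in carriers if p > threshold]
    cluster_o = [(s, p) for s, p in carriers if p <= threshold]
    return detected, cluster_o


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[i] = X[rng.integers(n)]
        else:
            centers[i] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[i]) ** 2, axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd iterations; returns (labels, centers, inertia, inertia history).

    Inertia is non-increasing across iterations; empty clusters are
    re-seeded at the point farthest from its assigned center.
    """
    k = centers.shape[0]
    history: list[float] = []
    labels = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), new_labels].sum())
        if history and inertia > history[-1] + 1e-9:  # Lloyd never ascends
            raise AssertionError("inertia increased during Lloyd iteration")
        history.append(inertia)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for i in range(k):
            members = X[labels == i]
            if len(members) == 0:
                far = d2[np.arange(len(X)), labels].argmax()
                centers[i] = X[far]
                labels[far] = i
            else:
                centers[i] = members.mean(axis=0)
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    history.append(inertia)
    return labels, centers, inertia, history


def kmeans_cluster(
    maps: list[RelevanceMap], k: int = 4, seed: int = 0, n_init: int = 10
) -> ClusterModel:
    """Euclidean k-means on flattened relevance maps, best of n_init restarts."""
    if len(maps) < k:
        raise ValueError(f"need at least k={k} maps, got {len(maps)}")
    shape = maps[0].matrix.shape
    if any(m.matrix.shape != shape for m in maps):
        raise ValueError("all relevance maps must share one shape")
    X = np.stack([m.matrix.ravel() for m in maps])
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_init):
        centers0 = _kmeanspp_init(X, k, rng)
        labels, centers, inertia, hist = _lloyd(X, centers0.copy())
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, hist)
    labels, centers, inertia, hist = best
    return ClusterModel(
        k=k,
        centers=centers.reshape(k, *shape),
        assignments={m.subject_id: int(c) for m, c in zip(maps, labels)},
        inertia=inertia,
        seed=seed,
        n_init=n_init,
        inertia_history=hist,
    )


def check_min_cluster_size(model: ClusterModel, minimum: int = 30) -> MinSizeReport:
    """Advisory check that every cluster keeps at least `minimum` subjects."""
    sizes = model.sizes()
    offending = [c for c, n in sizes.items() if n < minimum]
    if offending:
        logger.warning("clusters below the minimum size %d: %s", minimum, offending)
    return MinSizeReport(
        passed=not offending, minimum=minimum, sizes=sizes, offending=offending
    )


def _curve_diagnostics(curve: np.ndarray, avc_index: int) -> dict[str, float]:
    """Morphology summary of one mean apical-septal strain curve.

    ``deficit_time`` locates post-AVC re-shortening: the time (fraction of
    the cycle) where the curve falls furthest below its running maximum
    during diastole. It is 0 when the recovery is monotone.
    """
    T = len(curve)
    peak_idx = int(curve.argmin())
    post = curve[avc_index:]
    deficit = np.maximum.accumulate(post) - post
    d_idx = int(deficit.argmax())
    d_mag = float(deficit.max())
    # late-diastolic shortening: mean curve value over t in [0.60, 0.78],
    # where a second shortening peak pulls the curve down while a
    # post-AVC notch (earlier, smaller) barely registers
    lo, hi = int(round(0.60 * (T - 1))), int(round(0.78 * (T - 1))) + 1
    return {
        "peak_mag": float(-curve.min()),
        "peak_frac": peak_idx / (T - 1),
        "deficit_time": (avc_index + d_idx) / (T - 1) if d_mag > 0.05 else 0.0,
        "deficit_mag": d_mag,
        "late_shortening": float(curve[lo:hi].mean()),
        "post_avc_peak": float(peak_idx > avc_index),
    }


def assign_letters(
    model: ClusterModel,
    curves: dict[str, NormalizedCurveSet],
    avc_index: int = 38,
) -> dict[int, str]:
    """Map the k=4 cluster indices to morphology letters A-D (stable rule).

    For other k the clusters keep numeric labels K0..K{k-1}.
    """
    if model.k != 4:
        return {i: f"K{i}" for i in range(model.k)}
    seg = segment_index("apical-septal")
    mean_curves = {}
    for c in range(model.k):
        members = [curves[s].matrix[seg] for s, ci in model.assignments.items() if ci == c]
        mean_curves[c] = np.mean(members, axis=0)
    diag = {c: _curve_diagnostics(mc, avc_index) for c, mc in mean_curves.items()}

    letters: dict[int, str] = {}
    remaining = list(range(4))
    # D: reduced peak strain (smallest magnitude)
    d = min(remaining, key=lambda c: diag[c]["peak_mag"])
    letters[d] = "D"
    remaining.remove(d)
    # C: post-systolic shortening (latest global peak)
    c_ = max(remaining, key=lambda c: diag[c]["peak_frac"])
    letters[c_] = "C"
    remaining.remove(c_)
    # B: double peak — the second shortening peak depresses the mean curve
    # in late diastole, where A's earlier, shallower notch barely registers
    b = min(remaining, key=lambda c: diag[c]["late_shortening"])
    letters[b] = "B"
    remaining.remove(b)
    letters[remaining[0]] = "A"
    model.letters = letters
    return letters


def smooth_center(center: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Per-row Savitzky-Golay smoothing of a 6 x T cluster-center heatmap."""
    center = np.asarray(center, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > center.shape[-1]:
        raise ValueError("window longer than the time axis")
    return savgol_filter(center, window_length=window, polyorder=polyorder, axis=-1)


@dataclass
class ClusterSummary:
    label: str
    n_subjects: int
    mean_curves: np.ndarray      # (6, T)
    sd_curves: np.ndarray        # (6, T)
    heatmap: np.ndarray          # (6, T) smoothed relevance center
    control_mean: np.ndarray     # (6, T)
    avc_index: int


def plot_cluster_summary(summary: "ClusterSummary", path=None):
    """Render one cluster's panel: mean +/- SD curves per segment over the
    smoothed relevance heatmap, control reference dotted, AVC marked.

    Returns the matplotlib Figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .records import SEGMENTS

    T = summary.mean_curves.shape[1]
    t = np.linspace(0.0, 1.0, T)
    fig, axes = plt.subplots(6, 1, figsize=(5, 11), sharex=True)
    for i, (ax, seg) in enumerate(zip(axes, SEGMENTS)):
        ax.imshow(
            summary.heatmap[i : i + 1],
            aspect="auto",
            extent=(0.0, 1.0, -32.0, 8.0),
            cmap="Reds",
            alpha=0.5,
            vmin=0,
        )
        mean, sd = summary.mean_curves[i], summary.sd_curves[i]
        ax.fill_between(t, mean - sd, mean + sd, color="grey", alpha=0.4)
        ax.plot(t, mean, color="black", lw=1.5)
        ax.plot(t, summary.control_mean[i], color="black", ls=":", lw=1.0)
        ax.axvline(summary.avc_index / (T - 1), color="green", ls="--", lw=0.8)
        ax.set_ylim(-32, 8)
        ax.set_ylabel(seg, fontsize=7)
    axes[-1].set_xlabel("normalized time (fraction of cycle)")
    fig.suptitle(f"Cluster {summary.label} (n={summary.n_subjects})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def cluster_summary(
    model: ClusterModel,
    curves: dict[str, NormalizedCurveSet],
    control_mean: np.ndarray,
    avc_index: int = 38,
    window: int = 11,
    polyorder: int = 3,
) -> dict[str, ClusterSummary]:
    """Per-cluster mean/SD strain curves plus the smoothed relevance heatmap.

    The control reference (dotted curve in the figures) is the pointwise
    mean control curve per segment.
    """
    missing = [s for s in model.assignments if s not in curves]
    if missing:
        raise ValueError(f"missing curves for assigned subjects: {missing[:5]}")
    control_mean = np.asarray(control_mean, dtype=float)
    letters = model.letters or assign_letters(model, curves, avc_index)
    out: dict[str, ClusterSummary] = {}
    for c in range(model.k):
        stack = np.stack(
            [curves[s].matrix for s, ci in model.assignments.items() if ci == c]
        )
        if len(stack) == 1:
            warnings.warn(f"cluster {letters[c]} has a single subject; SD band is zero")
            sd = np.zeros_like(stack[0])
        else:
            sd = stack.std(axis=0, ddof=0)
        out[letters[c]] = ClusterSummary(
            label=letters[c],
            n_subjects=len(stack),
            mean_curves=stack.mean(axis=0),
            sd_curves=sd,
            heatmap=smooth_center(model.centers[c], window, polyorder),
            control_mean=control_mean,
            avc_index=avc_index,
        )
    return out
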