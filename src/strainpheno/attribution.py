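"""Relevance maps: Integrated Gradients combined with SmoothGrad-Squared.

Integrated Gradients attributes the classifier score F to each input sample
by integrating the gradient along the straight path from a baseline x' to
the input x (right-Riemann approximation with m steps):

    IG_i(x) = (x_i - x'_i) * (1/m) * sum_{k=1..m} dF(x' + (k/m)(x - x'))/dx_i

As m grows the completeness identity sum_i IG_i = F(x) - F(x') holds.
SmoothGrad-Squared then averages *squared* IG maps over n noisy copies of
the input (elementwise Gaussian noise, SD sigma), yielding a non-negative,
de-noised relevance map:

    SG2_i(x) = (1/n) * sum_{j=1..n} IG_i(x + eps_j)^2 .

F is the pre-threshold carrier probability — sigmoid(logit) for a single
network, the mean of the member probabilities for an ensemble. Working on
the probability scale keeps the completeness residual of the m-step Riemann
sum within a fixed absolute budget regardless of how confident (large-logit)
a trained network is; the residual of the right-rectangle rule scales with
the score range, which is 1 here. The default baseline is the all-zero
curve set — zero strain, i.e. no deformation at all, a physiologically
meaningful null; the mean control curve set is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import TrainedEnsemble, ensemble_probs_and_grads
from .records import NormalizedCurveSet
from .tcn import DilatedCausalNet, _sigmoid


@dataclass
class RelevanceMap:
    """Non-negative 6 x T attribution matrix for one subject."""

    subject_id: str
    matrix: np.ndarray
    baseline_kind: str = "zero"   # "zero" | "mean-control"
    ig_steps: int = 64
    sg_samples: int = 25
    sg_sigma: float = 0.0
    normalized: bool = False
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite relevance values")
        if self.matrix.min() < 0:
            raise ValueError("relevance values must be non-negative (squared attributions)")


class Scorer:
    """A differentiable scalar score F over 6 x T inputs.

    Implementations provide ``values_and_grads(X)`` mapping an (N, C, T)
    batch to the N score values and their input gradients.
    """

    def values_and_grads(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def value(self, x: np.ndarray) -> float:
        v, _ = self.values_and_grads(np.asarray(x, dtype=float)[None])
        return float(v[0])


class LinearScorer(Scorer):
    """F(x) = <w, x> + b; IG has a closed form for this scorer."""

    def __init__(self, weights: np.ndarray, bias: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)
        self.bias = float(bias)

    def values_and_grads(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = np.einsum("nct,ct->n", X, self.weights) + self.bias
        grads = np.broadcast_to(self.weights, X.shape).copy()
        return vals, grads


class NetworkScorer(Scorer):
    """Carrier probability of a single trained network."""

    def __init__(self, net: DilatedCausalNet):
        self.net = net

    def values_and_grads(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits, g = self.net.input_gradients(X)
        p = _sigmoid(logits)
        return p, (p * (1.0 - p))[:, None, None] * g


class EnsembleScorer(Scorer):
    """Ensemble-mean carrier probability of a trained ensemble."""

    def __init__(self, ensemble: TrainedEnsemble):
        self.ensemble = ensemble

    def values_and_grads(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return ensemble_probs_and_grads(self.ensemble, X)


def _as_matrix(x) -> tuple[np.ndarray, str]:
    if isinstance(x, NormalizedCurveSet):
        return x.matrix, x.subject_id
    return np.asarray(x, dtype=float), ""


def integrated_gradients(
    scorer: Scorer, x, baseline, m: int = 64, batch_size: int = 512
) -> np.ndarray:
    """Signed IG attribution matrix (same shape as x).

    Right-Riemann approximation of the path integral with m steps; exact for
    any m >= 1 when the scorer is linear.
    """
    X, _ = _as_matrix(x)
    B, _ = _as_matrix(baseline)
    if X.shape != B.shape:
        raise ValueError(f"input shape {X.shape} != baseline shape {B.shape}")
    if m < 1:
        raise ValueError("m must be >= 1")
    diff = X - B
    alphas = np.arange(1, m + 1) / m
    grad_sum = np.zeros_like(X)
    for start in range(0, m, batch_size):
        chunk = alphas[start : start + batch_size]
        points = B[None] + chunk[:, None, None] * diff[None]
        _, grads = scorer.values_and_grads(points)
        grad_sum += grads.sum(axis=0)
    return diff * grad_sum / m


def smoothgrad_squared(
    scorer: Scorer,
    x,
    baseline,
    m: int = 64,
    n: int = 25,
    sigma: float | None = None,
    seed: int = 0,
    subject_id: str | None = None,
    baseline_kind: str = "zero",
    batch_size: int = 512,
) -> RelevanceMap:
    """SmoothGrad-Squared relevance map: mean of squared IG over noisy inputs.

    sigma defaults to 0.15 x (input max - input min). With sigma = 0 and
    n = 1 the map degenerates to the elementwise square of plain IG. The
    noise is drawn from a seeded generator, so identical arguments give
    bit-identical maps.
    """
    X, sid = _as_matrix(x)
    B, _ = _as_matrix(baseline)
    if X.shape != B.shape:
        raise ValueError(f"input shape {X.shape} != baseline shape {B.shape}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma is None:
        sigma = 0.15 * float(X.max() - X.min())
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)

    diff_shape = X.shape
    alphas = np.arange(1, m + 1) / m
    acc = np.zeros(diff_shape)
    for j in range(n):
        eps = rng.normal(0.0, sigma, size=diff_shape) if sigma > 0 else 0.0
        Xj = X + eps
        diff = Xj - B
        grad_sum = np.zeros(diff_shape)
        for start in range(0, m, batch_size):
            chunk = alphas[start : start + batch_size]
            points = B[None] + chunk[:, None, None] * diff[None]
            _, grads = scorer.values_and_grads(points)
            grad_sum += grads.sum(axis=0)
        acc += (diff * grad_sum / m) ** 2
    return RelevanceMap(
        subject_id=subject_id if subject_id is not None else sid,
        matrix=acc / n,
        baseline_kind=baseline_kind,
        ig_steps=m,
        sg_samples=n,
        sg_sigma=float(sigma),
    )


def normalize_relevance(rmap: RelevanceMap) -> RelevanceMap:
    """Per-subject max-normalization: divide the map by its maximum value.

    An all-zero map stays all-zero and is flagged, never divided by zero.
    """
    peak = float(rmap.matrix.max())
    if peak == 0.0:
        return RelevanceMap(
            subject_id=rmap.subject_id,
            matrix=rmap.matrix.copy(),
            baseline_kind=rmap.baseline_kind,
            ig_steps=rmap.ig_steps,
            sg_samples=rmap.sg_samples,
            sg_sigma=rmap.sg_sigma,
            normalized=True,
            all_zero=True,
        )
    return RelevanceMap(
        subject_id=rmap.subject_id,
        matrix=rmap.matrix / peak,
        baseline_kind=rmap.baseline_kind,
        ig_steps=rmap.ig_steps,
        sg_samples=rmap.sg_samples,
        sg_sigma=rmap.sg_sigma,
        normalized=True,
        all_zero=False,
    )
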