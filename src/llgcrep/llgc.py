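"""Semi-supervised label spreading with local and global consistency (LLGC).

Drug–disease pairs are nodes of a weighted graph; known associated pairs
carry the positive label and labels spread along edges until a fixed point
that balances smoothness on the graph against fidelity to the initial
labels.  With the symmetrically normalized operator S = D^(-1/2) W D^(-1/2)
the iteration

    F(t+1) = α·S·F(t) + (1−α)·Y,   0 < α < 1

converges to F* = (1−α)(I − αS)^(-1) Y, which also minimizes the energy

    Q(F) = ½ [ Σ_{i<j} W_ij ‖F_i/√D_ii − F_j/√D_jj‖²
               + ((1−α)/α) Σ_i ‖F_i − Y_i‖² ].

The edge weights use a modified Gaussian kernel: pairwise Euclidean
distances between feature vectors are first passed through the power
transform T(d) = σ₀ (d/σ₀)^γ, which leaves d = σ₀ fixed, shrinks shorter
distances and stretches longer ones (γ > 1), sharpening the local
neighborhood structure around the reference scale σ₀.  σ₀ itself is read
off the pairwise-distance histogram as the midpoint of the sparse band —
a low-count gap between the two dominant modes that the manifold
assumption treats as the class boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import solve as _solve
from scipy.spatial.distance import pdist, squareform

from .core import ConfigurationError, DimensionError, ValidationError
from .relevance import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LLGCConfig",
    "LabelState",
    "transform_distance",
    "weight_matrix",
    "normalize_operator",
    "initial_labels",
    "llgc_iterate",
    "llgc_closed_form",
    "energy",
    "assign_labels",
    "suggest_sigma0",
]


@dataclass
class LLGCConfig:
    """Knobs of the label spreader.

    alpha: spreading coefficient in (0, 1); close to 1 favors propagation
        over clamping to the initial labels (default 0.99 — few labels are
        known, so label transfer is maximized).
    sigma0: reference distance of the power transform; ``None`` selects it
        from the sparse band of the pairwise-distance histogram.
    gamma: transform exponent ≥ 1 (default 2); 1 disables the transform.
    sigma: Gaussian kernel scale; ``None`` uses sigma0.
    tol / max_iter: stopping rule of the iterative solver.
    """

    alpha: float = 0.99
    sigma0: float | None = None
    gamma: float = 2.0
    sigma: float | None = None
    tol: float = 1e-9
    max_iter: int = 1000
    negatives: str = "all-unknown"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.gamma < 1.0:
            raise ValidationError(f"gamma={self.gamma} must be >= 1")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ValidationError("sigma0 must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.negatives not in ("all-unknown", "none"):
            raise ValidationError(f"unknown negatives mode {self.negatives!r}")


@dataclass
class LabelState:
    """Initial labels Y and current scores F of the spreader (n_pairs × 2).

    Column 0 is the associated class, column 1 the non-associated class;
    the ranking score of a pair is F[:, 0] − F[:, 1].
    """

    pairs: list[tuple[str, str]]
    Y: np.ndarray
    F: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.pairs), 2):
            raise DimensionError("Y must be (n_pairs, 2)")
        rows = {tuple(r) for r in self.Y}
        if not rows <= {(1.0, 0.0), (0.0, 1.0), (0.0, 0.0)}:
            raise ValidationError("Y rows must be one of (1,0), (0,1), (0,0)")

    @property
    def score(self) -> np.ndarray:
        if self.F is None:
            raise ValidationError("no scores yet: run the spreader first")
        return self.F[:, 0] - self.F[:, 1]


def transform_distance(d, sigma0: float, gamma: float = 2.0):
    """Power transform T(d) = σ₀ (d/σ₀)^γ of a nonnegative distance.

    T(σ₀) = σ₀ for every γ; for γ > 1 distances below σ₀ shrink and those
    above stretch, amplifying the locality of the kernel.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be nonnegative")
    if sigma0 <= 0:
        raise ValidationError("sigma0 must be positive")
    if gamma < 1.0:
        raise ValidationError("gamma must be >= 1")
    out = sigma0 * (d / sigma0) ** gamma
    return out if out.ndim else float(out)


def _resolve_scales(dist: np.ndarray, cfg: LLGCConfig) -> tuple[LLGCConfig, float, float]:
    sigma0 = cfg.sigma0
    if sigma0 is None:
        iu = np.triu_indices(dist.shape[0], k=1)
        *_, sigma0 = suggest_sigma0(dist[iu])
    sigma = cfg.sigma if cfg.sigma is not None else sigma0
    return replace(cfg, sigma0=sigma0, sigma=sigma), sigma0, sigma


def weight_matrix(features: FeatureMatrix | np.ndarray, cfg: LLGCConfig | None = None) -> np.ndarray:
    """Symmetric zero-diagonal weights from pairwise feature distances.

    W_ij = exp(−T(d_ij)² / (2σ²)) with d_ij the Euclidean distance between
    feature rows i and j and T the power transform above.
    """
    cfg = cfg or LLGCConfig()
    X = features.features if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.shape[0] < 2:
        raise ValidationError("weight_matrix needs at least two feature rows")
    dist = squareform(pdist(X, metric="euclidean"))
    cfg, sigma0, sigma = _resolve_scales(dist, cfg)
    T = transform_distance(dist, sigma0, cfg.gamma)
    W = np.exp(-(T**2) / (2.0 * sigma**2))
    np.fill_diagonal(W, 0.0)
    return W


def normalize_operator(W: np.ndarray) -> np.ndarray:
    """Symmetric normalization S = D^(−1/2) W D^(−1/2); spectral radius ≤ 1.

    Isolated nodes (all-zero rows) keep a zero row/column of S, with a
    warning: no label mass can reach them.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise DimensionError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValidationError("W must be symmetric")
    if np.any(W < 0):
        raise ValidationError("W must be nonnegative")
    d = W.sum(axis=1)
    isolated = d == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s): zero rows in S", stacklevel=2
        )
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, d)))
    return W * np.outer(inv_sqrt, inv_sqrt)


def initial_labels(
    pairs: Sequence[tuple[str, str]],
    known_associations: Sequence[tuple[str, str]],
    negatives: str = "all-unknown",
) -> LabelState:
    """Build Y: known pairs (1, 0); the rest (0, 1) or, in mode "none", (0, 0)."""
    if negatives not in ("all-unknown", "none"):
        raise ValidationError(f"unknown negatives mode {negatives!r}")
    pairs = list(pairs)
    index = {p: i for i, p in enumerate(pairs)}
    known = list(known_associations)
    if not known:
        raise ValidationError("no known associations: nothing to spread")
    Y = np.zeros((len(pairs), 2))
    if negatives == "all-unknown":
        Y[:, 1] = 1.0
    for p in known:
        if p not in index:
            raise ValidationError(f"known association {p!r} not among the pairs")
        Y[index[p]] = (1.0, 0.0)
    return LabelState(pairs=pairs, Y=Y)


def llgc_iterate(
    S: np.ndarray, Y: np.ndarray, cfg: LLGCConfig | None = None
) -> tuple[np.ndarray, int]:
    """Iterate F(t+1) = α·S·F(t) + (1−α)·Y from F(0) = Y until convergence.

    Returns the final iterate and the number of iterations taken; warns if
    ``max_iter`` is hit before the max-abs change drops below ``tol``.
    """
    cfg = cfg or LLGCConfig()
    Y = np.asarray(Y, dtype=float)
    F = Y.copy()
    a = cfg.alpha
    for it in range(1, cfg.max_iter + 1):
        F_next = a * (S @ F) + (1.0 - a) * Y
        delta = np.abs(F_next - F).max()
        F = F_next
        if delta < cfg.tol:
            return F, it
    warnings.warn(
        f"label spreading did not converge in {cfg.max_iter} iterations "
        f"(last change {delta:.3g})",
        stacklevel=2,
    )
    return F, cfg.max_iter


def llgc_closed_form(
    S: np.ndarray, Y: np.ndarray, cfg: LLGCConfig | None = None
) -> np.ndarray:
    """Closed-form solution F = (I − αS)^(−1) Y (constant factor dropped).

    Proportional to the iterative limit (1−α)(I − αS)^(−1) Y, hence rank-
    identical; solved as a linear system, never by explicit inversion.
    """
    cfg = cfg or LLGCConfig()
    S = np.asarray(S, dtype=float)
    A = np.eye(S.shape[0]) - cfg.alpha * S
    try:
        F = _solve(A, np.asarray(Y, dtype=float), assume_a="sym")
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            f"singular system I − αS (condition number ≈ {np.linalg.cond(A):.3g})"
        ) from exc
    logger.debug("closed-form solve, cond(I - alpha*S) ~ %.3g", np.linalg.cond(A))
    return F


def energy(
    F: np.ndarray, W: np.ndarray, Y: np.ndarray, cfg: LLGCConfig | None = None
) -> float:
    """LLGC energy Q(F): graph smoothness plus label-fit penalty.

    Q(F) = ½[Σ_{i<j} W_ij ‖F_i/√D_ii − F_j/√D_jj‖² + ((1−α)/α)Σ‖F_i−Y_i‖²];
    the pair sum counts each edge once and zero-degree nodes contribute no
    smoothness term.  The iterative limit is the unique minimizer.
    """
    cfg = cfg or LLGCConfig()
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    Y = np.asarray(Y, dtype=float)
    d = W.sum(axis=1)
    live = d > 0
    G = np.zeros_like(F)
    G[live] = F[live] / np.sqrt(d[live])[:, None]
    # sum_{i<j} W_ij ||G_i - G_j||^2 = sum_i d_i ||G_i||^2 - tr(G^T W G)
    smooth = float((d[:, None] * G**2).sum() - (G * (W @ G)).sum())
    mu = (1.0 - cfg.alpha) / cfg.alpha
    fit = float(((F - Y) ** 2).sum())
    return 0.5 * (smooth + mu * fit)


def assign_labels(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label each pair associated iff F[:,0] > F[:,1]; ties are negative.

    Returns ``(labels, scores)`` where labels is a boolean array (True =
    associated) and scores = F[:,0] − F[:,1] ranks the pairs.
    """
    F = np.asarray(F, dtype=float)
    if not np.isfinite(F).all():
        raise ValidationError("scores must be finite")
    scores = F[:, 0] - F[:, 1]
    return scores > 0, scores


def suggest_sigma0(
    distances: np.ndarray, bins: int = 50
) -> tuple[float, float, float]:
    """Locate the sparse band of a pairwise-distance histogram.

    The histogram (``bins`` equal-width bins) is scanned strictly between
    its two highest local maxima for the longest run of consecutive bins
    whose counts fall below 20% of the median occupied-bin count; the band is that
    run's extent and σ₀ its midpoint.  Without two peaks or without such a
    run, falls back to the median distance with a warning.

    Returns ``(band_low, band_high, sigma0)``; on fallback the band is
    degenerate at the median.
    """
    distances = np.asarray(distances, dtype=float).ravel()
    if distances.size < 100:
        raise ValidationError("suggest_sigma0 needs at least 100 distances")
    counts, edges = np.histogram(distances, bins=bins)

    def _fallback(reason: str) -> tuple[float, float, float]:
        med = float(np.median(distances))
        warnings.warn(f"no sparse band found ({reason}); using median distance", stacklevel=3)
        return med, med, med

    # local maxima (plateau-tolerant: >= neighbors, > at least one side)
    peaks = [
        i
        for i in range(len(counts))
        if counts[i] > 0
        and (i == 0 or counts[i] >= counts[i - 1])
        and (i == len(counts) - 1 or counts[i] >= counts[i + 1])
        and not (
            (0 < i < len(counts) - 1)
            and counts[i] == counts[i - 1] == counts[i + 1]
        )
    ]
    if len(peaks) < 2:
        return _fallback("fewer than two histogram peaks")
    top_two = sorted(sorted(peaks, key=lambda i: counts[i], reverse=True)[:2])
    lo_peak, hi_peak = top_two
    if hi_peak - lo_peak < 2:
        return _fallback("peaks are adjacent")
    # median over occupied bins: an empty gap must not zero the threshold
    threshold = 0.2 * float(np.median(counts[counts > 0]))
    best: tuple[int, int] | None = None
    run_start: int | None = None
    for i in range(lo_peak + 1, hi_peak):
        if counts[i] < threshold:
            if run_start is None:
                run_start = i
            if best is None or (i - run_start) > (best[1] - best[0]):
                best = (run_start, i)
        else:
            run_start = None
    if best is None:
        return _fallback("no bins below threshold between the peaks")
    lo, hi = float(edges[best[0]]), float(edges[best[1] + 1])
    return lo, hi, (lo + hi) / 2.0
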