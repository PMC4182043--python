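"""Cross-validated ranking evaluation with self-contained AUC and AUPR.

Known associations are split into k folds; each fold in turn is masked out
of the association matrix and the whole pipeline — topology similarities,
relevance vectors, feature kernel, label spreading — is rebuilt from the
training network only, so nothing about the held-out positives leaks into
the scores.  The test pool is the held-out positives plus the
never-associated pairs; AUC and AUPR of the score ranking are averaged
over all folds and repeats.

Both metrics are computed from first principles: AUC as the Mann–Whitney
probability P(score⁺ > score⁻) + ½P(tie), AUPR as the area Σ ΔR·P of the
precision–recall step curve swept in descending score order with tied
scores grouped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SimilarityMatrix, TripartiteNetwork, ValidationError
from .llgc import LLGCConfig
from .pipeline import score_pairs
from .similarity import SimilarityFusionConfig

__all__ = ["CVConfig", "kfold_split", "auc", "aupr", "cross_validate"]


@dataclass
class CVConfig:
    """k-fold repetition protocol; ``max_unknown`` subsamples the negative
    pool per fold (None = use every never-associated pair)."""

    k: int = 10
    repeats: int = 10
    seed: int = 0
    max_unknown: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


def kfold_split(known_pairs, k: int, seed: int = 0) -> list[list]:
    """Random partition into k folds with sizes differing by at most one."""
    known_pairs = list(known_pairs)
    if len(known_pairs) < k:
        raise ValidationError(f"need at least k={k} pairs, have {len(known_pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(known_pairs))
    return [[known_pairs[i] for i in order[f::k]] for f in range(k)]


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) + ½·P(score⁺ = score⁻)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("auc needs both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def aupr(scores, labels) -> float:
    """Area under the precision–recall step curve, ties grouped.

    Sweeping thresholds down the distinct score values, the area is
    Σ (R_t − R_{t−1})·P_t; a random ranking concentrates near the positive
    prevalence, a perfect one reaches 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("aupr needs at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # group tied scores: cumulative counts at the last index of each group
    boundary = np.nonzero(np.diff(s))[0]
    cut = np.append(boundary, len(s) - 1)
    tp = np.cumsum(y)[cut].astype(float)
    n_pred = (cut + 1).astype(float)
    precision = tp / n_pred
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def cross_validate(
    net: TripartiteNetwork,
    drug_bio: SimilarityMatrix,
    disease_bio: SimilarityMatrix,
    cfg: CVConfig | None = None,
    llgc_cfg: LLGCConfig | None = None,
    fusion_cfg: SimilarityFusionConfig | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Repeated k-fold CV of the full pipeline on one network.

    Per fold the held-out positives are removed from the association matrix
    before anything is computed, then scored alongside the never-associated
    pairs (optionally subsampled via ``cfg.max_unknown``).  Returns a
    summary dict (mean/sd of AUC and AUPR, prevalence) and the per-fold
    table.
    """
    cfg = cfg or CVConfig()
    llgc_cfg = llgc_cfg or LLGCConfig()
    fusion_cfg = fusion_cfg or SimilarityFusionConfig()
    known = net.known_pairs()
    unknown = [p for p in net.all_pairs() if p not in set(known)]
    rows = []
    rng = np.random.default_rng(cfg.seed)
    for rep in range(cfg.repeats):
        folds = kfold_split(known, cfg.k, seed=int(rng.integers(2**31)))
        for fold_idx, test_pos in enumerate(folds):
            if not test_pos:
                warnings.warn(f"fold {fold_idx} has no test positives; skipped", stacklevel=2)
                continue
            train_net = net.masked(test_pos)
            pool_neg = unknown
            if cfg.max_unknown is not None and len(unknown) > cfg.max_unknown:
                idx = rng.choice(len(unknown), size=cfg.max_unknown, replace=False)
                pool_neg = [unknown[i] for i in idx]
            train_pos = [p for p in known if p not in set(test_pos)]
            pool = train_pos + test_pos + pool_neg
            result = score_pairs(
                train_net, drug_bio, disease_bio, fusion_cfg, llgc_cfg, pairs=pool
            )
            pred = result.predictions.set_index(["drug_id", "disease_id"])["score"]
            test_pool = test_pos + pool_neg
            scores = np.array([pred.loc[p] for p in test_pool])
            labels = np.array([1] * len(test_pos) + [0] * len(pool_neg))
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold_idx,
                    "n_test_pos": len(test_pos),
                    "n_test_neg": len(pool_neg),
                    "auc": auc(scores, labels),
                    "aupr": aupr(scores, labels),
                }
            )
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise ValidationError("no evaluable folds")
    prevalence = per_fold["n_test_pos"].sum() / (
        per_fold["n_test_pos"].sum() + per_fold["n_test_neg"].sum()
    )
    summary = {
        "auc_mean": float(per_fold["auc"].mean()),
        "auc_sd": float(per_fold["auc"].std(ddof=0)),
        "aupr_mean": float(per_fold["aupr"].mean()),
        "aupr_sd": float(per_fold["aupr"].std(ddof=0)),
        "prevalence": float(prevalence),
        "n_folds": int(len(per_fold)),
    }
    return summary, per_fold
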