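"""End-to-end scoring pipeline: similarities → relevance → features → LLGC.

One call takes a tripartite network plus biological similarity matrices and
produces a ranked table of drug–disease pair scores.  The stages are the
public module functions; this file only wires them together and keeps the
intermediate arrays consistent (identifier order, pair order, bandwidths).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ConfigurationError,
    SimilarityMatrix,
    TripartiteNetwork,
    ValidationError,
    read_similarity_matrix,
)
from .llgc import (
    LLGCConfig,
    assign_labels,
    initial_labels,
    llgc_closed_form,
    normalize_operator,
    weight_matrix,
)
from .relevance import feature_matrix, gip_bandwidth, relevance_matrix
from .similarity import SimilarityFusionConfig, integrated_similarities

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "score_pairs", "run_pipeline", "run_configured"]


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration, loadable from one YAML/JSON file.

    ``data_dir`` must contain the edge lists and node rosters written by
    :meth:`TripartiteNetwork.write` plus ``drug_similarity.tsv`` and
    ``disease_similarity.tsv``.  The one global ``seed`` feeds every
    stochastic stage.
    """

    data_dir: str
    out_dir: str
    fusion: "SimilarityFusionConfig" = field(default_factory=lambda: SimilarityFusionConfig())
    llgc: LLGCConfig = field(default_factory=LLGCConfig)
    run_topology: bool = True
    run_robustness: bool = False
    run_evaluation: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, typ in (("fusion", SimilarityFusionConfig), ("llgc", LLGCConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Ranked predictions plus the intermediates worth keeping."""

    predictions: pd.DataFrame
    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    bandwidth: float
    llgc_cfg: LLGCConfig = field(repr=False)


def score_pairs(
    net: TripartiteNetwork,
    drug_bio: SimilarityMatrix,
    disease_bio: SimilarityMatrix,
    fusion_cfg: SimilarityFusionConfig | None = None,
    llgc_cfg: LLGCConfig | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> PipelineResult:
    """Score drug–disease pairs by spreading the known-association labels.

    ``pairs`` restricts the label-spreading graph (default: every drug ×
    disease combination); known associated pairs present in ``pairs`` carry
    the positive initial label.  Scores rank candidates; the binary call is
    F[:,0] > F[:,1].
    """
    fusion_cfg = fusion_cfg or SimilarityFusionConfig()
    llgc_cfg = llgc_cfg or LLGCConfig()
    drug_sim, disease_sim = integrated_similarities(net, drug_bio, disease_bio, fusion_cfg)

    known = net.known_pairs()
    if not known:
        raise ValidationError("network has no known associations to spread")
    if pairs is None:
        pairs = net.all_pairs()
    pairs = list(pairs)
    known_in_pool = [p for p in known if p in set(pairs)]

    V_all = relevance_matrix(net, drug_sim, disease_sim, pairs)
    V_known = relevance_matrix(net, drug_sim, disease_sim, known)
    r = gip_bandwidth(V_known)
    feats = feature_matrix(V_all, V_known, r, pairs=pairs)

    W = weight_matrix(feats, llgc_cfg)
    S = normalize_operator(W)
    state = initial_labels(pairs, known_in_pool, negatives=llgc_cfg.negatives)
    F = llgc_closed_form(S, state.Y, llgc_cfg)
    labels, scores = assign_labels(F)

    known_set = set(known)
    df = pd.DataFrame(
        {
            "drug_id": [d for d, _ in pairs],
            "disease_id": [s for _, s in pairs],
            "score": scores,
            "label": np.where(labels, "associated", "not-associated"),
            "known": [p in known_set for p in pairs],
        }
    )
    df = df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return PipelineResult(
        predictions=df,
        drug_sim=drug_sim,
        disease_sim=disease_sim,
        bandwidth=r,
        llgc_cfg=llgc_cfg,
    )


def run_pipeline(
    net: TripartiteNetwork,
    drug_bio: SimilarityMatrix,
    disease_bio: SimilarityMatrix,
    out_dir: str | Path,
    fusion_cfg: SimilarityFusionConfig | None = None,
    llgc_cfg: LLGCConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full pipeline and persist predictions plus a manifest.

    The manifest records a hash of the configuration and the seed so a
    rerun with the same inputs is verifiably identical.
    """
    fusion_cfg = fusion_cfg or SimilarityFusionConfig()
    llgc_cfg = llgc_cfg or LLGCConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = score_pairs(net, drug_bio, disease_bio, fusion_cfg, llgc_cfg)
    pred_path = out_dir / "predictions.tsv"
    result.predictions.to_csv(pred_path, sep="\t", index=False, float_format="%.10g")
    cfg_blob = json.dumps(
        {"fusion": asdict(fusion_cfg), "llgc": asdict(llgc_cfg), "seed": seed},
        sort_keys=True,
    )
    manifest = {
        "config_hash": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "seed": seed,
        "n_pairs": int(len(result.predictions)),
        "n_known": int(result.predictions["known"].sum()),
        "bandwidth_r": result.bandwidth,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline wrote %s", pred_path)
    return result


def run_configured(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full configured pipeline from the input directory.

    Always writes ranked predictions and the manifest; a topology report and
    robustness/evaluation reports are added when the corresponding flags are
    set.  Referenced input files must exist (errors name the missing path).
    """
    from .core import GraphLevel, build_integrated_graph
    from .topology import topology_report

    data_dir = Path(cfg.data_dir)
    for name in ("drug_similarity.tsv", "disease_similarity.tsv"):
        if not (data_dir / name).exists():
            raise ConfigurationError(f"missing input file: {data_dir / name}")
    net = TripartiteNetwork.read(data_dir)
    drug_bio = read_similarity_matrix(data_dir / "drug_similarity.tsv")
    disease_bio = read_similarity_matrix(data_dir / "disease_similarity.tsv")
    out = Path(cfg.out_dir)
    result = run_pipeline(
        net, drug_bio, disease_bio, out, fusion_cfg=cfg.fusion, llgc_cfg=cfg.llgc,
        seed=cfg.seed,
    )
    if cfg.run_topology:
        rows = {}
        for level in GraphLevel:
            g = build_integrated_graph(net, level, drug_bio, tau=cfg.fusion.tau)
            rows[level.value] = topology_report(g).to_series()
        pd.DataFrame(rows).T.rename_axis("level").to_csv(
            out / "topology.tsv", sep="\t", float_format="%.6g"
        )
    if cfg.run_robustness:
        from .robustness import RemovalExperiment, run_experiment

        g4 = build_integrated_graph(net, GraphLevel.M4, drug_bio, tau=cfg.fusion.tau)
        for mode in ("random", "targeted"):
            df = run_experiment(g4, RemovalExperiment(mode=mode, seed=cfg.seed))
            df.to_csv(out / f"robustness_{mode}.tsv", sep="\t", index=False)
    if cfg.run_evaluation:
        from .evaluation import CVConfig, cross_validate

        summary, per_fold = cross_validate(
            net, drug_bio, disease_bio, CVConfig(seed=cfg.seed),
            llgc_cfg=cfg.llgc, fusion_cfg=cfg.fusion,
        )
        pd.Series(summary).rename("value").rename_axis("statistic").to_csv(
            out / "cv_summary.tsv", sep="\t"
        )
        per_fold.to_csv(out / "cv_folds.tsv", sep="\t", index=False)
    return result
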