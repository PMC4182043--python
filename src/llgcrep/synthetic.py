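"""Synthetic tripartite networks with planted module structure.

Real drug–disease–target data of the kind the method targets is organized
around therapeutic areas: drugs of one class treat related diseases and hit
related targets, and similarity matrices (chemical, phenotypic) are elevated
within such a class.  The generator emulates exactly that: drugs, diseases
and targets are assigned to ``n_modules`` blocks round-robin; associations
and interactions are Bernoulli draws with a higher rate inside a block
(``p_in``) than across (``p_out``); similarity matrices are a same-block
signal plus Gaussian noise, clipped to [0, 1].

The planted blocks make recovery measurable: a useful pipeline should rank
masked within-block associations above cross-block noise.  A "published-shape"
preset reproduces the published dataset's dimensions exactly (203 drugs,
52 diseases, 192 targets, 609 associations, 668 drug–target interactions)
by sampling cell sets of fixed size, weighted toward within-block cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SimilarityMatrix, TripartiteNetwork, ValidationError

__all__ = ["SyntheticSpec", "generate", "generate_published_shape"]


@dataclass
class SyntheticSpec:
    """Study conditions of the generator (defaults are the test-bed network)."""

    n_drugs: int = 30
    n_diseases: int = 15
    n_targets: int = 20
    n_modules: int = 3
    p_in: float = 0.5
    p_out: float = 0.02
    p_dt_in: float = 0.3
    p_dt_out: float = 0.02
    sim_signal: float = 0.6
    sim_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "p_dt_in", "p_dt_out", "sim_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.sim_noise < 0:
            raise ValidationError("sim_noise must be nonnegative")
        for name in ("n_drugs", "n_diseases", "n_targets", "n_modules"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


def _modules(n: int, n_modules: int) -> np.ndarray:
    return np.arange(n) % n_modules


def _block_bernoulli(
    rng: np.random.Generator,
    mod_rows: np.ndarray,
    mod_cols: np.ndarray,
    p_in: float,
    p_out: float,
) -> np.ndarray:
    same = mod_rows[:, None] == mod_cols[None, :]
    p = np.where(same, p_in, p_out)
    return (rng.random(p.shape) < p).astype(np.int8)


def _block_similarity(
    rng: np.random.Generator, mods: np.ndarray, signal: float, noise: float
) -> np.ndarray:
    n = mods.size
    same = (mods[:, None] == mods[None, :]).astype(float)
    eps = rng.normal(0.0, noise, size=(n, n)) if noise > 0 else np.zeros((n, n))
    eps = (eps + eps.T) / 2.0
    v = np.clip(signal * same + eps, 0.0, 1.0)
    np.fill_diagonal(v, 1.0)
    return v


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def generate(
    spec: SyntheticSpec | None = None,
) -> tuple[TripartiteNetwork, SimilarityMatrix, SimilarityMatrix, dict[str, np.ndarray]]:
    """Draw one network plus similarity matrices; deterministic given the seed.

    Returns ``(network, drug_sim, disease_sim, truth)`` where ``truth`` maps
    node kind to the planted module assignment.  If the association matrix
    comes out empty it is redrawn once; a second empty draw is an error.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    drug_mod = _modules(spec.n_drugs, spec.n_modules)
    disease_mod = _modules(spec.n_diseases, spec.n_modules)
    target_mod = _modules(spec.n_targets, spec.n_modules)

    A_ds = _block_bernoulli(rng, drug_mod, disease_mod, spec.p_in, spec.p_out)
    if not A_ds.any():
        A_ds = _block_bernoulli(rng, drug_mod, disease_mod, spec.p_in, spec.p_out)
    if not A_ds.any():
        raise ValidationError("generated an empty association matrix twice; raise p_in/p_out")
    A_dt = _block_bernoulli(rng, drug_mod, target_mod, spec.p_dt_in, spec.p_dt_out)
    A_tt = _block_bernoulli(rng, target_mod, target_mod, spec.p_in, 0.0)
    A_tt = np.triu(A_tt, k=1)
    A_tt = A_tt + A_tt.T

    net = TripartiteNetwork(
        _ids("DR", spec.n_drugs),
        _ids("DI", spec.n_diseases),
        _ids("TG", spec.n_targets),
        A_ds,
        A_dt,
        A_tt,
    )
    drug_sim = SimilarityMatrix(
        net.drug_ids, _block_similarity(rng, drug_mod, spec.sim_signal, spec.sim_noise)
    )
    disease_sim = SimilarityMatrix(
        net.disease_ids,
        _block_similarity(rng, disease_mod, spec.sim_signal, spec.sim_noise),
    )
    truth = {"drugs": drug_mod, "diseases": disease_mod, "targets": target_mod}
    return net, drug_sim, disease_sim, truth


def _sample_exact(
    rng: np.random.Generator,
    mod_rows: np.ndarray,
    mod_cols: np.ndarray,
    n_edges: int,
    in_weight: float = 10.0,
) -> np.ndarray:
    """Sample exactly ``n_edges`` cells without replacement, within-module
    cells ``in_weight`` times as likely as cross-module cells."""
    n_r, n_c = mod_rows.size, mod_cols.size
    same = (mod_rows[:, None] == mod_cols[None, :]).ravel()
    w = np.where(same, in_weight, 1.0)
    idx = rng.choice(n_r * n_c, size=n_edges, replace=False, p=w / w.sum())
    A = np.zeros(n_r * n_c, dtype=np.int8)
    A[idx] = 1
    return A.reshape(n_r, n_c)


def generate_published_shape(seed: int = 0, n_modules: int = 4) -> TripartiteNetwork:
    """Network with the published dataset's exact dimensions.

    203 drugs, 52 diseases, 192 targets; exactly 609 drug–disease
    associations and 668 drug–target interactions, drawn without
    replacement with within-module cells up-weighted so the block structure
    survives the exact-count constraint.
    """
    rng = np.random.default_rng(seed)
    n_drugs, n_diseases, n_targets = 203, 52, 192
    drug_mod = _modules(n_drugs, n_modules)
    disease_mod = _modules(n_diseases, n_modules)
    target_mod = _modules(n_targets, n_modules)
    A_ds = _sample_exact(rng, drug_mod, disease_mod, 609)
    A_dt = _sample_exact(rng, drug_mod, target_mod, 668)
    A_tt = _block_bernoulli(rng, target_mod, target_mod, 0.1, 0.0)
    A_tt = np.triu(A_tt, k=1)
    A_tt = A_tt + A_tt.T
    return TripartiteNetwork(
        _ids("DR", n_drugs),
        _ids("DI", n_diseases),
        _ids("TG", n_targets),
        A_ds,
        A_dt,
        A_tt,
    )
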