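"""Synthetic character data: BM on a tree, white noise, and their mixture.

All generators take an explicit integer seed (or a Generator); there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bm import BMParams, CharacterMatrix, apply_intraspecific
from .errors import ValidationError
from .shrinkage import ReplicateTable
from .tree import TimeTree, phylo_vcv

__all__ = [
    "SimConfig",
    "simulate_bm",
    "simulate_wn",
    "blend",
    "simulate_mixture",
    "simulate_individuals",
]


def _rng(seed, rng):
    if rng is not None:
        return rng
    if seed is None:
        raise ValidationError("a seed is mandatory for stochastic simulation")
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Bundle of settings for a character-simulation experiment."""

    params: BMParams
    tree: TimeTree | None = None
    wn_mean: np.ndarray | None = None
    wn_variance: np.ndarray | None = None
    mixture_weight: float = 1.0
    n_individuals: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValidationError("mixture weight must lie in [0, 1]")


def simulate_bm(
    tree: TimeTree,
    params: BMParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CharacterMatrix:
    """Draw tip values from MVN(y0 kron 1, Sigma kron T (+ intraspecific))."""
    rng = _rng(seed, rng)
    labels = tree.taxon_labels()
    n = len(labels)
    sigma = params.sigma()
    k = sigma.shape[0]
    if isinstance(params.y0, str):
        raise ValidationError("simulation requires explicit root values y0")
    y0 = np.asarray(params.y0, dtype=float)
    T = phylo_vcv(tree, params.c_m)
    V = np.kron(sigma, T)
    verr = params.verr()
    if verr is not None:
        V = apply_intraspecific(V, verr)
    # eigh-based root: T is PSD (zero-length SA tips make it rank-deficient)
    w, U = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    z = U @ (np.sqrt(w) * rng.standard_normal(n * k))
    values = np.repeat(y0, n) + z
    return CharacterMatrix(labels, values.reshape(k, n).T)


def simulate_wn(
    labels,
    k: int,
    mean=0.0,
    variance=1.0,
    corr: np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CharacterMatrix:
    """I.i.d. rows from MVN(mean, diag(sd) corr diag(sd)); tree-free."""
    rng = _rng(seed, rng)
    labels = list(labels)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (k,))
    variance = np.broadcast_to(np.asarray(variance, dtype=float), (k,))
    if np.any(variance <= 0):
        raise ValidationError("white-noise variance must be > 0")
    if corr is None:
        corr = np.eye(k)
    sd = np.sqrt(variance)
    cov = np.outer(sd, sd) * np.asarray(corr, dtype=float)
    L = np.linalg.cholesky(cov)
    values = mean + rng.standard_normal((len(labels), k)) @ L.T
    return CharacterMatrix(labels, values)


def blend(M_WN: CharacterMatrix, M_BM: CharacterMatrix, w: float) -> CharacterMatrix:
    """Elementwise mixture (1 - w) * M_WN + w * M_BM.

    ``w = 1`` returns the BM matrix bit-exactly, ``w = 0`` the WN matrix.
    """
    if not 0.0 <= w <= 1.0:
        raise ValidationError("w must lie in [0, 1]")
    if M_WN.values.shape != M_BM.values.shape or M_WN.labels != M_BM.labels:
        raise ValidationError("matrices must share shape and taxon order")
    if w == 1.0:
        return CharacterMatrix(M_BM.labels, M_BM.values.copy(), M_BM.names)
    if w == 0.0:
        return CharacterMatrix(M_WN.labels, M_WN.values.copy(), M_WN.names)
    return CharacterMatrix(M_BM.labels, (1.0 - w) * M_WN.values + w * M_BM.values, M_BM.names)


def simulate_mixture(
    tree: TimeTree,
    params: BMParams,
    w: float,
    seed: int | None = None,
    wn_mean=None,
    wn_variance=None,
) -> CharacterMatrix:
    """BM/WN mixture with matched scale.

    Defaults (documented, configurable): the WN mean is y0 and the WN
    variance per character is the BM tip variance averaged over taxa, so the
    mixture varies phylogenetic signal rather than overall scale.
    """
    rng = _rng(seed, None)
    sigma = params.sigma()
    if wn_mean is None:
        wn_mean = np.asarray(params.y0, dtype=float)
    if wn_variance is None:
        T = phylo_vcv(tree, params.c_m)
        wn_variance = np.diag(sigma) * float(np.mean(np.diag(T)))
        wn_variance = np.clip(wn_variance, 1e-12, None)
    M_BM = simulate_bm(tree, params, rng=rng)
    M_WN = simulate_wn(
        M_BM.labels, sigma.shape[0], wn_mean, wn_variance, params.correlation(), rng=rng
    )
    return blend(M_WN, M_BM, w)


def simulate_individuals(
    species_means: CharacterMatrix,
    sigma,
    corr: np.ndarray | None,
    m: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, ReplicateTable]:
    """Per species, m draws from MVN(species mean, diag(sigma) corr diag(sigma))."""
    if m < 2:
        raise ValidationError("need m >= 2 individuals")
    rng = _rng(seed, rng)
    sd = np.broadcast_to(np.asarray(sigma, dtype=float), (species_means.k,))
    if np.any(sd < 0):
        raise ValidationError("sigma must be >= 0")
    if corr is None:
        corr = np.eye(species_means.k)
    cov = np.outer(sd, sd) * np.asarray(corr, dtype=float)
    w, U = np.linalg.eigh(cov)
    A = U * np.sqrt(np.clip(w, 0.0, None))
    out = {}
    for label, mean in zip(species_means.labels, species_means.values):
        draws = mean + rng.standard_normal((m, species_means.k)) @ A.T
        out[label] = ReplicateTable(label, draws, list(species_means.names))
    return out
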