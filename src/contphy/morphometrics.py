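"""Landmark preprocessing and multidimensional scaling.

Generalized Procrustes superimposition (translate to a common centroid,
scale to unit centroid size, rotate to a consensus), flattening of aligned
landmarks into a character matrix, and SMACOF stress-majorization MDS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .bm import CharacterMatrix
from .errors import ValidationError

__all__ = [
    "LandmarkSet",
    "MDSResult",
    "procrustes_superimpose",
    "procrustes_distance",
    "flatten_and_normalize",
    "mds_embed",
]


class LandmarkSet:
    """Specimen labels + (n_specimens, n_landmarks, 3) coordinate array."""

    def __init__(self, labels, coords, aligned: bool = False) -> None:
        self.labels = list(labels)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (specimens, landmarks, 3)")
        if self.coords.shape[0] != len(self.labels):
            raise ValidationError("label count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        self.aligned = aligned

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def to_tsv(self) -> str:
        lines = ["specimen\tlandmark\tx\ty\tz"]
        for lab, conf in zip(self.labels, self.coords):
            for j, (x, y, z) in enumerate(conf):
                lines.append(f"{lab}\t{j+1}\t{x:.12g}\t{y:.12g}\t{z:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "LandmarkSet":
        rows: dict[str, list[tuple[int, list[float]]]] = {}
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        for ln in lines[1:]:
            lab, lm, x, y, z = ln.split("\t")
            rows.setdefault(lab, []).append((int(lm), [float(x), float(y), float(z)]))
        labels = list(rows)
        coords = [
            [xyz for _, xyz in sorted(rows[lab], key=lambda p: p[0])] for lab in labels
        ]
        return cls(labels, np.array(coords))


def _center_scale(conf: np.ndarray) -> tuple[np.ndarray, float]:
    centered = conf - conf.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size == 0:
        raise ValidationError("degenerate configuration: all landmarks coincide")
    return centered / size, size


def procrustes_superimpose(
    specimens: LandmarkSet,
    allow_reflection: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[LandmarkSet, np.ndarray]:
    """Generalized Procrustes alignment; returns (aligned set, centroid sizes)."""
    if specimens.n_specimens < 2:
        raise ValidationError("need at least 2 specimens")
    if specimens.n_landmarks < 3:
        raise ValidationError("need at least 3 landmarks")
    configs = []
    sizes = []
    for conf in specimens.coords:
        c, s = _center_scale(conf)
        configs.append(c)
        sizes.append(s)
    configs = np.array(configs)

    # initialize the consensus at the plain average so that re-running GPA on
    # already-aligned data is (numerically) a no-op
    mean = configs.mean(axis=0)
    norm = np.linalg.norm(mean)
    mean = configs[0] if norm < 1e-8 else mean / norm
    for _ in range(max_iter):
        for i in range(len(configs)):
            R = _best_rotation(configs[i], mean, allow_reflection)
            configs[i] = configs[i] @ R
        new_mean = configs.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = LandmarkSet(specimens.labels, configs, aligned=True)
    return aligned, np.asarray(sizes)


def _best_rotation(a: np.ndarray, b: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal matrix R minimizing ||a R - b||_F."""
    if allow_reflection:
        R, _ = orthogonal_procrustes(a, b)
        return R
    U, _, Vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0] * (a.shape[1] - 1) + [d])
    return U @ D @ Vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Shape distance after optimal translation, scaling, and rotation.

    Square root of the summed squared landmark distances between the two
    superimposed configurations; zero iff the shapes coincide.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("configurations must share landmark dimensions")
    ca, _ = _center_scale(a)
    cb, _ = _center_scale(b)
    # full Procrustes fit: optimal rotation R and scale s (both preshapes have
    # unit norm, so s is the sum of singular values of ca' cb); the residual is
    # computed directly so identical shapes give ~0 rather than sqrt(eps)
    R, s = orthogonal_procrustes(ca, cb)
    return float(np.linalg.norm(min(s, 1.0) * ca @ R - cb))


def flatten_and_normalize(specimens: LandmarkSet, sd2_hat=None) -> CharacterMatrix:
    """Flatten aligned landmarks to n x 3L and divide columns by sqrt(variance)."""
    if not specimens.aligned:
        raise ValidationError("landmarks must be superimposed first")
    n, L, _ = specimens.coords.shape
    flat = specimens.coords.reshape(n, 3 * L)
    names = [f"lm{j+1}_{ax}" for j in range(L) for ax in "xyz"]
    if sd2_hat is None:
        return CharacterMatrix(specimens.labels, flat, names)
    sd2 = np.asarray(sd2_hat, dtype=float)
    if sd2.size != 3 * L:
        raise ValidationError("need one variance per flattened coordinate")
    if np.any(sd2 <= 0):
        raise ValidationError("variances must be > 0")
    return CharacterMatrix(specimens.labels, flat / np.sqrt(sd2), names, normalized=True)


@dataclass
class MDSResult:
    coords: np.ndarray
    stress: float  # raw stress: sum of squared distance residuals
    stress1: float  # Kruskal stress-1 (normalized)
    history: list[float]  # per-iteration raw stress of the winning start


def _raw_stress(D_target: np.ndarray, X: np.ndarray) -> float:
    D = _pairwise(X)
    iu = np.triu_indices_from(D, k=1)
    return float(np.sum((D_target[iu] - D[iu]) ** 2))


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def mds_embed(
    dist: np.ndarray,
    dim: int = 2,
    seed: int = 0,
    n_starts: int = 4,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> MDSResult:
    """Metric MDS via SMACOF majorization (stress non-increasing per step)."""
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValidationError("distance matrix must have zero diagonal")
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    best: MDSResult | None = None
    scale = D.max() if D.max() > 0 else 1.0
    for _ in range(n_starts):
        X = rng.standard_normal((n, dim)) * scale
        history = [_raw_stress(D, X)]
        for _ in range(max_iter):
            Dx = _pairwise(X)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(Dx > 0, D / Dx, 0.0)
            B = -ratio
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
            history.append(_raw_stress(D, X))
            if history[-2] - history[-1] < tol:
                break
        stress = history[-1]
        if best is None or stress < best.stress:
            denom = float(np.sum(D[np.triu_indices(n, k=1)] ** 2))
            stress1 = float(np.sqrt(stress / denom)) if denom > 0 else 0.0
            best = MDSResult(X, stress, stress1, history)
    return best
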