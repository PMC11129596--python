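"""Linear (ridge) shrinkage of within-species character correlation matrices.

The sample correlation matrix estimated from m individuals has rank at most
m - 1 and is singular whenever the number of characters exceeds m - 1.  The
archetypal ridge estimator blends it with the identity,

    rho_star = delta * I + (1 - delta) * rho_hat,

restoring invertibility for any delta > 0.  The shrinkage weight is chosen
by a deterministic leave-one-out cross-validation grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "ReplicateTable",
    "ShrinkageResult",
    "estimate_variances",
    "estimate_correlation",
    "ridge_shrink",
    "choose_delta",
    "shrink",
]

DELTA_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class ReplicateTable:
    """Raw measurements of k characters on m individuals of one species."""

    species: str
    values: np.ndarray  # m x k
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.names is None:
            self.names = [f"char{i+1}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValidationError("character name count mismatch")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_tsv(self) -> str:
        lines = ["species\tindividual\t" + "\t".join(self.names)]
        for i, row in enumerate(self.values):
            vals = "\t".join(f"{v:.12g}" for v in row)
            lines.append(f"{self.species}\t{i+1}\t{vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, species: str | None = None) -> "ReplicateTable":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        names = lines[0].split("\t")[2:]
        rows, sp = [], None
        for ln in lines[1:]:
            parts = ln.split("\t")
            if species is not None and parts[0] != species:
                continue
            sp = parts[0] if sp is None else sp
            rows.append([float(x) for x in parts[2:]])
        if not rows:
            raise ValidationError("no replicate rows found")
        return cls(sp, np.array(rows), names)


@dataclass
class ShrinkageResult:
    rho_hat: np.ndarray
    delta: float
    rho_star: np.ndarray
    sd2_hat: np.ndarray


def estimate_variances(reps: ReplicateTable) -> np.ndarray:
    """Per-character unbiased sample variances (denominator m - 1)."""
    if reps.m < 2:
        raise ValidationError("need at least 2 individuals to estimate variances")
    return np.var(reps.values, axis=0, ddof=1)


def estimate_correlation(reps: ReplicateTable) -> np.ndarray:
    """Sample correlation matrix; rank <= m - 1 (singular when k > m - 1)."""
    if reps.m < 2:
        raise ValidationError("need at least 2 individuals to estimate correlations")
    sd2 = estimate_variances(reps)
    for name, v in zip(reps.names, sd2):
        if v == 0:
            raise ValidationError(f"character {name!r} has zero variance")
    centered = reps.values - reps.values.mean(axis=0)
    cov = centered.T @ centered / (reps.m - 1)
    sd = np.sqrt(np.diag(cov))
    rho = cov / np.outer(sd, sd)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def ridge_shrink(rho_hat: np.ndarray, delta: float) -> np.ndarray:
    """Convex combination delta * I + (1 - delta) * rho_hat."""
    if not 0.0 <= delta <= 1.0:
        raise ValidationError("delta must lie in [0, 1]")
    rho_hat = np.asarray(rho_hat, dtype=float)
    return delta * np.eye(rho_hat.shape[0]) + (1.0 - delta) * rho_hat


def _gaussian_score(z: np.ndarray, rho: np.ndarray) -> float:
    """Log-density of standardized vector z under N(0, rho)."""
    sign, logdet = np.linalg.slogdet(rho)
    if sign <= 0:
        return -np.inf
    quad = z @ np.linalg.solve(rho, z)
    return float(-0.5 * (z.size * np.log(2 * np.pi) + logdet + quad))


def choose_delta(reps: ReplicateTable, grid: np.ndarray | None = None) -> float:
    """Deterministic LOOCV grid search for the shrinkage weight.

    Each individual is held out in turn; the remaining m - 1 rows provide
    means, variances, and a sample correlation from which rho_star(delta) is
    built, and the held-out (standardized) row is scored under
    N(0, rho_star(delta)).  The grid delta maximizing the summed score wins;
    ties break toward larger delta (more regularization).
    """
    if reps.m < 3:
        raise ValidationError("need at least 3 individuals for cross-validation")
    if grid is None:
        grid = DELTA_GRID
    if np.allclose(reps.values, reps.values[0]):
        warnings.warn("all individuals identical; returning delta = 1")
        return 1.0
    scores = np.zeros(len(grid))
    for i in range(reps.m):
        rest = np.delete(reps.values, i, axis=0)
        mu = rest.mean(axis=0)
        sd2 = np.var(rest, axis=0, ddof=1)
        if np.any(sd2 == 0):
            continue  # degenerate fold; skip
        rho_hat = estimate_correlation(ReplicateTable(reps.species, rest, reps.names))
        z = (reps.values[i] - mu) / np.sqrt(sd2)
        for g, delta in enumerate(grid):
            scores[g] += _gaussian_score(z, ridge_shrink(rho_hat, delta))
    best = np.flatnonzero(scores == scores.max())[-1]
    return float(grid[best])


def shrink(reps: ReplicateTable, delta: float | None = None) -> ShrinkageResult:
    """Full pipeline: variances, sample correlation, delta, shrunk correlation."""
    sd2 = estimate_variances(reps)
    rho_hat = estimate_correlation(reps)
    if delta is None:
        delta = choose_delta(reps)
    return ShrinkageResult(rho_hat, delta, ridge_shrink(rho_hat, delta), sd2)
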