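"""Lightweight prior distributions (fast log-densities, seeded sampling).

scipy.stats frozen distributions carry substantial per-call overhead; these
hand-rolled densities keep the MCMC inner loop cheap while delegating
quantiles to scipy when asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ValidationError

__all__ = [
    "LogNormalPrior",
    "NormalPrior",
    "UniformPrior",
    "ExponentialPrior",
    "PriorSpec",
]

_LOG2PI = math.log(2.0 * math.pi)


class Prior:
    def logpdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class LogNormalPrior(Prior):
    """Log-normal with mean/sd given in log space."""

    mean_log: float = 0.0
    sd_log: float = 1.0

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        z = (math.log(x) - self.mean_log) / self.sd_log
        return -0.5 * z * z - math.log(x * self.sd_log) - 0.5 * _LOG2PI

    def sample(self, rng) -> float:
        return float(math.exp(self.mean_log + self.sd_log * rng.standard_normal()))

    def mean(self) -> float:
        return math.exp(self.mean_log + 0.5 * self.sd_log**2)

    def var(self) -> float:
        s2 = self.sd_log**2
        return (math.exp(s2) - 1.0) * math.exp(2 * self.mean_log + s2)

    def quantile(self, p: float) -> float:
        from scipy.stats import norm

        return float(math.exp(self.mean_log + self.sd_log * norm.ppf(p)))


@dataclass(frozen=True)
class NormalPrior(Prior):
    mu: float = 0.0
    sd: float = 1.0

    def logpdf(self, x: float) -> float:
        z = (x - self.mu) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * _LOG2PI

    def sample(self, rng) -> float:
        return float(self.mu + self.sd * rng.standard_normal())

    def mean(self) -> float:
        return self.mu

    def var(self) -> float:
        return self.sd**2

    def quantile(self, p: float) -> float:
        from scipy.stats import norm

        return float(norm.ppf(p, loc=self.mu, scale=self.sd))


@dataclass(frozen=True)
class UniformPrior(Prior):
    lo: float = 0.0
    hi: float = 1.0

    def logpdf(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return -math.log(self.hi - self.lo)
        return -math.inf

    def sample(self, rng) -> float:
        return float(rng.uniform(self.lo, self.hi))

    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def var(self) -> float:
        return (self.hi - self.lo) ** 2 / 12.0

    def quantile(self, p: float) -> float:
        return self.lo + p * (self.hi - self.lo)


@dataclass(frozen=True)
class ExponentialPrior(Prior):
    rate: float = 1.0

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -math.inf
        return math.log(self.rate) - self.rate * x

    def sample(self, rng) -> float:
        return float(rng.exponential(1.0 / self.rate))

    def mean(self) -> float:
        return 1.0 / self.rate

    def var(self) -> float:
        return 1.0 / self.rate**2

    def quantile(self, p: float) -> float:
        return float(-math.log1p(-p) / self.rate)


@dataclass
class PriorSpec:
    """Named priors for the free parameters of a run.

    Any entry left ``None`` marks the corresponding parameter as fixed.
    ``tree_model`` selects the tree prior ("fbd", "bdss", or None for a
    fixed-ages analysis).
    """

    c_m: Prior | None = None
    y0: Prior | None = None
    L_diag: Prior | None = None
    L_offdiag: Prior | None = None
    branch_rate: Prior | None = None
    episode: dict[str, Prior] = field(default_factory=dict)
    tree_model: str | None = None

    def __post_init__(self) -> None:
        if self.tree_model not in (None, "fbd", "bdss"):
            raise ValidationError("tree_model must be 'fbd', 'bdss', or None")
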