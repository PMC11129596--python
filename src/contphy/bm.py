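"""Multivariate Brownian-motion likelihood for continuous characters.

Three equivalent routes are provided:

* :func:`dense_loglik` — builds the full nk x nk covariance (character
  covariance kron phylogenetic covariance, plus per-taxon intraspecific
  blocks) and evaluates the multivariate-normal density directly.  O((nk)^3);
  the reference oracle.
* :func:`pruning_loglik` with ``algorithm="felsenstein"`` — postorder message
  passing in moment form (conditional mean vector + k x k covariance per
  node), the multivariate generalization of the classic three-quantity
  pruning recursion.
* :func:`pruning_loglik` with ``algorithm="general"`` — postorder message
  passing in quadratic-coefficient (natural) form, integrating each branch
  transition in closed form and finishing with a Gaussian integral (or
  profile maximization) at the root.

Both pruning routes are linear in the number of taxa for fixed k, handle
sampled ancestors (zero-length terminal edges contribute no branch variance)
and intraspecific variance added at the tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import SingularCovarianceError, ValidationError
from .tree import TimeTree, phylo_vcv

__all__ = [
    "CharacterMatrix",
    "BMParams",
    "build_sigma",
    "sigma_from_factor",
    "apply_intraspecific",
    "normalize_by_sd",
    "dense_loglik",
    "pruning_loglik",
    "ml_root_values",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


class CharacterMatrix:
    """n x k matrix of continuous character values keyed to taxon labels."""

    def __init__(
        self,
        labels: Sequence[str],
        values,
        names: Sequence[str] | None = None,
        normalized: bool = False,
    ) -> None:
        self.values = np.atleast_2d(np.asarray(values, dtype=float))
        self.labels = list(labels)
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError("label count does not match row count")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate taxon labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("character values must be finite (no missing data)")
        k = self.values.shape[1]
        self.names = list(names) if names is not None else [f"char{i+1}" for i in range(k)]
        if len(self.names) != k:
            raise ValidationError("character name count does not match column count")
        self.normalized = normalized

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def reorder(self, labels: Sequence[str]) -> "CharacterMatrix":
        labels = list(labels)
        if labels == self.labels:
            return self
        idx = [self.labels.index(lab) for lab in labels]
        return CharacterMatrix(
            [self.labels[i] for i in idx], self.values[idx], self.names, self.normalized
        )

    def to_tsv(self) -> str:
        lines = ["taxon\t" + "\t".join(self.names)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{v:.12g}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CharacterMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0].split("\t")
        names = header[1:]
        labels, rows = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows), names)


@dataclass
class BMParams:
    """Parameters of the multivariate BM model.

    Exactly one of ``corr`` (with ``r``) or ``factor`` parameterizes the
    character covariance.  ``y0`` is either a length-k vector of root values
    or the sentinel string ``"ML"`` (profile the root values out via their
    maximum-likelihood estimate).  ``sigma_intra`` holds per-character
    intraspecific standard deviations (shared across species); alternatively
    a full k x k ``v_err`` matrix may be supplied.
    """

    c_m: float = 1.0
    r: np.ndarray | None = None
    corr: np.ndarray | None = None
    factor: np.ndarray | None = None
    y0: np.ndarray | str = "ML"
    sigma_intra: np.ndarray | None = None
    v_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValidationError("c_m must be > 0")
        if (self.corr is None) == (self.factor is None):
            raise ValidationError("supply exactly one of corr / factor")
        if self.corr is not None:
            k = np.asarray(self.corr).shape[0]
            if self.r is None:
                self.r = np.ones(k)
        if self.sigma_intra is not None and self.v_err is not None:
            raise ValidationError("supply at most one of sigma_intra / v_err")
        self._sigma_cache: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.sigma().shape[0]

    def sigma(self) -> np.ndarray:
        # cached: proposal machinery replaces (never mutates) parameter arrays
        if self._sigma_cache is None:
            if self.factor is not None:
                self._sigma_cache = sigma_from_factor(self.factor)
            else:
                self._sigma_cache = build_sigma(self.r, self.corr)
        return self._sigma_cache

    def correlation(self) -> np.ndarray:
        """Recover the correlation matrix (also from a factor parameterization)."""
        sig = self.sigma()
        r = np.sqrt(np.diag(sig))
        return sig / np.outer(r, r)

    def verr(self) -> np.ndarray | None:
        """The k x k intraspecific covariance added to each taxon block."""
        if self.v_err is not None:
            ve = np.asarray(self.v_err, dtype=float)
            if not np.allclose(ve, ve.T):
                raise ValidationError("v_err must be symmetric")
            return ve
        if self.sigma_intra is None:
            return None
        sd = np.asarray(self.sigma_intra, dtype=float)
        if np.any(sd < 0):
            raise ValidationError("intraspecific standard deviations must be >= 0")
        if np.all(sd == 0):
            return None
        return np.outer(sd, sd) * self.correlation()


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------


def build_sigma(r, corr) -> np.ndarray:
    """Character covariance diag(r) @ corr @ diag(r)."""
    r = np.asarray(r, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("relative character rates must be > 0")
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1] or corr.shape[0] != r.size:
        raise ValidationError("corr must be k x k matching r")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValidationError("correlation matrix must have unit diagonal")
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValidationError("correlation entries must lie in [-1, 1]")
    return np.outer(r, r) * corr


def sigma_from_factor(L) -> np.ndarray:
    """Character covariance from an upper-triangular factor, Sigma = L @ L.T."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValidationError("factor must be square")
    if not np.allclose(L, np.triu(L)):
        raise ValidationError("factor must be upper-triangular")
    if np.any(np.diag(L) == 0):
        raise SingularCovarianceError("factor has a zero diagonal element")
    return L @ L.T


def apply_intraspecific(V: np.ndarray, verr: np.ndarray) -> np.ndarray:
    """Add the k x k intraspecific covariance to each taxon's own block of V.

    ``V`` is laid out character-major (column-stacked vec(M), so entry
    ((i, u), (j, w)) sits at (i*n + u, j*n + w)); the per-taxon increment is
    therefore kron(verr, I_n).
    """
    verr = np.asarray(verr, dtype=float)
    if not np.allclose(verr, verr.T):
        raise ValidationError("verr must be symmetric")
    k = verr.shape[0]
    nk = V.shape[0]
    if V.shape[0] != V.shape[1] or nk % k != 0:
        raise ValidationError("dimension mismatch between V and verr")
    n = nk // k
    return V + np.kron(verr, np.eye(n))


def normalize_by_sd(M: CharacterMatrix, sd2_hat) -> CharacterMatrix:
    """Divide each character column by the square root of its variance estimate."""
    sd2 = np.asarray(sd2_hat, dtype=float)
    if sd2.size != M.k:
        raise ValidationError("need one variance per character")
    for name, v in zip(M.names, sd2):
        if v <= 0:
            raise ValidationError(f"non-positive variance for character {name!r}")
    return CharacterMatrix(M.labels, M.values / np.sqrt(sd2), M.names, normalized=True)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _chol(mat: np.ndarray, what: str = "covariance"):
    try:
        c, low = cho_factor(mat, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(f"singular {what}") from exc
    d = np.diag(c)
    if np.any(d <= 0) or np.any(d < 1e-12 * max(1.0, d.max())):
        raise SingularCovarianceError(f"singular {what}")
    return (c, low)


def _mvn_logpdf_chol(x: np.ndarray, chol) -> float:
    c, _ = chol
    z = cho_solve(chol, x, check_finite=False)
    return float(
        -0.5 * x @ z - np.log(np.diag(c)).sum() - 0.5 * x.size * _LOG2PI
    )


def _prepare(M: CharacterMatrix, tree: TimeTree, params: BMParams):
    labels = tree.taxon_labels()
    if set(labels) != set(M.labels):
        raise ValidationError("character matrix labels do not match tree taxa")
    data = M.reorder(labels).values
    sigma = params.sigma()
    if data.shape[1] != sigma.shape[0]:
        raise ValidationError("character count does not match parameter dimension")
    verr = params.verr()
    if verr is not None and verr.shape[0] != sigma.shape[0]:
        raise ValidationError("v_err dimension mismatch")
    return labels, data, sigma, verr


# ---------------------------------------------------------------------------
# dense oracle
# ---------------------------------------------------------------------------


def dense_loglik(M: CharacterMatrix, tree: TimeTree, params: BMParams) -> float:
    """Log-density of vec(M) under the full multivariate-normal construction."""
    labels, data, sigma, verr = _prepare(M, tree, params)
    n, k = data.shape
    T = phylo_vcv(tree, params.c_m)
    V = np.kron(sigma, T)
    if verr is not None:
        V = apply_intraspecific(V, verr)
    x = data.flatten(order="F")
    chol = _chol(V)
    if isinstance(params.y0, str) and params.y0 == "ML":
        X = np.kron(np.eye(k), np.ones((n, 1)))
        Vix = cho_solve(chol, X, check_finite=False)
        y0 = np.linalg.solve(X.T @ Vix, Vix.T @ x)
    else:
        y0 = np.asarray(params.y0, dtype=float)
        if y0.size != k:
            raise ValidationError("y0 must have one entry per character")
    mean = np.repeat(y0, n)
    return _mvn_logpdf_chol(x - mean, chol)


# ---------------------------------------------------------------------------
# felsenstein-style pruning (moment-form messages)
# ---------------------------------------------------------------------------


def _felsenstein_scalar(data, labels, tree, sigma, c_m):
    """Classic three-quantity recursion (variance scalar, mean, log-weight).

    Valid when there is no intraspecific variance: every message covariance
    is then a scalar multiple of Sigma, so only that scalar, the conditional
    mean vector, and the accumulated log-density need tracking.
    """
    k = sigma.shape[0]
    chol = _chol(sigma, "character covariance")
    logdet_sigma = 2.0 * np.log(np.diag(chol[0])).sum()
    sigma_inv = cho_solve(chol, np.eye(k), check_finite=False)
    row = {lab: i for i, lab in enumerate(labels)}
    log = math.log
    msgs: dict[int, tuple[np.ndarray, float, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            msgs[id(node)] = (data[row[node.label]], 0.0, 0.0)
            continue
        m = None
        v = w = 0.0
        for child in node.children:
            cm, cv, cw = msgs.pop(id(child))
            cv = cv + c_m * child.rate * child.edge_length()
            if m is None:
                m, v, w = cm, cv, cw
                continue
            s = v + cv
            if s <= 0:
                raise SingularCovarianceError("singular covariance (zero contrast variance)")
            d = m - cm
            quad = float(d @ sigma_inv @ d)
            w += cw - 0.5 * (k * (_LOG2PI + log(s)) + logdet_sigma + quad / s)
            m = m + (v / s) * (cm - m)
            v = v * cv / s
        msgs[id(node)] = (m, v, w)
    m, v, w = msgs[id(tree.root)]
    return m, v, w, sigma_inv, logdet_sigma


def _felsenstein_scalar_loglik(data, labels, tree, sigma, c_m, y0):
    m, v, w, sigma_inv, logdet_sigma = _felsenstein_scalar(data, labels, tree, sigma, c_m)
    k = sigma.shape[0]
    if v <= 0:
        raise SingularCovarianceError("singular root covariance")
    if isinstance(y0, str) and y0 == "ML":
        return w - 0.5 * (k * (_LOG2PI + math.log(v)) + logdet_sigma)
    d = m - np.asarray(y0, dtype=float)
    quad = float(d @ sigma_inv @ d)
    return w - 0.5 * (k * (_LOG2PI + math.log(v)) + logdet_sigma + quad / v)


def _felsenstein_root_message(data, labels, tree, sigma, verr, c_m):
    k = sigma.shape[0]
    row = {lab: i for i, lab in enumerate(labels)}
    msgs: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            m = data[row[node.label]].copy()
            C = verr.copy() if verr is not None else np.zeros((k, k))
            w = 0.0
        else:
            m = C = None
            w = 0.0
            for child in node.children:
                cm, cC, cw = msgs.pop(id(child))
                t_e = c_m * child.rate * child.edge_length()
                cC = cC + t_e * sigma
                if m is None:
                    m, C, w = cm, cC, cw
                    continue
                S = C + cC
                chol = _chol(S)
                w += cw + _mvn_logpdf_chol(m - cm, chol)
                gain = cho_solve(chol, C, check_finite=False)  # S^-1 C
                m = m + gain.T @ (cm - m)
                C = C - C @ gain
                C = 0.5 * (C + C.T)
        msgs[id(node)] = (m, C, w)
    return msgs[id(tree.root)]


def _felsenstein_loglik(data, labels, tree, sigma, verr, c_m, y0):
    m, C, w = _felsenstein_root_message(data, labels, tree, sigma, verr, c_m)
    k = sigma.shape[0]
    if isinstance(y0, str) and y0 == "ML":
        chol = _chol(C, "root covariance")
        return w - np.log(np.diag(chol[0])).sum() - 0.5 * k * _LOG2PI
    y0 = np.asarray(y0, dtype=float)
    return w + _mvn_logpdf_chol(m - y0, _chol(C, "root covariance"))


# ---------------------------------------------------------------------------
# general pruning (quadratic-coefficient messages)
# ---------------------------------------------------------------------------


@dataclass
class _Quad:
    A: np.ndarray
    b: np.ndarray
    c: float


@dataclass
class _Delta:
    y: np.ndarray
    c: float


def _quad_from_point(y: np.ndarray, c: float, V: np.ndarray) -> _Quad:
    k = y.size
    chol = _chol(V, "branch covariance")
    P = cho_solve(chol, np.eye(k), check_finite=False)
    logdet = 2.0 * np.log(np.diag(chol[0])).sum()
    return _Quad(
        A=-0.5 * P,
        b=P @ y,
        c=c - 0.5 * y @ P @ y - 0.5 * k * _LOG2PI - 0.5 * logdet,
    )


def _propagate_quad(q: _Quad, V: np.ndarray) -> _Quad:
    k = q.b.size
    cholV = _chol(V, "branch covariance")
    P = cho_solve(cholV, np.eye(k), check_finite=False)
    logdetV = 2.0 * np.log(np.diag(cholV[0])).sum()
    S = P - 2.0 * q.A
    cholS = _chol(S, "pruning intermediate")
    Sib = cho_solve(cholS, q.b, check_finite=False)
    SiP = cho_solve(cholS, P, check_finite=False)
    logdetS = 2.0 * np.log(np.diag(cholS[0])).sum()
    A = -0.5 * P + 0.5 * P @ SiP
    return _Quad(
        A=0.5 * (A + A.T),
        b=P @ Sib,
        c=q.c + 0.5 * q.b @ Sib - 0.5 * logdetV - 0.5 * logdetS,
    )


def _general_root_message(data, labels, tree, sigma, verr, c_m):
    k = sigma.shape[0]
    row = {lab: i for i, lab in enumerate(labels)}
    msgs: dict[int, _Quad | _Delta] = {}
    for node in tree.postorder():
        if node.is_tip:
            y = data[row[node.label]]
            if verr is not None:
                msg: _Quad | _Delta = _quad_from_point(y, 0.0, verr)
            else:
                msg = _Delta(y.copy(), 0.0)
        else:
            msg = None
            for child in node.children:
                cmsg = msgs.pop(id(child))
                t_e = c_m * child.rate * child.edge_length()
                if t_e > 0:
                    V = t_e * sigma
                    if isinstance(cmsg, _Delta):
                        cmsg = _quad_from_point(cmsg.y, cmsg.c, V)
                    else:
                        cmsg = _propagate_quad(cmsg, V)
                msg = cmsg if msg is None else _combine(msg, cmsg)
        msgs[id(node)] = msg
    return msgs[id(tree.root)]


def _combine(a: _Quad | _Delta, b: _Quad | _Delta):
    if isinstance(a, _Delta) and isinstance(b, _Delta):
        raise SingularCovarianceError(
            "two point-mass pruning messages meet (coincident zero-variance taxa)"
        )
    if isinstance(a, _Delta):
        a, b = b, a
    if isinstance(b, _Delta):
        return _Delta(b.y, b.c + float(b.y @ a.A @ b.y + a.b @ b.y + a.c))
    return _Quad(a.A + b.A, a.b + b.b, a.c + b.c)


def _general_loglik(data, labels, tree, sigma, verr, c_m, y0):
    msg = _general_root_message(data, labels, tree, sigma, verr, c_m)
    if isinstance(msg, _Delta):
        raise SingularCovarianceError("degenerate (point-mass) root message")
    if isinstance(y0, str) and y0 == "ML":
        chol = _chol(-2.0 * msg.A, "root precision")
        yhat = cho_solve(chol, msg.b, check_finite=False)
        return float(msg.c + 0.5 * msg.b @ yhat)
    y0 = np.asarray(y0, dtype=float)
    return float(y0 @ msg.A @ y0 + msg.b @ y0 + msg.c)


# ---------------------------------------------------------------------------
# public pruning interface
# ---------------------------------------------------------------------------


def pruning_loglik(
    M: CharacterMatrix,
    tree: TimeTree,
    params: BMParams,
    algorithm: str = "felsenstein",
) -> float:
    """Pruning-based log-likelihood; agrees with :func:`dense_loglik` to 1e-8."""
    labels, data, sigma, verr = _prepare(M, tree, params)
    _chol(sigma, "character covariance")  # fail fast, same contract as dense
    if algorithm == "felsenstein":
        if verr is None:
            return _felsenstein_scalar_loglik(data, labels, tree, sigma, params.c_m, params.y0)
        return _felsenstein_loglik(data, labels, tree, sigma, verr, params.c_m, params.y0)
    if algorithm == "general":
        return _general_loglik(data, labels, tree, sigma, verr, params.c_m, params.y0)
    raise ValidationError(f"unknown algorithm {algorithm!r}")


def ml_root_values(M: CharacterMatrix, tree: TimeTree, params: BMParams) -> np.ndarray:
    """Maximum-likelihood root character values (pruning byproduct).

    With no intraspecific variance this equals the generalized-least-squares
    estimate (1' T^-1 M) / (1' T^-1 1) per character.
    """
    labels, data, sigma, verr = _prepare(M, tree, params)
    _chol(sigma, "character covariance")
    if verr is None:
        m, _, _, _, _ = _felsenstein_scalar(data, labels, tree, sigma, params.c_m)
        return m
    m, C, _ = _felsenstein_root_message(data, labels, tree, sigma, verr, params.c_m)
    return m
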