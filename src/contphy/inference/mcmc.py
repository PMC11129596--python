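"""Single-chain Metropolis-Hastings over trees and BM parameters.

Every proposal works on a copy of the model state, so the posterior is
re-evaluated from scratch for the factors a move can touch; cached values
therefore always equal fresh recomputation.  Singular character covariances
raise inside the likelihood and are converted into proposal rejections.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..bm import BMParams, CharacterMatrix, pruning_loglik
from ..errors import SingularCovarianceError, ValidationError
from ..tree import CladeConstraint, TimeTree, _clade_map
from ..treeprocess import EpisodeParams, bdss_log_density, fbd_log_density
from .priors import PriorSpec

__all__ = [
    "ModelState",
    "Trace",
    "log_posterior",
    "run_chain",
    "ScalarScaleMove",
    "CmGibbsMove",
    "Y0GibbsMove",
    "TreeScaleMove",
    "Y0WalkMove",
    "LElementMove",
    "NodeAgeMove",
    "RootScaleMove",
    "NarrowExchange",
    "SAToggleMove",
    "EpisodeScale",
    "BranchRateScale",
]

_TOL = 1e-9


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    tree: TimeTree
    bm: BMParams
    episode: EpisodeParams | None = None
    log_likelihood: float | None = None
    log_prior: float | None = None

    def copy(self, copy_tree: bool = True) -> "ModelState":
        bm = dataclasses.replace(
            self.bm,
            r=None if self.bm.r is None else self.bm.r.copy(),
            corr=None if self.bm.corr is None else np.array(self.bm.corr),
            factor=None if self.bm.factor is None else np.array(self.bm.factor),
            y0=self.bm.y0 if isinstance(self.bm.y0, str) else np.array(self.bm.y0),
            sigma_intra=None
            if self.bm.sigma_intra is None
            else np.array(self.bm.sigma_intra),
            v_err=None if self.bm.v_err is None else np.array(self.bm.v_err),
        )
        bm._sigma_cache = self.bm._sigma_cache  # moves that alter Sigma reset this
        episode = None if self.episode is None else dataclasses.replace(self.episode)
        tree = self.tree.copy() if copy_tree else self.tree
        return ModelState(tree, bm, episode)


def log_posterior(
    state: ModelState,
    data: CharacterMatrix | None,
    priors: PriorSpec,
) -> float:
    """Pruning likelihood + tree prior + parameter priors (log scale).

    A singular character covariance contributes -inf (proposal rejection),
    never an exception.
    """
    lik = 0.0
    if data is not None and data.n > 0 and data.k > 0:
        try:
            lik = pruning_loglik(data, state.tree, state.bm)
        except SingularCovarianceError:
            lik = -math.inf
    prior = _log_prior(state, priors)
    state.log_likelihood = lik
    state.log_prior = prior
    if not (math.isfinite(lik) and math.isfinite(prior)):
        return -math.inf
    return lik + prior


def _log_prior(state: ModelState, priors: PriorSpec) -> float:
    total = 0.0
    if priors.tree_model is not None:
        if state.episode is None:
            raise ValidationError("tree prior requested but no episode parameters set")
        dens = fbd_log_density if priors.tree_model == "fbd" else bdss_log_density
        total += dens(state.tree, state.episode)
        if not math.isfinite(total):
            return -math.inf
    if priors.c_m is not None:
        total += priors.c_m.logpdf(state.bm.c_m)
    if priors.y0 is not None and not isinstance(state.bm.y0, str):
        total += sum(priors.y0.logpdf(float(v)) for v in np.atleast_1d(state.bm.y0))
    if state.bm.factor is not None and (priors.L_diag or priors.L_offdiag):
        L = state.bm.factor
        k = L.shape[0]
        for i in range(k):
            if priors.L_diag is not None:
                total += priors.L_diag.logpdf(float(L[i, i]))
            if priors.L_offdiag is not None:
                for j in range(i + 1, k):
                    total += priors.L_offdiag.logpdf(float(L[i, j]))
    if priors.branch_rate is not None:
        for node in state.tree.preorder():
            if node.parent is not None:
                total += priors.branch_rate.logpdf(node.rate)
    for name, prior in priors.episode.items():
        total += prior.logpdf(getattr(state.episode, name))
    return total


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------


class Move:
    name = "move"
    weight = 1.0
    changes_topology = False

    def propose(self, state: ModelState, rng) -> tuple[ModelState, float] | None:
        raise NotImplementedError  # pragma: no cover


class ScalarScaleMove(Move):
    """Multiplier proposal x -> x * exp(U(-step, step)) on a positive scalar."""

    name = "scale_c_m"

    def __init__(self, step: float = 0.5, weight: float = 1.0) -> None:
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy(copy_tree=False)
        u = rng.uniform(-self.step, self.step)
        new.bm.c_m = state.bm.c_m * math.exp(u)
        return new, u


class EpisodeScale(Move):
    """Multiplier proposal on one EpisodeParams rate field."""

    def __init__(self, field_name: str, step: float = 0.5, weight: float = 1.0) -> None:
        self.field_name = field_name
        self.name = f"scale_{field_name}"
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy(copy_tree=False)
        u = rng.uniform(-self.step, self.step)
        setattr(new.episode, self.field_name, getattr(state.episode, self.field_name) * math.exp(u))
        return new, u


class Y0WalkMove(Move):
    name = "walk_y0"

    def __init__(self, step: float = 0.3, weight: float = 1.0) -> None:
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        if isinstance(state.bm.y0, str):
            return None
        new = state.copy(copy_tree=False)
        j = int(rng.integers(np.atleast_1d(new.bm.y0).size))
        new.bm.y0[j] += rng.normal(0.0, self.step)
        return new, 0.0


class LElementMove(Move):
    """Random walk on one element of the upper-triangular covariance factor.

    Diagonal elements get a multiplier proposal (kept positive), off-diagonal
    elements a symmetric normal walk.
    """

    name = "walk_L"

    def __init__(self, step: float = 0.2, weight: float = 1.0) -> None:
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        if state.bm.factor is None:
            return None
        new = state.copy(copy_tree=False)
        new.bm._sigma_cache = None
        k = new.bm.factor.shape[0]
        idx = [(i, j) for i in range(k) for j in range(i, k)]
        i, j = idx[int(rng.integers(len(idx)))]
        if i == j:
            u = rng.uniform(-self.step, self.step)
            new.bm.factor[i, j] *= math.exp(u)
            return new, u
        new.bm.factor[i, j] += rng.normal(0.0, self.step)
        return new, 0.0


class BranchRateScale(Move):
    name = "scale_branch_rate"

    def __init__(self, step: float = 0.5, weight: float = 1.0) -> None:
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy()
        nodes = [n for n in new.tree.preorder() if n.parent is not None]
        node = nodes[int(rng.integers(len(nodes)))]
        u = rng.uniform(-self.step, self.step)
        node.rate *= math.exp(u)
        return new, u


def _age_free(node) -> bool:
    return not any(c.sampled_ancestor for c in node.children)


class NodeAgeMove(Move):
    """Uniform redraw of an internal node age between its children and parent."""

    name = "node_age"

    def __init__(self, weight: float = 1.0) -> None:
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy()
        eligible = [
            n
            for n in new.tree.internal_nodes(include_root=False)
            if _age_free(n)
        ]
        if not eligible:
            return None
        node = eligible[int(rng.integers(len(eligible)))]
        lo = max(c.age for c in node.children)
        hi = node.parent.age
        if hi - lo <= _TOL:
            return None
        node.age = rng.uniform(lo, hi)
        return new, 0.0


class RootScaleMove(Move):
    """Scale the root age above its oldest child: x' = c + (x - c) e^u."""

    name = "root_scale"

    def __init__(self, step: float = 0.5, weight: float = 1.0) -> None:
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy()
        root = new.tree.root
        if not root.children or not _age_free(root):
            return None
        cmax = max(c.age for c in root.children)
        u = rng.uniform(-self.step, self.step)
        root.age = cmax + (root.age - cmax) * math.exp(u)
        return new, u


class CmGibbsMove(Move):
    """Inverse-gamma independence proposal for the global rate c_m.

    With everything else fixed, the log-likelihood is exactly
    ``A - (D/2) log c - B / c`` because the tip covariance is linear in c_m;
    A, D, B are recovered from three likelihood evaluations and the implied
    inverse-gamma shape is used as an independence proposal (the usual MH
    ratio then reduces to the prior ratio).  Falls back to rejecting when the
    fit is unusable (e.g. intraspecific variance breaks linearity).
    """

    name = "gibbs_c_m"

    def __init__(self, weight: float = 1.0) -> None:
        self.weight = weight
        self._data: CharacterMatrix | None = None

    def bind(self, data: CharacterMatrix | None, priors: PriorSpec | None = None) -> None:
        self._data = data

    def propose(self, state, rng):
        if self._data is None or state.bm.verr() is not None:
            return None
        c0 = state.bm.c_m
        # exponent D is known from the tree structure: k contrasts per
        # child-combination plus the root factor
        n_contrasts = 1 + sum(
            len(n.children) - 1 for n in state.tree.internal_nodes()
        )
        D = self._data.k * n_contrasts
        try:
            l1 = state.log_likelihood
            if l1 is None or not math.isfinite(l1):
                l1 = pruning_loglik(self._data, state.tree, state.bm)
            l2 = pruning_loglik(
                self._data, state.tree, dataclasses.replace(state.bm, c_m=2 * c0)
            )
        except SingularCovarianceError:
            return None
        B = 2 * c0 * ((D / 2.0) * math.log(2.0) - (l1 - l2))
        alpha = D / 2.0 - 1.0
        if not (B > 0 and alpha > 0.5):
            return None
        new = state.copy(copy_tree=False)
        g = rng.gamma(alpha)
        if g <= 0:
            return None
        c_new = B / g
        new.bm.c_m = c_new

        def log_q(c: float) -> float:
            return alpha * math.log(B) - math.lgamma(alpha) - (alpha + 1) * math.log(c) - B / c

        return new, log_q(c0) - log_q(c_new)


class Y0GibbsMove(Move):
    """Exact Gibbs update of the root character values.

    Given everything else, the likelihood depends on y0 only through
    N(m_root; y0, v_root * Sigma) (pruning byproducts); with a normal prior
    the conditional is Gaussian and is sampled directly (acceptance 1).
    """

    name = "gibbs_y0"

    def __init__(self, weight: float = 1.0) -> None:
        self.weight = weight
        self._data: CharacterMatrix | None = None
        self._prior = None

    def bind(self, data: CharacterMatrix | None, priors: PriorSpec | None = None) -> None:
        self._data = data
        self._prior = priors.y0 if priors is not None else None

    def propose(self, state, rng):
        from .priors import NormalPrior

        if (
            self._data is None
            or not isinstance(self._prior, NormalPrior)
            or isinstance(state.bm.y0, str)
            or state.bm.verr() is not None
        ):
            return None
        from ..bm import _felsenstein_scalar, _prepare

        try:
            labels, data, sigma, _ = _prepare(self._data, state.tree, state.bm)
            m, v, _, sigma_inv, _ = _felsenstein_scalar(
                data, labels, state.tree, sigma, state.bm.c_m
            )
        except SingularCovarianceError:
            return None
        if v <= 0:
            return None
        k = sigma.shape[0]
        P_post = sigma_inv / v + np.eye(k) / self._prior.sd**2
        cov = np.linalg.inv(P_post)
        cov = 0.5 * (cov + cov.T)
        mean = cov @ (sigma_inv @ m / v + np.full(k, self._prior.mu) / self._prior.sd**2)
        L = np.linalg.cholesky(cov)
        y_new = mean + L @ rng.standard_normal(k)

        def log_q(y):
            d = np.linalg.solve(L, y - mean)
            return float(-0.5 * d @ d - np.log(np.diag(L)).sum() - 0.5 * k * _LOG2PI_K)

        new = state.copy(copy_tree=False)
        new.bm.y0 = y_new
        return new, log_q(np.asarray(state.bm.y0, dtype=float)) - log_q(y_new)


_LOG2PI_K = math.log(2.0 * math.pi)


class TreeScaleMove(Move):
    """Joint scaling of free internal node ages (x f) and the clock (/ f).

    Travels along the rate-time ridge: with contemporaneous tips the
    phylogenetic covariance is exactly invariant, so the move mixes the
    otherwise strongly correlated root age and c_m.  Node ages tied to
    fossil attachments are left untouched; proposals that break age order
    are rejected.
    """

    name = "tree_scale"

    def __init__(self, step: float = 0.3, weight: float = 1.0) -> None:
        self.step = step
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy()
        u = rng.uniform(-self.step, self.step)
        f = math.exp(u)
        scaled = 0
        for node in new.tree.internal_nodes():
            if _age_free(node):
                node.age *= f
                scaled += 1
        if scaled == 0:
            return None
        for node in new.tree.preorder():
            if node.parent is not None and node.parent.age < node.age - _TOL:
                return None  # age order broken by fixed fossil ages
        new.bm.c_m = state.bm.c_m / f
        return new, (scaled - 1) * u


def _is_ancestor(a, b) -> bool:
    while b is not None:
        if b is a:
            return True
        b = b.parent
    return False


class NarrowExchange(Move):
    """Swap two age-compatible subtrees (symmetric selection)."""

    name = "subtree_exchange"
    changes_topology = True

    def __init__(self, weight: float = 1.0) -> None:
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy()
        nodes = [
            n
            for n in new.tree.preorder()
            if n.parent is not None and not n.sampled_ancestor
        ]
        if len(nodes) < 2:
            return None
        a = nodes[int(rng.integers(len(nodes)))]
        b = nodes[int(rng.integers(len(nodes)))]
        if a is b or a.parent is b.parent:
            return None
        if _is_ancestor(a, b) or _is_ancestor(b, a):
            return None
        pa, pb = a.parent, b.parent
        if b.age >= pa.age - _TOL or a.age >= pb.age - _TOL:
            return None
        pa.children[pa.children.index(a)] = b
        pb.children[pb.children.index(b)] = a
        a.parent, b.parent = pb, pa
        return new, 0.0


def _sa_candidates(tree: TimeTree):
    cands = []
    for tip in tree.tips():
        p = tip.parent
        if p is None or p.parent is None:
            continue
        if tip.sampled_ancestor:
            sibs = [c for c in p.children if c is not tip]
            if len(sibs) != 1:
                continue
            lo = max(tip.age, sibs[0].age)
            if p.parent.age - lo > _TOL:
                cands.append(("sa2tip", tip))
        elif tip.age > _TOL:
            sibs = [c for c in p.children if c is not tip]
            if len(sibs) != 1 or sibs[0].sampled_ancestor:
                continue
            if sibs[0].age + _TOL < tip.age < p.parent.age - _TOL:
                cands.append(("tip2sa", tip))
    return cands


class SAToggleMove(Move):
    """Reversible toggle between fossil tip and sampled-ancestor placements.

    Tip -> SA collapses the attachment node onto the fossil age
    (deterministic); SA -> tip redraws the attachment age uniformly, with the
    matching Hastings correction for the dimension change and for the change
    in the number of available toggle candidates.
    """

    name = "sa_toggle"
    changes_topology = True

    def __init__(self, weight: float = 1.0) -> None:
        self.weight = weight

    def propose(self, state, rng):
        new = state.copy()
        cands = _sa_candidates(new.tree)
        if not cands:
            return None
        kind, tip = cands[int(rng.integers(len(cands)))]
        p = tip.parent
        sib = [c for c in p.children if c is not tip][0]
        if kind == "tip2sa":
            p.age = tip.age
            tip.sampled_ancestor = True
            lo, hi = max(tip.age, sib.age), p.parent.age
            log_hr = math.log(len(cands)) - math.log(len(_sa_candidates(new.tree)))
            log_hr -= math.log(hi - lo)
        else:
            lo, hi = max(tip.age, sib.age), p.parent.age
            p.age = rng.uniform(lo, hi)
            tip.sampled_ancestor = False
            log_hr = math.log(len(cands)) - math.log(len(_sa_candidates(new.tree)))
            log_hr += math.log(hi - lo)
        return new, log_hr


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    df: pd.DataFrame
    trees: list[str]
    seed: int
    config: dict = field(default_factory=dict)

    def burned(self, fraction: float = 0.1) -> pd.DataFrame:
        start = int(len(self.df) * fraction)
        return self.df.iloc[start:]

    def to_tsv(self) -> str:
        return self.df.to_csv(sep="\t", index=False)


def _extant_bipartitions(tree: TimeTree) -> frozenset:
    extant = {
        t.label for t in tree.tips() if not t.sampled_ancestor and t.age <= _TOL
    }
    clades = _clade_map(tree)
    out = set()
    for node in tree.internal_nodes():
        c = frozenset(clades[id(node)] & extant)
        if 1 < len(c) < len(extant):
            out.add(c)
    return frozenset(out)


def _record(state: ModelState, it: int) -> dict:
    row = {
        "Sample": it,
        "posterior": (state.log_likelihood or 0.0) + (state.log_prior or 0.0),
        "likelihood": state.log_likelihood,
        "prior": state.log_prior,
        "c_m": state.bm.c_m,
        "root_age": state.tree.root.age,
        "sa_count": state.tree.count_sampled_ancestors(),
        "tree_length": state.tree.total_branch_length(),
    }
    if not isinstance(state.bm.y0, str):
        for i, v in enumerate(np.atleast_1d(state.bm.y0)):
            row[f"y0_{i+1}"] = float(v)
    if state.bm.factor is not None:
        L = state.bm.factor
        for i in range(L.shape[0]):
            for j in range(i, L.shape[1]):
                row[f"L_{i+1}_{j+1}"] = float(L[i, j])
    if state.episode is not None:
        row.update(
            lam=state.episode.lam,
            mu=state.episode.mu,
            psi=state.episode.psi,
            p_extant=state.episode.p_extant,
        )
    return row


def run_chain(
    data: CharacterMatrix | None,
    tree_init: TimeTree,
    bm_init: BMParams,
    priors: PriorSpec,
    moves: Sequence[Move],
    chain_length: int,
    sample_every: int = 10,
    seed: int = 0,
    episode: EpisodeParams | None = None,
    constraints: Sequence[CladeConstraint] = (),
    fix_extant_topology: bool = False,
    record_trees: bool = True,
) -> Trace:
    """Metropolis-Hastings sampling of the restricted total-evidence posterior.

    Deterministic given ``seed``.  Constraint-violating topology proposals
    are rejected outright.
    """
    if chain_length < 1 or sample_every < 1:
        raise ValidationError("chain_length and sample_every must be >= 1")
    if not moves:
        raise ValidationError("need at least one move")
    rng = np.random.default_rng(seed)
    state = ModelState(tree_init.copy(), bm_init, episode).copy()
    lp = log_posterior(state, data, priors)
    if not math.isfinite(lp):
        raise ValidationError(
            "initial state has zero posterior probability; re-initialize"
        )
    init_extant = _extant_bipartitions(state.tree) if fix_extant_topology else None

    for m in moves:
        if hasattr(m, "bind"):
            m.bind(data, priors)
    weights = np.array([m.weight for m in moves], dtype=float)
    weights /= weights.sum()
    rows = [_record(state, 0)]
    trees = [state.tree.newick()] if record_trees else []
    accepted = {m.name: 0 for m in moves}
    proposed = {m.name: 0 for m in moves}

    for it in range(1, chain_length + 1):
        move = moves[int(rng.choice(len(moves), p=weights))]
        proposed[move.name] += 1
        out = move.propose(state, rng)
        if out is not None:
            prop, log_hr = out
            ok = True
            if move.changes_topology:
                try:
                    ok = all(c.satisfied_by(prop.tree) for c in constraints)
                except ValidationError:
                    ok = False
                if ok and init_extant is not None:
                    ok = _extant_bipartitions(prop.tree) == init_extant
            if ok:
                lp_prop = log_posterior(prop, data, priors)
                if math.log(rng.random()) < lp_prop - lp + log_hr:
                    state, lp = prop, lp_prop
                    accepted[move.name] += 1
        if it % sample_every == 0:
            rows.append(_record(state, it))
            if record_trees:
                trees.append(state.tree.newick())

    df = pd.DataFrame(rows)
    config = {
        "chain_length": chain_length,
        "sample_every": sample_every,
        "moves": {m.name: m.weight for m in moves},
        "acceptance": {
            name: (accepted[name] / proposed[name] if proposed[name] else float("nan"))
            for name in accepted
        },
    }
    return Trace(df, trees, seed, config)
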