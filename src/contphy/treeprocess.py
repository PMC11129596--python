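"""Fossilized-birth-death and birth-death-sequential-sampling tree models.

Forward simulation is event-driven (Gillespie over lineages) with Poisson
fossilization along branches and Bernoulli extant sampling at the present,
followed by pruning of all unsampled history.  Densities follow the standard
single-lineage factorization: with

    c1 = sqrt((lambda - mu - psi)^2 + 4 lambda psi)
    c2 = -(lambda - mu - 2 lambda rho - psi) / c1
    q(t)  = 4 e^{-c1 t} / (e^{-c1 t}(1 - c2) + (1 + c2))^2
    p0(t) = prob. a lineage at age t leaves no sampled descendants

the log-density of a sampled tree with origin age x0, conditioned on at
least one sample, is

    log q(x0) - log(1 - p0(x0))
      + sum_births  [log lambda + log q(x)]
      + sum_SA      log psi
      + sum_fossil_tips [log psi + log p0(y) - log q(y)]
      + n_extant * log rho_extant

The BDSS density is defined here over left-to-right oriented trees and
differs from the FBD density by a documented orientation constant of
``-(#bifurcations) * log 2``; the direct BDSS simulator draws conditioned on
the requested sample counts and orients children by youngest descendant tip
age (ties broken by simulation event order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SimulationError, ValidationError
from .tree import Node, TimeTree

__all__ = [
    "EpisodeParams",
    "simulate_fbd",
    "simulate_bdss_direct",
    "fbd_log_density",
    "bdss_log_density",
    "count_sampled_ancestors",
]

_EXTANT_TOL = 1e-9
MAX_RETRIES = 10_000
_MAX_LINEAGES = 100_000


@dataclass
class EpisodeParams:
    """Birth/death/fossil-sampling/extant-sampling rates."""

    lam: float
    mu: float = 0.0
    psi: float = 0.0
    p_extant: float = 1.0
    origin_time: float | None = None

    def __post_init__(self) -> None:
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValidationError("speciation rate must be positive and finite")
        if self.mu < 0 or self.psi < 0:
            raise ValidationError("mu and psi must be >= 0")
        if not 0 < self.p_extant <= 1:
            raise ValidationError("p_extant must lie in (0, 1]")


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


class _Lin:
    __slots__ = ("start", "end", "fossils", "children", "extant", "order")

    def __init__(self, start: float, order: int) -> None:
        self.start = start  # forward time at which the lineage begins
        self.end: float | None = None
        self.fossils: list[float] = []
        self.children: list["_Lin"] = []
        self.extant = False  # survives to the present AND is rho-sampled
        self.order = order


def _forward_simulate(params: EpisodeParams, present: float | None, n_extant: int | None, rng):
    """Run the event loop in forward time (0 at the origin).

    Either ``present`` is fixed (origin-time conditioning) or the simulation
    stops when the number of living lineages first reaches ``n_extant``, the
    moment of that birth becoming the present.
    """
    total_event_rate = params.lam + params.mu + params.psi
    root_lin = _Lin(0.0, 0)
    alive = [root_lin]
    t = 0.0
    counter = 1
    n_created = 1
    while alive:
        if n_extant is not None and len(alive) >= n_extant:
            # stop just before the next event so pendant edges are positive
            present = t + rng.exponential(1.0 / (len(alive) * total_event_rate))
            break
        wait = rng.exponential(1.0 / (len(alive) * total_event_rate))
        t_next = t + wait
        if present is not None and t_next >= present:
            break
        t = t_next
        lin = alive[int(rng.integers(len(alive)))]
        u = rng.random() * total_event_rate
        if u < params.lam:
            lin.end = t
            alive.remove(lin)
            for _ in range(2):
                child = _Lin(t, counter)
                counter += 1
                lin.children.append(child)
                alive.append(child)
            n_created += 2
            if n_created > _MAX_LINEAGES:
                raise SimulationError("simulation exceeded the lineage cap")
        elif u < params.lam + params.mu:
            lin.end = t
            alive.remove(lin)
        else:
            lin.fossils.append(t)
    if present is None:  # n_extant mode but the process died out first
        return None, None
    for lin in alive:
        lin.end = present
        lin.extant = rng.random() < params.p_extant
    return root_lin, present


def _build_sampled(lin: _Lin, present: float) -> Node | None:
    """Prune unsampled history below ``lin``; ages are time-before-present."""
    subs = [s for s in (_build_sampled(c, present) for c in lin.children) if s is not None]
    if lin.extant:
        base: Node | None = Node(0, age=0.0)
    elif len(subs) == 2:
        base = Node(0, age=present - lin.end)
        for s in subs:
            base.add_child(s)
    elif len(subs) == 1:
        base = subs[0]
    else:
        base = None
    for f in sorted(lin.fossils, reverse=True):  # youngest first
        age = present - f
        if base is None:
            base = Node(0, age=age)
        else:
            attach = Node(0, age=age)
            attach.add_child(Node(0, age=age, sampled_ancestor=True))
            attach.add_child(base)
            base = attach
    return base


def _label_tips(tree: TimeTree) -> None:
    counters = {"T": 0, "F": 0, "A": 0}
    for node in tree.preorder():
        if node.is_tip:
            if node.sampled_ancestor:
                kind = "A"
            elif node.age <= _EXTANT_TOL:
                kind = "T"
            else:
                kind = "F"
            counters[kind] += 1
            node.label = f"{kind}{counters[kind]}"


def simulate_fbd(
    params: EpisodeParams,
    stop_time: float | None = None,
    n_extant: int | None = None,
    seed: int | None = None,
    max_retries: int = MAX_RETRIES,
    rng: np.random.Generator | None = None,
) -> TimeTree:
    """Simulate a sampled FBD tree, conditioned on at least one sample.

    Exactly one of ``stop_time`` (origin age) or ``n_extant`` (number of
    living lineages at which the simulation stops, pre-thinning) must be
    given; ``params.origin_time`` backs ``stop_time`` when both are absent.
    """
    if stop_time is None and n_extant is None:
        stop_time = params.origin_time
    if (stop_time is None) == (n_extant is None):
        raise ValidationError("specify exactly one stopping criterion")
    if stop_time is not None and stop_time <= 0:
        raise ValidationError("stop_time must be positive")
    if n_extant is not None and n_extant < 1:
        raise ValidationError("n_extant must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        root_lin, present = _forward_simulate(params, stop_time, n_extant, rng)
        if root_lin is None:
            continue
        root = _build_sampled(root_lin, present)
        if root is None:
            continue
        tree = TimeTree(root)
        _label_tips(tree)
        tree.reindex()
        tree.validate()
        return tree
    raise SimulationError(f"no surviving sample in {max_retries} attempts")


def _sample_counts(tree: TimeTree) -> tuple[int, int]:
    extant = sum(1 for t in tree.tips() if not t.sampled_ancestor and t.age <= _EXTANT_TOL)
    fossil = tree.n_tips() - extant
    return extant, fossil


def _orient(tree: TimeTree) -> None:
    """Order children left-to-right by youngest descendant tip age."""
    youngest: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            youngest[id(node)] = node.age
        else:
            youngest[id(node)] = min(youngest[id(c)] for c in node.children)
    for node in tree.preorder():
        node.children.sort(key=lambda c: youngest[id(c)])


def simulate_bdss_direct(
    params: EpisodeParams,
    n_extant: int,
    n_fossil: int = 0,
    seed: int | None = None,
    max_retries: int = MAX_RETRIES,
) -> TimeTree:
    """Draw a tree conditioned on its sample counts and tip-time orientation.

    Implemented as exact rejection sampling of the forward process (origin
    fixed at ``params.origin_time``) on the requested number of extant
    samples and fossil samples (fossil tips + sampled ancestors combined).
    """
    if params.origin_time is None:
        raise ValidationError("BDSS simulation requires params.origin_time")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        try:
            tree = simulate_fbd(params, stop_time=params.origin_time, max_retries=1, rng=rng)
        except SimulationError:
            continue
        extant, fossil = _sample_counts(tree)
        if extant == n_extant and fossil == n_fossil:
            _orient(tree)
            tree.reindex()
            return tree
    raise SimulationError(
        f"no tree with {n_extant} extant / {n_fossil} fossil samples "
        f"in {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def _c1c2(params: EpisodeParams) -> tuple[float, float]:
    lam, mu, psi, rho = params.lam, params.mu, params.psi, params.p_extant
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
    if c1 <= 0:
        raise ValidationError("degenerate process (c1 = 0) is not supported")
    c2 = -(lam - mu - 2 * lam * rho - psi) / c1
    return c1, c2


def _log_q(t: float, c1: float, c2: float) -> float:
    return math.log(4.0) - c1 * t - 2.0 * math.log(math.exp(-c1 * t) * (1 - c2) + (1 + c2))


def _p0(t: float, params: EpisodeParams, c1: float, c2: float) -> float:
    lam, mu, psi = params.lam, params.mu, params.psi
    e = math.exp(-c1 * t)
    frac = (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))
    return (lam + mu + psi + c1 * frac) / (2 * lam)


def fbd_log_density(tree: TimeTree, params: EpisodeParams) -> float:
    """Log-prior of a sampled tree under the FBD process.

    Conditioned on the origin age (``params.origin_time``, defaulting to the
    root age) and on at least one sample.  Trees impossible under the
    parameters (e.g. fossils with psi = 0) score ``-inf``.
    """
    c1, c2 = _c1c2(params)
    x0 = params.origin_time if params.origin_time is not None else tree.root.age
    if tree.root.age > x0 + _EXTANT_TOL:
        return -math.inf
    logf = _log_q(x0, c1, c2) - math.log1p(-_p0(x0, params, c1, c2))
    for node in tree.preorder():
        if node.is_tip:
            if node.sampled_ancestor:
                if params.psi == 0:
                    return -math.inf
                logf += math.log(params.psi)
            elif node.age <= _EXTANT_TOL:
                logf += math.log(params.p_extant)
            else:
                if params.psi == 0:
                    return -math.inf
                p0y = _p0(node.age, params, c1, c2)
                if p0y <= 0:
                    return -math.inf
                logf += math.log(params.psi) + math.log(p0y) - _log_q(node.age, c1, c2)
        else:
            if len(node.children) != 2:
                raise ValidationError("density requires binary (or SA degree-2) nodes")
            sa_children = [c for c in node.children if c.sampled_ancestor]
            if len(sa_children) > 1:
                return -math.inf
            if not sa_children:  # genuine bifurcation
                logf += math.log(params.lam) + _log_q(node.age, c1, c2)
            # SA attachment nodes contribute only the SA's psi factor (above)
    return logf


def _n_bifurcations(tree: TimeTree) -> int:
    return sum(
        1
        for node in tree.internal_nodes()
        if not any(c.sampled_ancestor for c in node.children)
    )


def bdss_log_density(tree: TimeTree, params: EpisodeParams) -> float:
    """Log-prior over left-to-right oriented trees.

    Equals :func:`fbd_log_density` minus ``(#bifurcations) * log 2`` — each
    bifurcation carries a uniform choice between its two planar embeddings,
    of which the tip-time orientation fixes one.
    """
    base = fbd_log_density(tree, params)
    if not math.isfinite(base):
        return base
    return base - _n_bifurcations(tree) * math.log(2.0)


def count_sampled_ancestors(tree: TimeTree) -> int:
    """Number of fossils placed as direct ancestors (degree-2 samples)."""
    return tree.count_sampled_ancestors()
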