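"""Well-calibrated coverage and accuracy/precision simulation studies.

The coverage study draws parameters from the same priors used in inference
(tree-process rates drawn per replicate are conditioned on — fixed — during
inference, which preserves calibration), simulates a fossilized-birth-death
tree and correlated BM characters, runs MCMC, and counts replicates whose
95%-HPD interval contains the simulated truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..bm import BMParams
from ..errors import SimulationError
from ..simdata import simulate_bm, simulate_mixture
from ..tree import TimeTree, parse_tree, prune_taxa, _clade_map
from ..treeprocess import EpisodeParams, simulate_fbd
from .mcmc import (
    CmGibbsMove,
    Move,
    NodeAgeMove,
    RootScaleMove,
    ScalarScaleMove,
    TreeScaleMove,
    Y0GibbsMove,
    Y0WalkMove,
    run_chain,
)
from .priors import LogNormalPrior, NormalPrior, Prior, PriorSpec
from .summaries import ess, hpd_interval

__all__ = ["CoverageConfig", "CoverageResult", "coverage_study", "AccuracyScenario", "accuracy_study"]


@dataclass
class CoverageConfig:
    """Reduced-scale configuration mirroring the method-validation study."""

    episode: EpisodeParams = field(
        default_factory=lambda: EpisodeParams(lam=1.0, mu=0.25, psi=0.1, p_extant=1.0, origin_time=3.0)
    )
    lam_hyper: Prior | None = field(default_factory=lambda: LogNormalPrior(0.0, 0.25))
    k: int = 4
    pairwise_corr: float = 0.5
    c_m_prior: Prior = field(default_factory=lambda: LogNormalPrior(0.0, 0.5))
    y0_prior: Prior = field(default_factory=lambda: NormalPrior(0.0, 1.0))
    tip_window: tuple[int, int] = (5, 14)
    sample_node_ages: bool = True
    chain_length: int = 12000
    sample_every: int = 8
    burnin: float = 0.1
    hpd_level: float = 0.95
    ess_target: float = 200.0
    max_doublings: int = 2
    wrong_c_m_prior: Prior | None = None  # miscalibration control (inference-side)


@dataclass
class CoverageResult:
    table: pd.DataFrame  # per parameter: n, coverage_count, mean_abs_error, mean_width
    replicates: pd.DataFrame
    n_excluded: int


def _corr_matrix(k: int, pairwise: float) -> np.ndarray:
    rho = np.full((k, k), pairwise)
    np.fill_diagonal(rho, 1.0)
    return rho


def _draw_tree(cfg: CoverageConfig, episode: EpisodeParams, rng) -> TimeTree:
    lo, hi = cfg.tip_window
    for _ in range(1000):
        tree = simulate_fbd(episode, stop_time=episode.origin_time, rng=rng)
        if not (lo <= tree.n_tips() <= hi):
            continue
        if tree.n_tips() - tree.count_sampled_ancestors() < 2:
            continue
        # a fossil attached at the root (zero path length) makes the BM
        # covariance singular when there is no intraspecific variance
        if any(c.sampled_ancestor for c in tree.root.children):
            continue
        return tree
    raise SimulationError("could not draw a tree inside the tip-count window")


def coverage_study(
    n_reps: int,
    sim_config: CoverageConfig | None = None,
    seed: int = 0,
) -> CoverageResult:
    """Run the well-calibrated coverage experiment.

    Focal parameters: the global character evolutionary rate ``c_m``, the
    first root character value ``y0_1`` and (when node ages are sampled)
    the root age.  Non-converged replicates (focal ESS below target after
    the allowed chain doublings) are excluded and reported.
    """
    cfg = sim_config or CoverageConfig()
    params_watched = ["c_m", "y0_1"] + (["root_age"] if cfg.sample_node_ages else [])
    records = []
    n_excluded = 0
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(max(n_reps, 0))):
        rng = np.random.default_rng(child)
        episode = dataclasses.replace(cfg.episode)
        if cfg.lam_hyper is not None:
            episode.lam = cfg.lam_hyper.sample(rng)
        tree = _draw_tree(cfg, episode, rng)
        rho = _corr_matrix(cfg.k, cfg.pairwise_corr)
        c_m_true = cfg.c_m_prior.sample(rng)
        y0_true = np.array([cfg.y0_prior.sample(rng) for _ in range(cfg.k)])
        truth = {"c_m": c_m_true, "y0_1": y0_true[0], "root_age": tree.root.age}
        bm_true = BMParams(c_m=c_m_true, corr=rho, y0=y0_true)
        data = simulate_bm(tree, bm_true, rng=rng)

        priors = PriorSpec(
            c_m=cfg.wrong_c_m_prior or cfg.c_m_prior,
            y0=cfg.y0_prior,
            tree_model="fbd" if cfg.sample_node_ages else None,
        )
        moves: list[Move] = [
            CmGibbsMove(weight=2.0),
            ScalarScaleMove(step=0.5, weight=0.5),
            Y0GibbsMove(weight=1.0),
            Y0WalkMove(step=0.5, weight=0.5),
        ]
        if cfg.sample_node_ages:
            moves += [
                NodeAgeMove(weight=2.0),
                RootScaleMove(step=0.4, weight=0.5),
                TreeScaleMove(step=0.5, weight=2.0),
                TreeScaleMove(step=0.15, weight=1.0),
            ]
        bm_init = BMParams(c_m=cfg.c_m_prior.mean(), corr=rho, y0=np.zeros(cfg.k))

        chain_length = cfg.chain_length
        for attempt in range(cfg.max_doublings + 1):
            trace = run_chain(
                data,
                tree,
                bm_init,
                priors,
                moves,
                chain_length=chain_length,
                sample_every=cfg.sample_every,
                seed=int(rng.integers(2**31)),
                episode=episode if cfg.sample_node_ages else None,
                record_trees=False,
            )
            post = trace.burned(cfg.burnin)
            focal_ess = ess(post["c_m"].to_numpy())
            if focal_ess >= cfg.ess_target or attempt == cfg.max_doublings:
                break
            chain_length *= 2
        converged = focal_ess >= cfg.ess_target
        if not converged:
            n_excluded += 1
        rec = {"rep": rep, "ess_c_m": focal_ess, "converged": converged, "n_tips": tree.n_tips()}
        for name in params_watched:
            samples = post[name].to_numpy()
            lo, hi = hpd_interval(samples, cfg.hpd_level)
            rec[f"{name}_true"] = truth[name]
            rec[f"{name}_mean"] = float(samples.mean())
            rec[f"{name}_lo"], rec[f"{name}_hi"] = lo, hi
            rec[f"{name}_covered"] = bool(lo <= truth[name] <= hi)
        records.append(rec)

    reps = pd.DataFrame(records)
    rows = []
    conv = reps[reps["converged"]] if len(reps) else reps
    for name in params_watched:
        if len(conv):
            rows.append(
                {
                    "parameter": name,
                    "n": len(conv),
                    "coverage_count": int(conv[f"{name}_covered"].sum()),
                    "mean_abs_error": float(
                        (conv[f"{name}_mean"] - conv[f"{name}_true"]).abs().mean()
                    ),
                    "mean_hpd_width": float(
                        (conv[f"{name}_hi"] - conv[f"{name}_lo"]).mean()
                    ),
                }
            )
    table = pd.DataFrame(rows, columns=["parameter", "n", "coverage_count", "mean_abs_error", "mean_hpd_width"])
    return CoverageResult(table, reps, n_excluded)


# ---------------------------------------------------------------------------
# accuracy / precision study
# ---------------------------------------------------------------------------


@dataclass
class AccuracyScenario:
    """One cell of the accuracy/precision experiments.

    ``rho_true`` generates the data; ``rho_assumed`` is used in inference.
    ``w`` is the BM/white-noise mixture weight (1 = pure BM).  Fossils can be
    dropped by age with ``keep_fossils`` ("all", "oldest-half",
    "youngest-half", "none").
    """

    k: int = 4
    rho_true: float = 0.9
    rho_assumed: float = 0.9
    w: float = 1.0
    keep_fossils: str = "all"
    episode: EpisodeParams = field(
        default_factory=lambda: EpisodeParams(lam=1.0, mu=0.3, psi=0.4, p_extant=1.0, origin_time=3.0)
    )
    c_m_prior: Prior = field(default_factory=lambda: LogNormalPrior(0.0, 0.1))
    tip_window: tuple[int, int] = (6, 14)
    chain_length: int = 1500
    sample_every: int = 3
    burnin: float = 0.1


def _filter_fossils(tree: TimeTree, keep: str) -> TimeTree:
    fossils = sorted(
        (t for t in tree.tips() if t.sampled_ancestor or t.age > 1e-9),
        key=lambda t: t.age,
    )
    labels = [t.label for t in fossils]  # sorted youngest -> oldest
    if keep == "all" or not labels:
        return tree
    if keep == "none":
        drop = labels
    elif keep == "oldest-half":
        drop = labels[: len(labels) // 2]  # drop the youngest half
    elif keep == "youngest-half":
        drop = labels[len(labels) // 2 :]
    else:
        raise ValueError(f"unknown fossil filter {keep!r}")
    if not drop or tree.n_tips() - len(drop) < 2:
        return tree
    return prune_taxa(tree, drop)


def _extant_node_ages(tree: TimeTree, fossil_labels: set[str]) -> dict[frozenset, float]:
    keep = set(tree.taxon_labels()) - fossil_labels
    if len(keep) < 2:
        return {}
    pruned = prune_taxa(tree, fossil_labels & set(tree.taxon_labels()))
    clades = _clade_map(pruned)
    return {
        clades[id(n)]: n.age for n in pruned.internal_nodes()
    }


def accuracy_study(scenario: AccuracyScenario, n_reps: int, seed: int = 0) -> pd.DataFrame:
    """Per-replicate node-age accuracy (|truth - posterior mean|) and precision
    (95%-HPD width) for the root and for internal nodes averaged after fossil
    lineages are pruned off."""
    rows = []
    root_seed = np.random.SeedSequence(seed)
    for rep, child in enumerate(root_seed.spawn(n_reps)):
        rng = np.random.default_rng(child)
        lo, hi = scenario.tip_window
        for _ in range(1000):
            tree = simulate_fbd(scenario.episode, stop_time=scenario.episode.origin_time, rng=rng)
            n_extant = sum(1 for t in tree.tips() if not t.sampled_ancestor and t.age <= 1e-9)
            if (
                lo <= tree.n_tips() <= hi
                and n_extant >= 3
                and not any(c.sampled_ancestor for c in tree.root.children)
            ):
                break
        else:
            raise SimulationError("no suitable tree")
        tree = _filter_fossils(tree, scenario.keep_fossils)

        rho_t = _corr_matrix(scenario.k, scenario.rho_true)
        c_m_true = scenario.c_m_prior.sample(rng)
        y0_true = np.zeros(scenario.k)
        bm_true = BMParams(c_m=c_m_true, corr=rho_t, y0=y0_true)
        data = simulate_mixture(tree, bm_true, scenario.w, seed=int(rng.integers(2**31)))

        rho_a = _corr_matrix(scenario.k, scenario.rho_assumed)
        bm_infer = BMParams(c_m=scenario.c_m_prior.mean(), corr=rho_a, y0=y0_true.copy())
        priors = PriorSpec(c_m=scenario.c_m_prior, tree_model="fbd")
        moves = [ScalarScaleMove(step=0.5, weight=2.0), NodeAgeMove(weight=3.0), RootScaleMove(step=0.4, weight=1.0)]
        trace = run_chain(
            data,
            tree,
            bm_infer,
            priors,
            moves,
            chain_length=scenario.chain_length,
            sample_every=scenario.sample_every,
            seed=int(rng.integers(2**31)),
            episode=scenario.episode,
            record_trees=True,
        )
        nburn = int(len(trace.trees) * scenario.burnin)
        post_df = trace.burned(scenario.burnin)

        fossil_labels = {
            t.label for t in tree.tips() if t.sampled_ancestor or t.age > 1e-9
        }
        true_ages = _extant_node_ages(tree, fossil_labels)
        sampled: dict[frozenset, list[float]] = {cl: [] for cl in true_ages}
        for nwk in trace.trees[nburn:]:
            ages = _extant_node_ages(parse_tree(nwk), fossil_labels)
            for cl, lst in sampled.items():
                if cl in ages:
                    lst.append(ages[cl])

        root_true = tree.root.age
        root_samples = post_df["root_age"].to_numpy()
        r_lo, r_hi = hpd_interval(root_samples)
        node_err, node_width = [], []
        for cl, vals in sampled.items():
            if len(vals) < 2:
                continue
            lo_h, hi_h = hpd_interval(vals)
            node_err.append(abs(float(np.mean(vals)) - true_ages[cl]))
            node_width.append(hi_h - lo_h)
        rows.append(
            {
                "rep": rep,
                "root_true": root_true,
                "root_abs_error": abs(float(root_samples.mean()) - root_true),
                "root_error_pct": 100.0 * abs(float(root_samples.mean()) - root_true) / root_true,
                "root_hpd_width": r_hi - r_lo,
                "node_abs_error": float(np.mean(node_err)) if node_err else np.nan,
                "node_hpd_width": float(np.mean(node_width)) if node_width else np.nan,
            }
        )
    return pd.DataFrame(rows)
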