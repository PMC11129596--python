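import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")

from contphy.bm import BMParams, CharacterMatrix
from contphy.tree import TimeTree, parse_tree
from contphy.treeprocess import EpisodeParams, simulate_fbd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_tip_tree() -> TimeTree:
    return parse_tree("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def sa_tree() -> TimeTree:
    # F is a sampled ancestor at age 1 on the lineage leading to A
    return parse_tree("((A:1.0,F:0.0):1.0,C:2.0);")


def random_fbd_tree(rng, lam=1.0, mu=0.3, psi=0.3, origin=2.5, min_tips=2, max_tips=12,
                    allow_root_sa=True):
    """Draw a random FBD tree inside a tip-count window (test helper)."""
    params = EpisodeParams(lam=lam, mu=mu, psi=psi, p_extant=1.0, origin_time=origin)
    for _ in range(500):
        tree = simulate_fbd(params, stop_time=origin, rng=rng)
        if not (min_tips <= tree.n_tips() <= max_tips):
            continue
        if not allow_root_sa and any(c.sampled_ancestor for c in tree.root.children):
            continue
        return tree
    raise RuntimeError("no tree drawn in window")


def random_bm_params(rng, k, with_verr=False, y0_ml=False):
    """Random valid BMParams with a well-conditioned correlation matrix."""
    r = rng.uniform(0.5, 2.0, size=k)
    A = rng.standard_normal((k, k + 2))
    cov = A @ A.T + 0.5 * np.eye(k)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return BMParams(
        c_m=float(rng.uniform(0.3, 2.0)),
        r=r,
        corr=corr,
        y0="ML" if y0_ml else rng.standard_normal(k),
        sigma_intra=rng.uniform(0.1, 0.6, size=k) if with_verr else None,
    )


def random_chars(rng, tree, k) -> CharacterMatrix:
    labels = tree.taxon_labels()
    return CharacterMatrix(labels, rng.standard_normal((len(labels), k)))
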