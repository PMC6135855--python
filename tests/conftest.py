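import numpy as np
import pytest

from loopforge import fixtures, fragment_db
from loopforge.config import SearchConfig


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of
    # execution order
    return np.random.default_rng(20_240_101)


def random_flank_points(rng, n=8, spread=4.0):
    """Non-degenerate random point set resembling flank C-alphas."""
    while True:
        pts = rng.normal(scale=spread, size=(n, 3))
        centered = pts - pts.mean(axis=0)
        if np.linalg.det(centered.T @ centered) > 1.0:
            return pts


def planted_setup(tmp_path, loop_length=7, seed=1, n_decoys=4, sigma=0.0):
    """Target + planted database + gapped template, all from one seed."""
    target = fixtures.make_helix_loop_helix(loop_length, seed=seed)
    db_dir = tmp_path / f"db_{loop_length}_{seed}"
    fixtures.make_planted_db(target, n_decoys, seed=seed + 500,
                             out_dir=db_dir)
    db = fragment_db.build_database(db_dir)
    template = fixtures.perturb_template(target, sigma, seed=seed + 900)
    return target, db, template


@pytest.fixture()
def small_planted(tmp_path):
    return planted_setup(tmp_path)


@pytest.fixture(scope="session")
def default_config():
    return SearchConfig()
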