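import numpy as np
import pytest

import canopyshift as cs


@pytest.fixture(scope="session")
def default_scene():
    """Default synthetic scene: known couplings, windows and trends."""
    cfg = cs.SceneConfig(seed=1)
    lai, climate, mask, truth = cs.simulate_scene(cfg)
    return {"config": cfg, "lai": lai, "climate": climate,
            "mask": mask, "truth": truth}


@pytest.fixture(scope="session")
def default_vlai(default_scene):
    return cs.compute_vlai(default_scene["lai"])


@pytest.fixture(scope="session")
def default_attribution(default_scene, default_vlai):
    """VLAI attribution maps for every analysis month of the default scene."""
    climate = default_scene["climate"]
    return {m: cs.attribute_month(default_vlai.month_cube(m), climate, m)
            for m in range(4, 11)}


@pytest.fixture(scope="session")
def null_scene():
    """Scene with no trends and no couplings (pure noise increments)."""
    cfg = cs.null_scene_config(seed=1)
    lai, climate, mask, truth = cs.simulate_scene(cfg)
    return {"config": cfg, "lai": lai, "climate": climate,
            "mask": mask, "truth": truth}


@pytest.fixture
def small_grid():
    return cs.GridSpec(n_rows=4, n_cols=4,
                       geotransform=(0.0, 10.0, 0.0, 0.0, 0.0, -10.0),
                       crs="local-projected")


def make_lai_stack(values_by_month, grid=None, years=(2001,)):
    """Build a small LAI stack from {month: scalar or 2-D plane}."""
    months = sorted(values_by_month)
    if grid is None:
        grid = cs.GridSpec(n_rows=2, n_cols=2)
    cube = np.empty((len(years), len(months), grid.n_rows, grid.n_cols))
    for im, m in enumerate(months):
        cube[:, im] = np.broadcast_to(np.asarray(values_by_month[m], dtype=float),
                                      grid.shape)
    return cs.MonthlyStack(variable="LAI", grid=grid,
                           years=np.asarray(years), months=np.asarray(months),
                           values=cube)
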