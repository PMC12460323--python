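import numpy as np
import pandas as pd
import pytest

from spatioepi.panel import CrossSection, PanelDataset
from spatioepi.synthetic import (
    make_grid_weights,
    simulate_nonstationary_panel,
    simulate_stratified_covariate,
)


@pytest.fixture(scope="session")
def grid48():
    """6 x 8 rook lattice: the 48-unit study geometry."""
    return make_grid_weights(6, 8)


@pytest.fixture(scope="session")
def grid4x4():
    return make_grid_weights(4, 4)


def constant_panel(values_by_unit: dict, years=range(1991, 2021), covs: dict | None = None):
    """Panel whose outcome (and covariates) are constant over time per unit."""
    rows = []
    covs = covs or {}
    for u, v in values_by_unit.items():
        for y in years:
            rows.append({"unit_id": u, "year": y, "outcome": v,
                         **{k: covs[k][u] for k in covs}})
    return PanelDataset(pd.DataFrame(rows), list(covs))


@pytest.fixture(scope="session")
def planted_factor_panel():
    """48-unit, 30-year panel with one strong stratified factor (q ~ 0.8)
    and one pure-noise factor.

    The strong covariate forms four well-separated clumps; the outcome is
    built so its stratified variance ratio over those clumps is exactly 0.8.
    """
    rng = np.random.default_rng(11)
    strata = np.repeat(np.arange(4), 12)
    W = make_grid_weights(6, 8)
    units = list(W.unit_ids)
    x_strong = strata * 1.0 + rng.uniform(0.0, 0.2, size=48)
    sec, q = simulate_stratified_covariate(strata, 0.8, seed=5, unit_ids=units)
    x_noise = rng.normal(size=48)
    panel = constant_panel(
        dict(zip(units, sec.values)),
        covs={"strong": dict(zip(units, x_strong)),
              "noise": dict(zip(units, x_noise))},
    )
    return panel, strata, q


@pytest.fixture(scope="session")
def nonstationary_run():
    """The 6 x 8 x 30 coefficient-recovery benchmark input (noise sd 0.5)."""
    return simulate_nonstationary_panel(seed=7, noise_sd=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def checkerboard(nrows=4, ncols=4) -> CrossSection:
    W = make_grid_weights(nrows, ncols)
    vals = np.array(
        [1.0 if (i + j) % 2 == 0 else -1.0 for i in range(nrows) for j in range(ncols)]
    )
    return CrossSection(list(W.unit_ids), vals, "checkerboard")
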