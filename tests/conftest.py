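import numpy as np
import pytest

import eeldiet as e
from eeldiet.acquisition import sample_bounded_simplex
from eeldiet.formulations import SimplexPoint
from eeldiet.surrogate import KernelSpec
from eeldiet.synthetic import CampaignProtocol, TrialPlan


@pytest.fixture(scope="session")
def formulation_table():
    return e.load_formulations()


@pytest.fixture(scope="session")
def bounds(formulation_table):
    return e.default_bounds(formulation_table)


@pytest.fixture(scope="session")
def truth(bounds):
    return e.make_ground_truth(seed=11, bounds=bounds)


@pytest.fixture(scope="session")
def screening_campaign(truth, bounds):
    """Two single-tank screening trials: 9 synthetic diets each + references."""
    rng = np.random.default_rng(11)
    pts = sample_bounded_simplex(bounds, 18, rng)
    forms = {
        f"S{i + 1}": SimplexPoint(p / p.sum(), bounds=bounds)
        for i, p in enumerate(pts)
    }
    ids = list(forms)
    protocol = CampaignProtocol(
        trials=(
            TrialPlan("T1", tuple(ids[:9]) + ("FSD", "FSY")),
            TrialPlan("T2", tuple(ids[9:]) + ("FSD", "FSY")),
        )
    )
    records = e.simulate_campaign(truth, protocol, forms, seed=11)
    return records, forms


@pytest.fixture(scope="session")
def fast_kernels():
    """Small candidate list keeping CV selection quick in tests."""
    return [KernelSpec("rbf"), KernelSpec("matern")]


@pytest.fixture(scope="session")
def fitted_surrogates(screening_campaign, bounds, fast_kernels):
    """One fitted survival/TL surrogate pair on the early period."""
    from eeldiet.pipeline import RoundConfig, run_bo_round
    from eeldiet.acquisition import AcquisitionConfig

    records, forms = screening_campaign
    cfg = RoundConfig(
        acquisition=AcquisitionConfig(pool_size=20_000, seed=5),
        bounds=bounds,
        kernel_candidates=tuple(fast_kernels),
        n_restarts=1,
        seed=5,
    )
    return run_bo_round(records, forms, cfg), cfg
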