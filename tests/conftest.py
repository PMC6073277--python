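import numpy as np
import pytest

from mdcompare.synthetic import (ContactPlan, HBondPlan, SaltBridgePlan,
                                 SyntheticSpec, generate)


@pytest.fixture(scope="session")
def rich_spec():
    """A system exercising every planted feature at moderate length."""
    return SyntheticSpec(
        n_res_a=14, n_res_b=14, n_frames=400,
        rmsf_profile=np.full(28, 0.4),
        contact_plan=[ContactPlan(2, 2), ContactPlan(4, 4, break_frame=200)],
        hbond_plan=[HBondPlan(6, 6, persistence=0.7)],
        saltbridge_plan=[SaltBridgePlan(8, 8, distance=3.5, bidentate=True),
                         SaltBridgePlan(10, 10, distance=3.8,
                                        bidentate=False)],
        n_bridge_waters=1, n_bulk_waters=8, seed=11,
    )


@pytest.fixture(scope="session")
def rich_system(rich_spec):
    traj, truth = generate(rich_spec, with_truth=True)
    return traj, truth


@pytest.fixture(scope="session")
def static_traj():
    """Small all-features-off trajectory with zero fluctuation."""
    spec = SyntheticSpec(n_res_a=6, n_res_b=6, n_frames=10, seed=0)
    return generate(spec)
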