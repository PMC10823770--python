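import numpy as np
import pandas as pd
import pytest

from immucast import simulate_reference, simulate_study


@pytest.fixture(scope="session")
def small_reference():
    """Noiseless 6-type reference with 20 planted markers per type."""
    return simulate_reference(
        n_cell_types=6,
        n_genes=400,
        markers_per_type=20,
        marker_fc=5.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact planted-cluster study shared by feature-level tests."""
    return simulate_study(seed=3)


@pytest.fixture()
def toy_meta():
    """Two control groups x two times with three controls and two treated."""
    rows = []
    for t, key in ((3.0, "c3"), (24.0, "c24")):
        for r in range(1, 4):
            rows.append(
                {
                    "sample_id": f"ctl_{key}_{r}",
                    "compound": "vehicle",
                    "dose_group": "high",
                    "time_h": t,
                    "replicate": r,
                    "is_control": True,
                    "control_group_key": key,
                    "alt": 20.0,
                }
            )
        rows.append(
            {
                "sample_id": f"trt_{key}",
                "compound": "drugA",
                "dose_group": "high",
                "time_h": t,
                "replicate": 1,
                "is_control": False,
                "control_group_key": key,
                "alt": 120.0,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
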