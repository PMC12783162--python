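import numpy as np
import pandas as pd
import pytest

import cooccupancy as co


def make_dataset(hA, hB=None, site_covs=None, occ_covs=None):
    """Tiny in-memory dataset builder for likelihood-level tests."""
    hA = np.asarray(hA, dtype=float)
    n = hA.shape[0]
    hist = {"A": hA}
    if hB is not None:
        hist["B"] = np.asarray(hB, dtype=float)
    return co.DetectionDataset(
        site_id=np.array([f"s{i}" for i in range(n)]),
        area=np.array(["all"] * n),
        histories=hist,
        site_covariates=site_covs if site_covs is not None else pd.DataFrame(index=range(n)),
        occasion_covariates=occ_covs or {},
    )


@pytest.fixture(scope="session")
def emulation():
    return co.generate_study_emulation(seed=1)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full 768-site pipeline run shared across the suite."""
    return co.run_pipeline(co.PipelineConfig(seed=1))
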