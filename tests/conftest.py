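import warnings

import numpy as np
import pytest

from devconnectome import synthetic as syn
from devconnectome.io import Cohort, Connectome, RegionTable, ScanRecord


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    # boundary-variance warnings are expected in small simulated fits
    warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
    warnings.filterwarnings("ignore", message=".*boundary.*")
    warnings.filterwarnings(
        "ignore", category=RuntimeWarning, module="statsmodels"
    )
    yield


@pytest.fixture(scope="session")
def regions90():
    return syn.make_regions(90, seed=11)


@pytest.fixture(scope="session")
def small_cohort(regions90):
    """Modest synthetic cohort reused across read-only tests."""
    params = syn.CohortParams(n_subjects=40)
    return syn.simulate_cohort(regions90, seed=12, params=params)


@pytest.fixture(scope="session")
def expression_bundle(regions90, small_cohort):
    _, gt = small_cohort
    expr, gt_expr = syn.simulate_expression(regions90, gt.nodal_slope_field, seed=13)
    return expr, gt_expr, gt


def toy_region_table(R=4, module=None):
    rng = np.random.default_rng(0)
    half = R // 2
    pts = rng.uniform(-50, 50, (half, 3))
    pts[:, 0] = np.abs(pts[:, 0]) + 5
    centroids = np.vstack([pts, pts * [-1, 1, 1]])
    return RegionTable(
        ids=np.arange(1, R + 1),
        names=[f"r{i}" for i in range(R)],
        hemisphere=np.array(["R"] * half + ["L"] * half),
        centroids=centroids,
        module=np.asarray(module if module is not None else ["m0"] * R),
        cortical=np.ones(R, dtype=bool),
    )


def make_scan(W, subject="S0", wave=1, age=9.0, lengths=None, sex="M",
              tbv=1.2e6, centre="A"):
    return ScanRecord(
        subject_id=subject, wave=wave, age=age, sex=sex, tbv=tbv, centre=centre,
        connectome=Connectome(np.asarray(W, float), lengths),
    )
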