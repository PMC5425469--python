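import numpy as np
import pandas as pd
import pytest

from transitloss.synthetic_data import (
    DEFAULT_TRUE_RATES,
    GeneratorConfig,
    generate,
    simulate_records,
)
from transitloss.zinb_glmm import ModelSpec, fit_zinb_glmm

#: Published per-cell condemnation rates (heat-index axis), used across the
#: definitional worked-example tests.
PRINTED_HI_CR = {
    ("roaster", "baseline"): 0.00123,
    ("roaster", "moderate"): 0.00173,
    ("roaster", "hot"): 0.00098,
    ("roaster", "very_hot"): 0.00015,
    ("market", "baseline"): 0.0030,
    ("market", "moderate"): 0.0038,
    ("market", "hot"): 0.0041,
    ("market", "very_hot"): 0.0035,
    ("cull_sow", "baseline"): 0.0027,
    ("cull_sow", "moderate"): 0.0056,
    ("cull_sow", "hot"): 0.0052,
    ("cull_sow", "very_hot"): 0.0061,
}

#: Published per-cell condemnation rates (minimum-temperature axis).
PRINTED_COLD_CR = {
    ("roaster", "baseline"): 0.00123,
    ("roaster", "cool"): 0.00149,
    ("roaster", "cold"): 0.00191,
    ("roaster", "very_cold"): 0.00271,
    ("market", "baseline"): 0.0030,
    ("market", "cool"): 0.0029,
    ("market", "cold"): 0.0033,
    ("market", "very_cold"): 0.0043,
    ("cull_sow", "baseline"): 0.0027,
    ("cull_sow", "cool"): 0.0022,
    ("cull_sow", "cold"): 0.0023,
    ("cull_sow", "very_cold"): 0.0029,
}

#: Published risk ratios the CRs must reproduce after 2-decimal rounding.
PRINTED_HI_RR = {
    ("roaster", "moderate"): 1.41,
    ("roaster", "hot"): 0.80,
    ("roaster", "very_hot"): 0.12,
    ("market", "moderate"): 1.27,
    ("market", "hot"): 1.37,
    ("market", "very_hot"): 1.17,
    ("cull_sow", "moderate"): 2.07,
    ("cull_sow", "hot"): 1.93,
    ("cull_sow", "very_hot"): 2.26,
}

PRINTED_COLD_RR = {
    ("roaster", "cool"): 1.21,
    ("roaster", "cold"): 1.55,
    ("roaster", "very_cold"): 2.20,
    ("market", "cool"): 0.97,
    ("market", "cold"): 1.10,
    ("market", "very_cold"): 1.43,
    ("cull_sow", "cool"): 0.81,
    ("cull_sow", "cold"): 0.85,
    ("cull_sow", "very_cold"): 1.07,
}

#: Published revenue summary rows: (class, category) ->
#: (increased condemns, foregone USD thousands, head thousands, percent).
PRINTED_REVENUE = {
    ("roaster", "very_cold"): (260, 14.6, 134, 0.194),
    ("roaster", "cold"): (2_303, 124.1, 1_236, 0.186),
    ("roaster", "cool"): (1_256, 71.3, 897, 0.140),
    ("roaster", "moderate"): (125, 7.9, 136, 0.092),
    ("roaster", "hot"): (62, 4.4, 161, 0.039),
    ("roaster", "very_hot"): (1, 0.05, 51, 0.001),
    ("market", "very_cold"): (11_650, 1_945.1, 46_109, 0.025),
    ("market", "cold"): (46_913, 8_231.3, 216_300, 0.022),
    ("market", "cool"): (22_790, 4_210.6, 123_649, 0.018),
    ("market", "moderate"): (5_917, 1_165.4, 8_350, 0.071),
    ("market", "hot"): (10_720, 2_075.9, 14_432, 0.074),
    ("market", "very_hot"): (283, 53.7, 2_102, 0.014),
    ("cull_sow", "very_cold"): (834, 231.1, 520, 0.160),
    ("cull_sow", "cold"): (7_131, 1_793.6, 6_057, 0.118),
    ("cull_sow", "cool"): (7_500, 1_982.3, 4_133, 0.181),
    ("cull_sow", "moderate"): (992, 262.7, 368, 0.334),
    ("cull_sow", "hot"): (2_275, 538.2, 682, 0.269),
    ("cull_sow", "very_hot"): (814, 211.6, 154, 0.528),
}


@pytest.fixture(scope="session")
def recovery():
    """Full-design parameter-recovery dataset: 5 groups x 2,000 rows each.

    Generating values are the published per-cell rates with theta=1.5,
    pi=0.45, sigma_u=0.3; the fit is shared by several tests.
    """
    records, truth = simulate_records(seed=20100104, n_rows=10_000)
    fit = fit_zinb_glmm(records, ModelSpec(), quad_points=15)
    return {"records": records, "truth": truth, "fit": fit}


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully featured synthetic bundle (40 plants x 2 years)."""
    return generate(GeneratorConfig(seed=7, n_plants=40, years=2))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete pipeline run on a small synthetic configuration."""
    from transitloss.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        outdir=str(outdir),
        seed=5,
        synthetic={"n_plants": 40, "years": 2},
        quad_points=9,
    )
    manifest = run_pipeline(cfg)
    return {"config": cfg, "manifest": manifest, "outdir": outdir}
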