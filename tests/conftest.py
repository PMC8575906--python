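"""Shared fixtures: one default synthetic cohort, generated once per session."""

import numpy as np
import pandas as pd
import pytest

from ovodyn import core_types, fecundity, stereology, synthetic, ultrametric

COHORT_SEED = 42


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SyntheticDataset:
    return synthetic.generate_dataset(synthetic.SimulationConfig(), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def pipeline_tables(default_dataset):
    """ORC, OPD and fecundity tables computed once from the default cohort."""
    ds = default_dataset
    orc_df, reports = ultrametric.orc_table(ds.wholemount, ds.females)
    samples = core_types.histology_samples(ds.histology_hits, ds.histology_axes)
    stages = ds.females.set_index("female_id")["maturity_stage"].to_dict()
    opd_df = stereology.opd_tables(samples.values(), stages)
    fec_df = fecundity.fecundity_table(opd_df, ds.females)
    return {
        "dataset": ds,
        "orc": orc_df,
        "cleaning": reports,
        "opd": opd_df,
        "fecundity": fec_df,
    }
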