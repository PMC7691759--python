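"""Shared fixtures: small simulated datasets with known truth."""

import pandas as pd
import pytest

from metgains import SimConfig, generate_met


@pytest.fixture(scope="session")
def small_met():
    """3 LYE sites x 10 genotypes x 2 reps, one series, no sub-block noise."""
    cfg = SimConfig(
        n_series=1,
        sites_per_class=(3, 0, 0),
        entries_per_trial=10,
        n_checks=2,
        n_subblocks=2,
        sigma2_subblock=0.0,
        seed=20,
    )
    plots, truth = generate_met(cfg)
    return plots, truth


@pytest.fixture(scope="session")
def one_trial():
    """A single 20-entry trial with all variance components active."""
    cfg = SimConfig(
        n_series=1,
        sites_per_class=(1, 0, 0),
        entries_per_trial=20,
        n_checks=2,
        n_subblocks=4,
        seed=21,
    )
    plots, _ = generate_met(cfg)
    return plots


def make_plots(records):
    """Plot table from (trial, series, site, geno, check, rep, sb, yield) tuples."""
    return pd.DataFrame(
        records,
        columns=[
            "trial_id",
            "series",
            "site_id",
            "genotype_id",
            "is_check",
            "replicate",
            "sub_block",
            "yield_t_ha",
        ],
    )
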