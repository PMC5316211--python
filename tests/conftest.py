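"""Shared fixtures: small simulated cohorts reused across test modules."""

import warnings

import pandas as pd
import pytest

import omicsweave as ow
from omicsweave.peaks import assign_peaks, filter_peaks


def abundance_table(bundle: ow.CohortBundle) -> pd.DataFrame:
    """samples x metabolites abundance table from a cohort bundle."""
    filtered = filter_peaks(bundle.peaks)
    assigned = assign_peaks(filtered, bundle.reference)
    return pd.DataFrame({m: assigned.abundance_of(m)
                         for m in assigned.assigned_metabolites})


@pytest.fixture(scope="session")
def planted_bundle() -> ow.CohortBundle:
    """Default study conditions: 10 horses, 54 peaks, planted structure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ow.simulate(ow.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def null_bundle() -> ow.CohortBundle:
    """Pure-null cohort: no planted metabolites, DE features or regulators."""
    cfg = ow.SyntheticConfig(
        n_horses=20, n_metabolites=40, n_genes=2000, n_mirnas=200,
        n_pathways=8, genes_per_pathway=20, n_active_metabolites=0,
        n_active_regulators=0, frac_de_genes=0.0, seed=77)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ow.simulate(cfg)
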