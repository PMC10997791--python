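"""Shared fixtures: small record builders and null-simulation tables."""

import numpy as np
import pytest

from hetfdr.core_stats import GroupAssociation, PhenotypeRecord, compute_stat_table


def make_records(beta_a, se_a, beta_b, se_b, n_a=1000, n_b=4000, kind="continuous"):
    """Paired records from parallel arrays of per-group estimates."""
    beta_a, beta_b = np.atleast_1d(beta_a), np.atleast_1d(beta_b)
    se_a, se_b = np.broadcast_to(se_a, beta_a.shape), np.broadcast_to(se_b, beta_b.shape)
    return [
        PhenotypeRecord(
            phenotype_id=f"p{i:05d}",
            trait_kind=kind,
            assoc_a=GroupAssociation("AFR", float(beta_a[i]), float(se_a[i]), n_a),
            assoc_b=GroupAssociation("EUR", float(beta_b[i]), float(se_b[i]), n_b),
        )
        for i in range(len(beta_a))
    ]


@pytest.fixture(scope="session")
def null_stat_table():
    """Step-I table for 10,000 phenotypes with no effect in either group."""
    rng = np.random.default_rng(2024)
    m = 10_000
    se_a, se_b = 0.02, 0.01
    records = make_records(
        rng.normal(0.0, se_a, m), se_a, rng.normal(0.0, se_b, m), se_b
    )
    return compute_stat_table(records)
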