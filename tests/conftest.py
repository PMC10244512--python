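import numpy as np
import pandas as pd
import pytest

import radml as r
from radml import cis_correlation as cc
from radml import dml_calling as dml
from radml import expression_de as de


@pytest.fixture(scope="session")
def fixture_pair():
    """The deterministic demonstration cohort pair."""
    return r.generate_demo_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_run(fixture_pair):
    """The demonstration fixture run end-to-end; shared across tests."""
    disc, valid = fixture_pair
    records = dml.call_radml(disc.beta, disc.meta)
    radmls = dml.radml_subset(records)
    survivors, cascade = dml.noncoding_filter_cascade(
        radmls, disc.manifest, disc.genes
    )
    probes = {p.probe_id: p for p in disc.manifest}
    surv_probes = [probes[s.probe_id] for s in survivors]
    pairs = cc.correlate_pairs(
        cc.enumerate_cis_pairs(surv_probes, disc.genes),
        disc.beta,
        de.log_cpm(disc.counts),
    )
    sig = cc.significant_pairs(pairs)
    replicated = cc.replicate_pairs(sig, valid.beta, de.log_cpm(valid.counts))
    valid_records = dml.radml_subset(dml.call_radml(valid.beta, valid.meta))
    return {
        "discovery": disc,
        "validation": valid,
        "records": records,
        "radmls": radmls,
        "survivors": survivors,
        "cascade": cascade,
        "pairs": pairs,
        "significant": sig,
        "replicated": replicated,
        "validation_radmls": valid_records,
    }


@pytest.fixture
def tiny_beta():
    """4 probes x 10 samples with known group structure (A = s0..s4)."""
    samples = [f"s{i}" for i in range(10)]
    rows = {
        # separated: delta = +0.12, complete separation
        "cg_up": [0.56, 0.57, 0.58, 0.59, 0.60, 0.44, 0.45, 0.46, 0.47, 0.48],
        # separated the other way: delta = -0.12
        "cg_dn": [0.44, 0.45, 0.46, 0.47, 0.48, 0.56, 0.57, 0.58, 0.59, 0.60],
        # no group difference
        "cg_null": [0.50, 0.52, 0.48, 0.51, 0.49, 0.50, 0.52, 0.48, 0.51, 0.49],
        # clearly separated but delta = 0.09, below the 0.10 threshold
        "cg_small": [0.545, 0.555, 0.565, 0.575, 0.585,
                     0.455, 0.465, 0.475, 0.485, 0.495],
    }
    beta = r.BetaMatrix(pd.DataFrame(rows, index=samples).T)
    meta = [
        r.SampleMeta(s, "A" if i < 5 else "B", 50.0 + i) for i, s in enumerate(samples)
    ]
    return beta, meta


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
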