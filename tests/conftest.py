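import numpy as np
import pandas as pd
import pytest

import methdecon as md
from methdecon.matrix_io import BetaMatrix, ProbeAnnotation, SampleSheet


@pytest.fixture
def small_config():
    """Fast six-cell-type study: 1,200 probes, 6 sorted replicates per type."""
    return md.SimulationConfig(seed=11, n_probes=1200, n_mixture_samples=60)


@pytest.fixture
def small_reference(small_config):
    ref, truth = md.simulate_reference(small_config)
    return ref, truth


@pytest.fixture
def small_signature(small_reference):
    ref, truth = small_reference
    return md.select_signature(md.one_vs_rest_tstats(ref), ref)


@pytest.fixture
def toy_beta():
    """3-probe x 4-sample beta matrix with exact values."""
    return BetaMatrix(
        values=pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4], [0.5, 0.5, 0.5, 0.5], [0.9, 0.8, 0.7, 0.6]],
            index=["cg1", "cg2", "cg3"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def toy_annotation():
    return ProbeAnnotation(
        table=pd.DataFrame(
            {
                "chromosome": ["chr1", "chrX", "chr2"],
                "snp_at_cpg": [False, True, False],
                "snp_at_sbe": [False, False, False],
                "snp_in_probe": [False, False, True],
                "gene_id": ["g1", "g2", None],
            },
            index=["cg1", "cg2", "cg3"],
        )
    )


@pytest.fixture
def toy_sheet():
    return SampleSheet(
        table=pd.DataFrame(
            {"age": [30.0, 40.0, 50.0, 60.0], "cell_type": ["A", "A", "B", "B"]},
            index=["s1", "s2", "s3", "s4"],
        )
    )


def make_sorted_reference(
    rng, n_probes=200, cell_types=("A", "B", "C"), n_rep=4, sd=0.02, ages=None
):
    """Hand-rolled sorted reference with no planted structure (null probes)."""
    cols, labels, age_map = {}, {}, {}
    base = rng.uniform(0.2, 0.8, n_probes)
    if ages is None:
        ages = rng.uniform(20, 60, n_rep)
    for ct in cell_types:
        for r in range(n_rep):
            sid = f"{ct}_{r}"
            cols[sid] = np.clip(base + rng.normal(0, sd, n_probes), 0.01, 0.99)
            labels[sid] = ct
            age_map[sid] = ages[r]
    beta = BetaMatrix(
        values=pd.DataFrame(cols, index=[f"cg{i:05d}" for i in range(n_probes)])
    )
    return md.SortedReference(
        beta=beta, labels=pd.Series(labels), ages=pd.Series(age_map)
    )
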