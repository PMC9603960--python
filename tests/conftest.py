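import numpy as np
import pandas as pd
import pytest

import cernakit as ck

SAMPLES = ["H1", "H2", "H3", "L1", "L2", "L3"]
GROUPS = {s: s[0] for s in SAMPLES}


def make_matrix(values, feature_ids=None, layer="counts"):
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    ncol = values.shape[1]
    if ncol <= 6:
        cols = SAMPLES[:ncol]
    else:  # wider designs: alternate H/L sample labels
        cols = [f"{'H' if i % 2 == 0 else 'L'}{i}" for i in range(ncol)]
    df = pd.DataFrame(values, index=feature_ids, columns=cols)
    groups = {s: s[0] for s in df.columns}
    return ck.ExpressionMatrix(df, groups, layer=layer)


@pytest.fixture(scope="session")
def small_config():
    # desk-scale dataset: quick but large enough to exercise every stage
    return ck.SimulationConfig(
        n_mrna=150, n_lncrna=80, n_circrna=60, n_mirna=30,
        n_lnc_triplets=4, n_circ_triplets=2, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ck.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    ds = small_dataset
    return ck.run_pipeline(
        ds.matrices, ds.lengths, ds.biotypes, ds.target_pairs,
        mirna_seqs=ds.mirna_seqs, target_seqs=ds.target_seqs,
    )
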