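import numpy as np
import pandas as pd
import pytest

import reosig as rs


@pytest.fixture(scope="session")
def sim47():
    """A small simulated training cohort: 400 genes x 47 samples (36/11)."""
    cfg = rs.SimConfig(
        n_genes=400, n_samples=47, n_responders=36,
        n_planted_pairs=3, planted_flip_prob=0.05,
        n_response_genes=20, seed=11,
    )
    expr, clinical, truth = rs.simulate_dataset(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture(scope="session")
def labels47(sim47):
    _, _, clinical, _ = sim47
    return rs.derive_labels(clinical)


@pytest.fixture()
def tiny_expr():
    """Hand-built 4-gene x 4-sample matrix for exact-value tests."""
    data = pd.DataFrame(
        [[5.0, 6.0, 1.0, 3.0],
         [3.0, 4.0, 2.0, 2.0],
         [7.0, 1.0, 8.0, 6.0],
         [2.0, 9.0, 4.0, 1.0]],
        index=["A", "B", "C", "D"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return rs.ExpressionMatrix(data)


def make_labels(sample_ids, responder_flags):
    flags = np.asarray(responder_flags, dtype=bool)
    return rs.ResponseLabels(
        labels=pd.Series(
            np.where(flags, "responder", "non_responder"), index=list(sample_ids)
        )
    )
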