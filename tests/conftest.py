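import numpy as np
import pytest

import ifnprog as ip


@pytest.fixture
def small_expr():
    """3 target genes + reference over 4 samples, with scattered missing Ct."""
    return ip.ExpressionMatrix(
        genes=["g1", "g2", "g3", "REF"],
        samples=["s1", "s2", "s3", "s4"],
        ct=np.array(
            [
                [25.0, 22.0, 24.0, np.nan],
                [20.0, 21.0, np.nan, 23.0],
                [27.0, 26.5, 25.0, 24.0],
                [20.0, 20.0, 20.0, 20.0],
            ]
        ),
        reference_gene="REF",
    )


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared read-only across tests."""
    return ip.generate(ip.default_config(seed=11))


@pytest.fixture(scope="session")
def cohort_scores(cohort):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dct = ip.compute_delta_ct(cohort.expression)
        return ip.compute_scores(dct, cohort.partition).to_frame()
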