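import pytest

from covertsearch import TrialCondition, load_params, simulate_batch


@pytest.fixture(scope="session")
def p11():
    return load_params("m11")


@pytest.fixture(scope="session")
def p12():
    return load_params("m12")


@pytest.fixture(scope="session")
def table_batches(p11, p12):
    """6000-trial-per-condition batches for both subjects and all set sizes.

    One batch per (subject, set size), each pooling the congruent (target
    upper right, right-facing E) and incongruent (target upper left,
    right-facing E) conditions, with mean LIP trajectories recorded.
    """
    out = {}
    for name, params in (("m11", p11), ("m12", p12)):
        for ss in (2, 4, 6):
            conds = [TrialCondition(ss, "R1", "E_right"),
                     TrialCondition(ss, "L1", "E_right")]
            out[(name, ss)] = simulate_batch(
                params, conds, 6000, seed=20250 + ss,
                record_trajectories=True)
    return out
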