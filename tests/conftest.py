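import pytest

import imprintatlas as ia


@pytest.fixture(scope="session")
def sim_config():
    return ia.SimConfig(seed=11)


@pytest.fixture(scope="session")
def expr_sim(sim_config):
    return ia.simulate_reciprocal_expression(sim_config)


@pytest.fixture(scope="session")
def meth_sim(sim_config):
    return ia.simulate_methylomes(sim_config)


@pytest.fixture(scope="session")
def mark_sim(sim_config):
    return ia.simulate_mark_tracks(sim_config)


@pytest.fixture(scope="session")
def epc_matrix(expr_sim):
    """Paternal-ratio matrix for the extraembryonic (EPC) samples."""
    rec = ia.annotate_expression(
        expr_sim.counts[expr_sim.counts.tissue == "EPC"], expr_sim.annotation)
    return ia.build_ratio_matrix(rec)


@pytest.fixture(scope="session")
def epiblast_matrix(expr_sim):
    rec = ia.annotate_expression(
        expr_sim.counts[expr_sim.counts.tissue == "epiblast"],
        expr_sim.annotation)
    return ia.build_ratio_matrix(rec)


def jaccard(a, b):
    """Interval Jaccard overlap for (start, end) pairs."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
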