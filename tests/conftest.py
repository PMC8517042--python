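import numpy as np
import pandas as pd
import pytest

from usvsyntax.call_dataset import CallSequence


def make_sequence(
    calls,
    pup_id="p1",
    genotype="WT",
    age="P8",
    duration=30.0,
    mafmi=60.0,
) -> CallSequence:
    """Build a CallSequence with constant acoustics for structural tests."""
    n = len(calls)
    acoustics = pd.DataFrame(
        {"duration_ms": np.full(n, duration), "MaFmi_kHz": np.full(n, mafmi)}
    )
    return CallSequence(pup_id=pup_id, genotype=genotype, age=age,
                       calls=list(calls), acoustics=acoustics)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_sim_config():
    """Small, fast synthetic dataset: 6 WT + 5 DEL pups."""
    from usvsyntax.synthetic_data import SimConfig

    return SimConfig(n_pups={"WT": 6, "DEL": 5}, seed=7)
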