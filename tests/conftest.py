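import numpy as np
import pytest

from promsplice.motifscan import PWM
from promsplice.synthetic_data import SimConfig, generate_dataset


def sharp_pwm(word: str, motif_id: str = "M1", name: str = "TF1", weight: float = 197.0) -> PWM:
    """A near-deterministic PWM whose consensus is ``word``."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.ones((4, len(word)))
    for j, b in enumerate(word):
        counts[base_index[b], j] = weight
    return PWM(id=motif_id, name=name, counts=counts)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study shared by pipeline-level tests."""
    cfg = SimConfig(
        n_genes=40, n_tissues=10, n_tfs=12, n_causal_tfs=2,
        effect_size=2.0, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    from promsplice import pipeline

    profiles = pipeline.build_profiles(small_bundle)
    events, zpsi = pipeline.delta_events(small_bundle, profiles)
    return small_bundle, profiles, events, zpsi
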