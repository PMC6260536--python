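import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecgbeats as eb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_templates():
    """Noise-free rendering context: templates without RR jitter."""
    from dataclasses import replace

    return [replace(p, rr_jitter=0.0) for p in eb.default_class_params()]


@pytest.fixture(scope="session")
def mixed_record():
    """One synthetic record with all 18 classes (30 beats each, 4 for 'e')."""
    counts = {s: 30 for s in eb.BEAT_SYMBOLS}
    counts["e"] = 4
    cfg = eb.SyntheticConfig(n_beats_per_class=counts, seed=123)
    return eb.synthesize_record(cfg)


@pytest.fixture(scope="session")
def mixed_dataset(mixed_record):
    return eb.build_dataset(mixed_record)


@pytest.fixture(scope="session")
def six_class_record():
    """Six well-separated classes, 300 beats each (the end-to-end fixture)."""
    cfg = eb.SyntheticConfig(
        n_beats_per_class={s: 300 for s in ["N", "L", "V", "/", "!", "e"]}, seed=7
    )
    return eb.synthesize_record(cfg)


@pytest.fixture(scope="session")
def six_class_dataset(six_class_record):
    return eb.build_dataset(six_class_record)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
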