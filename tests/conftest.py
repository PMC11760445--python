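import numpy as np
import pytest

from glenostab.synthetic import (
    PhantomSpec,
    TestBenchSpec,
    generate_marker_recording,
    generate_phantom_ct,
)


@pytest.fixture(scope="session")
def identity_phantom():
    """Phantom scanned by an identity scanner (no gain/offset/noise)."""
    spec = PhantomSpec(noise_sd=0.0, scanner_gain=1.0, scanner_offset=0.0, seed=11)
    return generate_phantom_ct(spec)


@pytest.fixture(scope="session")
def noiseless_bench_pair():
    """Noiseless pre/post recording pair with a graft body."""
    spec = TestBenchSpec(
        elastic_amplitude_um=50.0,
        post_added_um=20.0,
        rot_amplitude_deg=0.2,
        graft_split=0.53,
        marker_noise_um=0.0,
        seed=5,
    )
    return (
        generate_marker_recording(spec, "pre"),
        generate_marker_recording(spec, "post"),
        spec,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
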