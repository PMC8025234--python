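import pytest

from synaptoquant import synthdata as sd


@pytest.fixture(scope="session")
def snr5_field():
    """A standard noisy 200-puncta field with well-separated spots."""
    spec = sd.PunctaFieldSpec(n_puncta=200, min_separation=8.0, seed=1)
    img, truth = sd.generate_puncta_field(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noiseless_field():
    spec = sd.PunctaFieldSpec(n_puncta=50, seed=2, noise=sd.NOISE_OFF)
    img, truth = sd.generate_puncta_field(spec)
    return spec, img, truth
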