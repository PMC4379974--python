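import pytest

from isgap import integrator, simfix


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free paired-assembly fixture (200 transcripts)."""
    return simfix.simulate(simfix.PRESETS["noise-free"])


@pytest.fixture(scope="session")
def noise_free_result(noise_free):
    return integrator.annotate(
        noise_free.assembly_a, noise_free.alignments, noise_free.abinitio
    )


@pytest.fixture(scope="session")
def noisy():
    """Noisy fixture: 500 transcripts, boundary jitter, ab initio errors."""
    return simfix.simulate(simfix.PRESETS["default"])


@pytest.fixture(scope="session")
def noisy_result(noisy):
    return integrator.annotate(noisy.assembly_a, noisy.alignments, noisy.abinitio)
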