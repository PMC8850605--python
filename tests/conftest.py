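import numpy as np
import pytest
from hypothesis import settings

import entosense as es

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_event(snippet, sample_rate=20000.0, peak_snr_value=50.0):
    """Wrap a (8, n) snippet array into an InsectEvent for feature tests."""
    snippet = np.asarray(snippet, dtype=float)
    return es.InsectEvent(
        start=0, end=snippet.shape[1], snippet=snippet,
        peak_snr={c: peak_snr_value for c in es.CHANNELS},
        sample_rate=sample_rate,
    )


@pytest.fixture(scope="session")
def demo_pipeline():
    """The packaged worked example run end-to-end: scene -> extraction ->
    features.  Shared across tests; everything downstream is read-only."""
    scene = es.SceneConfig(
        duration=4.0, noise_sd=1.0, insects=[es.demo_preset(t0=2.0)], seed=7,
    )
    recording, truth = es.synth_recording(scene)
    events, model = es.extract_events(recording)
    features = [es.extract_features(ev) for ev in events]
    return {
        "scene": scene, "recording": recording, "truth": truth,
        "events": events, "model": model, "features": features,
    }
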