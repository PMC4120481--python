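import pytest

from scggate import simulate as sim


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, jitter-free 30 s normal-breathing recording (12 bpm, 70 bpm HR)."""
    cfg = sim.SimConfig(
        protocol=[sim.ProtocolSegment(30.0, 12.0, 1.0, 0.0, "normal")],
        hrv_sd=0.0, ao_ac_jitter_sd=0.0, noise_sd=0.0, belt_lag=0.0, seed=3,
    )
    rec, truth = sim.simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def default_sim():
    """Full three-pattern protocol at default noise and heart-rate variability."""
    cfg = sim.SimConfig(seed=1)
    rec, truth = sim.simulate_recording(cfg)
    return cfg, rec, truth
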