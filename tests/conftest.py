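import numpy as np
import pytest

from replaydecoder import SessionConfig, SimConfig, run_session, simulate_session
from replaydecoder.ripples import RippleConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def short_session(tmp_path_factory):
    """One 60 s synthetic session replayed end to end, shared across tests.

    The ripple threshold is set well above the analytically determined noise
    ceiling (z ~ 11 over minutes of 1/f background) so detections correspond
    to injected bursts only.
    """
    d = tmp_path_factory.mktemp("session")
    sim = SimConfig(duration_s=60.0, task1_end_s=30.0, seed=11, n_ripples=3,
                    ripple_free_start_s=12.0)
    paths, truth = simulate_session(sim, d)
    cfg = SessionConfig(
        spikes_path=str(paths["spikes"]),
        lfp_path=str(paths["lfp"]),
        position_path=str(paths["position"]),
        output_path=str(d / "records.bin"),
        task1_end_s=30.0,
        ripple=RippleConfig(z_threshold=25.0),
    )
    report = run_session(cfg)
    return {"sim": sim, "paths": paths, "truth": truth, "config": cfg,
            "report": report, "records": d / "records.bin"}
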