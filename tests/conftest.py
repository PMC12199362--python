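import numpy as np
import pytest

import havokrisk as hk
from havokrisk.timeseries import EventSeries


@pytest.fixture(scope="session")
def patient_embedding():
    """One structured synthetic patient, preprocessed and delay-embedded.

    Shared across test modules: 540 days with planted 7- and 20-day cycles,
    chaotic amplitude modulation and rising-phase long events.
    """
    cfg = hk.SyntheticPatientConfig(duration_hours=24 * 540, seed=3)
    series, events, latent = hk.generate_patient(cfg, return_latent=True)
    pp = hk.preprocess_series(series)
    emb = hk.delay_embed(pp.filtered.values, d=100, k=22)
    n = emb.V.shape[0]
    cut = pp.trimmed_hours
    events_aligned = EventSeries(
        events.le_counts[cut : cut + n], events.seizure_flags[cut : cut + n]
    )
    return {
        "config": cfg,
        "series": series,
        "events": events,
        "events_aligned": events_aligned,
        "pp": pp,
        "emb": emb,
        "latent": latent,
    }


@pytest.fixture(scope="session")
def lorenz_fixture():
    """Lorenz first coordinate, standardized, with its delay embedding."""
    cfg = hk.LorenzConfig(dt=0.005, n_steps=60_000, seed=0)
    x = hk.generate_lorenz(cfg)
    x = (x - x.mean()) / x.std()
    emb = hk.delay_embed(x, d=40, k=15)
    return {"config": cfg, "x": x, "emb": emb}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
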