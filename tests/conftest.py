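import numpy as np
import pandas as pd
import pytest

from unicub.extraction import ExtractionParams
from unicub.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """20 noisy biparental nests, 60-s cadence, with injected desertions."""
    cfg = SimConfig(
        n_nests=20,
        sampling_interval_s=60,
        typical_incubation_period_d=12,
        desertion_prob=0.6,
        desertion_day_range=(3, 7),
        solo_days_range=(2.5, 5),
        nest_noise_sd=0.4,
        ambient_noise_sd=0.4,
        seed=7,
    )
    ds, ledger = generate_dataset(cfg)
    return cfg, ds, ledger


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free nests with zero exchange gaps: extraction must be exact."""
    cfg = SimConfig(
        n_nests=6,
        sampling_interval_s=60,
        typical_incubation_period_d=12,
        desertion_prob=1.0,
        desertion_day_range=(3, 6),
        solo_days_range=(2.5, 4),
        exchange_gap_min=0.0,
        seed=5,
    )
    ds, ledger = generate_dataset(cfg)
    return cfg, ds, ledger


@pytest.fixture
def exact_params():
    """Extraction parameters for exact recovery on noise-free data."""
    return ExtractionParams(smooth_window_min=1.0)


def make_trace_frame(start, n, dt_s, nest, surface):
    """Helper: build a temperature-trace DataFrame from arrays/scalars."""
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * dt_s, unit="s")
    return pd.DataFrame(
        {
            "timestamp_utc": ts,
            "nest_temp_c": np.broadcast_to(np.asarray(nest, dtype=float), n).copy(),
            "surface_temp_c": np.broadcast_to(np.asarray(surface, dtype=float), n).copy(),
        }
    )
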