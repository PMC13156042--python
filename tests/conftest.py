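import numpy as np
import pytest

from miniens import SimConfig, generate_session_pair


@pytest.fixture(scope="session")
def small_pair():
    """A modest synthetic session pair shared across matching tests."""
    cfg = SimConfig(
        n_neurons=50,
        duration_s=30.0,
        shared_fraction=0.3,
        shift_px=(3.0, -2.0),
        jitter_px=1.0,
        min_separation_px=15.0,
        fov_px=(300, 300),
        seed=42,
    )
    return generate_session_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def cluster_onsets(row: np.ndarray) -> np.ndarray:
    """Onset indices of runs of consecutive 1s in a binary event row."""
    ev = np.asarray(row).astype(bool)
    onset = ev.copy()
    onset[1:] &= ~ev[:-1]
    return np.flatnonzero(onset)


def score_detection(raster_events, spike_trains, fps, decim):
    """Cluster-level recall/precision at +/-1 decimated-point tolerance."""
    tp_r = n_spk = tp_p = n_ev = 0
    for i, train in enumerate(spike_trains):
        ev = cluster_onsets(raster_events[i])
        bins = np.floor(np.asarray(train) * fps / decim).astype(int)
        n_ev += ev.size
        n_spk += bins.size
        for b in bins:
            if ev.size and np.min(np.abs(ev - b)) <= 1:
                tp_r += 1
        for e in ev:
            if bins.size and np.min(np.abs(bins - e)) <= 1:
                tp_p += 1
    recall = tp_r / n_spk if n_spk else float("nan")
    precision = tp_p / n_ev if n_ev else float("nan")
    return recall, precision
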