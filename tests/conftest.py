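import numpy as np
import pytest

from sdckit.ethogram import BehavioralSequence, Repertoire


@pytest.fixture
def repertoire() -> Repertoire:
    return Repertoire.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_sequence(postures, subject_id="s1", window=300.0, span=None):
    """Build a valid sequence from a list of posture codes, times 1 s apart."""
    events = [(float(i), p) for i, p in enumerate(postures)]
    return BehavioralSequence(
        subject_id=subject_id, events=events, window_length=window, observed_span=span
    )


def random_sequence(rng, repertoire, n_events, subject_id="r1", window=300.0):
    """A random sequence over the repertoire (uniform iid postures)."""
    codes = [repertoire.labels[i] for i in rng.integers(0, len(repertoire), n_events)]
    times = np.sort(rng.uniform(0, window, n_events))
    times = np.maximum.accumulate(times + np.arange(n_events) * 1e-9)
    return BehavioralSequence(
        subject_id=subject_id,
        events=list(zip(times.tolist(), codes)),
        window_length=window,
        observed_span=window,
    )
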