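import numpy as np
import pytest

from afburden import EpochStream
from afburden.streams import AF, INVALID, SINUS

CODE = {"A": AF, "S": SINUS, "I": INVALID}


def stream_from_string(s: str, start: str = "2024-01-01T00:00", **kw) -> EpochStream:
    """Compact stream builder: 'AASIA' -> AF,AF,SINUS,INVALID,AF."""
    return EpochStream.from_labels([CODE[c] for c in s], start=start, **kw)


def random_stream(rng: np.random.Generator, n: int, p_af=0.3, p_invalid=0.2,
                  start="2024-01-01T00:00") -> EpochStream:
    labels = rng.choice([AF, SINUS, INVALID], size=n,
                        p=[p_af, 1 - p_af - p_invalid, p_invalid])
    pulse = rng.uniform(50, 160, n)
    return EpochStream.from_labels(labels, start=start, pulse_bpm=pulse)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
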