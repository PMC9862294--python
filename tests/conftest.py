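import numpy as np
import pytest

import slowave as sw


@pytest.fixture(scope="session")
def small_spec():
    # 9 channels (one per area), 30 s: big enough for MPF windows,
    # too short for the default 825-tap filters (use filter-free configs)
    return sw.SynthSpec(n_channels=9, duration_s=30.0, seed=11)


@pytest.fixture(scope="session")
def small_background(small_spec):
    return sw.generate_background(small_spec)


@pytest.fixture(scope="session")
def montage():
    return sw.default_montage()


@pytest.fixture(scope="session")
def full_background():
    return sw.generate_background(sw.SynthSpec(n_channels=60, duration_s=240.0, seed=21))


def mpf_oracle(freqs, power, fmin, fmax):
    """Brute-force cumulative half-power search with linear interpolation.

    Independent loop-based implementation of the stated MPF convention.
    """
    pairs = [
        (float(f), float(p))
        for f, p in zip(freqs, power)
        if fmin - 1e-12 <= f <= fmax + 1e-12
    ]
    cum = 0.0
    for _, p in pairs:
        cum += p
    total = cum
    if total <= 0:
        return float("nan")
    half = total / 2.0
    cum = 0.0
    for k, (f, p) in enumerate(pairs):
        if cum + p >= half:
            if k == 0:
                return f
            f_prev = pairs[k - 1][0]
            frac = (half - cum) / p
            return f_prev + (f - f_prev) * frac
        cum += p
    return pairs[-1][0]


@pytest.fixture(scope="session")
def sine_recording():
    """Two identical 10 Hz channels, 60 s at 250 Hz."""
    t = np.arange(60 * 250) / 250.0
    x = np.sin(2 * np.pi * 10 * t)
    return sw.Recording(
        samples=np.vstack([x, x]),
        fs=250.0,
        labels=("F3", "F4"),
        types=("EEG", "EEG"),
    )
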