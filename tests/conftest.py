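import numpy as np
import pytest

from ribbit import FrequencyBand, Spectrogram, load_profile


@pytest.fixture(scope="session")
def boreal():
    return load_profile("boreal_chorus_frog")


@pytest.fixture(scope="session")
def harlequin():
    return load_profile("variable_harlequin_frog")


@pytest.fixture
def toy_spectrogram():
    """4-frequency-row spectrogram builder for hand-checkable band sums.

    Bin centers sit at 0, 1, 2, 3 Hz with an 8 Hz sample rate, so
    signal band [0.5, 2.5] -> rows {1, 2} and noise bands [0, 0.4] /
    [2.6, 3.5] -> rows {0} and {3}.
    """

    def build(columns):
        values = np.asarray(columns, dtype=float).T  # rows = freq, cols = time
        n = values.shape[1]
        return Spectrogram(
            values=values,
            freq_axis=np.array([0.0, 1.0, 2.0, 3.0]),
            time_axis=np.arange(n, dtype=float),
            window_samples=2,
            overlap_samples=0,
            sample_rate=8.0,
        )

    return build


@pytest.fixture
def toy_bands():
    return dict(
        signal=FrequencyBand(0.5, 2.5),
        noise=(FrequencyBand(0.0, 0.4), FrequencyBand(2.6, 3.5)),
    )
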