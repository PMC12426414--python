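import numpy as np
import pytest

from tmsreact import Montage
from tmsreact.containers import RestingRecording


@pytest.fixture(scope="session")
def montage():
    return Montage()


@pytest.fixture
def tiny_montage():
    return Montage(names=("A", "B", "C", "D"), clusters={"pair": ("A", "B")})


def make_recording(data, fs=1000.0, names=None):
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    return RestingRecording(np.asarray(data, float), fs,
                            Montage(names=names, clusters={}))


@pytest.fixture
def make_rec():
    return make_recording
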