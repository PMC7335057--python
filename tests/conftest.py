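import numpy as np
import pytest

from pupilbench.preprocessing import PupilTrace


def make_trace(diameter_mm, fs=120.0, quality=None, blink=None, t0=0.0, meta=None):
    """Build a PupilTrace from a diameter array with clean defaults."""
    d = np.asarray(diameter_mm, dtype=float)
    n = d.size
    return PupilTrace(
        time_s=t0 + np.arange(n) / fs,
        diameter_mm=d,
        quality_pct=np.full(n, 100.0) if quality is None else np.asarray(quality, float),
        blink=np.zeros(n, dtype=bool) if blink is None else np.asarray(blink, bool),
        meta=meta or {},
    )


@pytest.fixture(scope="session")
def channels():
    from pupilbench.synthetic import default_channels

    return default_channels()


@pytest.fixture(scope="session")
def study_spectra():
    from pupilbench.study import default_study_spectra

    return default_study_spectra()


@pytest.fixture(scope="session")
def study_metrics(study_spectra):
    from pupilbench.colorimetry import stimulus_metrics

    return {lbl: stimulus_metrics(sp) for lbl, sp in study_spectra.items()}
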