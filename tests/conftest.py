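import numpy as np
import pytest

from sleeptopo import ACEParams, CohortSpec, Hypnogram, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ace():
    """The reference ACE decomposition used throughout the spec examples."""
    return ACEParams(a2=0.5, c2=0.3, e2=0.2, template_var=0.0,
                     n_channels=58, smoothness=1)


def make_recording(samples, fs=250.0, labels=None, **kw):
    samples = np.atleast_2d(samples)
    if labels is None:
        labels = [f"E{i + 1}" for i in range(samples.shape[0])]
    return Recording(samples=samples, sampling_rate=fs,
                     channel_labels=labels, **kw)


def make_hypnogram(stages):
    return Hypnogram(stages=np.array(stages, dtype=object))


@pytest.fixture
def fast_transitions():
    """Stage-transition rows with a quickly reached NREM/REM mixture."""
    row = {"S2": 0.40, "SWS": 0.15, "REM": 0.45}
    return {s: dict(row) for s in
            ("Wake", "S1", "S2", "SWS", "REM", "Movement")}


def pair_correlations(maps, truth, band="delta", time_point=1):
    """Per-group within-pair correlations of generated maps."""
    idx = {(m.subject_id, m.time_point): m for m in maps}
    out = {"MZ": [], "DZ": []}
    for fam, s1, s2, zyg in truth.pairs:
        a = idx[(s1, time_point)].band(band)
        b = idx[(s2, time_point)].band(band)
        out[zyg].append(float(np.corrcoef(a, b)[0, 1]))
    return out
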