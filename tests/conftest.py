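import numpy as np
import pytest

from masynth import MAResult, Study


@pytest.fixture
def rng():
    return np.random.default_rng(20230821)


def make_studies(effects, ses, prefix="s"):
    return [
        Study(effect=float(y), within_se=float(s), study_id=f"{prefix}{i}")
        for i, (y, s) in enumerate(zip(effects, ses))
    ]


def make_results(means, ses):
    return [MAResult.from_summary(m, s) for m, s in zip(means, ses)]
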