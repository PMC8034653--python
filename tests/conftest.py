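import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def hairpin():
    """The smallest legal hairpin: GGGAAACCC / (((...)))."""
    from shapebench import read_dotbracket

    return read_dotbracket(">hp\nGGGAAACCC\n(((...)))")


def make_profile(freqs, coverage=1000, transcript_id="t", min_coverage=100):
    """MutationProfile with the requested per-base frequencies (NaN allowed:
    realised as zero coverage)."""
    from shapebench import MutationProfile

    freqs = np.asarray(freqs, dtype=float)
    cov = np.full(len(freqs), coverage, dtype=np.int64)
    counts = np.zeros(len(freqs), dtype=np.int64)
    defined = ~np.isnan(freqs)
    counts[defined] = np.round(freqs[defined] * coverage).astype(np.int64)
    cov[~defined] = 0
    return MutationProfile(transcript_id=transcript_id, sequence="A" * len(freqs),
                           counts=counts, coverage=cov, min_coverage=min_coverage)


@pytest.fixture
def profile_factory():
    return make_profile
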